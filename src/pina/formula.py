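"""Formula-level indication scoring (multi-compound mixtures, e.g. TCM).

A formula is treated as a set of independent compound components; its score
for a disease is the noisy-OR of the component scores,
P(F,D) = 1 - prod_i (1 - P(C_i,D)) — the probability that at least one
component works, under independence.  Indications are called at a fixed
threshold (default 0.6, the F1-maximising cross-validation threshold).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .evaluation import ScoreMatrix

logger = logging.getLogger("pina")

__all__ = [
    "Formula",
    "FormulaPrediction",
    "formula_score",
    "predict_formula_indications",
    "read_formula_table",
    "write_formula_predictions",
]

DEFAULT_CALL_THRESHOLD = 0.6


@dataclass
class Formula:
    formula_id: str
    components: list[str]

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError(f"formula {self.formula_id!r} has no components")
        seen: list[str] = []
        for c in self.components:
            if c not in seen:
                seen.append(c)
        self.components = seen


@dataclass
class FormulaPrediction:
    formula_id: str
    disease_id: str
    score: float
    called: bool
    supporting: list[tuple[str, float]]  # (compound, component score) desc


def formula_score(component_scores: Sequence[float]) -> float:
    """Noisy-OR combination of component scores: 1 - prod(1 - s_i).

    Empty input scores 0 with a warning (no evidence, not negative
    evidence); any component at 1.0 is absorbing.
    """
    if len(component_scores) == 0:
        logger.warning("formula_score of an empty component list is 0")
        return 0.0
    prod = 1.0
    for s in component_scores:
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"component score {s} outside [0, 1]")
        prod *= 1.0 - s
    return 1.0 - prod


def predict_formula_indications(
    formula: Formula,
    scores: ScoreMatrix,
    threshold: float = DEFAULT_CALL_THRESHOLD,
) -> list[FormulaPrediction]:
    """One prediction per disease, sorted by score descending (ties by id).

    Components missing from the score matrix contribute 0 (missing evidence
    is neutral under noisy-OR); a formula with no component covered at all is
    an error.
    """
    covered = [c for c in formula.components if c in scores.compounds]
    if not covered:
        raise ValueError(
            f"no component of formula {formula.formula_id!r} is covered by the scores"
        )
    dropped = len(formula.components) - len(covered)
    if dropped:
        logger.warning(
            "formula %s: %d unresolvable component(s) dropped", formula.formula_id, dropped
        )
    out: list[FormulaPrediction] = []
    for d in scores.diseases:
        comp = sorted(
            ((c, scores.get(c, d)) for c in covered), key=lambda t: (-t[1], t[0])
        )
        s = formula_score([v for _, v in comp])
        out.append(
            FormulaPrediction(formula.formula_id, d, s, s >= threshold, comp)
        )
    out.sort(key=lambda p: (-p.score, p.disease_id))
    return out


def read_formula_table(path: str | Path) -> list[Formula]:
    """Read (formula_id, compound_id) TSV rows into Formula records."""
    groups: dict[str, list[str]] = {}
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected formula_id<TAB>compound_id")
            if fields[0].lower() in {"formula", "formula_id"}:
                continue
            groups.setdefault(fields[0], []).append(fields[1])
    return [Formula(fid, comps) for fid, comps in sorted(groups.items())]


def write_formula_predictions(
    predictions: Iterable[FormulaPrediction], path: str | Path
) -> None:
    with Path(path).open("w") as fh:
        fh.write("formula_id\tdisease_id\tscore\tcalled\tsupporting\n")
        for p in predictions:
            supp = ",".join(f"{c}:{v:.6g}" for c, v in p.supporting)
            fh.write(
                f"{p.formula_id}\t{p.disease_id}\t{p.score:.10g}\t"
                f"{int(p.called)}\t{supp}\n"
            )
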