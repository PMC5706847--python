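"""Nearest-profile predictors NP_C (chemical) and NP_D (disease).

Guilt by association: structurally similar compounds treat the same disease,
and similar diseases are treated by the same compound.  The default
``single_linkage_max`` aggregation scores a candidate (compound, disease)
pair by the maximum similarity between the query entity and the set of
entities already holding the association; the ``nearest_neighbor`` variant
projects the whole profile of the single most similar neighbour, scaled by
that similarity.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .types import AssociationMatrix, SimilarityMatrix

logger = logging.getLogger("pina")

__all__ = ["NPConfig", "tanimoto", "similarity_from_fingerprints", "np_score", "score_np"]


@dataclass
class NPConfig:
    axis: str = "compound"  # or "disease"
    aggregation: str = "single_linkage_max"  # or "nearest_neighbor"
    exclude_self: bool = True

    def __post_init__(self) -> None:
        if self.axis not in {"compound", "disease"}:
            raise ValueError(f"unknown axis {self.axis!r}")
        if self.aggregation not in {"single_linkage_max", "nearest_neighbor"}:
            raise ValueError(f"unknown aggregation {self.aggregation!r}")


def tanimoto(fp_a: np.ndarray, fp_b: np.ndarray) -> float:
    """Tanimoto (Jaccard) similarity of two equal-length bit vectors."""
    a = np.asarray(fp_a, dtype=bool)
    b = np.asarray(fp_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("fingerprint length mismatch")
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        logger.warning("tanimoto of two all-zero fingerprints defined as 0")
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def similarity_from_fingerprints(fps: dict[str, np.ndarray]) -> SimilarityMatrix:
    """All-pairs Tanimoto similarity over a fingerprint table."""
    ids = sorted(fps)
    mat = np.eye(len(ids))
    for i, a in enumerate(ids):
        for j in range(i + 1, len(ids)):
            mat[i, j] = mat[j, i] = tanimoto(fps[a], fps[ids[j]])
    return SimilarityMatrix(ids, mat)


def np_score(
    query_id: str,
    sim: SimilarityMatrix,
    assoc: AssociationMatrix,
    cfg: NPConfig | None = None,
) -> np.ndarray:
    """Nearest-profile scores for one query compound against every disease.

    axis="compound": sim is compound-compound; score(query, d) is the
    maximum similarity from the query to any *other* compound known (in
    ``assoc``, the training positives) to treat d — 0 when no treater has
    non-zero similarity.

    axis="disease": sim is disease-disease; score(query, d) is the maximum
    similarity from d to any other disease the query compound is known to
    treat.
    """
    cfg = cfg or NPConfig()
    diseases = assoc.diseases
    out = np.zeros(len(diseases))

    if cfg.axis == "compound":
        if query_id not in sim:
            raise KeyError(f"query {query_id!r} absent from similarity matrix")
        candidates = [
            c
            for c in assoc.compounds
            if c in sim and not (cfg.exclude_self and c == query_id)
        ]
        if cfg.aggregation == "nearest_neighbor":
            if candidates:
                best = max(candidates, key=lambda c: (sim.get(query_id, c), c))
                s = sim.get(query_id, best)
                out = s * np.array([assoc.get(best, d) for d in diseases], float)
            return out
        for j, d in enumerate(diseases):
            vals = [sim.get(query_id, c) for c in candidates if assoc.get(c, d)]
            out[j] = max(vals, default=0.0)
        return out

    # axis == "disease": transpose construction over the query compound's diseases
    if query_id not in assoc.compounds:
        return out
    treated = [d for d in diseases if assoc.get(query_id, d) and d in sim]
    for j, d in enumerate(diseases):
        if d not in sim:
            continue
        if cfg.aggregation == "nearest_neighbor":
            others = [
                dd for dd in diseases if dd in sim and not (cfg.exclude_self and dd == d)
            ]
            if not others:
                continue
            best = max(others, key=lambda dd: (sim.get(d, dd), dd))
            out[j] = sim.get(d, best) * assoc.get(query_id, best)
        else:
            vals = [
                sim.get(d, dd)
                for dd in treated
                if not (cfg.exclude_self and dd == d)
            ]
            out[j] = max(vals, default=0.0)
    return out


def score_np(
    sim: SimilarityMatrix,
    train: AssociationMatrix,
    cfg: NPConfig | None = None,
) -> np.ndarray:
    """Full compound x disease nearest-profile score matrix."""
    cfg = cfg or NPConfig()
    rows = []
    for c in train.compounds:
        if cfg.axis == "compound" and c not in sim:
            rows.append(np.zeros(len(train.diseases)))
        else:
            rows.append(np_score(c, sim, train, cfg))
    return np.vstack(rows)
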