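"""Disease pathway-pair profiles and the PIPP compound scorer.

The model: a disease arises from dysfunctional pathways, so a compound that
perturbs those pathways (directly or through cross-talking / interacting
partners) is a candidate treatment.  For every known (compound, disease)
association the pathways enriched in the compound's targets are paired with
the pathways enriched in the disease's genes; a pair survives when

  * the two pathways are the same (``common``), or
  * they share at least one gene (``crosstalk``), or
  * a protein-protein interaction bridges them (``interacting``),

and, for the latter two kinds, their mean-expression activities correlate
significantly across normal tissues (Pearson, two-sided t-test, p below
``correlation_alpha``).  Per disease, each surviving pair is scored by the
fraction of the disease's treating compounds that exhibit it; a query
compound is then scored by a per-type noisy-OR of the profile scores it
matches, combined with type weights alpha.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from itertools import product
from typing import Iterable, Mapping

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import (
    CompoundRecord,
    DatasetBundle,
    DiseaseRecord,
    ExpressionMatrix,
    GeneSetCollection,
    PPINetwork,
    AssociationMatrix,
)

logger = logging.getLogger("pina")

__all__ = [
    "PairType",
    "PathwayPair",
    "DiseaseProfile",
    "PIPPConfig",
    "CorrelationResult",
    "enrich_pathways",
    "pathway_activity",
    "classify_pair",
    "correlation_keep",
    "compound_disease_pairs",
    "PairComputer",
    "build_disease_profiles",
    "pipp_score",
    "all_pair_sets",
    "score_pipp",
]


class PairType(Enum):
    """The three kinds of qualifying pathway pair; ``index`` selects alpha_m."""

    COMMON = 1
    CROSSTALK = 2
    INTERACTING = 3

    @property
    def index(self) -> int:
        return self.value - 1


@dataclass(frozen=True)
class PathwayPair:
    """Canonically ordered pathway pair with its type.

    Identity (equality/hash) is the ordered id pair plus the type, so pair
    sets deduplicate regardless of which enrichment route produced a pair;
    correlation statistics ride along without affecting identity.
    """

    pathway_a: str
    pathway_b: str
    ptype: PairType
    r: float | None = field(default=None, compare=False)
    p_value: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.pathway_a > self.pathway_b:
            raise ValueError("PathwayPair ids must be canonically ordered")
        if (self.ptype is PairType.COMMON) != (self.pathway_a == self.pathway_b):
            raise ValueError("common pairs are exactly the identical-id pairs")

    @classmethod
    def make(
        cls,
        pa: str,
        pb: str,
        ptype: PairType,
        r: float | None = None,
        p_value: float | None = None,
    ) -> "PathwayPair":
        if pa > pb:
            pa, pb = pb, pa
        return cls(pa, pb, ptype, r, p_value)


@dataclass
class DiseaseProfile:
    """Per-disease map from pathway pair to the fraction of treaters showing it."""

    disease_id: str
    pair_scores: dict[PathwayPair, float]
    n_treating: int


@dataclass
class PIPPConfig:
    alpha: tuple[float, float, float] = (0.5, 0.3, 0.2)
    enrichment_fdr: float = 0.05
    correlation_alpha: float = 0.01
    profile_min_score: float = 0.0
    eq2_variant: str = "per_type"  # or "complement"
    positive_r_only: bool = False
    background: frozenset[str] | None = None  # default: union of pathway genes

    def __post_init__(self) -> None:
        if len(self.alpha) != 3 or any(a < 0 for a in self.alpha):
            raise ValueError("alpha must be three non-negative weights")
        if not math.isclose(sum(self.alpha), 1.0, abs_tol=1e-9):
            raise ValueError("alpha must sum to 1")
        if self.eq2_variant not in {"per_type", "complement"}:
            raise ValueError(f"unknown eq2_variant {self.eq2_variant!r}")


# -------------------------------------------------------------- enrichment


def enrich_pathways(
    query_genes: Iterable[str],
    pathways: GeneSetCollection,
    background: Iterable[str] | None = None,
    fdr: float = 0.05,
) -> dict[str, float]:
    """Hypergeometric over-representation of ``query_genes`` in each pathway.

    Genes outside the background are dropped with a warning.  P-values are
    Benjamini-Hochberg adjusted across all pathways in the collection;
    pathways with adjusted p <= ``fdr`` are returned mapped to that adjusted
    p-value.
    """
    bg = frozenset(background) if background is not None else pathways.gene_universe()
    if not bg:
        raise ValueError("empty enrichment background")
    query = frozenset(query_genes)
    dropped = query - bg
    if dropped:
        logger.warning("%d query genes outside background dropped", len(dropped))
    query &= bg
    if not query:
        logger.warning("empty query after background intersection")
        return {}

    pids = pathways.pathway_ids
    m_total = len(bg)
    n_query = len(query)
    pvals = np.empty(len(pids))
    for i, pid in enumerate(pids):
        members = pathways[pid] & bg
        k = len(query & members)
        # P(overlap >= k) drawing n_query genes from m_total with len(members) marked
        pvals[i] = stats.hypergeom.sf(k - 1, m_total, len(members), n_query)
    reject, qvals, _, _ = multipletests(pvals, alpha=fdr, method="fdr_bh")
    return {pid: float(q) for pid, q, rej in zip(pids, qvals, reject) if rej}


# ---------------------------------------------------------------- activity


def pathway_activity(expr: ExpressionMatrix, pathway_genes: Iterable[str]) -> np.ndarray:
    """Per-tissue pathway activity: mean expression of the measured member genes."""
    measured = sorted(g for g in pathway_genes if g in expr)
    if not measured:
        raise ValueError("pathway has no genes measured in the expression matrix")
    return expr.rows(measured).mean(axis=0)


# ------------------------------------------------------------- pair logic


def classify_pair(
    pa: str, pb: str, pathways: GeneSetCollection, ppi: PPINetwork
) -> PairType | None:
    """Type of the (pa, pb) pathway pair, or None if unrelated.

    Precedence: common (same pathway) > crosstalk (shared gene) > interacting
    (bridging PPI edge).
    """
    if pa not in pathways or pb not in pathways:
        missing = [p for p in (pa, pb) if p not in pathways]
        raise KeyError(f"unknown pathway id(s): {missing}")
    if pa == pb:
        return PairType.COMMON
    genes_a, genes_b = pathways[pa], pathways[pb]
    if genes_a & genes_b:
        return PairType.CROSSTALK
    for a, b in ppi.edges:
        if (a in genes_a and b in genes_b) or (a in genes_b and b in genes_a):
            return PairType.INTERACTING
    return None


@dataclass(frozen=True)
class CorrelationResult:
    keep: bool
    r: float | None
    p_value: float | None
    degenerate: bool = False


def correlation_keep(
    act_a: np.ndarray,
    act_b: np.ndarray,
    alpha: float = 0.01,
    positive_only: bool = False,
) -> CorrelationResult:
    """Pearson-correlation gate for crosstalk/interacting pairs.

    Two-sided p-value from the t-distribution with n-2 df; keep iff
    p < ``alpha`` (and r > 0 when ``positive_only``).  Constant activity
    vectors make r undefined: the pair is rejected with a degenerate flag.
    Common pairs never reach this gate.
    """
    a = np.asarray(act_a, float)
    b = np.asarray(act_b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("activity vectors must be 1-D and of equal length")
    if a.size < 3:
        raise ValueError("need at least 3 tissues for the correlation test")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return CorrelationResult(False, None, None, degenerate=True)
    r, p = stats.pearsonr(a, b)
    keep = bool(p < alpha) and (r > 0 or not positive_only)
    return CorrelationResult(keep, float(r), float(p))


class PairComputer:
    """Caches enrichment, activities and per-pathway-pair decisions.

    Enrichment depends only on targets / disease genes (never on the
    association labels), so compound and disease enrichments are computed
    once and reused across cross-validation folds without leaking held-out
    associations.
    """

    def __init__(
        self,
        pathways: GeneSetCollection,
        ppi: PPINetwork,
        expr: ExpressionMatrix,
        cfg: PIPPConfig | None = None,
    ):
        self.pathways = pathways
        self.ppi = ppi
        self.expr = expr
        self.cfg = cfg or PIPPConfig()
        self._background = self.cfg.background or pathways.gene_universe()
        self._enrichment: dict[tuple[str, frozenset[str]], frozenset[str]] = {}
        self._activity: dict[str, np.ndarray] = {}
        self._pair_cache: dict[tuple[str, str], PathwayPair | None] = {}

    def enriched(self, key: str, genes: frozenset[str]) -> frozenset[str]:
        ck = (key, genes)
        if ck not in self._enrichment:
            self._enrichment[ck] = frozenset(
                enrich_pathways(
                    genes, self.pathways, self._background, self.cfg.enrichment_fdr
                )
            )
        return self._enrichment[ck]

    def activity(self, pid: str) -> np.ndarray:
        if pid not in self._activity:
            self._activity[pid] = pathway_activity(self.expr, self.pathways[pid])
        return self._activity[pid]

    def evaluate_pair(self, pa: str, pb: str) -> PathwayPair | None:
        """Classify + correlation-gate one canonical pathway pair (cached)."""
        if pa > pb:
            pa, pb = pb, pa
        key = (pa, pb)
        if key in self._pair_cache:
            return self._pair_cache[key]
        ptype = classify_pair(pa, pb, self.pathways, self.ppi)
        result: PathwayPair | None = None
        if ptype is PairType.COMMON:
            result = PathwayPair.make(pa, pb, ptype)
        elif ptype is not None:
            try:
                corr = correlation_keep(
                    self.activity(pa),
                    self.activity(pb),
                    self.cfg.correlation_alpha,
                    self.cfg.positive_r_only,
                )
            except ValueError:
                corr = CorrelationResult(False, None, None, degenerate=True)
            if corr.keep:
                result = PathwayPair.make(pa, pb, ptype, corr.r, corr.p_value)
        self._pair_cache[key] = result
        return result

    def pairs_for(self, compound: CompoundRecord, disease: DiseaseRecord) -> frozenset[PathwayPair]:
        enr_c = self.enriched("c:" + compound.compound_id, compound.targets)
        enr_d = self.enriched("d:" + disease.disease_id, disease.genes)
        out: set[PathwayPair] = set()
        for pa, pb in product(sorted(enr_c), sorted(enr_d)):
            pair = self.evaluate_pair(pa, pb)
            if pair is not None:
                out.add(pair)
        return frozenset(out)


def compound_disease_pairs(
    compound: CompoundRecord,
    disease: DiseaseRecord,
    pathways: GeneSetCollection,
    ppi: PPINetwork,
    expr: ExpressionMatrix,
    cfg: PIPPConfig | None = None,
) -> frozenset[PathwayPair]:
    """Qualifying pathway pairs linking one compound to one disease.

    Cartesian product of the compound's enriched pathways with the disease's
    enriched pathways, classified and (for crosstalk/interacting) filtered by
    cross-tissue activity correlation; canonical and deduplicated.
    """
    return PairComputer(pathways, ppi, expr, cfg).pairs_for(compound, disease)


# ----------------------------------------------------------------- profile


def build_disease_profiles(
    train: AssociationMatrix,
    pair_sets: Mapping[tuple[str, str], frozenset[PathwayPair]],
    cfg: PIPPConfig | None = None,
) -> dict[str, DiseaseProfile]:
    """Score every pathway pair per disease over that disease's treaters.

    For disease D with n treating compounds in ``train``, the score of pair p
    is (number of treaters whose pair set contains p) / n.  Pairs at or below
    ``profile_min_score`` are dropped; diseases without treaters get no
    profile.
    """
    cfg = cfg or PIPPConfig()
    profiles: dict[str, DiseaseProfile] = {}
    for d in train.diseases:
        treaters = [c for c in train.compounds if train.get(c, d)]
        if not treaters:
            continue
        counts: dict[PathwayPair, int] = {}
        for c in treaters:
            for pair in pair_sets.get((c, d), frozenset()):
                counts[pair] = counts.get(pair, 0) + 1
        n = len(treaters)
        scores = {
            pair: k / n for pair, k in counts.items() if k / n > cfg.profile_min_score
        }
        profiles[d] = DiseaseProfile(d, scores, n)
    return profiles


def pipp_score(
    pairs: Iterable[PathwayPair],
    profile: DiseaseProfile | None,
    cfg: PIPPConfig | None = None,
) -> float:
    """Score a query compound's pair set against one disease profile.

    Default reading: per-type noisy-OR of matched profile scores, combined as
    a weighted sum — score = sum_m alpha_m * (1 - prod_{p in type m}(1 - P(p|D))).
    The ``complement`` variant computes 1 - sum_m alpha_m * prod(1 - P).
    Either way the result lies in [0, 1] and is monotone in every matched
    profile score.
    """
    cfg = cfg or PIPPConfig()
    if profile is None:
        return 0.0
    surv = [1.0, 1.0, 1.0]  # prod(1 - P) per type
    for pair in pairs:
        p = profile.pair_scores.get(pair)
        if p is not None:
            surv[pair.ptype.index] *= 1.0 - p
    if cfg.eq2_variant == "per_type":
        return float(sum(a * (1.0 - s) for a, s in zip(cfg.alpha, surv)))
    return float(1.0 - sum(a * s for a, s in zip(cfg.alpha, surv)))


def all_pair_sets(
    bundle: DatasetBundle,
    computer: PairComputer | None = None,
    cfg: PIPPConfig | None = None,
) -> dict[tuple[str, str], frozenset[PathwayPair]]:
    """Qualifying pair sets for every (compound, disease) combination.

    Independent of the association labels, so one computation serves every
    cross-validation fold.
    """
    cfg = cfg or PIPPConfig()
    computer = computer or PairComputer(bundle.pathways, bundle.ppi, bundle.expression, cfg)
    cmap = bundle.compound_map()
    dmap = bundle.disease_map()
    return {
        (c, d): computer.pairs_for(cmap[c], dmap[d])
        for c in sorted(cmap)
        for d in sorted(dmap)
    }


def score_pipp(
    bundle: DatasetBundle,
    train: AssociationMatrix,
    computer: PairComputer | None = None,
    cfg: PIPPConfig | None = None,
    pair_sets: Mapping[tuple[str, str], frozenset[PathwayPair]] | None = None,
) -> np.ndarray:
    """PIPP score matrix (compound x disease) under ``train`` associations.

    Profiles are built from ``train`` only; every compound in the bundle is
    scored against every disease.  Ordering follows ``train`` ID lists.
    """
    cfg = cfg or PIPPConfig()
    if pair_sets is None:
        pair_sets = all_pair_sets(bundle, computer, cfg)
    profiles = build_disease_profiles(train, pair_sets, cfg)
    scores = np.zeros((len(train.compounds), len(train.diseases)))
    for i, c in enumerate(train.compounds):
        for j, d in enumerate(train.diseases):
            scores[i, j] = pipp_score(pair_sets[(c, d)], profiles.get(d), cfg)
    return scores
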