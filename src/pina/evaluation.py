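"""Metrics, 5-fold cross-validation and the AUC-weighted ensemble (PINA).

The three base predictors (PIPP, NP_C, NP_D) each produce a compound x
disease score matrix.  The ensemble combines them as P(C,D) = sum_i w_i M_i
with w_i set to each method's ROC AUC (normalised to sum 1 by default).
Cross-validation masks each fold's positive associations before profiles and
nearest-profile lookups are built, scores the held-out positives against all
never-positive pairs, and selects the decision threshold that maximises F1.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .neighbors import NPConfig, score_np, similarity_from_fingerprints
from .profiles import PIPPConfig, PairComputer, all_pair_sets, score_pipp
from .types import AssociationMatrix, DatasetBundle, SimilarityMatrix

logger = logging.getLogger("pina")

__all__ = [
    "ScoreMatrix",
    "EnsembleConfig",
    "CVReport",
    "auc",
    "precision_recall_f1",
    "kfold_split",
    "ensemble_score",
    "select_threshold",
    "compute_method_scores",
    "run_cv",
    "fit_ensemble",
]

BASE_METHODS = ("PIPP", "NP_C", "NP_D")
ENSEMBLE = "PINA"


@dataclass
class ScoreMatrix:
    """Compound x disease real-valued predictions for one method."""

    compounds: list[str]
    diseases: list[str]
    values: np.ndarray
    method: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.compounds), len(self.diseases)):
            raise ValueError("score matrix shape does not match ID lists")
        if not np.isfinite(self.values).all():
            raise ValueError("score matrix has non-finite values")
        self._crow = {c: i for i, c in enumerate(self.compounds)}
        self._dcol = {d: j for j, d in enumerate(self.diseases)}

    def get(self, compound_id: str, disease_id: str) -> float:
        return float(self.values[self._crow[compound_id], self._dcol[disease_id]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.compounds, columns=self.diseases)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, method: str = "") -> "ScoreMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(float), method)


@dataclass
class EnsembleConfig:
    weights: dict[str, float] = field(default_factory=dict)
    normalize: bool = True

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("ensemble weights must be non-negative")

    def effective(self, methods: Iterable[str]) -> dict[str, float]:
        missing = [m for m in methods if m not in self.weights]
        if missing:
            raise KeyError(f"no ensemble weight for method(s) {missing}")
        w = {m: self.weights[m] for m in methods}
        if self.normalize:
            total = sum(w.values())
            if total <= 0:
                raise ValueError("ensemble weights sum to zero")
            w = {m: v / total for m, v in w.items()}
        return w


# ------------------------------------------------------------------ metrics


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC via the Mann-Whitney rank formulation; ties count 1/2."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs at least one positive and one negative")
    ranks = rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def precision_recall_f1(
    scores: np.ndarray, labels: np.ndarray, threshold: float
) -> tuple[float, float, float]:
    """Precision, recall and F1 at ``score >= threshold``.

    With no predicted positives, precision (and F1) are 0 and a warning is
    logged rather than dividing by zero.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    pred = scores >= threshold
    tp = int((pred & labels).sum())
    n_pred = int(pred.sum())
    n_true = int(labels.sum())
    if n_pred == 0:
        logger.warning("no predictions at threshold %g; precision set to 0", threshold)
        precision = 0.0
    else:
        precision = tp / n_pred
    recall = tp / n_true if n_true else 0.0
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return precision, recall, f1


def select_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """F1-maximising threshold over the grid of distinct observed scores.

    Ties are broken toward the smallest maximising threshold (favours
    recall).
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    if labels.sum() == 0:
        raise ValueError("threshold selection needs at least one positive")
    best_t, best_f1 = None, -1.0
    for t in np.unique(scores):
        _, _, f1 = precision_recall_f1(scores, labels, float(t))
        if f1 > best_f1:  # strict: first (smallest) maximiser wins ties
            best_t, best_f1 = float(t), f1
    return best_t


def kfold_split(
    positives: Sequence[tuple[str, str]], k: int, seed: int
) -> dict[tuple[str, str], int]:
    """Seeded uniform shuffle then round-robin fold assignment.

    Deterministic in (positives, k, seed); fold sizes differ by at most one.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(positives):
        raise ValueError(f"k={k} exceeds the {len(positives)} positives")
    order = np.random.default_rng(seed).permutation(len(positives))
    return {tuple(positives[idx]): i % k for i, idx in enumerate(order)}


def ensemble_score(
    method_scores: Mapping[str, float], cfg: EnsembleConfig
) -> float:
    """Weighted combination of per-method scores for one (compound, disease)."""
    w = cfg.effective(method_scores.keys())
    return float(sum(w[m] * method_scores[m] for m in method_scores))


# --------------------------------------------------------------------- CV


def _chem_similarity(bundle: DatasetBundle) -> SimilarityMatrix:
    if bundle.chem_sim is not None:
        return bundle.chem_sim
    fps = {
        c.compound_id: c.fingerprint
        for c in bundle.compounds
        if c.fingerprint is not None
    }
    if not fps:
        raise ValueError("bundle has neither chem_sim nor fingerprints")
    return similarity_from_fingerprints(fps)


def compute_method_scores(
    bundle: DatasetBundle,
    train: AssociationMatrix,
    pair_sets=None,
    pipp_cfg: PIPPConfig | None = None,
    chem_sim: SimilarityMatrix | None = None,
) -> dict[str, np.ndarray]:
    """Score matrices of the three base methods under ``train`` associations."""
    chem = chem_sim or _chem_similarity(bundle)
    return {
        "PIPP": score_pipp(bundle, train, cfg=pipp_cfg, pair_sets=pair_sets),
        "NP_C": score_np(chem, train, NPConfig(axis="compound")),
        "NP_D": score_np(bundle.disease_sim, train, NPConfig(axis="disease")),
    }


@dataclass
class CVReport:
    k: int
    seed: int
    fold_of_positive: dict[tuple[str, str], int]
    per_method: dict[str, dict[str, float]]
    per_fold_auc: dict[str, list[float]]
    ensemble_weights: dict[str, float]
    threshold: float
    pooled_scores: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    pooled_labels: np.ndarray | None = field(default=None, repr=False)

    def to_table(self) -> pd.DataFrame:
        rows = [
            {
                "method": m,
                "AUC": v["auc"],
                "Precision": v["precision"],
                "Recall": v["recall"],
                "F1": v["f1"],
            }
            for m, v in self.per_method.items()
        ]
        return pd.DataFrame(rows).set_index("method")


def run_cv(
    bundle: DatasetBundle,
    k: int = 5,
    seed: int = 0,
    pipp_cfg: PIPPConfig | None = None,
    ensemble_cfg: EnsembleConfig | None = None,
) -> CVReport:
    """K-fold cross-validation of PIPP, NP_C, NP_D and the PINA ensemble.

    Each fold's positives are masked from the association matrix before the
    fold models are built; the masked model then scores the fold's held-out
    positives and every never-positive pair.  Predictions are pooled across
    folds for the headline metrics (per-fold AUC means are reported
    alongside).  Ensemble weights are each method's AUC measured on the
    fold's training associations; the pooled ensemble's F1-maximising
    threshold is reported.
    """
    pipp_cfg = pipp_cfg or PIPPConfig()
    normalize = ensemble_cfg.normalize if ensemble_cfg is not None else True
    assoc = bundle.associations
    positives = assoc.positives()
    fold_of = kfold_split(positives, k, seed)

    chem = _chem_similarity(bundle)
    computer = PairComputer(bundle.pathways, bundle.ppi, bundle.expression, pipp_cfg)
    pair_sets = all_pair_sets(bundle, computer, pipp_cfg)

    never_mask = assoc.values == 0  # negatives: pairs never labelled positive
    pooled: dict[str, list[np.ndarray]] = {m: [] for m in (*BASE_METHODS, ENSEMBLE)}
    pooled_labels: list[np.ndarray] = []
    fold_auc: dict[str, list[float]] = {m: [] for m in (*BASE_METHODS, ENSEMBLE)}
    fold_weights: list[dict[str, float]] = []

    for fold in range(k):
        held = [p for p, f in fold_of.items() if f == fold]
        train = assoc.mask(held)
        if train.n_positive() == 0:
            raise ValueError(
                f"fold {fold} leaves no training positives; use a smaller k"
            )
        scores = compute_method_scores(
            bundle, train, pair_sets=pair_sets, pipp_cfg=pipp_cfg, chem_sim=chem
        )

        # ensemble weights from the fold's training associations only
        train_pos = train.values == 1
        train_eval = train_pos | never_mask  # held-out pairs excluded
        weights = {
            m: auc(scores[m][train_eval], train_pos[train_eval])
            for m in BASE_METHODS
        }
        fold_weights.append(weights)
        cfg = EnsembleConfig(weights, normalize=normalize)
        w = cfg.effective(BASE_METHODS)
        scores[ENSEMBLE] = sum(w[m] * scores[m] for m in BASE_METHODS)

        held_idx = (
            np.array([assoc._crow[c] for c, _ in held]),
            np.array([assoc._dcol[d] for _, d in held]),
        )
        labels = np.concatenate(
            [np.ones(len(held), dtype=bool), np.zeros(int(never_mask.sum()), dtype=bool)]
        )
        pooled_labels.append(labels)
        for m in (*BASE_METHODS, ENSEMBLE):
            vec = np.concatenate([scores[m][held_idx], scores[m][never_mask]])
            pooled[m].append(vec)
            fold_auc[m].append(auc(vec, labels))

    labels_all = np.concatenate(pooled_labels)
    pooled_all = {m: np.concatenate(v) for m, v in pooled.items()}
    per_method: dict[str, dict[str, float]] = {}
    for m in (*BASE_METHODS, ENSEMBLE):
        t = select_threshold(pooled_all[m], labels_all)
        p, r, f1 = precision_recall_f1(pooled_all[m], labels_all, t)
        per_method[m] = {
            "auc": auc(pooled_all[m], labels_all),
            "precision": p,
            "recall": r,
            "f1": f1,
            "threshold": t,
        }
    mean_weights = {
        m: float(np.mean([fw[m] for fw in fold_weights])) for m in BASE_METHODS
    }
    return CVReport(
        k=k,
        seed=seed,
        fold_of_positive=fold_of,
        per_method=per_method,
        per_fold_auc=fold_auc,
        ensemble_weights=mean_weights,
        threshold=per_method[ENSEMBLE]["threshold"],
        pooled_scores=pooled_all,
        pooled_labels=labels_all,
    )


def fit_ensemble(
    bundle: DatasetBundle,
    pipp_cfg: PIPPConfig | None = None,
    normalize: bool = True,
) -> tuple[ScoreMatrix, dict[str, float]]:
    """Deployment model: methods fit on all associations, weights = full AUC.

    Returns the combined PINA score matrix and the (normalised) weights used.
    """
    assoc = bundle.associations
    scores = compute_method_scores(bundle, assoc, pipp_cfg=pipp_cfg)
    labels = assoc.values == 1
    flat_labels = labels.ravel()
    weights = {m: auc(scores[m].ravel(), flat_labels) for m in BASE_METHODS}
    cfg = EnsembleConfig(weights, normalize=normalize)
    w = cfg.effective(BASE_METHODS)
    combined = sum(w[m] * scores[m] for m in BASE_METHODS)
    return (
        ScoreMatrix(list(assoc.compounds), list(assoc.diseases), combined, ENSEMBLE),
        w,
    )
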