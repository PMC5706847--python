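"""Shared domain containers.

Everything downstream (profile construction, nearest-profile scoring,
cross-validation, module detection) operates on the small set of containers
defined here.  IDs are opaque strings throughout: mapping between Entrez /
PubChem / OMIM namespaces is the caller's business.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np

__all__ = [
    "GeneSetCollection",
    "CompoundRecord",
    "DiseaseRecord",
    "AssociationMatrix",
    "PPINetwork",
    "ExpressionMatrix",
    "SimilarityMatrix",
    "DatasetBundle",
    "ValidationReport",
]


def _canonical_edge(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class GeneSetCollection:
    """Named collection of gene sets (pathways).

    ``sets`` maps a pathway id to the frozen set of its member gene ids.
    Every set is non-empty and deduplicated by construction.
    """

    sets: dict[str, frozenset[str]]
    name: str = "pathways"

    def __post_init__(self) -> None:
        clean: dict[str, frozenset[str]] = {}
        for pid, genes in self.sets.items():
            fs = frozenset(genes)
            if not fs:
                raise ValueError(f"pathway {pid!r} has an empty gene set")
            clean[pid] = fs
        self.sets = clean

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, pid: str) -> bool:
        return pid in self.sets

    def __getitem__(self, pid: str) -> frozenset[str]:
        return self.sets[pid]

    @property
    def pathway_ids(self) -> list[str]:
        return sorted(self.sets)

    def gene_universe(self) -> frozenset[str]:
        """Union of all member genes — the default enrichment background."""
        out: set[str] = set()
        for genes in self.sets.values():
            out |= genes
        return frozenset(out)


@dataclass
class CompoundRecord:
    compound_id: str
    targets: frozenset[str] = frozenset()
    fingerprint: np.ndarray | None = None  # uint8 0/1 vector

    def __post_init__(self) -> None:
        self.targets = frozenset(self.targets)
        if self.fingerprint is not None:
            fp = np.asarray(self.fingerprint, dtype=np.uint8)
            if fp.ndim != 1 or not np.isin(fp, (0, 1)).all():
                raise ValueError(
                    f"fingerprint of {self.compound_id!r} must be a 1-D 0/1 vector"
                )
            self.fingerprint = fp


@dataclass
class DiseaseRecord:
    disease_id: str
    genes: frozenset[str] = frozenset()
    disease_class: str | None = None

    def __post_init__(self) -> None:
        self.genes = frozenset(self.genes)


@dataclass
class AssociationMatrix:
    """Binary compound x disease association matrix.

    Row/column ordering is part of the value: loaders sort lexicographically
    so matrices built from the same pairs are identical regardless of file
    row order.
    """

    compounds: list[str]
    diseases: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.compounds), len(self.diseases)):
            raise ValueError("association matrix shape does not match ID lists")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("association values must be 0/1")
        if len(set(self.compounds)) != len(self.compounds):
            raise ValueError("duplicate compound ids")
        if len(set(self.diseases)) != len(self.diseases):
            raise ValueError("duplicate disease ids")
        self._crow = {c: i for i, c in enumerate(self.compounds)}
        self._dcol = {d: j for j, d in enumerate(self.diseases)}

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[str, str]],
        compounds: Iterable[str] | None = None,
        diseases: Iterable[str] | None = None,
    ) -> "AssociationMatrix":
        pairs = list(pairs)
        comp = sorted(set(compounds) if compounds is not None else {c for c, _ in pairs})
        dis = sorted(set(diseases) if diseases is not None else {d for _, d in pairs})
        mat = np.zeros((len(comp), len(dis)), dtype=np.int8)
        ci = {c: i for i, c in enumerate(comp)}
        di = {d: j for j, d in enumerate(dis)}
        for c, d in pairs:
            mat[ci[c], di[d]] = 1
        return cls(comp, dis, mat)

    def get(self, compound_id: str, disease_id: str) -> int:
        return int(self.values[self._crow[compound_id], self._dcol[disease_id]])

    def positives(self) -> list[tuple[str, str]]:
        """Known associations as (compound_id, disease_id), row-major order."""
        rows, cols = np.nonzero(self.values)
        return [(self.compounds[i], self.diseases[j]) for i, j in zip(rows, cols)]

    def mask(self, pairs: Iterable[tuple[str, str]]) -> "AssociationMatrix":
        """Copy with the given positive pairs switched off (CV hold-out)."""
        vals = self.values.copy()
        for c, d in pairs:
            vals[self._crow[c], self._dcol[d]] = 0
        return AssociationMatrix(list(self.compounds), list(self.diseases), vals)

    def n_positive(self) -> int:
        return int(self.values.sum())


@dataclass
class PPINetwork:
    """Undirected protein-protein interaction network.

    Edges are canonical sorted tuples; scores (0..1000 confidence) and
    evidence-type labels are optional per-edge annotations.
    """

    edges: set[tuple[str, str]]
    score: dict[tuple[str, str], float] = field(default_factory=dict)
    evidence: dict[tuple[str, str], frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        canon = set()
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            canon.add(_canonical_edge(a, b))
        self.edges = canon
        self.score = {_canonical_edge(*e): s for e, s in self.score.items()}
        self.evidence = {
            _canonical_edge(*e): frozenset(v) for e, v in self.evidence.items()
        }

    def __len__(self) -> int:
        return len(self.edges)

    def has_edge(self, a: str, b: str) -> bool:
        return _canonical_edge(a, b) in self.edges

    def neighbors_map(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for a, b in self.edges:
            out.setdefault(a, set()).add(b)
            out.setdefault(b, set()).add(a)
        return out


@dataclass
class ExpressionMatrix:
    """Gene x tissue expression values; complete (no NaN) by loader policy."""

    genes: list[str]
    tissues: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.tissues)):
            raise ValueError("expression matrix shape does not match ID lists")
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains missing values")
        self._gidx = {g: i for i, g in enumerate(self.genes)}

    def __contains__(self, gene: str) -> bool:
        return gene in self._gidx

    def row(self, gene: str) -> np.ndarray:
        return self.values[self._gidx[gene]]

    def rows(self, genes: Iterable[str]) -> np.ndarray:
        return self.values[[self._gidx[g] for g in genes]]


@dataclass
class SimilarityMatrix:
    """Symmetric entity similarity in [0,1] with unit diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (len(self.ids), len(self.ids)):
            raise ValueError("similarity matrix shape does not match ID list")
        if not np.allclose(vals, vals.T, atol=1e-9):
            raise ValueError("similarity matrix is not symmetric")
        vals = np.clip(vals, 0.0, 1.0)
        np.fill_diagonal(vals, 1.0)
        self.values = vals
        self._idx = {e: i for i, e in enumerate(self.ids)}

    def __contains__(self, entity: str) -> bool:
        return entity in self._idx

    def get(self, a: str, b: str) -> float:
        return float(self.values[self._idx[a], self._idx[b]])

    def row(self, entity: str) -> np.ndarray:
        return self.values[self._idx[entity]]


@dataclass
class DatasetBundle:
    """All cross-referenced inputs for one experiment."""

    pathways: GeneSetCollection
    compounds: list[CompoundRecord]
    diseases: list[DiseaseRecord]
    associations: AssociationMatrix
    ppi: PPINetwork
    expression: ExpressionMatrix
    disease_sim: SimilarityMatrix
    chem_sim: SimilarityMatrix | None = None

    def compound_map(self) -> dict[str, CompoundRecord]:
        return {c.compound_id: c for c in self.compounds}

    def disease_map(self) -> dict[str, DiseaseRecord]:
        return {d.disease_id: d for d in self.diseases}


@dataclass
class ValidationReport:
    """Soft findings from cross-checking a bundle's identifiers."""

    compounds_without_targets: list[str] = field(default_factory=list)
    diseases_without_genes: list[str] = field(default_factory=list)
    pathway_genes_missing_expression: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def is_clean(self) -> bool:
        return not (
            self.compounds_without_targets
            or self.diseases_without_genes
            or self.pathway_genes_missing_expression
            or self.warnings
        )


class BundleValidationError(ValueError):
    """Raised when association IDs cannot be resolved to records."""

    def __init__(self, missing_compounds: list[str], missing_diseases: list[str]):
        self.missing_compounds = missing_compounds
        self.missing_diseases = missing_diseases
        parts = []
        if missing_compounds:
            parts.append(f"unresolved compound ids: {sorted(missing_compounds)}")
        if missing_diseases:
            parts.append(f"unresolved disease ids: {sorted(missing_diseases)}")
        super().__init__("; ".join(parts))
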