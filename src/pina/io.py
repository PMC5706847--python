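"""Readers and writers for the plain-text interchange formats.

Formats:
  * gene sets         — GMT (id, description, genes...)
  * associations      — two-column TSV (compound_id, disease_id)
  * compound targets  — two-column TSV (compound_id, gene_id)
  * disease genes     — two-column TSV (disease_id, gene_id)
  * disease classes   — two-column TSV (disease_id, class)
  * fingerprints      — TSV compound_id <tab> bitstring, e.g. "0110..."
  * expression / similarity — TSV matrix with header row and index column
  * PPI edges         — TSV gene_a, gene_b [, score [, evidence-csv]]

All loaders order IDs lexicographically so the in-memory objects are
independent of file row order, and every writer round-trips exactly through
its reader.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .types import (
    AssociationMatrix,
    BundleValidationError,
    DatasetBundle,
    ExpressionMatrix,
    GeneSetCollection,
    PPINetwork,
    SimilarityMatrix,
    ValidationReport,
)

logger = logging.getLogger("pina")

__all__ = [
    "read_gene_sets",
    "write_gene_sets",
    "read_association_table",
    "write_association_table",
    "read_pair_table",
    "write_pair_table",
    "read_class_table",
    "write_class_table",
    "read_fingerprints",
    "write_fingerprints",
    "read_matrix",
    "write_matrix",
    "read_expression",
    "write_expression",
    "read_similarity",
    "write_similarity",
    "read_ppi",
    "write_ppi",
    "filter_interactions",
    "validate_bundle",
]


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------- gene sets


def read_gene_sets(path: str | Path, name: str | None = None) -> GeneSetCollection:
    """Read a GMT file: one gene set per line, tab-separated
    ``id <tab> description <tab> gene1 <tab> gene2 ...``.

    Duplicate genes within a line are collapsed; the description is dropped.
    """
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            pid = fields[0]
            if pid in sets:
                raise ParseError(f"{path}:{lineno}: duplicate pathway id {pid!r}")
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise ParseError(f"{path}:{lineno}: pathway {pid!r} has no genes")
            sets[pid] = genes
    if not sets:
        logger.warning("%s: empty gene-set file", path)
    return GeneSetCollection(sets, name=name or path.stem)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for pid in collection.pathway_ids:
            genes = "\t".join(sorted(collection[pid]))
            fh.write(f"{pid}\tna\t{genes}\n")


# ------------------------------------------------------------- long tables


def _read_two_columns(path: str | Path, what: str) -> list[tuple[str, str]]:
    path = Path(path)
    rows: list[tuple[str, str]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(
                    f"{path}:{lineno}: expected >=2 tab-separated columns for {what}"
                )
            rows.append((fields[0], fields[1]))
    return rows


def read_association_table(path: str | Path) -> AssociationMatrix:
    """Read a long-format (compound_id, disease_id) TSV into a binary matrix.

    An optional header row (``compound_id`` / ``compound`` in column 1) is
    skipped.  Duplicate rows collapse to a single association with a warning;
    an empty file is an error.
    """
    rows = _read_two_columns(path, "associations")
    if rows and rows[0][0].lower() in {"compound", "compound_id"}:
        rows = rows[1:]
    if not rows:
        raise ParseError(f"{path}: association table is empty")
    if len(set(rows)) != len(rows):
        logger.warning(
            "%s: %d duplicate association rows collapsed", path, len(rows) - len(set(rows))
        )
    return AssociationMatrix.from_pairs(set(rows))


def write_association_table(assoc: AssociationMatrix, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("compound_id\tdisease_id\n")
        for c, d in assoc.positives():
            fh.write(f"{c}\t{d}\n")


def read_pair_table(path: str | Path) -> dict[str, frozenset[str]]:
    """Read an (entity_id, gene_id) TSV into entity -> gene-set; header optional."""
    rows = _read_two_columns(path, "pairs")
    if rows and rows[0][1].lower() in {"gene", "gene_id"}:
        rows = rows[1:]
    out: dict[str, set[str]] = {}
    for eid, gid in rows:
        out.setdefault(eid, set()).add(gid)
    return {k: frozenset(v) for k, v in out.items()}


def write_pair_table(
    mapping: Mapping[str, Iterable[str]], path: str | Path, header: tuple[str, str]
) -> None:
    with Path(path).open("w") as fh:
        fh.write(f"{header[0]}\t{header[1]}\n")
        for eid in sorted(mapping):
            for gid in sorted(mapping[eid]):
                fh.write(f"{eid}\t{gid}\n")


def read_class_table(path: str | Path) -> dict[str, str]:
    rows = _read_two_columns(path, "classes")
    if rows and rows[0][1].lower() in {"class", "disease_class"}:
        rows = rows[1:]
    out: dict[str, str] = {}
    for did, cls in rows:
        if did in out and out[did] != cls:
            raise ParseError(f"{path}: conflicting class for disease {did!r}")
        out[did] = cls
    return out


def write_class_table(classes: Mapping[str, str], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("disease_id\tclass\n")
        for did in sorted(classes):
            fh.write(f"{did}\t{classes[did]}\n")


def read_fingerprints(path: str | Path) -> dict[str, np.ndarray]:
    """Read compound_id <tab> bitstring rows into uint8 vectors.

    All bitstrings must share one length.
    """
    rows = _read_two_columns(path, "fingerprints")
    if rows and rows[0][1].lower() in {"fingerprint", "bits"}:
        rows = rows[1:]
    out: dict[str, np.ndarray] = {}
    length: int | None = None
    for cid, bits in rows:
        if set(bits) - {"0", "1"}:
            raise ParseError(f"{path}: fingerprint for {cid!r} is not a 0/1 string")
        if length is None:
            length = len(bits)
        elif len(bits) != length:
            raise ParseError(f"{path}: fingerprint length mismatch at {cid!r}")
        out[cid] = np.frombuffer(bits.encode(), dtype=np.uint8) - ord("0")
    return out


def write_fingerprints(fps: Mapping[str, np.ndarray], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("compound_id\tfingerprint\n")
        for cid in sorted(fps):
            bits = "".join("1" if b else "0" for b in fps[cid])
            fh.write(f"{cid}\t{bits}\n")


# ----------------------------------------------------------------- matrices


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a gene x tissue TSV matrix; missing values are rejected, not imputed."""
    df = read_matrix(path)
    if df.isna().any().any():
        raise ParseError(f"{path}: expression matrix has missing values")
    return ExpressionMatrix(list(df.index), list(df.columns), df.to_numpy(float))


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    write_matrix(
        pd.DataFrame(expr.values, index=expr.genes, columns=expr.tissues), path
    )


def read_similarity(path: str | Path) -> SimilarityMatrix:
    df = read_matrix(path)
    if list(df.index) != list(df.columns):
        raise ParseError(f"{path}: similarity matrix rows and columns differ")
    return SimilarityMatrix(list(df.index), df.to_numpy(float))


def write_similarity(sim: SimilarityMatrix, path: str | Path) -> None:
    write_matrix(pd.DataFrame(sim.values, index=sim.ids, columns=sim.ids), path)


# ---------------------------------------------------------------------- PPI


def read_ppi(path: str | Path) -> PPINetwork:
    """Read a PPI edge list: ``gene_a <tab> gene_b [<tab> score [<tab> evidence,csv]]``."""
    path = Path(path)
    edges: set[tuple[str, str]] = set()
    score: dict[tuple[str, str], float] = {}
    evidence: dict[tuple[str, str], frozenset[str]] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: PPI line needs >=2 columns")
            a, b = fields[0], fields[1]
            if a == b:
                logger.warning("%s:%d: self-loop %s dropped", path, lineno, a)
                continue
            edge = (a, b) if a <= b else (b, a)
            edges.add(edge)
            if len(fields) >= 3 and fields[2] != "":
                score[edge] = float(fields[2])
            if len(fields) >= 4 and fields[3] != "":
                evidence[edge] = frozenset(fields[3].split(","))
    return PPINetwork(edges, score, evidence)


def write_ppi(ppi: PPINetwork, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for a, b in sorted(ppi.edges):
            edge = (a, b)
            s = ppi.score.get(edge)
            ev = ppi.evidence.get(edge)
            cols = [a, b]
            if s is not None or ev is not None:
                cols.append("" if s is None else f"{s:g}")
            if ev is not None:
                cols.append(",".join(sorted(ev)))
            fh.write("\t".join(cols) + "\n")


# ------------------------------------------------------------------ filters


def filter_interactions(
    ppi: PPINetwork,
    min_score: float = 700,
    excluded_evidence: Iterable[str] = ("prediction", "textmining"),
) -> PPINetwork:
    """Keep high-confidence interactions.

    Edges with a declared score must reach ``min_score`` (STITCH-style 0..1000
    confidence); edges whose evidence labels intersect ``excluded_evidence``
    are dropped.  Edges without declared score or evidence pass the respective
    filter — the filters act only on declared metadata.
    """
    excluded = frozenset(excluded_evidence)
    keep: set[tuple[str, str]] = set()
    for edge in ppi.edges:
        s = ppi.score.get(edge)
        if s is not None and s < min_score:
            continue
        ev = ppi.evidence.get(edge)
        if ev is not None and ev & excluded:
            continue
        keep.add(edge)
    return PPINetwork(
        keep,
        {e: s for e, s in ppi.score.items() if e in keep},
        {e: v for e, v in ppi.evidence.items() if e in keep},
    )


# --------------------------------------------------------------- validation


def validate_bundle(bundle: DatasetBundle) -> ValidationReport:
    """Cross-check identifiers in a bundle.

    Soft findings (compounds without targets, diseases without genes, pathway
    genes absent from the expression matrix) are reported; association IDs
    that resolve to no record are a hard error.
    """
    comp_ids = {c.compound_id for c in bundle.compounds}
    dis_ids = {d.disease_id for d in bundle.diseases}
    missing_c = sorted(set(bundle.associations.compounds) - comp_ids)
    missing_d = sorted(set(bundle.associations.diseases) - dis_ids)
    if missing_c or missing_d:
        raise BundleValidationError(missing_c, missing_d)

    report = ValidationReport()
    report.compounds_without_targets = sorted(
        c.compound_id for c in bundle.compounds if not c.targets
    )
    report.diseases_without_genes = sorted(
        d.disease_id for d in bundle.diseases if not d.genes
    )
    missing_expr = sorted(
        g for g in bundle.pathways.gene_universe() if g not in bundle.expression
    )
    report.pathway_genes_missing_expression = missing_expr
    for did in dis_ids - set(bundle.disease_sim.ids):
        report.warnings.append(f"disease {did!r} absent from disease similarity")
    if bundle.chem_sim is not None:
        for cid in comp_ids - set(bundle.chem_sim.ids):
            report.warnings.append(f"compound {cid!r} absent from chemical similarity")
    return report
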