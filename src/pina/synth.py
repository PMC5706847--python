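"""Seeded synthetic dataset generator with planted, recoverable structure.

The generator emulates the statistical assumptions the predictors rely on:

  * diseases arise from a small set of causal pathways; diseases in the same
    cluster share their causal pathways (this is what disease similarity and
    NP_D exploit);
  * compounds treating a disease target genes of its causal pathways —
    either the pathway itself, or a gene-sharing (crosstalk) or PPI-bridged
    (interacting) partner pathway whose tissue activity tracks the causal
    pathway's;
  * compounds treating the same disease cluster share a fingerprint
    archetype (what chemical similarity and NP_C exploit);
  * non-treating compounds target decoy pathways unrelated to any disease.

Every planted fact is recorded in a ground-truth ledger so tests assert
against the plan, never against re-derived outputs.  Noise knobs corrupt
disease genes, targets, fingerprints, labels and expression independently;
``shuffle_labels`` additionally permutes the association rows, destroying
the compound-disease correspondence entirely (a permutation null).
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import io as pio
from .types import (
    AssociationMatrix,
    CompoundRecord,
    DatasetBundle,
    DiseaseRecord,
    ExpressionMatrix,
    GeneSetCollection,
    PPINetwork,
    SimilarityMatrix,
)

__all__ = ["SynthConfig", "generate_bundle", "write_bundle", "load_bundle", "PRESETS"]


@dataclass
class SynthConfig:
    # sizes
    n_pathways: int = 36
    genes_per_pathway: int = 12
    n_diseases: int = 20
    pathways_per_disease: int = 2
    n_compounds: int = 30
    treaters_per_disease: int = 4
    disease_cluster_size: int = 4
    n_tissues: int = 36  # mirrors the 36-normal-tissue correlation setting
    fingerprint_len: int = 128
    # noise
    gene_noise_rate: float = 0.2
    target_noise_rate: float = 0.1
    fingerprint_flip_rate: float = 0.1
    label_flip_rate: float = 0.1
    expression_sd: float = 0.3
    # planted structure
    crosstalk_rate: float = 0.25
    interacting_rate: float = 0.25
    shuffle_labels: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        rates = (
            self.gene_noise_rate,
            self.target_noise_rate,
            self.fingerprint_flip_rate,
            self.label_flip_rate,
            self.crosstalk_rate,
            self.interacting_rate,
        )
        if any(not 0 <= r <= 1 for r in rates):
            raise ValueError("all rates must lie in [0, 1]")
        if self.crosstalk_rate + self.interacting_rate > 1:
            raise ValueError("crosstalk_rate + interacting_rate must be <= 1")
        if self.n_tissues < 3:
            raise ValueError("need at least 3 tissues")
        if min(
            self.n_pathways,
            self.genes_per_pathway,
            self.n_diseases,
            self.pathways_per_disease,
            self.n_compounds,
            self.treaters_per_disease,
            self.disease_cluster_size,
            self.fingerprint_len,
        ) < 1:
            raise ValueError("all counts must be positive")

    # derived layout ------------------------------------------------------
    @property
    def n_clusters(self) -> int:
        return math.ceil(self.n_diseases / self.disease_cluster_size)

    @property
    def n_causal(self) -> int:
        return self.n_clusters * self.pathways_per_disease

    def validate_feasible(self) -> None:
        n_partner_kinds = int(self.crosstalk_rate > 0) + int(self.interacting_rate > 0)
        reserved = self.n_causal * (1 + n_partner_kinds)
        n_treaters = self.n_clusters * self.treaters_per_disease
        n_free = self.n_compounds - n_treaters
        if n_free < 0:
            raise ValueError(
                f"{n_treaters} treaters exceed n_compounds={self.n_compounds}"
            )
        min_decoys = 2 if n_free > 0 else 0
        if reserved + min_decoys > self.n_pathways:
            raise ValueError(
                f"n_pathways={self.n_pathways} too small: {self.n_causal} causal + "
                f"{reserved - self.n_causal} partner + {min_decoys} decoy pathways needed"
            )


def generate_bundle(cfg: SynthConfig) -> tuple[DatasetBundle, dict]:
    """Generate one bundle plus its ground-truth ledger (JSON-serialisable)."""
    cfg.validate_feasible()
    rng = np.random.default_rng(cfg.seed)
    gpp = cfg.genes_per_pathway

    # ---- pathway gene blocks (disjoint) --------------------------------
    pids = [f"PW{i:03d}" for i in range(cfg.n_pathways)]
    blocks = {
        pid: [f"G{i * gpp + j:05d}" for j in range(gpp)] for i, pid in enumerate(pids)
    }
    universe = [g for pid in pids for g in blocks[pid]]

    n_partner_kinds = int(cfg.crosstalk_rate > 0) + int(cfg.interacting_rate > 0)
    causal_pids = pids[: cfg.n_causal]
    cursor = cfg.n_causal
    crosstalk_partner: dict[str, str] = {}
    interacting_partner: dict[str, str] = {}
    if cfg.crosstalk_rate > 0:
        for p in causal_pids:
            crosstalk_partner[p] = pids[cursor]
            cursor += 1
    if cfg.interacting_rate > 0:
        for p in causal_pids:
            interacting_partner[p] = pids[cursor]
            cursor += 1
    decoy_pids = pids[cursor:]

    # pathway sets: own block, plus shared genes for crosstalk partners
    n_overlap = max(1, gpp // 4)
    sets: dict[str, frozenset[str]] = {}
    for pid in pids:
        sets[pid] = frozenset(blocks[pid])
    for p, q in crosstalk_partner.items():
        sets[q] = frozenset(list(sets[q]) + blocks[p][:n_overlap])
    pathways = GeneSetCollection(sets, name="synthetic")

    # ---- PPI: chains within blocks + bridges to interacting partners ----
    edges: set[tuple[str, str]] = set()
    for pid in pids:
        b = blocks[pid]
        edges.update((b[j], b[j + 1]) for j in range(len(b) - 1))
    for p, q in interacting_partner.items():
        for j in range(2):
            edges.add((blocks[p][j], blocks[q][j]))
    ppi = PPINetwork(edges)

    # ---- expression: shared latent tissue factor per causal group -------
    latent_group = {pid: pid for pid in pids}
    for p, q in crosstalk_partner.items():
        latent_group[q] = p
    for p, q in interacting_partner.items():
        latent_group[q] = p
    latents = {
        pid: rng.normal(size=cfg.n_tissues)
        for pid in pids
        if latent_group[pid] == pid
    }
    tissues = [f"T{i:02d}" for i in range(cfg.n_tissues)]
    expr_rows = np.empty((len(universe), cfg.n_tissues))
    gene_index = {g: i for i, g in enumerate(universe)}
    for pid in pids:
        base = latents[latent_group[pid]]
        for g in blocks[pid]:
            offset = rng.normal()
            noise = rng.normal(scale=cfg.expression_sd, size=cfg.n_tissues) \
                if cfg.expression_sd > 0 else 0.0
            expr_rows[gene_index[g]] = base + offset + noise
    expression = ExpressionMatrix(universe, tissues, expr_rows)

    # ---- disease clusters ----------------------------------------------
    dids = [f"D{i:03d}" for i in range(cfg.n_diseases)]
    cluster_of = {d: i // cfg.disease_cluster_size for i, d in enumerate(dids)}
    cluster_causal = {
        ci: causal_pids[ci * cfg.pathways_per_disease : (ci + 1) * cfg.pathways_per_disease]
        for ci in range(cfg.n_clusters)
    }
    n_dg = max(2, math.ceil(0.75 * gpp))
    diseases: list[DiseaseRecord] = []
    for d in dids:
        genes: list[str] = []
        for p in cluster_causal[cluster_of[d]]:
            genes.extend(rng.choice(blocks[p], size=min(n_dg, gpp), replace=False))
        n_noise = round(cfg.gene_noise_rate * len(genes))
        if n_noise:
            idx = rng.choice(len(genes), size=n_noise, replace=False)
            for i in idx:
                genes[i] = universe[rng.integers(len(universe))]
        diseases.append(
            DiseaseRecord(d, frozenset(genes), f"class{cluster_of[d]:02d}")
        )

    # ---- compounds ------------------------------------------------------
    cids = [f"C{i:03d}" for i in range(cfg.n_compounds)]
    n_treaters = cfg.n_clusters * cfg.treaters_per_disease
    role: dict[str, int | None] = {}
    for i, c in enumerate(cids):
        role[c] = i // cfg.treaters_per_disease if i < n_treaters else None

    archetypes = {
        ci: rng.integers(0, 2, size=cfg.fingerprint_len, dtype=np.uint8)
        for ci in range(cfg.n_clusters)
    }
    n_tg = max(2, math.ceil(0.5 * gpp))
    compounds: list[CompoundRecord] = []
    target_route: dict[str, dict[str, str]] = {}
    for c in cids:
        ci = role[c]
        targets: list[str] = []
        if ci is not None:
            routes: dict[str, str] = {}
            for p in cluster_causal[ci]:
                u = rng.random()
                if u < cfg.interacting_rate:
                    src, route = interacting_partner[p], "interacting"
                elif u < cfg.interacting_rate + cfg.crosstalk_rate:
                    src, route = crosstalk_partner[p], "crosstalk"
                else:
                    src, route = p, "common"
                routes[p] = route
                targets.extend(rng.choice(blocks[src], size=n_tg, replace=False))
            target_route[c] = routes
            fp = archetypes[ci].copy()
            if cfg.fingerprint_flip_rate > 0:
                flips = rng.random(cfg.fingerprint_len) < cfg.fingerprint_flip_rate
                fp[flips] ^= 1
        else:
            picks = rng.choice(decoy_pids, size=min(2, len(decoy_pids)), replace=False)
            for p in picks:
                targets.extend(rng.choice(blocks[p], size=n_tg, replace=False))
            fp = rng.integers(0, 2, size=cfg.fingerprint_len, dtype=np.uint8)
        n_noise = round(cfg.target_noise_rate * len(targets))
        if n_noise:
            idx = rng.choice(len(targets), size=n_noise, replace=False)
            for i in idx:
                targets[i] = universe[rng.integers(len(universe))]
        compounds.append(CompoundRecord(c, frozenset(targets), fp))

    # ---- disease similarity: overlap coefficient of causal sets ---------
    dsim = np.zeros((len(dids), len(dids)))
    for i, a in enumerate(dids):
        for j, b in enumerate(dids):
            sa = set(cluster_causal[cluster_of[a]])
            sb = set(cluster_causal[cluster_of[b]])
            dsim[i, j] = len(sa & sb) / min(len(sa), len(sb))
    disease_sim = SimilarityMatrix(dids, dsim)

    # ---- associations: planted links, optional corruption ---------------
    planted = [
        (c, d)
        for c in cids
        if role[c] is not None
        for d in dids
        if cluster_of[d] == role[c]
    ]
    positives = set(planted)
    flipped_out: list[tuple[str, str]] = []
    flipped_in: list[tuple[str, str]] = []
    if cfg.label_flip_rate > 0:
        for pair in planted:
            if rng.random() < cfg.label_flip_rate:
                positives.discard(pair)
                flipped_out.append(pair)
        all_pairs = [(c, d) for c in cids for d in dids]
        while len(flipped_in) < len(flipped_out):
            c, d = all_pairs[rng.integers(len(all_pairs))]
            if (c, d) not in positives:
                positives.add((c, d))
                flipped_in.append((c, d))
    assoc = AssociationMatrix.from_pairs(sorted(positives), compounds=cids, diseases=dids)
    if cfg.shuffle_labels:
        perm = rng.permutation(len(cids))
        assoc = AssociationMatrix(list(assoc.compounds), list(assoc.diseases),
                                  assoc.values[perm])

    bundle = DatasetBundle(
        pathways=pathways,
        compounds=compounds,
        diseases=diseases,
        associations=assoc,
        ppi=ppi,
        expression=expression,
        disease_sim=disease_sim,
    )
    ledger = {
        "config": asdict(cfg),
        "cluster_of_disease": cluster_of,
        "cluster_causal_pathways": {str(k): v for k, v in cluster_causal.items()},
        "compound_cluster": {c: role[c] for c in cids},
        "target_route": target_route,
        "crosstalk_partner": crosstalk_partner,
        "interacting_partner": interacting_partner,
        "decoy_pathways": decoy_pids,
        "planted_positives": sorted(planted),
        "flipped_out": sorted(flipped_out),
        "flipped_in": sorted(flipped_in),
        "final_positives": sorted(positives),
    }
    return bundle, ledger


# ------------------------------------------------------------------- files

_FILES = {
    "pathways": "pathways.gmt",
    "targets": "targets.tsv",
    "disease_genes": "disease_genes.tsv",
    "disease_classes": "disease_classes.tsv",
    "associations": "associations.tsv",
    "ppi": "ppi.tsv",
    "expression": "expression.tsv",
    "disease_sim": "disease_sim.tsv",
    "fingerprints": "fingerprints.tsv",
    "ledger": "ledger.json",
}


def write_bundle(bundle: DatasetBundle, out_dir: str | Path, ledger: dict | None = None) -> None:
    """Write a bundle to a directory in the standard text formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pio.write_gene_sets(bundle.pathways, out / _FILES["pathways"])
    pio.write_pair_table(
        {c.compound_id: c.targets for c in bundle.compounds},
        out / _FILES["targets"],
        ("compound_id", "gene_id"),
    )
    pio.write_pair_table(
        {d.disease_id: d.genes for d in bundle.diseases},
        out / _FILES["disease_genes"],
        ("disease_id", "gene_id"),
    )
    classes = {
        d.disease_id: d.disease_class
        for d in bundle.diseases
        if d.disease_class is not None
    }
    if classes:
        pio.write_class_table(classes, out / _FILES["disease_classes"])
    pio.write_association_table(bundle.associations, out / _FILES["associations"])
    pio.write_ppi(bundle.ppi, out / _FILES["ppi"])
    pio.write_expression(bundle.expression, out / _FILES["expression"])
    pio.write_similarity(bundle.disease_sim, out / _FILES["disease_sim"])
    fps = {
        c.compound_id: c.fingerprint
        for c in bundle.compounds
        if c.fingerprint is not None
    }
    if fps:
        pio.write_fingerprints(fps, out / _FILES["fingerprints"])
    if ledger is not None:
        with (out / _FILES["ledger"]).open("w") as fh:
            json.dump(ledger, fh, indent=1, sort_keys=True)


def load_bundle(in_dir: str | Path) -> DatasetBundle:
    """Read a bundle directory written by :func:`write_bundle`."""
    d = Path(in_dir)
    pathways = pio.read_gene_sets(d / _FILES["pathways"], name="synthetic")
    targets = pio.read_pair_table(d / _FILES["targets"])
    disease_genes = pio.read_pair_table(d / _FILES["disease_genes"])
    classes_path = d / _FILES["disease_classes"]
    classes = pio.read_class_table(classes_path) if classes_path.exists() else {}
    assoc = pio.read_association_table(d / _FILES["associations"])
    fp_path = d / _FILES["fingerprints"]
    fps = pio.read_fingerprints(fp_path) if fp_path.exists() else {}
    compound_ids = sorted(set(targets) | set(fps) | set(assoc.compounds))
    disease_ids = sorted(set(disease_genes) | set(classes) | set(assoc.diseases))
    assoc = AssociationMatrix.from_pairs(
        assoc.positives(), compounds=compound_ids, diseases=disease_ids
    )
    compounds = [
        CompoundRecord(c, targets.get(c, frozenset()), fps.get(c)) for c in compound_ids
    ]
    diseases = [
        DiseaseRecord(x, disease_genes.get(x, frozenset()), classes.get(x))
        for x in disease_ids
    ]
    return DatasetBundle(
        pathways=pathways,
        compounds=compounds,
        diseases=diseases,
        associations=assoc,
        ppi=pio.read_ppi(d / _FILES["ppi"]),
        expression=pio.read_expression(d / _FILES["expression"]),
        disease_sim=pio.read_similarity(d / _FILES["disease_sim"]),
    )


def _tiny(seed: int = 0) -> SynthConfig:
    """Noise-free preset: two disease clusters whose planted structure is
    perfectly recoverable by every predictor."""
    return SynthConfig(
        n_pathways=8,
        genes_per_pathway=12,
        n_diseases=14,
        pathways_per_disease=2,
        n_compounds=20,
        treaters_per_disease=7,
        disease_cluster_size=7,
        n_tissues=36,
        fingerprint_len=128,
        gene_noise_rate=0.0,
        target_noise_rate=0.0,
        fingerprint_flip_rate=0.0,
        label_flip_rate=0.0,
        expression_sd=0.0,
        crosstalk_rate=0.0,
        interacting_rate=0.0,
        seed=seed,
    )


def _default(seed: int = 0) -> SynthConfig:
    """Moderate-noise benchmark preset (the generator defaults)."""
    return SynthConfig(seed=seed)


PRESETS = {"tiny": _tiny, "default": _default}
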