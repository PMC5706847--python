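"""Disease-disease network from shared pathways and dense-module detection.

Two diseases are linked when they share at least one associated pathway.
Dense modules are extracted with an MCODE-style procedure: vertices are
weighted by the core-clustering density of their neighbourhood, then modules
grow greedily from high-weight seeds.  Expansion admits a neighbour only if
(a) its weight reaches the vertex-weight-percentage (VWP) cut relative to
the seed and (b) the growing module's edge density stays within the same
fraction of the seed's core-clustering density.  The density guard keeps
loosely bridged dense regions (e.g. two cliques joined by a single edge)
from collapsing into one module.  Modules are annotated with the mean
pairwise disease similarity and per-class membership coverage.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

from .profiles import DiseaseProfile
from .types import SimilarityMatrix

logger = logging.getLogger("pina")

__all__ = [
    "DiseaseNetwork",
    "ModuleRecord",
    "MCODEParams",
    "build_disease_network",
    "mcode_modules",
    "annotate_module",
    "pathway_class_specificity",
]


@dataclass
class DiseaseNetwork:
    nodes: list[str]
    edges: set[tuple[str, str]]
    shared: dict[tuple[str, str], frozenset[str]]

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g


@dataclass
class ModuleRecord:
    module_id: str
    members: frozenset[str]
    avg_similarity: float
    class_coverage: dict[str, float]


@dataclass
class MCODEParams:
    k_core: int = 2
    vwp: float = 0.2
    haircut: bool = True
    fluff: bool = False
    fluff_density: float = 0.1
    min_size: int = 3

    def __post_init__(self) -> None:
        if not 0 <= self.vwp < 1:
            raise ValueError("vwp must be in [0, 1)")
        if self.k_core < 1:
            raise ValueError("k_core must be >= 1")


def build_disease_network(
    profiles: Mapping[str, DiseaseProfile] | Mapping[str, Iterable[str]],
) -> DiseaseNetwork:
    """Link every pair of diseases sharing at least one pathway.

    Accepts either plain disease -> pathway-id sets, or disease profiles (the
    pathways are then the ids appearing in the profile's pairs).
    """
    path_sets: dict[str, frozenset[str]] = {}
    for did, val in profiles.items():
        if isinstance(val, DiseaseProfile):
            pids = {p.pathway_a for p in val.pair_scores} | {
                p.pathway_b for p in val.pair_scores
            }
        else:
            pids = set(val)
        path_sets[did] = frozenset(pids)
    nodes = sorted(path_sets)
    edges: set[tuple[str, str]] = set()
    shared: dict[tuple[str, str], frozenset[str]] = {}
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            common = path_sets[a] & path_sets[b]
            if common:
                edges.add((a, b))
                shared[(a, b)] = common
    return DiseaseNetwork(nodes, edges, shared)


# ------------------------------------------------------------------- MCODE


def _core_weight(g: nx.Graph, v) -> tuple[float, float]:
    """(weight, core-clustering density) of v's closed neighbourhood.

    Weight is k_max * density(highest k-core of N[v]); isolated vertices
    weigh 0.
    """
    nbhd = g.subgraph(list(g.neighbors(v)) + [v])
    if nbhd.number_of_edges() == 0:
        return 0.0, 0.0
    cores = nx.core_number(nbhd)
    kmax = max(cores.values())
    top = nbhd.subgraph([u for u, c in cores.items() if c == kmax])
    dens = nx.density(top)
    return kmax * dens, dens


def mcode_modules(
    network: DiseaseNetwork | nx.Graph, params: MCODEParams | None = None
) -> list[frozenset[str]]:
    """Density-guarded MCODE-style module member sets.

    Deterministic: seeds are taken in (weight desc, id) order; candidates in
    (module-connectivity desc, weight desc, global degree asc, id) order, so
    hub/bridge vertices join only after the dense neighbourhood they belong
    to.  A candidate failing the density guard is permanently retired for
    the current module.  Post-processing keeps the module's
    ``k_core``-core (haircut) and drops modules below ``min_size``.
    """
    params = params or MCODEParams()
    g = network.to_graph() if isinstance(network, DiseaseNetwork) else network
    if g.number_of_edges() == 0:
        return []

    info = {v: _core_weight(g, v) for v in g.nodes}
    weight = {v: w for v, (w, _) in info.items()}
    ccd = {v: d for v, (_, d) in info.items()}
    cut = 1.0 - params.vwp

    visited: set = set()
    raw_modules: list[set] = []
    for seed in sorted(g.nodes, key=lambda v: (-weight[v], v)):
        if seed in visited or weight[seed] <= 0:
            continue
        module = {seed}
        internal_edges = 0
        dead: set = set()
        while True:
            candidates = [
                u
                for m in module
                for u in g.neighbors(m)
                if u not in module
                and u not in visited
                and u not in dead
                and weight[u] >= cut * weight[seed]
            ]
            if not candidates:
                break
            conn = {u: sum(1 for x in g.neighbors(u) if x in module) for u in set(candidates)}
            best = min(
                set(candidates),
                key=lambda u: (-conn[u], -weight[u], g.degree(u), u),
            )
            n = len(module) + 1
            dens = (internal_edges + conn[best]) / (n * (n - 1) / 2)
            if dens >= cut * ccd[seed]:
                module.add(best)
                internal_edges += conn[best]
            else:
                dead.add(best)
        visited |= module
        raw_modules.append(module)

    out: list[frozenset[str]] = []
    for module in raw_modules:
        sub = g.subgraph(module)
        if params.haircut:
            sub = nx.k_core(sub, params.k_core)
        elif nx.k_core(sub, params.k_core).number_of_nodes() == 0:
            continue
        members = set(sub.nodes)
        if params.fluff:
            for m in list(members):
                for u in g.neighbors(m):
                    if u not in members and ccd.get(u, 0.0) >= params.fluff_density:
                        members.add(u)
        if len(members) >= params.min_size:
            out.append(frozenset(members))

    def score(mem: frozenset[str]) -> float:
        return nx.density(g.subgraph(mem)) * len(mem)

    out.sort(key=lambda m: (-score(m), -len(m), min(m)))
    return out


def annotate_module(
    members: Iterable[str],
    disease_sim: SimilarityMatrix,
    classes: Mapping[str, str] | None = None,
    module_id: str = "",
) -> ModuleRecord:
    """Mean pairwise member similarity and per-class membership fractions.

    Members lacking a class label are grouped under ``unknown``; coverage
    fractions sum to 1 across the represented classes.
    """
    members = sorted(set(members))
    if len(members) < 2:
        raise ValueError("module annotation needs >= 2 members")
    missing = [m for m in members if m not in disease_sim]
    if missing:
        raise KeyError(f"module members absent from similarity matrix: {missing}")
    sims = [
        disease_sim.get(a, b)
        for i, a in enumerate(members)
        for b in members[i + 1 :]
    ]
    classes = classes or {}
    counts: dict[str, int] = {}
    for m in members:
        cls = classes.get(m, "unknown")
        counts[cls] = counts.get(cls, 0) + 1
    coverage = {cls: c / len(members) for cls, c in counts.items()}
    return ModuleRecord(module_id, frozenset(members), float(np.mean(sims)), coverage)


def pathway_class_specificity(
    disease_pathways: Mapping[str, Iterable[str]],
    classes: Mapping[str, str],
) -> tuple[dict[str, int], float]:
    """Distinct disease classes per pathway, plus the single-class fraction.

    Returns ({pathway: n_distinct_classes}, fraction of pathways associated
    with exactly one class).  Diseases without a class label count as class
    ``unknown``.
    """
    path_classes: dict[str, set[str]] = {}
    for did, pids in disease_pathways.items():
        cls = classes.get(did, "unknown")
        for pid in pids:
            path_classes.setdefault(pid, set()).add(cls)
    counts = {pid: len(cs) for pid, cs in sorted(path_classes.items())}
    if not counts:
        return {}, 0.0
    frac = sum(1 for n in counts.values() if n == 1) / len(counts)
    return counts, frac
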