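"""Similarity network from pairwise HSP P-values, force-directed layout, and
cluster extraction.

Each genome pair's best ungapped nucleotide HSP provides a P-value; pairs
significant at the chosen E-value ceiling become edges whose attraction
weight maps P in [1e-200, 1] onto (0, 1]. Groups are read off the network as
connected components of the thresholded graph (the reproducible counterpart
of eyeballing a force-directed embedding); the embedding itself is a
classical Fruchterman-Reingold iteration with linear cooling, kept for
visual inspection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .records import GenomeRecord
from .similarity import local_hsps

logger = logging.getLogger(__name__)

P_FLOOR = 1e-200
ATTRACTION_NORM = 200.0  # -log10(P_FLOOR): maps p in [floor, 1] onto (0, 1]


@dataclass
class AttractionGraph:
    graph: nx.Graph
    e_ceiling: float

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def edge_weight(self, a: str, b: str) -> float:
        return self.graph.edges[a, b]["attraction"]


@dataclass
class LayoutEmbedding:
    coordinates: dict[str, np.ndarray]
    seed: int
    iterations: int
    energy_trace: np.ndarray = field(default=None, repr=False)


@dataclass
class GroupAssignment:
    labels: dict[str, str]
    singletons: set[str]

    def as_list(self, order: list[str]) -> list[str]:
        return [self.labels[n] for n in order]


def _hsp_p_value(a: str, b: str, e_ceiling: float, word_size: int) -> tuple[float, float] | None:
    """(e, p) of the best HSP, or None if nothing reaches the ceiling."""
    hits = local_hsps(a, b, mode="nucleotide", word_size=word_size, e_ceiling=e_ceiling)
    if not hits:
        return None
    return hits[0].e_value, hits[0].p_value


def build_attraction_graph(
    genomes: list[GenomeRecord],
    e_ceiling: float = 1e-5,
    word_size: int = 7,
) -> AttractionGraph:
    """All-against-all nucleotide comparison into a weighted similarity graph.

    For each pair the best HSP P-value is taken (the ungapped engine is
    symmetric in its scoring, so one comparison covers both directions); the
    pair is kept when the E-value is within ``e_ceiling``. Attraction =
    min(1, -log10(p) / 200) with p floored at 1e-200.
    """
    if len(genomes) < 3:
        raise ValueError("need at least 3 genomes to build a similarity network")
    g = nx.Graph()
    g.add_nodes_from(rec.id for rec in genomes)
    for i in range(len(genomes)):
        for j in range(i + 1, len(genomes)):
            res = _hsp_p_value(
                genomes[i].sequence, genomes[j].sequence, e_ceiling, word_size
            )
            if res is None:
                continue
            e, p = res
            p = max(p, P_FLOOR)
            attraction = min(1.0, -np.log10(p) / ATTRACTION_NORM)
            g.add_edge(genomes[i].id, genomes[j].id, p_value=p, attraction=attraction)
    if g.number_of_edges() == 0:
        logger.warning("attraction graph has no edges at e_ceiling=%g", e_ceiling)
    return AttractionGraph(graph=g, e_ceiling=e_ceiling)


def layout_fr(
    graph: AttractionGraph,
    dims: int = 2,
    iterations: int = 10000,
    seed: int = 0,
) -> LayoutEmbedding:
    """Fruchterman-Reingold force-directed embedding.

    Attractive force attraction * d^2 / k along each edge, repulsive force
    k^2 / d between all node pairs, displacement capped by a linearly cooling
    temperature. Initial positions are uniform random from ``seed``; the same
    (graph, seed, iterations, dims) always returns identical coordinates.
    """
    if dims not in (2, 3):
        raise ValueError("dims must be 2 or 3")
    nodes = sorted(graph.graph.nodes)
    n = len(nodes)
    rng = np.random.default_rng(seed)
    pos = rng.random((n, dims))
    if n == 1:
        return LayoutEmbedding(
            coordinates={nodes[0]: pos[0]}, seed=seed, iterations=iterations,
            energy_trace=np.zeros(1),
        )
    idx = {v: i for i, v in enumerate(nodes)}
    w = np.zeros((n, n))
    for a, b, data in graph.graph.edges(data=True):
        w[idx[a], idx[b]] = w[idx[b], idx[a]] = data["attraction"]
    k_opt = np.sqrt(1.0 / n)
    t0 = 0.1
    eps = 1e-9
    trace = np.zeros(iterations)
    for it in range(iterations):
        delta = pos[:, None, :] - pos[None, :, :]
        dist = np.sqrt((delta**2).sum(axis=2))
        np.fill_diagonal(dist, 1.0)
        dist = np.maximum(dist, eps)
        unit = delta / dist[:, :, None]
        rep = k_opt**2 / dist
        np.fill_diagonal(rep, 0.0)
        att = w * dist**2 / k_opt
        force = ((rep - att)[:, :, None] * unit).sum(axis=1)
        fnorm = np.sqrt((force**2).sum(axis=1))
        t = t0 * (1.0 - it / iterations)
        step = np.minimum(fnorm, t) / np.maximum(fnorm, eps)
        pos = pos + force * step[:, None]
        trace[it] = _fr_energy(pos, w, k_opt)
    return LayoutEmbedding(
        coordinates={v: pos[idx[v]].copy() for v in nodes},
        seed=seed,
        iterations=iterations,
        energy_trace=trace,
    )


def _fr_energy(pos: np.ndarray, w: np.ndarray, k_opt: float) -> float:
    """FR potential: the forces above are its negative gradient."""
    delta = pos[:, None, :] - pos[None, :, :]
    dist = np.sqrt((delta**2).sum(axis=2))
    iu = np.triu_indices(len(pos), k=1)
    d = np.maximum(dist[iu], 1e-12)
    attract = (w[iu] * d**3 / (3.0 * k_opt)).sum()
    repel = -(k_opt**2 * np.log(d)).sum()
    return float(attract + repel)


def extract_clusters(graph: AttractionGraph, p_cutoff: float = 1e-5) -> GroupAssignment:
    """Connected components of the subgraph with edge p-value <= cutoff;
    size-1 components are flagged singletons."""
    sub = nx.Graph()
    sub.add_nodes_from(graph.graph.nodes)
    for a, b, data in graph.graph.edges(data=True):
        if data["p_value"] <= p_cutoff:
            sub.add_edge(a, b)
    labels: dict[str, str] = {}
    singletons: set[str] = set()
    components = sorted(nx.connected_components(sub), key=lambda c: sorted(c)[0])
    for c_idx, comp in enumerate(components):
        name = f"cluster{c_idx}"
        for node in comp:
            labels[node] = name
        if len(comp) == 1:
            singletons.add(next(iter(comp)))
    return GroupAssignment(labels=labels, singletons=singletons)
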