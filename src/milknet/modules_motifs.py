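"""Motif census and dense-module (cluster) detection.

Two complementary views of network mesoscale structure:

* a census of connected induced subgraphs on 3 and 4 nodes, classified
  by isomorphism class (edge signs ignored);
* MCODE-style cluster detection — vertices are weighted by the density of
  the highest k-core of their closed neighborhood, complexes are grown
  greedily from high-weight seeds, then post-processed. Each cluster is
  scored as internal edges divided by member nodes, the module-strength
  convention used in the study design this package reproduces.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import networkx as nx
from sklearn.base import BaseEstimator

__all__ = [
    "MOTIF_CLASSES_3",
    "MOTIF_CLASSES_4",
    "classify_motif",
    "motif_census",
    "ClusterResult",
    "cluster_score",
    "mcode_vertex_weights",
    "mcode_clusters",
    "negative_links_in_cluster",
    "MCODE",
]

MOTIF_CLASSES_3 = ("path_3", "triangle")
MOTIF_CLASSES_4 = ("path_4", "star_4", "cycle_4", "paw", "diamond", "clique_4")


def classify_motif(g: nx.Graph, nodes: Sequence) -> str | None:
    """Isomorphism class of the induced subgraph on 3 or 4 nodes, or None
    if it is disconnected. Classes are fully determined by the induced
    edge count plus, for 3- and 4-edge graphs on 4 nodes, the maximum
    degree."""
    k = len(nodes)
    sub = g.subgraph(nodes)
    m = sub.number_of_edges()
    if k == 3:
        if m < 2:
            return None
        return "triangle" if m == 3 else "path_3"
    if k == 4:
        if m < 3 or not nx.is_connected(sub):
            return None
        if m == 3:
            return "star_4" if max(d for _, d in sub.degree()) == 3 else "path_4"
        if m == 4:
            return "paw" if max(d for _, d in sub.degree()) == 3 else "cycle_4"
        return "diamond" if m == 5 else "clique_4"
    raise ValueError("motif classification supports sizes 3 and 4 only")


def _esu_subgraphs(g: nx.Graph, k: int):
    """Enumerate every connected induced k-node subgraph exactly once
    (the ESU enumeration scheme)."""
    index = {v: i for i, v in enumerate(g.nodes)}

    def extend(sub: set, extension: set, v):
        if len(sub) == k:
            yield tuple(sub)
            return
        ext = set(extension)
        while ext:
            w = ext.pop()
            # exclusive neighborhood of w w.r.t. current subgraph
            excl = {
                u for u in g.neighbors(w)
                if index[u] > index[v] and u not in sub and not any(
                    u in g[s] for s in sub
                )
            }
            yield from extend(sub | {w}, ext | excl, v)

    for v in g.nodes:
        ext = {u for u in g.neighbors(v) if index[u] > index[v]}
        yield from extend({v}, ext, v)


def motif_census(net: nx.Graph, k: int) -> dict[str, int]:
    """Count connected induced subgraphs of ``net`` per isomorphism class.

    ``k`` must be 3 or 4. Edge signs are ignored; counting is induced
    (a triangle is not also counted as three paths).
    """
    if k not in (3, 4):
        raise ValueError(f"motif size must be 3 or 4, got {k}")
    classes = MOTIF_CLASSES_3 if k == 3 else MOTIF_CLASSES_4
    counts = dict.fromkeys(classes, 0)
    for nodes in _esu_subgraphs(net, k):
        cls = classify_motif(net, nodes)
        if cls is not None:
            counts[cls] += 1
    return counts


# ---------------------------------------------------------------------------
# MCODE-style dense-module detection


@dataclass(frozen=True)
class ClusterResult:
    """A detected dense module.

    ``score`` is internal edges / member nodes, recomputable exactly from
    the member set and the parent graph.
    """

    nodes: tuple
    n_nodes: int
    n_edges: int
    score: float
    rank: int = 0

    @classmethod
    def from_nodes(cls, net: nx.Graph, nodes: Iterable, rank: int = 0) -> "ClusterResult":
        nodes = tuple(sorted(nodes, key=str))
        missing = [v for v in nodes if v not in net]
        if missing:
            raise ValueError(f"cluster nodes absent from network: {missing}")
        sub = net.subgraph(nodes)
        if len(nodes) > 1 and not nx.is_connected(sub):
            raise ValueError("cluster's induced subgraph is not connected")
        n, m = sub.number_of_nodes(), sub.number_of_edges()
        return cls(nodes=nodes, n_nodes=n, n_edges=m, score=cluster_score(m, n), rank=rank)


def cluster_score(n_edges: int, n_nodes: int) -> float:
    """Module strength: internal edge count divided by node count."""
    if n_nodes <= 0:
        raise ValueError("cluster must have at least one node")
    return n_edges / n_nodes


def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2 * g.number_of_edges() / (n * (n - 1))


def mcode_vertex_weights(net: nx.Graph, degree_cutoff: int = 2) -> dict:
    """Core-clustering vertex weights.

    For each vertex v with degree >= ``degree_cutoff``: take the closed
    neighborhood, find its highest k-core, and weight v by k times the
    density of that core. Low-degree vertices weigh 0.
    """
    weights = {}
    for v in net.nodes:
        if net.degree(v) < degree_cutoff:
            weights[v] = 0.0
            continue
        nbhd = net.subgraph(set(net.neighbors(v)) | {v})
        core_numbers = nx.core_number(nbhd)
        k_max = max(core_numbers.values())
        core = nbhd.subgraph([u for u, c in core_numbers.items() if c >= k_max])
        weights[v] = k_max * _density(core)
    return weights


def mcode_clusters(
    net: nx.Graph,
    degree_cutoff: int = 2,
    node_score_cutoff: float = 0.2,
    k_core: int = 2,
    max_depth: int = 100,
    haircut: bool = True,
    fluff: bool = False,
    fluff_density_cutoff: float = 0.1,
) -> list[ClusterResult]:
    """Detect densely interconnected regions (clusters) of a network.

    Seeded greedy expansion: unassigned vertices are visited in order of
    decreasing weight; from each seed, neighbors within ``max_depth`` are
    admitted while their weight exceeds
    ``seed_weight * (1 - node_score_cutoff)`` and they are not already in
    another cluster. Post-processing drops complexes that contain no
    ``k_core``-core, and ``haircut`` trims them to their 2-core (removing
    tree-like fringes). ``fluff`` optionally re-adds boundary neighbors
    whose closed-neighborhood density exceeds ``fluff_density_cutoff``.

    Clusters are returned ranked by descending score (ties: larger, then
    lexicographically earlier member sets); the result is deterministic
    for a fixed graph and parameters.
    """
    if net.number_of_nodes() == 0:
        return []
    weights = mcode_vertex_weights(net, degree_cutoff=degree_cutoff)
    order = sorted(net.nodes, key=lambda v: (-weights[v], str(v)))
    assigned: set = set()
    raw_complexes: list[set] = []
    for seed in order:
        if seed in assigned or weights[seed] <= 0:
            continue
        threshold = weights[seed] * (1.0 - node_score_cutoff)
        members = {seed}
        frontier = [(seed, 0)]
        while frontier:
            v, depth = frontier.pop(0)
            if depth >= max_depth:
                continue
            for u in sorted(net.neighbors(v), key=str):
                if u in members or u in assigned:
                    continue
                if weights[u] > threshold:
                    members.add(u)
                    frontier.append((u, depth + 1))
        assigned |= members
        raw_complexes.append(members)

    results: list[ClusterResult] = []
    for members in raw_complexes:
        sub = net.subgraph(members)
        cores = nx.core_number(sub) if sub.number_of_edges() else {v: 0 for v in sub}
        if not cores or max(cores.values()) < k_core:
            continue  # no k_core-core: not a complex
        if haircut:
            members = {v for v, c in cores.items() if c >= 2}
            if not members:
                continue
        if fluff:
            extra = set()
            for v in members:
                for u in net.neighbors(v):
                    if u in members or u in extra:
                        continue
                    if _density(net.subgraph(set(net.neighbors(u)) | {u})) > fluff_density_cutoff:
                        extra.add(u)
            members = members | extra
        sub = net.subgraph(members)
        for comp in nx.connected_components(sub):
            if len(comp) < 2:
                continue
            results.append(ClusterResult.from_nodes(net, comp))

    results.sort(key=lambda c: (-c.score, -c.n_nodes, c.nodes))
    return [
        ClusterResult(nodes=c.nodes, n_nodes=c.n_nodes, n_edges=c.n_edges,
                      score=c.score, rank=i + 1)
        for i, c in enumerate(results)
    ]


def negative_links_in_cluster(net: nx.Graph, cluster: ClusterResult) -> list[tuple]:
    """Negative internal edges of a cluster, as sorted (node_a, node_b) pairs."""
    missing = [v for v in cluster.nodes if v not in net]
    if missing:
        raise ValueError(f"cluster nodes absent from network: {missing}")
    sub = net.subgraph(cluster.nodes)
    pairs = [
        tuple(sorted((a, b), key=str))
        for a, b, attrs in sub.edges(data=True)
        if attrs.get("sign") == "neg"
    ]
    return sorted(pairs, key=lambda p: (str(p[0]), str(p[1])))


class MCODE(BaseEstimator):
    """Dense-module detector with the seeded-growth algorithm above.

    Estimator-style interface: :meth:`fit` takes a ``networkx.Graph`` and
    exposes the ranked clusters as ``clusters_``.

    Parameters mirror :func:`mcode_clusters`; the published defaults are
    used (degree cutoff 2, node score cutoff 0.2, 2-core filter, haircut
    on, fluff off).
    """

    def __init__(
        self,
        degree_cutoff: int = 2,
        node_score_cutoff: float = 0.2,
        k_core: int = 2,
        max_depth: int = 100,
        haircut: bool = True,
        fluff: bool = False,
        fluff_density_cutoff: float = 0.1,
    ):
        self.degree_cutoff = degree_cutoff
        self.node_score_cutoff = node_score_cutoff
        self.k_core = k_core
        self.max_depth = max_depth
        self.haircut = haircut
        self.fluff = fluff
        self.fluff_density_cutoff = fluff_density_cutoff

    def fit(self, G: nx.Graph, y=None):
        self.clusters_ = mcode_clusters(G, **self.get_params())
        self.vertex_weights_ = mcode_vertex_weights(G, degree_cutoff=self.degree_cutoff)
        return self

    def fit_predict(self, G: nx.Graph, y=None) -> list[ClusterResult]:
        return self.fit(G).clusters_
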