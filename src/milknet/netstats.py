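"""Summary statistics for signed correlation networks.

The panel mirrors what microbial co-occurrence studies report per network:
size, mean degree, local clustering, diameter and mean path length (on the
largest connected component, the only convention that stays finite for the
multi-component graphs these studies produce), community count and
modularity, density, and the positive/negative link ratio (P/N) — the
count of positive-correlation edges over negative ones, which has been
proposed as a dysbiosis signature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, field

import networkx as nx
import pandas as pd

from .io_tables import FeatureTable

__all__ = ["NetworkSummary", "signed_edge_counts", "pn_ratio", "summarize",
           "annotate_hubs_and_mao", "summary_frame"]

#: sentinel returned when a network has positive links but none negative
NO_NEGATIVE_LINKS = math.inf


@dataclass
class NetworkSummary:
    n_nodes: int
    n_edges: int
    average_degree: float
    average_local_clustering: float
    diameter: int
    average_path_length: float
    n_communities: int
    density: float
    modularity: float
    n_positive: int
    n_negative: int
    pn_ratio: float

    def as_dict(self) -> dict:
        return asdict(self)


def signed_edge_counts(net: nx.Graph) -> tuple[int, int]:
    """(positive, negative) edge counts; edges lacking a sign are an error."""
    pos = neg = 0
    for _, _, attrs in net.edges(data=True):
        sign = attrs.get("sign")
        if sign == "pos":
            pos += 1
        elif sign == "neg":
            neg += 1
        else:
            raise ValueError(f"edge without a pos/neg sign attribute: {attrs!r}")
    return pos, neg


def pn_ratio(net: nx.Graph) -> float:
    """Positive/negative link ratio.

    Returns ``inf`` (the :data:`NO_NEGATIVE_LINKS` sentinel) when there are
    positive links but no negative ones, and ``nan`` for an edgeless
    network, where the ratio is undefined; never raises a division error.
    """
    pos, neg = signed_edge_counts(net)
    if neg == 0:
        return NO_NEGATIVE_LINKS if pos > 0 else math.nan
    return pos / neg


def _communities(net: nx.Graph, method: str, seed: int):
    if method == "greedy":
        return list(nx.community.greedy_modularity_communities(net))
    if method == "louvain":
        return list(nx.community.louvain_communities(net, seed=seed))
    raise ValueError(f"unknown community_method {method!r}; use 'greedy' or 'louvain'")


def summarize(net: nx.Graph, community_method: str = "greedy", seed: int = 0) -> NetworkSummary:
    """Compute the full summary panel for a signed network.

    All metrics are on the unweighted, undirected graph. Local clustering
    uses the 0-for-degree<2 convention; diameter and average path length
    are evaluated on the largest connected component. Community structure
    comes from greedy modularity maximization by default (deterministic);
    ``louvain`` with a fixed seed is available.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("cannot summarize an empty network")
    n, m = net.number_of_nodes(), net.number_of_edges()
    pos, neg = signed_edge_counts(net)
    largest = net.subgraph(max(nx.connected_components(net), key=len))
    if largest.number_of_nodes() > 1:
        diameter = nx.diameter(largest)
        apl = nx.average_shortest_path_length(largest)
    else:
        diameter, apl = 0, 0.0
    if m > 0:
        comms = _communities(net, community_method, seed)
        modularity = nx.community.modularity(net, comms)
    else:
        comms = [ {v} for v in net.nodes ]
        modularity = math.nan
    return NetworkSummary(
        n_nodes=n,
        n_edges=m,
        average_degree=2 * m / n,
        average_local_clustering=nx.average_clustering(net),
        diameter=diameter,
        average_path_length=apl,
        n_communities=len(comms),
        density=nx.density(net),
        modularity=modularity,
        n_positive=pos,
        n_negative=neg,
        pn_ratio=pn_ratio(net) if m else math.nan,
    )


def _top_k_with_ties(scores: dict, k: int) -> set:
    """Members whose score reaches the k-th largest value; ties at the
    boundary are all included rather than arbitrarily dropped."""
    if not scores or k <= 0:
        return set()
    ranked = sorted(scores.values(), reverse=True)
    cutoff = ranked[min(k, len(ranked)) - 1]
    return {node for node, s in scores.items() if s >= cutoff}


def annotate_hubs_and_mao(
    net: nx.Graph, otu_table: FeatureTable | None = None, k: int = 3
) -> dict[str, dict[str, bool]]:
    """Flag hubs (top-k degree) and most-abundant OTUs (top-k total reads).

    Abundance comes from ``otu_table`` when given, else from each node's
    ``total_abundance`` attribute. Annotations are stored as boolean node
    attributes ``hub``, ``mao``, ``dual_role`` and also returned.
    """
    degrees = dict(net.degree())
    hubs = _top_k_with_ties(degrees, k)
    if otu_table is not None:
        totals = otu_table.feature_totals()
        abund = {v: float(totals[v]) for v in net.nodes if v in totals.index}
    else:
        abund = {
            v: float(d["total_abundance"])
            for v, d in net.nodes(data=True)
            if "total_abundance" in d
        }
    maos = _top_k_with_ties(abund, k)
    out = {}
    for v in net.nodes:
        ann = {"hub": v in hubs, "mao": v in maos, "dual_role": v in hubs and v in maos}
        net.nodes[v].update(ann)
        out[v] = ann
    return out


def summary_frame(summaries: dict[str, NetworkSummary]) -> pd.DataFrame:
    """One row per network, columns in the conventional reporting order."""
    df = pd.DataFrame({name: s.as_dict() for name, s in summaries.items()}).T
    df.index.name = "network"
    return df
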