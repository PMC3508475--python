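"""Per-node metric panel and hub combined-rank scoring.

The regional report lists, per node: degree (binary) or strength (weighted),
clustering coefficient, betweenness centrality normalized to [0, 1], module
membership, regional efficiency (mean inverse distance to every other node),
and participation coefficient. Hubs are scored by the combined rank of
strength, betweenness centrality, and regional efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np
from scipy.stats import rankdata

from .graph_build import ThresholdedGraph
from .metrics_global import ModulePartition, _as_nx, _DISTANCE_KEY

__all__ = [
    "NodalMetrics",
    "node_degree_strength",
    "betweenness_centrality",
    "regional_efficiency",
    "local_efficiency",
    "participation_coefficient",
    "hub_combined_rank",
    "degree_histogram",
    "compute_nodal_metrics",
]


@dataclass
class NodalMetrics:
    """Per-node vectors of the regional report, index-aligned with nodes."""

    degree: list[float]  # degree in binary mode, strength in weighted mode
    clustering: list[float]
    betweenness: list[float]
    module: list[int]
    regional_efficiency: list[float]
    participation: list[float]

    def to_dict(self) -> dict:
        return asdict(self)

    def __len__(self) -> int:
        return len(self.degree)


def _is_weighted(G: nx.Graph) -> bool:
    return any(d.get("weight", 1.0) != 1.0 for _, _, d in G.edges(data=True))


def node_degree_strength(g: ThresholdedGraph | nx.Graph) -> list[float]:
    """Edge count per node (binary) or sum of incident weights (weighted)."""
    G = g.to_networkx() if isinstance(g, ThresholdedGraph) else g
    weight = "weight" if _is_weighted(G) else None
    return [float(d) for _, d in sorted(G.degree(weight=weight))]


def betweenness_centrality(g: ThresholdedGraph | nx.Graph) -> list[float]:
    """Fraction of shortest paths through each node, normalized to [0, 1].

    Weighted graphs route shortest paths along 1/weight distances.
    """
    G = _as_nx(g)
    weight = _DISTANCE_KEY if _is_weighted(G) else None
    bc = nx.betweenness_centrality(G, normalized=True, weight=weight)
    return [float(bc[v]) for v in sorted(G.nodes())]


def regional_efficiency(g: ThresholdedGraph | nx.Graph) -> list[float]:
    """Nodal efficiency: mean over j != i of 1/d(i, j); 0 for unreachable j."""
    G = _as_nx(g)
    n = G.number_of_nodes()
    if n < 2:
        return [0.0] * n
    weight = _DISTANCE_KEY if _is_weighted(G) else None
    eff = np.zeros(n)
    for i, dists in nx.all_pairs_dijkstra_path_length(G, weight=weight):
        eff[i] = sum(1.0 / d for d in dists.values() if d > 0) / (n - 1)
    return eff.tolist()


def local_efficiency(g: ThresholdedGraph | nx.Graph) -> list[float]:
    """Alternative regional measure: global efficiency of each node's
    neighborhood subgraph (node removed). 0 for degree <= 1 nodes."""
    from .metrics_global import global_efficiency

    G = g.to_networkx() if isinstance(g, ThresholdedGraph) else g
    out = []
    for v in sorted(G.nodes()):
        nbrs = list(G.neighbors(v))
        if len(nbrs) < 2:
            out.append(0.0)
            continue
        out.append(global_efficiency(G.subgraph(nbrs)))
    return out


def participation_coefficient(
    g: ThresholdedGraph | nx.Graph, partition: ModulePartition
) -> list[float]:
    """P_i = 1 - sum_s (k_is / k_i)^2 over modules s; 0 when k_i = 0.

    k_is is node i's (binary or weighted) connection to module s. P is 0 for
    provincial nodes whose neighbors all share the node's module and
    approaches 1 for connectors spreading evenly over many modules.
    """
    G = g.to_networkx() if isinstance(g, ThresholdedGraph) else g
    labels = partition.labels
    if len(labels) != G.number_of_nodes():
        raise ValueError("partition does not cover the node set")
    weighted = _is_weighted(G)
    out = []
    for v in sorted(G.nodes()):
        k_i = 0.0
        per_module: dict[int, float] = {}
        for u in G.neighbors(v):
            w = G[v][u].get("weight", 1.0) if weighted else 1.0
            k_i += w
            per_module[labels[u]] = per_module.get(labels[u], 0.0) + w
        if k_i == 0:
            out.append(0.0)
        else:
            out.append(1.0 - sum((k_s / k_i) ** 2 for k_s in per_module.values()))
    return out


def hub_combined_rank(nodal: NodalMetrics) -> list[int]:
    """Order nodes by combined rank of strength, betweenness, regional efficiency.

    Each node gets a descending rank position per metric (average ranks for
    ties); nodes are sorted by ascending rank sum, ties resolved by original
    node order (stable).
    """
    ranks = np.zeros(len(nodal))
    for values in (nodal.degree, nodal.betweenness, nodal.regional_efficiency):
        # descending: highest value gets rank 1
        ranks += rankdata([-v for v in values], method="average")
    return [int(i) for i in np.argsort(ranks, kind="stable")]


def degree_histogram(
    g: ThresholdedGraph | nx.Graph, n_bins: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Bin node degrees; returns (bin_edges, counts), counts summing to n."""
    G = g.to_networkx() if isinstance(g, ThresholdedGraph) else g
    degrees = np.array([d for _, d in G.degree()], dtype=float)
    counts, edges = np.histogram(degrees, bins=n_bins)
    return edges, counts


def compute_nodal_metrics(
    g: ThresholdedGraph | nx.Graph, partition: ModulePartition
) -> NodalMetrics:
    """Assemble the full regional panel for a thresholded graph."""
    G = _as_nx(g)
    weighted = _is_weighted(G)
    cc = nx.clustering(G, weight="weight" if weighted else None)
    return NodalMetrics(
        degree=node_degree_strength(G),
        clustering=[float(cc[v]) for v in sorted(G.nodes())],
        betweenness=betweenness_centrality(G),
        module=list(partition.labels),
        regional_efficiency=regional_efficiency(G),
        participation=participation_coefficient(G, partition),
    )
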