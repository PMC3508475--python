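"""Global graph-theory metric panel with null-model small-world attributes.

Computes the global rows of an analyzed-network report: raw and chosen
connection density, characteristic path length L, mean clustering coefficient
C, number of components, global efficiency, modularity Q with its partition,
the small-world attributes gamma = C/C_rand, lambda = L/L_rand and
sigma = gamma/lambda against degree-preserving rewired null networks, and
edge weight / edge Euclidean-length statistics.

Conventions: weighted shortest-path distances are 1/weight; weighted
clustering is the geometric-mean triangle-intensity generalization with
weights scaled by the maximum weight; metrics undefined on the input
(e.g. L on a disconnected graph) are carried as ``None``, never as 0 or inf.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np

from .bundle_io import ConnectivityMatrix, RegionSet
from .graph_build import ThresholdedGraph, raw_density

__all__ = [
    "GlobalMetrics",
    "ModulePartition",
    "characteristic_path_length",
    "mean_clustering",
    "global_efficiency",
    "count_components",
    "modularity_partition",
    "degree_preserving_null",
    "small_world_attributes",
    "edge_weight_stats",
    "euclidean_length_stats",
    "compute_global_metrics",
]

_DISTANCE_KEY = "distance"


@dataclass
class ModulePartition:
    """Module label per node, labels contiguous from 0."""

    labels: tuple[int, ...]

    def __post_init__(self) -> None:
        labels = tuple(int(x) for x in self.labels)
        uniq = sorted(set(labels))
        if uniq != list(range(len(uniq))):
            # relabel to contiguous 0..m-1 preserving first-appearance order
            seen: dict[int, int] = {}
            relabeled = []
            for x in labels:
                if x not in seen:
                    seen[x] = len(seen)
                relabeled.append(seen[x])
            labels = tuple(relabeled)
        self.labels = labels

    @property
    def n_modules(self) -> int:
        return len(set(self.labels)) if self.labels else 0

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class GlobalMetrics:
    """The global metric panel. ``None`` marks an undefined value."""

    raw_density: float
    chosen_density: float
    cpl: float | None
    mcc: float
    n_components: int
    global_efficiency: float
    modularity_q: float | None
    gamma: float | None
    lam: float | None
    sigma: float | None
    raw_edge_weight_mean: float | None
    raw_edge_weight_sd: float | None
    thresholded_edge_weight_mean: float | None
    thresholded_edge_weight_sd: float | None
    raw_euclidean_mean: float | None
    raw_euclidean_sd: float | None
    thresholded_euclidean_mean: float | None
    thresholded_euclidean_sd: float | None

    def to_dict(self) -> dict:
        return asdict(self)


def _as_nx(g: ThresholdedGraph | nx.Graph) -> nx.Graph:
    if isinstance(g, ThresholdedGraph):
        g = g.to_networkx()
    # distances along edges are inverse weights
    for _, _, d in g.edges(data=True):
        w = d.get("weight", 1.0)
        d[_DISTANCE_KEY] = 1.0 / w if w > 0 else np.inf
    return g


def characteristic_path_length(g: ThresholdedGraph | nx.Graph) -> float | None:
    """Mean shortest-path length over all unordered pairs; None if disconnected."""
    G = _as_nx(g)
    if G.number_of_nodes() < 2 or not nx.is_connected(G):
        return None
    return float(nx.average_shortest_path_length(G, weight=_DISTANCE_KEY))


def mean_clustering(g: ThresholdedGraph | nx.Graph) -> float:
    """Node-average clustering coefficient; degree-0/1 nodes contribute 0.

    Weighted graphs use the geometric-mean triangle-intensity form with
    weights scaled by the maximum edge weight.
    """
    G = _as_nx(g)
    if G.number_of_nodes() == 0:
        return 0.0
    weighted = any(d.get("weight", 1.0) != 1.0 for _, _, d in G.edges(data=True))
    cc = nx.clustering(G, weight="weight" if weighted else None)
    return float(np.mean(list(cc.values())))


def global_efficiency(g: ThresholdedGraph | nx.Graph) -> float:
    """Mean of 1/d(i, j) over unordered pairs, 0 for unreachable pairs."""
    G = _as_nx(g)
    n = G.number_of_nodes()
    if n < 2:
        return 0.0
    total = 0.0
    for _, dists in nx.all_pairs_dijkstra_path_length(G, weight=_DISTANCE_KEY):
        for v, d in dists.items():
            if d > 0:
                total += 1.0 / d
    return total / (n * (n - 1))


def count_components(g: ThresholdedGraph | nx.Graph) -> int:
    """Number of connected components; isolated nodes count."""
    G = g.to_networkx() if isinstance(g, ThresholdedGraph) else g
    return nx.number_connected_components(G)


def modularity_partition(
    g: ThresholdedGraph | nx.Graph, seed: int = 0, method: str = "greedy"
) -> tuple[ModulePartition, float | None]:
    """Community partition and its Newman-Girvan modularity Q.

    method 'greedy' is deterministic agglomerative (CNM) modularity
    maximization; 'louvain' is the seeded Louvain heuristic. An edgeless
    graph yields a singleton-module partition with Q undefined (None).
    """
    G = g.to_networkx() if isinstance(g, ThresholdedGraph) else g
    n = G.number_of_nodes()
    if G.number_of_edges() == 0:
        return ModulePartition(tuple(range(n))), None
    if method == "greedy":
        communities = nx.community.greedy_modularity_communities(G, weight="weight")
    elif method == "louvain":
        communities = nx.community.louvain_communities(G, weight="weight", seed=seed)
    else:
        raise ValueError(f"unknown community method {method!r}")
    labels = [0] * n
    for label, nodes in enumerate(communities):
        for v in nodes:
            labels[v] = label
    q = float(nx.community.modularity(G, communities, weight="weight"))
    return ModulePartition(tuple(labels)), q


def degree_preserving_null(
    g: ThresholdedGraph | nx.Graph, swap_factor: int = 10, seed: int = 0
) -> nx.Graph:
    """Degree-preserving rewiring by attempted double-edge swaps.

    Performs swap_factor x |E| attempted swaps on the binarized topology.
    Graphs that admit no legal swap (complete, star) are returned unchanged
    with a warning. The returned graph is unweighted (weight 1 edges).
    """
    G = g.to_networkx() if isinstance(g, ThresholdedGraph) else g.copy()
    null = nx.Graph()
    null.add_nodes_from(G.nodes())
    null.add_edges_from(G.edges())  # binarized topology
    m = null.number_of_edges()
    if swap_factor == 0 or m == 0:
        return null
    try:
        nx.double_edge_swap(null, nswap=swap_factor * m, max_tries=100 * swap_factor * m,
                            seed=seed)
    except nx.NetworkXError:
        warnings.warn("no legal double-edge swap exists; returning the input topology",
                      stacklevel=2)
    except nx.NetworkXAlgorithmError:
        warnings.warn("double-edge swap budget exhausted before requested swap count",
                      stacklevel=2)
    return null


def _reassign_weights_rank_order(original: nx.Graph, null: nx.Graph) -> nx.Graph:
    """Give the null graph the original weight multiset.

    Original weights sorted descending are assigned to the null's edges in
    lexicographic edge order — a deterministic convention for computing
    weighted C and L on rewired topologies.
    """
    orig_edges = set(tuple(sorted(e)) for e in original.edges())
    null_edges = set(tuple(sorted(e)) for e in null.edges())
    if orig_edges == null_edges:  # identity null keeps original weights in place
        return original.copy()
    weights = sorted((d.get("weight", 1.0) for _, _, d in original.edges(data=True)),
                     reverse=True)
    out = nx.Graph()
    out.add_nodes_from(null.nodes())
    for (u, v), w in zip(sorted(tuple(sorted(e)) for e in null.edges()), weights):
        out.add_edge(u, v, weight=w)
    return out


def small_world_attributes(
    g: ThresholdedGraph | nx.Graph,
    n_null_networks: int = 10,
    swap_factor: int = 10,
    seed: int = 0,
    max_retries: int = 10,
) -> tuple[float | None, float | None, float | None]:
    """(gamma, lambda, sigma) against degree-preserving null networks.

    gamma = C / mean(C_null), lambda = L / mean(L_null), sigma = gamma/lambda.
    Nulls are rewired on the binarized topology; for weighted graphs the
    original weight multiset is reassigned to null edges before measuring.
    Disconnected nulls are resampled up to max_retries times each. On a
    disconnected input, gamma is computed but lambda and sigma are None.
    """
    G = g.to_networkx() if isinstance(g, ThresholdedGraph) else g
    if G.number_of_edges() == 0:
        return None, None, None
    c_obs = mean_clustering(G)
    l_obs = characteristic_path_length(G)
    connected = l_obs is not None

    rng = np.random.default_rng(seed)
    c_nulls: list[float] = []
    l_nulls: list[float] = []
    for _ in range(n_null_networks):
        null = None
        for _retry in range(max_retries):
            sub_seed = int(rng.integers(0, 2**31 - 1))
            candidate = degree_preserving_null(G, swap_factor=swap_factor, seed=sub_seed)
            if not connected or nx.is_connected(candidate):
                null = candidate
                break
        if null is None:
            null = candidate  # accept a disconnected null after retries
        null_w = _reassign_weights_rank_order(G, null)
        c_nulls.append(mean_clustering(null_w))
        if connected:
            l_null = characteristic_path_length(null_w)
            if l_null is not None:
                l_nulls.append(l_null)

    c_rand = float(np.mean(c_nulls)) if c_nulls else None
    gamma = c_obs / c_rand if c_rand else None
    lam = None
    if connected and l_nulls:
        l_rand = float(np.mean(l_nulls))
        lam = l_obs / l_rand if l_rand > 0 else None
    sigma = gamma / lam if (gamma is not None and lam is not None and lam != 0) else None
    return gamma, lam, sigma


def _edge_weights(obj: ConnectivityMatrix | ThresholdedGraph) -> np.ndarray:
    if isinstance(obj, ConnectivityMatrix):
        iu = np.triu_indices(obj.n, k=1)
        w = obj.weights[iu]
        return w[w != 0]
    return np.array([w for _, _, w in obj.edges])


def edge_weight_stats(obj: ConnectivityMatrix | ThresholdedGraph) -> tuple[float | None, float | None]:
    """Mean and population sd of edge weights.

    For a raw matrix, over nonzero unordered pairs; for a thresholded graph,
    over retained edges. (None, None) when there are no edges.
    """
    w = _edge_weights(obj)
    if w.size == 0:
        return None, None
    return float(np.mean(w)), float(np.std(w))


def euclidean_length_stats(
    obj: ConnectivityMatrix | ThresholdedGraph, regions: RegionSet | None = None
) -> tuple[float | None, float | None]:
    """Mean and population sd of straight-line edge lengths (mm)."""
    if regions is None:
        regions = obj.regions
    if regions is None:
        raise ValueError("no region coordinates available")
    coords = regions.coords
    if isinstance(obj, ConnectivityMatrix):
        iu, ju = np.triu_indices(obj.n, k=1)
        mask = obj.weights[iu, ju] != 0
        pairs = np.stack([iu[mask], ju[mask]], axis=1)
    else:
        pairs = np.array([(i, j) for i, j, _ in obj.edges], dtype=int).reshape(-1, 2)
    if pairs.shape[0] == 0:
        return None, None
    d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
    return float(np.mean(d)), float(np.std(d))


def compute_global_metrics(
    cm: ConnectivityMatrix,
    g: ThresholdedGraph,
    partition_q: tuple[ModulePartition, float | None] | None = None,
    n_null_networks: int = 10,
    swap_factor: int = 10,
    seed: int = 0,
    community_method: str = "greedy",
) -> tuple[GlobalMetrics, ModulePartition]:
    """Assemble the full global panel for a raw matrix and its thresholded graph."""
    if partition_q is None:
        partition_q = modularity_partition(g, seed=seed, method=community_method)
    partition, q = partition_q
    cpl = characteristic_path_length(g)
    gamma, lam, sigma = small_world_attributes(
        g, n_null_networks=n_null_networks, swap_factor=swap_factor, seed=seed
    )
    rw_mean, rw_sd = edge_weight_stats(cm)
    tw_mean, tw_sd = edge_weight_stats(g)
    re_mean, re_sd = euclidean_length_stats(cm)
    te_mean, te_sd = euclidean_length_stats(g, regions=cm.regions)
    metrics = GlobalMetrics(
        raw_density=raw_density(cm),
        chosen_density=g.chosen_density_percent,
        cpl=cpl,
        mcc=mean_clustering(g),
        n_components=count_components(g),
        global_efficiency=global_efficiency(g),
        modularity_q=q,
        gamma=gamma,
        lam=lam,
        sigma=sigma,
        raw_edge_weight_mean=rw_mean,
        raw_edge_weight_sd=rw_sd,
        thresholded_edge_weight_mean=tw_mean,
        thresholded_edge_weight_sd=tw_sd,
        raw_euclidean_mean=re_mean,
        raw_euclidean_sd=re_sd,
        thresholded_euclidean_mean=te_mean,
        thresholded_euclidean_sd=te_sd,
    )
    return metrics, partition
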