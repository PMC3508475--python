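"""Edge-density thresholding, weighting schemes, and virtual lesions.

A raw connectivity matrix becomes an analyzable graph in two steps: keep the
k strongest edges, k set by the requested edge density (percent of all
possible unordered node pairs), then either binarize the retained edges or
keep their raw weights. Lesioning zeroes all connections of selected nodes
on the raw matrix; the lesioned matrix is then re-thresholded like any other.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np

from .bundle_io import ConnectivityMatrix, RegionSet

__all__ = [
    "AnalysisConfig",
    "ThresholdedGraph",
    "raw_density",
    "threshold_by_density",
    "apply_weighting",
    "build_graph",
    "lesion",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Analysis options, mirroring the interactive defaults.

    weighting: 'binary' sets all retained edges to 1; 'weighted' keeps raw
        weights (all retained weights must then be positive, since distances
        are 1/weight).
    density_percent: integer percent of possible edges to retain, in (0, 100].
    orientation: which anatomical plane a plotting layer would project
        ('axial', 'sagittal', 'coronal'); has no effect on any metric.
    n_null_networks / swap_factor: how many degree-preserving rewired nulls
        to average for gamma/lambda, and how many attempted double-edge swaps
        per edge each null uses.
    seed: single seed from which all randomness (null rewiring, community
        tie-breaks) is derived.
    """

    weighting: str = "binary"
    density_percent: int = 20
    orientation: str = "axial"
    n_null_networks: int = 10
    swap_factor: int = 10
    seed: int = 0
    community_method: str = "greedy"  # 'greedy' (CNM) or 'louvain'

    def __post_init__(self) -> None:
        if self.weighting not in ("binary", "weighted"):
            raise ValueError(f"weighting must be 'binary' or 'weighted', got {self.weighting!r}")
        if not (0 < self.density_percent <= 100):
            raise ValueError(f"density_percent must be in (0, 100], got {self.density_percent}")
        if self.orientation not in ("axial", "sagittal", "coronal"):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.n_null_networks < 1:
            raise ValueError("n_null_networks must be >= 1")
        if self.swap_factor < 0:
            raise ValueError("swap_factor must be >= 0")
        if self.community_method not in ("greedy", "louvain"):
            raise ValueError(f"unknown community_method {self.community_method!r}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ThresholdedGraph:
    """A graph after density thresholding and (optionally) weighting.

    Edges are (i, j, weight) with i < j and no self-loops. achieved_density
    is the fraction of possible unordered pairs actually retained — the
    "chosen density" of the report; it can fall below the requested density
    when the raw matrix has too few nonzero entries.
    """

    edges: list[tuple[int, int, float]]
    n: int
    achieved_density: float
    weighting: str = "raw"  # raw (pre-weighting), binary, or weighted
    regions: RegionSet | None = None

    @property
    def chosen_density_percent(self) -> float:
        return 100.0 * self.achieved_density

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_weighted_edges_from(self.edges)
        return g

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n, self.n))
        for i, j, w in self.edges:
            a[i, j] = a[j, i] = w
        return a


def _possible_pairs(n: int) -> int:
    return n * (n - 1) // 2


def raw_density(cm: ConnectivityMatrix) -> float:
    """Percent of unordered node pairs with a nonzero raw weight."""
    n = cm.n
    iu = np.triu_indices(n, k=1)
    nonzero = int(np.count_nonzero(cm.weights[iu]))
    return 100.0 * nonzero / _possible_pairs(n)


def threshold_by_density(cm: ConnectivityMatrix, density_percent: int | float) -> ThresholdedGraph:
    """Retain the k strongest edges, k = floor(density/100 * n(n-1)/2).

    Edges are ranked by signed weight descending (negative functional
    correlations are the weakest candidates), ties broken by lexicographic
    (i, j) so results are bit-reproducible. Zero-weight pairs are never
    eligible even when k exceeds the nonzero count; in that case all nonzero
    edges are kept and the smaller achieved density is recorded.
    """
    if not (0 < density_percent <= 100):
        raise ValueError(f"density_percent must be in (0, 100], got {density_percent}")
    n = cm.n
    possible = _possible_pairs(n)
    k = int(np.floor(density_percent / 100.0 * possible))
    iu, ju = np.triu_indices(n, k=1)
    w = cm.weights[iu, ju]
    nz = w != 0
    iu, ju, w = iu[nz], ju[nz], w[nz]
    # stable sort on (-w, i, j): lexsort keys are listed minor-to-major
    order = np.lexsort((ju, iu, -w))[:k]
    edges = sorted((int(iu[idx]), int(ju[idx]), float(w[idx])) for idx in order)
    return ThresholdedGraph(
        edges=edges,
        n=n,
        achieved_density=len(edges) / possible,
        weighting="raw",
        regions=cm.regions,
    )


def apply_weighting(g: ThresholdedGraph, weighting: str) -> ThresholdedGraph:
    """Binarize retained edges, or keep raw weights (which must be positive)."""
    if weighting == "binary":
        edges = [(i, j, 1.0) for i, j, _ in g.edges]
    elif weighting == "weighted":
        bad = [(i, j, w) for i, j, w in g.edges if w <= 0]
        if bad:
            i, j, w = bad[0]
            raise ValueError(
                f"weighted analysis retained a non-positive weight {w:g} on edge ({i}, {j}); "
                "distances 1/weight are undefined — lower the density or use binary weighting"
            )
        edges = list(g.edges)
    else:
        raise ValueError(f"weighting must be 'binary' or 'weighted', got {weighting!r}")
    return ThresholdedGraph(
        edges=edges,
        n=g.n,
        achieved_density=g.achieved_density,
        weighting=weighting,
        regions=g.regions,
    )


def build_graph(cm: ConnectivityMatrix, config: AnalysisConfig) -> ThresholdedGraph:
    """threshold_by_density followed by apply_weighting, per config."""
    return apply_weighting(threshold_by_density(cm, config.density_percent), config.weighting)


def lesion(cm: ConnectivityMatrix, node_indices) -> ConnectivityMatrix:
    """Zero all connections of the selected nodes ("virtual lesion").

    Returns a copy with the rows and columns of every selected node zeroed;
    node count and region set are unchanged, so the lesioned nodes remain in
    the network as isolates.
    """
    nodes = sorted(set(int(i) for i in node_indices))
    n = cm.n
    for i in nodes:
        if not (0 <= i < n):
            raise ValueError(f"lesion node index {i} out of range for n={n}")
    w = cm.weights.copy()
    w[nodes, :] = 0.0
    w[:, nodes] = 0.0
    return ConnectivityMatrix(w, cm.regions, copy.deepcopy(cm.metadata))
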