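"""Function-vs-structure comparison statistics.

Compares two connectivity matrices over the same node set: Pearson
correlation of edge weights (optionally restricted to pairs with an existent
structural connection, i.e. weight > 1 fiber in the structural matrix),
Pearson/Spearman correlation of nodal metric vectors with two-sided
t-distribution p-values, and the Hubert-Arabie adjusted Rand index between
module partitions.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from .bundle_io import ConnectivityMatrix
from .metrics_global import ModulePartition

__all__ = [
    "CrossModalStats",
    "edge_weight_correlation",
    "nodal_metric_correlation",
    "adjusted_rand_index",
    "compute_crossmodal_stats",
]

#: an "existent" structural connection carries strictly more than 1 fiber
EXISTENT_WEIGHT_THRESHOLD = 1.0


@dataclass
class CrossModalStats:
    """Cross-modal comparison panel for two same-sized networks."""

    edge_r_all: float | None
    edge_r_existent: float | None
    nodal_r: dict[str, tuple[float, float] | None]  # metric -> (r, p)
    nodal_rho: dict[str, tuple[float, float] | None]  # metric -> (rho, p)
    ari: float | None

    def to_dict(self) -> dict:
        return asdict(self)


def _upper(cm: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    w = cm.weights if isinstance(cm, ConnectivityMatrix) else np.asarray(cm, dtype=float)
    iu = np.triu_indices(w.shape[0], k=1)
    return w[iu]


def edge_weight_correlation(
    cm_a: ConnectivityMatrix | np.ndarray,
    cm_b: ConnectivityMatrix | np.ndarray,
    mask: str = "all",
) -> float | None:
    """Pearson r of upper-triangle edge weights between two matrices.

    mask='all' uses every unordered pair; mask='existent_in_b' keeps only
    pairs whose weight in cm_b (the structural side) exceeds 1. Returns None
    when fewer than 3 pairs survive or either vector is constant.
    """
    a = _upper(cm_a)
    b = _upper(cm_b)
    if a.shape != b.shape:
        raise ValueError("matrices must share the node count")
    if mask == "existent_in_b":
        keep = b > EXISTENT_WEIGHT_THRESHOLD
        a, b = a[keep], b[keep]
    elif mask != "all":
        raise ValueError(f"unknown mask {mask!r}; use 'all' or 'existent_in_b'")
    if a.size < 3 or np.std(a) == 0 or np.std(b) == 0:
        return None
    return float(stats.pearsonr(a, b).statistic)


def nodal_metric_correlation(
    values_a, values_b, method: str = "pearson"
) -> tuple[float, float] | None:
    """Correlate two nodal metric vectors; returns (r, two-sided p) or None.

    p-values come from the t-distribution with n-2 degrees of freedom;
    Spearman is Pearson on average-ranked data. None for constant vectors or
    fewer than 3 nodes.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    if a.size < 3 or np.std(a) == 0 or np.std(b) == 0:
        return None
    if method == "pearson":
        res = stats.pearsonr(a, b)
    elif method == "spearman":
        res = stats.spearmanr(a, b)
    else:
        raise ValueError(f"unknown method {method!r}; use 'pearson' or 'spearman'")
    return float(res.statistic), float(res.pvalue)


def adjusted_rand_index(part_a: ModulePartition, part_b: ModulePartition) -> float:
    """Hubert-Arabie adjusted Rand index between two module partitions.

    1 for identical partitions (up to relabeling), ~0 for independent ones;
    can be negative for partitions that agree less than chance.
    """
    if len(part_a) != len(part_b):
        raise ValueError(
            f"partitions cover different node sets ({len(part_a)} vs {len(part_b)} nodes)"
        )
    return float(adjusted_rand_score(part_a.labels, part_b.labels))


_NODAL_METRICS = ("degree", "clustering", "betweenness", "regional_efficiency", "participation")


def compute_crossmodal_stats(
    cm_a: ConnectivityMatrix,
    cm_b: ConnectivityMatrix,
    nodal_a=None,
    nodal_b=None,
    partition_a: ModulePartition | None = None,
    partition_b: ModulePartition | None = None,
) -> CrossModalStats:
    """Assemble the full cross-modal panel (cm_b is the structural side)."""
    nodal_r: dict = {}
    nodal_rho: dict = {}
    if nodal_a is not None and nodal_b is not None:
        for m in _NODAL_METRICS:
            va, vb = getattr(nodal_a, m), getattr(nodal_b, m)
            nodal_r[m] = nodal_metric_correlation(va, vb, "pearson")
            nodal_rho[m] = nodal_metric_correlation(va, vb, "spearman")
    ari = None
    if partition_a is not None and partition_b is not None:
        ari = adjusted_rand_index(partition_a, partition_b)
    return CrossModalStats(
        edge_r_all=edge_weight_correlation(cm_a, cm_b, "all"),
        edge_r_existent=edge_weight_correlation(cm_a, cm_b, "existent_in_b"),
        nodal_r=nodal_r,
        nodal_rho=nodal_rho,
        ari=ari,
    )
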