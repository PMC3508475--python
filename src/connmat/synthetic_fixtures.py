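"""Synthetic connectivity bundles with controlled, known structure.

Generates matrices that emulate the two families of real connectomes the
analysis targets: functional-like matrices (correlation weights in [-1, 1],
denser within planted modules than between) and structural-like matrices
(sparse, fiber-count-like weights spanning 10^0 to 10^4). Also builds
canonical reference graphs (cliques, paths, stars, ring lattices, barbells)
and coupled functional/structural pairs whose edge weights correlate at a
requested level. The planted truth (partition, target correlation) is
recorded in the metadata so tests never re-derive it.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .bundle_io import ConnectivityMatrix, NetworkMetadata, RegionSet

__all__ = ["FixtureSpec", "make_modular_bundle", "make_reference_graph", "make_coupled_pair"]

MODULE_CENTROID_SPACING_MM = 60.0  # separated module centroids
COORD_JITTER_MM = 8.0  # isotropic within-module scatter


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a planted-modular synthetic network.

    n_nodes, n_modules: network size and number of planted modules.
    p_within / p_between: edge probabilities inside vs. across modules
        (p_within > p_between plants recoverable structure).
    weight_model: 'functional' draws weights from truncated normals on
        [-1, 1] with a higher within-module mean; 'structural' draws
        log-uniform fiber-count-like weights over 10^0-10^4 on existing edges.
    r_target: for coupled pairs, the desired edge-weight correlation.
    seed: deterministic generator seed.
    """

    n_nodes: int = 40
    n_modules: int = 4
    p_within: float = 0.9
    p_between: float = 0.05
    weight_model: str = "functional"
    r_target: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_modules > self.n_nodes:
            raise ValueError(
                f"n_modules ({self.n_modules}) cannot exceed n_nodes ({self.n_nodes})"
            )
        if self.n_modules < 1 or self.n_nodes < 2:
            raise ValueError("need n_nodes >= 2 and n_modules >= 1")
        for p in (self.p_within, self.p_between):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"edge probability {p} outside [0, 1]")
        if self.weight_model not in ("functional", "structural"):
            raise ValueError(f"unknown weight_model {self.weight_model!r}")
        if not (-1.0 < self.r_target < 1.0):
            raise ValueError(f"r_target must lie in (-1, 1), got {self.r_target}")


def _planted_labels(n_nodes: int, n_modules: int) -> np.ndarray:
    return np.arange(n_nodes) % n_modules


def _module_coords(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Place module centroids on a loose 3D grid, jitter nodes around them."""
    n_modules = int(labels.max()) + 1
    centroids = np.zeros((n_modules, 3))
    for m in range(n_modules):
        centroids[m] = [
            MODULE_CENTROID_SPACING_MM * (m % 3 - 1),
            MODULE_CENTROID_SPACING_MM * ((m // 3) % 3 - 1),
            MODULE_CENTROID_SPACING_MM * (m // 9),
        ]
    return centroids[labels] + rng.normal(0.0, COORD_JITTER_MM, size=(len(labels), 3))


def _region_set_for(n: int, coords: np.ndarray) -> RegionSet:
    names = tuple(f"Region {i:03d}" for i in range(n))
    abbrevs = tuple(f"R{i:03d}" for i in range(n))
    return RegionSet(names, abbrevs, coords)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Rejection-sampled normal truncated to [-1, 1]."""
    out = rng.normal(mean, sd, size)
    bad = (out < -1) | (out > 1)
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < -1) | (out > 1)
    return out


def _fill_weights(
    mask_within: np.ndarray,
    mask_between: np.ndarray,
    weight_model: str,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Weights for within- and between-module edges under the chosen model."""
    n_w, n_b = int(mask_within.sum()), int(mask_between.sum())
    if weight_model == "functional":
        # correlation-like weights; within-module mean clearly above between
        w_within = _truncated_normal(rng, 0.6, 0.15, n_w)
        w_between = _truncated_normal(rng, 0.1, 0.15, n_b)
    else:
        # fiber-count-like: log-uniform over four orders of magnitude,
        # within-module connections biased toward the strong end
        w_within = 10.0 ** rng.uniform(1.0, 4.0, n_w)
        w_between = 10.0 ** rng.uniform(0.0, 2.5, n_b)
    return w_within, w_between


def make_modular_bundle(
    spec: FixtureSpec,
) -> tuple[ConnectivityMatrix, RegionSet, NetworkMetadata]:
    """Symmetric matrix with a planted modular partition, plus regions/metadata.

    The planted labels are stored in ``metadata.preprocessing_flags
    ["planted_partition"]``. Deterministic per spec.seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_nodes
    labels = _planted_labels(n, spec.n_modules)
    same = labels[:, None] == labels[None, :]
    iu, ju = np.triu_indices(n, k=1)
    within = same[iu, ju]
    p_edge = np.where(within, spec.p_within, spec.p_between)
    edge_on = rng.random(len(iu)) < p_edge

    w = np.zeros((n, n))
    w_within, w_between = _fill_weights(
        edge_on & within, edge_on & ~within, spec.weight_model, rng
    )
    vals = np.zeros(len(iu))
    vals[edge_on & within] = w_within
    vals[edge_on & ~within] = w_between
    w[iu, ju] = vals
    w += w.T

    coords = _module_coords(labels, rng)
    regions = _region_set_for(n, coords)
    metadata = NetworkMetadata(
        study_name="synthetic_modular",
        network_name=f"modular_n{n}_m{spec.n_modules}_seed{spec.seed}",
        modality="fMRI" if spec.weight_model == "functional" else "dwMRI/DTI",
        preprocessing_flags={
            "synthetic": True,
            "planted_partition": labels.tolist(),
            "p_within": spec.p_within,
            "p_between": spec.p_between,
            "weight_model": spec.weight_model,
        },
    )
    return ConnectivityMatrix(w, regions, metadata), regions, metadata


_REFERENCE_BUILDERS = {
    "complete": (2, lambda n, k: nx.complete_graph(n)),
    "path": (2, lambda n, k: nx.path_graph(n)),
    "star": (3, lambda n, k: nx.star_graph(n - 1)),
    "ring_lattice": (5, lambda n, k: nx.watts_strogatz_graph(n, k, p=0.0)),
    "two_cliques": (4, lambda n, k: nx.disjoint_union(
        nx.complete_graph(n // 2), nx.complete_graph(n - n // 2))),
    "barbell": (7, lambda n, k: _barbell_via_bridge(n)),
}


def _barbell_via_bridge(n: int) -> nx.Graph:
    """Two cliques joined through a single shared bridge node.

    For n = 7 this is two triangles connected through node 3: lesioning the
    bridge splits the graph into three components.
    """
    half = (n - 1) // 2
    g = nx.complete_graph(half + 1)  # clique 0..half-1 plus bridge node `half`
    other = nx.complete_graph(n - half)  # bridge plus clique half+1..n-1
    mapping = {0: half}
    mapping.update({i: half + i for i in range(1, n - half)})
    g.add_edges_from((mapping[u], mapping[v]) for u, v in other.edges())
    return g


def make_reference_graph(kind: str, n: int, k: int = 4) -> ConnectivityMatrix:
    """Canonical binary graph as a unit-weight matrix with grid coordinates.

    kind in {complete, path, star, ring_lattice, two_cliques, barbell};
    ring_lattice takes the even neighbor count k (default 4).
    """
    if kind not in _REFERENCE_BUILDERS:
        raise ValueError(f"unknown reference kind {kind!r}; options: {sorted(_REFERENCE_BUILDERS)}")
    n_min, builder = _REFERENCE_BUILDERS[kind]
    if n < n_min:
        raise ValueError(f"{kind} graph needs n >= {n_min}, got {n}")
    g = builder(n, k)
    w = nx.to_numpy_array(g, nodelist=range(n))
    coords = np.array([[10.0 * (i % 10), 10.0 * (i // 10), 0.0] for i in range(n)])
    regions = _region_set_for(n, coords)
    metadata = NetworkMetadata(
        study_name="synthetic_reference",
        network_name=f"{kind}_n{n}",
        modality="other",
        preprocessing_flags={"synthetic": True, "kind": kind},
    )
    return ConnectivityMatrix(w, regions, metadata)


def make_coupled_pair(
    spec: FixtureSpec,
) -> tuple[ConnectivityMatrix, ConnectivityMatrix]:
    """A functional/structural matrix pair with correlated edge weights.

    Both matrices share one region set. The structural side carries the
    planted modular structure: a latent edge score (modular base plus noise)
    is censored at its 60th percentile and mapped linearly to positive
    fiber-count-like weights, leaving a sparse matrix. The sparsification
    attenuates any linear association by a factor c = corr(score, weight)
    measured on the realized sample, so the functional score is drawn with
    latent coupling rho = r_target / c against the standardized structural
    score; the realized upper-triangle Pearson correlation then lands near
    r_target by construction. Functional weights are an affine map of the
    functional score clipped to [-1, 1].
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_nodes
    labels = _planted_labels(n, spec.n_modules)
    iu, ju = np.triu_indices(n, k=1)
    within = (labels[iu] == labels[ju]).astype(float)
    m = len(iu)

    # structural side: modular base + noise, censored, linear fiber-like map
    score_b = 0.8 * within + 0.6 * rng.normal(size=m)
    cutoff = np.quantile(score_b, 0.6)
    keep = score_b > cutoff
    struct = np.zeros(m)
    lo, hi = score_b[keep].min(), score_b[keep].max()
    span = hi - lo if hi > lo else 1.0
    struct[keep] = 1.0 + 9999.0 * (score_b[keep] - lo) / span  # spans ~10^0-10^4

    sb = (score_b - score_b.mean()) / score_b.std()
    c = float(np.corrcoef(sb, struct)[0, 1])
    rho = np.clip(spec.r_target / c, -0.99, 0.99)
    score_a = rho * sb + np.sqrt(max(0.0, 1.0 - rho**2)) * rng.normal(size=m)
    func = np.clip(0.2 + 0.25 * score_a, -1.0, 1.0)

    def _to_cm(vals: np.ndarray) -> np.ndarray:
        w = np.zeros((n, n))
        w[iu, ju] = vals
        return w + w.T

    coords = _module_coords(labels, rng)
    regions = _region_set_for(n, coords)
    flags = {
        "synthetic": True,
        "planted_partition": labels.tolist(),
        "r_target": spec.r_target,
    }
    cm_func = ConnectivityMatrix(
        _to_cm(func),
        regions,
        NetworkMetadata(
            study_name="synthetic_coupled",
            network_name=f"coupled_fcmri_seed{spec.seed}",
            modality="fMRI",
            preprocessing_flags=dict(flags),
        ),
    )
    cm_struct = ConnectivityMatrix(
        _to_cm(struct),
        regions,
        NetworkMetadata(
            study_name="synthetic_coupled",
            network_name=f"coupled_dti_seed{spec.seed}",
            modality="dwMRI/DTI",
            preprocessing_flags=dict(flags),
        ),
    )
    return cm_func, cm_struct
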