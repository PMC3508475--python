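import numpy as np
import pytest

from connmat import (
    AnalysisConfig,
    ConnectivityMatrix,
    NetworkMetadata,
    RegionSet,
    build_graph,
    make_reference_graph,
)


@pytest.fixture
def simple_regions():
    return RegionSet(
        names=("Left A", "Right A", "Left B", "Right B"),
        abbreviations=("LA", "RA", "LB", "RB"),
        coords=np.array([[0.0, 0, 0], [3, 4, 0], [10, 0, 0], [0, 10, 0]]),
    )


@pytest.fixture
def simple_metadata():
    return NetworkMetadata(study_name="test_study", network_name="net0", modality="fMRI")


def cm_from_upper(upper_weights, coords=None):
    """Build a ConnectivityMatrix from upper-triangle weights (row-major i<j)."""
    m = len(upper_weights)
    n = int((1 + np.sqrt(1 + 8 * m)) / 2)
    w = np.zeros((n, n))
    w[np.triu_indices(n, k=1)] = upper_weights
    w += w.T
    if coords is None:
        coords = np.arange(3 * n, dtype=float).reshape(n, 3)
    regions = RegionSet(
        tuple(f"node{i}" for i in range(n)),
        tuple(f"n{i}" for i in range(n)),
        np.asarray(coords, dtype=float),
    )
    return ConnectivityMatrix(
        w, regions, NetworkMetadata(study_name="test", network_name="upper")
    )


def binary_graph(kind: str, n: int, k: int = 4, density: int = 100):
    """Reference graph thresholded at the given density, binary weighting."""
    cm = make_reference_graph(kind, n, k=k)
    return build_graph(cm, AnalysisConfig(weighting="binary", density_percent=density))


def random_symmetric_cm(n: int, rng: np.random.Generator, density: float = 0.5):
    iu = np.triu_indices(n, k=1)
    vals = rng.random(len(iu[0]))
    vals[rng.random(len(vals)) > density] = 0.0
    w = np.zeros((n, n))
    w[iu] = vals
    w += w.T
    return cm_from_upper(w[iu])
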