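import numpy as np
import pytest

from tractnet import CohortSpec, WeightedNetwork


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def small_spec():
    """A reduced cohort (12 nodes, 4 per group, 2 scans) for fast pipeline tests."""
    return CohortSpec(n_per_group=4, n_nodes=12, n_scans=2, base_density=0.6,
                      voxel_range=(50, 200), seed=42)


@pytest.fixture
def path_net():
    """Unit-weight path graph a - b - c."""
    w = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 1.0], [0.0, 1.0, 0.0]])
    return WeightedNetwork(w, ("a", "b", "c"))


def make_network(weights, labels=None):
    return WeightedNetwork(np.asarray(weights, dtype=float), labels or ())
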