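import numpy as np
import pytest

from senodyn import HierarchicalParams, PopulationState


def same_partition(a: np.ndarray, b: np.ndarray) -> bool:
    """True if two label maps define the same partition up to renaming."""
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape or not np.array_equal(a > 0, b > 0):
        return False
    fg = a > 0
    pairs = set(zip(a[fg].tolist(), b[fg].tolist()))
    return len(pairs) == len({p[0] for p in pairs}) == len({p[1] for p in pairs})


@pytest.fixture
def csc_seed():
    """Unit CSC-only initial state for a given N."""

    def make(n: int) -> PopulationState:
        return PopulationState(0, 1.0, np.zeros(n), 0.0)

    return make


@pytest.fixture
def cc_seed():
    """Unit CC seed spread uniformly over ages 1..N."""

    def make(n: int) -> PopulationState:
        return PopulationState(0, 0.0, np.full(n, 1.0 / n), 0.0)

    return make


@pytest.fixture
def melanoma_params():
    """Parameters typical of the long-term melanoma culture emulation."""
    return HierarchicalParams(
        delta=0.15, n_senescence=100, death_prob=0.05, division_rate=1.1
    )
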