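import numpy as np
import pytest

from gcnfr import GCN, SynthSpec, synth_gcn, synth_profiles


@pytest.fixture
def staircase() -> np.ndarray:
    """Perfectly nested 3x3 binary staircase (NODF = 1)."""
    return np.array([[1, 1, 1], [1, 1, 0], [1, 0, 0]])


@pytest.fixture
def small_gcn() -> GCN:
    """Hand-built 3-species x 4-gene GCN with copy numbers."""
    return GCN(
        ["spA", "spB", "spC"],
        ["g1", "g2", "g3", "g4"],
        np.array([[2, 1, 0, 0], [1, 1, 1, 0], [0, 0, 1, 3]]),
    )


@pytest.fixture
def nested_gcn() -> GCN:
    return synth_gcn(SynthSpec("nested", 12, 12, fill=0.5, seed=0))


@pytest.fixture
def random_gcn() -> GCN:
    return synth_gcn(SynthSpec("random", 15, 40, fill=0.3, seed=3))


@pytest.fixture
def profiles(random_gcn):
    return synth_profiles(12, random_gcn, richness=6, concentration=1.0, seed=5)


def random_gcn_matrix(rng: np.random.Generator, max_n: int = 8, max_m: int = 8,
                      max_copy: int = 4) -> np.ndarray:
    """Random integer copy-number matrix without empty rows/columns."""
    n = rng.integers(2, max_n + 1)
    m = rng.integers(2, max_m + 1)
    mat = rng.integers(0, max_copy + 1, size=(n, m))
    for i in np.flatnonzero(mat.sum(axis=1) == 0):
        mat[i, rng.integers(m)] = 1
    for a in np.flatnonzero(mat.sum(axis=0) == 0):
        mat[rng.integers(n), a] = 1
    return mat
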