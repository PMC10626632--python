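import numpy as np
import pytest

from lodekit.structures import Structure


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_cluster(rng):
    """Aperiodic 5-atom cluster with two species and mixed weights."""
    pos = rng.uniform(-2.0, 2.0, (5, 3))
    return Structure(
        pos, ["A", "A", "B", "B", "A"], None, rng.uniform(0.5, 1.5, 5)
    )


@pytest.fixture
def small_periodic(rng):
    """Random 4-atom periodic cell with ±-type weights."""
    pos = rng.uniform(0.0, 4.0, (4, 3))
    return Structure(
        pos, ["A", "A", "B", "B"], np.eye(3) * 4.0,
        np.array([1.0, -1.0, 0.5, -0.5]),
    )
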