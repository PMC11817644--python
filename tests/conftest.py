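import numpy as np
import pytest

from cathdose import synthetic


@pytest.fixture(scope="session")
def small_grid():
    """Down-scaled phantom geometry (128x128 matrix) for fast tests."""
    return synthetic.make_geometry(matrix_shape=(128, 128))


@pytest.fixture(scope="session")
def small_thresholds(small_grid):
    return synthetic.thresholds_for(small_grid)


@pytest.fixture(scope="session")
def full_grid():
    """Full-scale 512x512 geometry matching the default region thresholds."""
    return synthetic.make_geometry()


@pytest.fixture(scope="session")
def small_field(small_grid):
    params = synthetic.ScatterFieldParams(reference_cc=0.9, seed=0)
    return synthetic.make_scatter_field(params, small_grid)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
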