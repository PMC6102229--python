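import numpy as np
import pytest

from ridge2reef.core_io.grid import Grid
from ridge2reef.synthetic_island import make_island, make_reef_surveys


@pytest.fixture(scope="session")
def island():
    """Shared synthetic island (seed 1, 200-cell side)."""
    return make_island(1, 200)


@pytest.fixture(scope="session")
def island_surveys(island):
    return make_reef_surveys(island, island.truth, n_sites=163, seed=2)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_grid(values, cell_size=30.0, origin=None, nodata=float("nan")):
    values = np.asarray(values)
    if origin is None:
        origin = (0.0, values.shape[0] * cell_size)
    return Grid(values, cell_size, origin, nodata, "test")


@pytest.fixture
def grid_factory():
    return make_grid
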