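import numpy as np
import pytest

from urbannature import CityMask, Grid


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def make_grid(values, cell_size=10.0, nodata=None, **kw):
    return Grid(np.asarray(values), cell_size=cell_size, nodata=nodata, **kw)


def full_mask(grid: Grid) -> CityMask:
    return CityMask(grid.with_values(np.ones(grid.shape, dtype=np.uint8)))
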