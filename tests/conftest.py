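import numpy as np
import pytest
from shapely.geometry import box

from ozoneyield.grid import GridSpec, RasterField, assign_cells


@pytest.fixture
def unit_grid_4x4():
    """4x4 grid of 1-degree cells over [0,4) x [0,4)."""
    return GridSpec(0.0, 0.0, 1.0, 1.0, 4, 4)


@pytest.fixture
def two_region_map(unit_grid_4x4):
    """Vertical split of the 4x4 domain at the midline: A west, B east."""
    polys = {"A": box(0, 0, 2, 4), "B": box(2, 0, 4, 4)}
    return assign_cells(unit_grid_4x4, polys)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
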