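import numpy as np
import pytest

import isogloss as ig


@pytest.fixture
def uniform_raster():
    """Small uniform periodic landscape."""
    return ig.PopulationRaster(np.ones((32, 32)), cell_size=1.0,
                               boundary_mode="periodic")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_landscape(rng):
    """Random closed landscape with a patchy metropolitan field."""
    vals = rng.uniform(0.5, 2.0, (20, 20))
    raster = ig.PopulationRaster(vals, cell_size=1.0, boundary_mode="closed")
    M = ig.MetropolitanField((rng.random((20, 20)) < 0.3).astype(float))
    return raster, M
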