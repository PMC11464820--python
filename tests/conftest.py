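import numpy as np
import pytest

from urbanmosaic import default_registry
from urbanmosaic.fixtures import CityRecipe, generate_city
from urbanmosaic.raster import CategoricalRaster, GridSpec


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def city(registry):
    """The default synthetic city (200x200 cells, ~500 features)."""
    return generate_city(CityRecipe(seed=7), registry)


@pytest.fixture
def small_grid():
    return GridSpec((0.0, 0.0, 300.0, 300.0), 30.0, "test-meters")


def random_stack(rng, reg, shape=(32, 32), n_classes=5, transform=(0.0, 960.0, 30.0)):
    """Random binary class masks on a shared grid, for merge tests."""
    codes = rng.choice(reg.codes(), size=n_classes, replace=False)
    masks = {}
    for code in codes:
        vals = np.where(rng.random(shape) < 0.4, code, 0).astype(np.int32)
        masks[int(code)] = CategoricalRaster(
            values=vals, transform=transform, crs="test-meters", nodata=0
        )
    return masks
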