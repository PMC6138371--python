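import numpy as np
import pytest

from isomatch import GridSpec, IsoscapeRaster, IsoscapeStack
from isomatch.synthetic import SyntheticWorldSpec, make_world


@pytest.fixture
def grid10():
    return GridSpec(lon_min=0.0, lat_max=10.0, n_rows=10, n_cols=10, resolution=1.0)


@pytest.fixture
def constant_raster(grid10):
    return IsoscapeRaster(grid=grid10, isotope="2H",
                          mean=np.full(grid10.shape, -40.0))


def plane_raster(grid, isotope="2H", a=0.0, b_lon=1.0, b_lat=0.0, sd=None):
    """mean = a + b_lon*lon + b_lat*lat evaluated at cell centers."""
    lon = grid.lon_centers()[None, :]
    lat = grid.lat_centers()[:, None]
    mean = a + b_lon * lon + b_lat * lat + 0.0 * (lon + lat)
    mean = np.broadcast_to(mean, grid.shape).copy()
    return IsoscapeRaster(grid=grid, isotope=isotope, mean=mean, sd=sd)


@pytest.fixture
def random_stack():
    """A 20x20 random three-isotope feather stack with per-cell SDs."""
    rng = np.random.default_rng(7)
    g = GridSpec(lon_min=0.0, lat_max=20.0, n_rows=20, n_cols=20, resolution=1.0)
    layers = []
    for iso, loc, scale in (("2H", -60.0, 25.0), ("13C", -20.0, 4.0), ("15N", 8.0, 3.0)):
        mean = rng.normal(loc, scale, g.shape)
        sd = rng.uniform(0.5, 3.0, g.shape)
        layers.append(IsoscapeRaster(grid=g, isotope=iso, mean=mean, sd=sd))
    return IsoscapeStack(layers)


@pytest.fixture(scope="session")
def small_world():
    spec = SyntheticWorldSpec(
        grid=GridSpec(lon_min=-10.0, lat_max=10.0, n_rows=60, n_cols=60,
                      resolution=0.33),
        seed=11,
    )
    return make_world(spec)
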