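import numpy as np
import pytest
from shapely.geometry import box

from uavheight import ElevationRaster, SimulationConfig, simulate_field


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A scaled-down two-site study that keeps every design feature."""
    return SimulationConfig(
        n_lines=24, n_sites=2, n_reps=2, n_plot_columns=8, seed=7
    )


@pytest.fixture(scope="session")
def small_field(small_config):
    return simulate_field(small_config)


@pytest.fixture
def plane_raster():
    """Tilted plane z = 100 + 0.01 x + 0.02 y on a 2 m x 2 m grid."""

    def make(nx=80, ny=80, px=0.025, a=100.0, b=0.01, c=0.02):
        raster = ElevationRaster(
            data=np.zeros((ny, nx)), x_origin=0.0, y_origin=ny * px, pixel_size=px
        )
        xx, yy = np.meshgrid(raster.x_centers(), raster.y_centers())
        raster.data[:] = a + b * xx + c * yy
        return raster

    return make


@pytest.fixture
def unit_square():
    return box(0.2, 0.2, 1.4, 1.6)
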