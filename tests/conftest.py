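import numpy as np
import pytest
from hypothesis import settings

import carbonfish as cf

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def band_grid(n_lon: int) -> cf.GeoGrid:
    """Single-latitude-band grid: all n_lon cells have identical area."""
    return cf.GeoGrid(lat_edges=np.array([-90.0, 90.0]),
                      lon_edges=np.linspace(-180.0, 180.0, n_lon + 1))


def band_field(values, units="", name="f", valid=None) -> cf.GriddedField:
    values = np.atleast_2d(np.asarray(values, dtype=float))
    grid = band_grid(values.shape[1])
    return cf.GriddedField(grid=grid, values=values, valid=valid,
                           units=units, name=name)


@pytest.fixture(scope="session")
def regional_table():
    return cf.load_regional_fixture()


@pytest.fixture(scope="session")
def small_world():
    """One deterministic synthetic world shared across tests."""
    return cf.gen_fields(cf.SyntheticConfig(resolution=4.0, seed=11))
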