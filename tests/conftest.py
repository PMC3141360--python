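import numpy as np
import pytest
from shapely.geometry import Polygon

from heatrisk import CityConfig, ZoneSet, analyse, generate_city


@pytest.fixture
def unit_square_km():
    """1 km x 1 km square at the origin (area exactly 1 km^2)."""
    return Polygon([(0, 0), (1000, 0), (1000, 1000), (0, 1000)])


@pytest.fixture
def grid_zones():
    """2 x 2 grid of 1 km squares, ids A..D in file order."""
    def square(x0, y0):
        return Polygon(
            [(x0, y0), (x0 + 1000, y0), (x0 + 1000, y0 + 1000), (x0, y0 + 1000)]
        )

    return ZoneSet(
        ids=["A", "B", "C", "D"],
        polygons=[square(0, 0), square(1000, 0), square(0, 1000), square(1000, 1000)],
    )


@pytest.fixture(scope="session")
def default_city():
    return generate_city(CityConfig(seed=7))


@pytest.fixture(scope="session")
def default_result(default_city):
    c = default_city
    return analyse(c.zones, c.raster, c.households, c.buildings)
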