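"""Per-zone hazard layer: mean urban-heat-island magnitude.

The hazard is a single-scene surface-UHI raster (deg C). Each zone's
hazard value is the zonal mean of the raster, kept in raw degrees here;
standardization to [0, 1] happens downstream in the risk engine. Values
may be negative (zones cooler than the reference surface, e.g. parks).
"""

from __future__ import annotations

from .errors import CoverageError
from .geo_core import HazardRaster, ZoneSet, zonal_mean


def compute_hazard_layer(raster: HazardRaster, zones: ZoneSet) -> dict[str, float]:
    """Mean UHI magnitude (deg C) per zone.

    Raises CoverageError when the raster extent and the zone extent are
    disjoint (the nearest-cell sliver fallback would otherwise silently
    smear edge values over every zone).
    """
    r_minx = raster.xllcorner
    r_maxx = raster.xllcorner + raster.ncols * raster.cellsize
    r_miny = raster.yllcorner
    r_maxy = raster.yllcorner + raster.nrows * raster.cellsize
    import numpy as np

    z_bounds = np.array([p.bounds for p in zones.polygons])
    z_minx, z_miny = z_bounds[:, 0].min(), z_bounds[:, 1].min()
    z_maxx, z_maxy = z_bounds[:, 2].max(), z_bounds[:, 3].max()
    if z_maxx < r_minx or z_minx > r_maxx or z_maxy < r_miny or z_miny > r_maxy:
        raise CoverageError("raster extent and zone extent do not overlap")
    return zonal_mean(raster, zones)
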