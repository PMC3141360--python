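import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import Polygon
from shapely import affinity

from heatrisk import (
    HazardRaster,
    InvalidGeometryError,
    ValidationError,
    ZoneSet,
    assign_points_to_zones,
    make_polygon,
    point_in_polygon,
    polygon_area,
    read_households,
    read_raster,
    read_zones,
    write_households,
    write_raster,
    write_zones,
    zonal_mean,
)
from heatrisk.geo_core import make_household_table


def hh_table(points, types=None):
    types = types if types is not None else [1] * len(points)
    return make_household_table(
        pd.DataFrame(
            {
                "hh_id": [f"h{i}" for i in range(len(points))],
                "x": [p[0] for p in points],
                "y": [p[1] for p in points],
                "mosaic_type": types,
            }
        )
    )


class TestPolygonArea:
    @pytest.mark.parametrize(
        "ring,holes,expected",
        [
            ([(0, 0), (1000, 0), (1000, 1000), (0, 1000)], [], 1.0),
            ([(0, 0), (2000, 0), (0, 2000)], [], 2.0),
            (
                [(0, 0), (1000, 0), (1000, 1000), (0, 1000)],
                [[(250, 250), (750, 250), (750, 750), (250, 750)]],
                0.75,
            ),
        ],
    )
    def test_known_areas_km2(self, ring, holes, expected):
        assert polygon_area(make_polygon(ring, holes)) == pytest.approx(expected)

    def test_degenerate_ring_rejected(self):
        with pytest.raises(InvalidGeometryError):
            make_polygon([(0, 0), (1, 1), (0, 0)])

    @settings(deadline=None, max_examples=50)
    @given(
        dx=st.floats(-1e5, 1e5),
        dy=st.floats(-1e5, 1e5),
        angle=st.floats(0, 360),
        scale=st.floats(0.1, 50),
    )
    def test_rigid_invariance_and_quadratic_scaling(self, dx, dy, angle, scale):
        poly = Polygon([(0, 0), (800, 100), (1100, 900), (200, 1200)])
        base = polygon_area(poly)
        moved = affinity.rotate(affinity.translate(poly, dx, dy), angle)
        assert polygon_area(moved) == pytest.approx(base, rel=1e-9)
        scaled = affinity.scale(poly, scale, scale, origin=(0, 0))
        assert polygon_area(scaled) == pytest.approx(base * scale**2, rel=1e-9)


class TestPointInPolygon:
    @pytest.mark.parametrize(
        "x,y,expected",
        [(500, 500, True), (1500, 500, False), (1000, 500, True), (0, 0, True)],
    )
    def test_membership_with_inclusive_boundary(self, unit_square_km, x, y, expected):
        assert point_in_polygon(x, y, unit_square_km) is expected


class TestAssignment:
    def test_unique_containment_and_unassigned(self, grid_zones):
        table = hh_table([(500, 500), (5000, 5000)])
        res = assign_points_to_zones(table, grid_zones)
        assert res.zone_ids == ["A", None]
        assert res.unassigned == 1
        assert res.assigned + res.unassigned == len(table)

    def test_overlap_resolved_by_file_order(self, unit_square_km):
        zones = ZoneSet(ids=["first", "second"],
                        polygons=[unit_square_km, unit_square_km])
        res = assign_points_to_zones(hh_table([(500, 500)]), zones)
        assert res.zone_ids == ["first"]

    def test_matches_exhaustive_point_in_polygon(self, rng=np.random.default_rng(3)):
        polys, ids = [], []
        for i in range(12):
            x0, y0 = rng.uniform(0, 3000, 2)
            w, h = rng.uniform(200, 1500, 2)
            ids.append(f"z{i}")
            polys.append(Polygon([(x0, y0), (x0 + w, y0), (x0 + w, y0 + h),
                                  (x0, y0 + h)]))
        zones = ZoneSet(ids=ids, polygons=polys)
        pts = [tuple(p) for p in rng.uniform(-200, 4000, (80, 2))]
        res = assign_points_to_zones(hh_table(pts), zones)
        for (x, y), got in zip(pts, res.zone_ids):
            expected = next(
                (zid for zid, poly in zip(ids, polys) if point_in_polygon(x, y, poly)),
                None,
            )
            assert got == expected


def raster_from(values, cellsize=1000.0, nodata=-9999.0):
    values = np.asarray(values, dtype=float)
    return HazardRaster(
        ncols=values.shape[1], nrows=values.shape[0],
        xllcorner=0.0, yllcorner=0.0, cellsize=cellsize,
        nodata=nodata, values=values,
    )


class TestZonalMean:
    def test_constant_raster(self, grid_zones):
        r = raster_from(np.full((2, 2), 3.0))
        assert zonal_mean(r, grid_zones) == {z: 3.0 for z in "ABCD"}

    def test_two_cells_average(self):
        # one wide zone covering both cell centres of a 2-cell raster
        zone = ZoneSet(
            ids=["W"],
            polygons=[Polygon([(0, 0), (2000, 0), (2000, 1000), (0, 1000)])],
        )
        r = raster_from([[2.0, 4.0]])
        assert zonal_mean(r, zone)["W"] == pytest.approx(3.0)

    def test_sliver_zone_nearest_cell_fallback(self):
        sliver = ZoneSet(
            ids=["S"],
            polygons=[Polygon([(900, 900), (950, 900), (950, 950), (900, 950)])],
        )
        r = raster_from([[1.0, 7.0], [9.0, 5.0]])  # row 0 is the top row
        # sliver centroid (925, 925) -> nearest centre is (500, 500): the
        # bottom-left cell, i.e. value 9.0 in the row-0-on-top layout
        assert zonal_mean(r, sliver)["S"] == 9.0

    def test_nodata_cells_masked(self, grid_zones):
        r = raster_from([[2.0, -9999.0], [4.0, -9999.0]])
        out = zonal_mean(r, grid_zones)
        assert out["C"] == 2.0  # top-left cell
        assert out["A"] == 4.0
        # nodata zones fall back to nearest valid cell, never -9999
        assert all(v != -9999.0 for v in out.values())

    def test_means_bounded_by_raster_range(self, grid_zones):
        rng = np.random.default_rng(11)
        r = raster_from(rng.normal(2, 3, (8, 8)), cellsize=250.0)
        out = zonal_mean(r, grid_zones)
        lo, hi = r.data_range()
        assert all(lo <= v <= hi for v in out.values())


class TestRoundTrips:
    def test_zone_geojson_round_trip(self, tmp_path, grid_zones):
        path = tmp_path / "zones.geojson"
        write_zones(grid_zones, path)
        back = read_zones(path)
        assert back.ids == grid_zones.ids
        np.testing.assert_allclose(back.area_km2, grid_zones.area_km2, rtol=1e-9)

    def test_raster_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        r = raster_from(rng.normal(0, 2, (4, 6)), cellsize=123.456)
        path = tmp_path / "uhi.asc"
        write_raster(r, path)
        back = read_raster(path)
        assert (back.ncols, back.nrows) == (r.ncols, r.nrows)
        assert back.cellsize == pytest.approx(r.cellsize, rel=1e-9)
        np.testing.assert_allclose(back.values, r.values, rtol=1e-9)

    def test_household_round_trip(self, tmp_path):
        table = hh_table([(1.23456789, 2.3456789), (100.5, 200.25)], [20, 47])
        path = tmp_path / "hh.csv"
        write_households(table, path)
        back = read_households(path)
        np.testing.assert_allclose(back["x"], table["x"], rtol=1e-9)
        assert back["mosaic_type"].tolist() == [20, 47]

    def test_out_of_range_mosaic_type_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("hh_id,x,y,mosaic_type\nh1,0,0,70\n")
        with pytest.raises(ValidationError, match="mosaic_type"):
            read_households(path)

    def test_malformed_raster_header_named(self, tmp_path):
        path = tmp_path / "bad.asc"
        path.write_text("ncols 2\nnrows\n1 2\n")
        with pytest.raises(ValidationError):
            read_raster(path)

    def test_duplicate_zone_ids_rejected(self, unit_square_km):
        with pytest.raises(ValidationError, match="unique"):
            ZoneSet(ids=["a", "a"], polygons=[unit_square_km, unit_square_km])
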