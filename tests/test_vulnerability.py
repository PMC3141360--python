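import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

from heatrisk import (
    BuildingSet,
    InvalidGeometryError,
    ValidationError,
    ZoneSet,
    assign_points_to_zones,
    count_flagged_per_zone,
    default_mosaic_key,
    density_layer,
    high_rise_layer,
    load_mosaic_key,
)
from heatrisk.vulnerability import ELDERLY_TYPES, ILL_TYPES, write_mosaic_key
from heatrisk.geo_core import make_household_table


def hh_table(points, types):
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


class TestMosaicKey:
    def test_default_flag_sets(self):
        key = default_mosaic_key()
        assert key.elderly == frozenset({20, 21, 22, 23, 50, 51, 52, 53})
        assert key.ill == frozenset({38, 39, 42, 43, 44, 45, 47, 65})
        assert not key.elderly & key.ill

    @pytest.mark.parametrize(
        "mosaic_type,elderly,ill",
        [(20, True, False), (47, False, True), (64, False, False)],
    )
    def test_individual_type_flags(self, mosaic_type, elderly, ill):
        key = default_mosaic_key()
        assert key.is_elderly(mosaic_type) is elderly
        assert key.is_ill(mosaic_type) is ill

    def test_csv_round_trip(self, tmp_path):
        path = tmp_path / "key.csv"
        write_mosaic_key(default_mosaic_key(), path)
        back = load_mosaic_key(path)
        assert back.elderly == ELDERLY_TYPES
        assert back.ill == ILL_TYPES

    def test_duplicate_type_rows_rejected(self, tmp_path):
        path = tmp_path / "key.csv"
        path.write_text(
            "mosaic_type,group,elderly,ill\n20,E,1,0\n20,E,1,0\n"
        )
        with pytest.raises(ValidationError, match="duplicate"):
            load_mosaic_key(path)


class TestFlaggedCounts:
    def test_small_zone_mix(self, grid_zones):
        table = hh_table([(100, 100), (200, 200), (300, 300)], [20, 51, 64])
        assignment = assign_points_to_zones(table, grid_zones)
        counts = count_flagged_per_zone(
            table, assignment, default_mosaic_key(), "elderly", grid_zones
        )
        assert counts == {"A": 2, "B": 0, "C": 0, "D": 0}

    def test_matches_linear_scan_oracle(self, grid_zones):
        rng = np.random.default_rng(9)
        pts = rng.uniform(0, 2000, (200, 2))
        types = rng.integers(1, 68, 200)
        table = hh_table([tuple(p) for p in pts], types)
        assignment = assign_points_to_zones(table, grid_zones)
        key = default_mosaic_key()
        for flag, flagged_set in (("elderly", ELDERLY_TYPES), ("ill", ILL_TYPES)):
            got = count_flagged_per_zone(table, assignment, key, flag, grid_zones)
            expected = {z: 0 for z in grid_zones.ids}
            for zid, t in zip(assignment.zone_ids, types):
                if zid is not None and t in flagged_set:
                    expected[zid] += 1
            assert got == expected


def tower(x, y, half=20):
    return Polygon([(x - half, y - half), (x + half, y - half),
                    (x + half, y + half), (x - half, y + half)])


class TestHighRise:
    def test_strictly_greater_than_threshold_boundary(self, grid_zones):
        pts = [(100, 100)] * 10 + [(300, 300)] * 11
        table = hh_table(pts, [1] * 21)
        buildings = BuildingSet(
            ids=["ten", "eleven"], polygons=[tower(100, 100), tower(300, 300)]
        )
        counts = high_rise_layer(table, buildings, grid_zones)
        assert counts == {"A": 11, "B": 0, "C": 0, "D": 0}

    def test_no_buildings_all_zero(self, grid_zones):
        table = hh_table([(100, 100)], [1])
        counts = high_rise_layer(table, BuildingSet(ids=[], polygons=[]), grid_zones)
        assert set(counts.values()) == {0}

    def test_three_buildings_one_zone(self, grid_zones):
        # buildings with 4, 11 and 25 households -> 11 + 25 = 36 counted
        pts = [(100, 100)] * 4 + [(300, 300)] * 11 + [(500, 500)] * 25
        table = hh_table(pts, [1] * 40)
        buildings = BuildingSet(
            ids=["b4", "b11", "b25"],
            polygons=[tower(100, 100), tower(300, 300), tower(500, 500)],
        )
        assert high_rise_layer(table, buildings, grid_zones)["A"] == 36

    def test_monotone_nonincreasing_in_threshold(self, grid_zones):
        rng = np.random.default_rng(4)
        centres = rng.uniform(100, 1900, (6, 2))
        pts, polys, ids = [], [], []
        for i, (cx, cy) in enumerate(centres):
            pts += [(cx, cy)] * int(rng.integers(1, 30))
            polys.append(tower(cx, cy))
            ids.append(f"b{i}")
        table = hh_table(pts, [1] * len(pts))
        buildings = BuildingSet(ids=ids, polygons=polys)
        prev = None
        for thr in range(0, 31, 5):
            counts = high_rise_layer(table, buildings, grid_zones, threshold=thr)
            if prev is not None:
                assert all(counts[z] <= prev[z] for z in grid_zones.ids)
            prev = counts


class TestDensity:
    def test_stated_formula(self):
        # one zone of 0.1 km^2 holding 150 households
        zone = ZoneSet(
            ids=["Z"],
            polygons=[Polygon([(0, 0), (500, 0), (500, 200), (0, 200)])],
        )
        table = hh_table([(50.0 + i, 100.0) for i in range(150)], [1] * 150)
        assignment = assign_points_to_zones(table, zone)
        assert density_layer(table, assignment, zone)["Z"] == pytest.approx(1500.0)

    def test_empty_zone_zero(self, grid_zones):
        table = hh_table([(100, 100)], [1])
        assignment = assign_points_to_zones(table, grid_zones)
        dens = density_layer(table, assignment, grid_zones)
        assert dens["D"] == 0.0

    def test_two_zone_oracle(self, grid_zones):
        rng = np.random.default_rng(6)
        pts = [tuple(p) for p in rng.uniform(0, 2000, (120, 2))]
        table = hh_table(pts, [1] * 120)
        assignment = assign_points_to_zones(table, grid_zones)
        dens = density_layer(table, assignment, grid_zones)
        for z, area in zip(grid_zones.ids, grid_zones.area_km2):
            tally = sum(1 for zid in assignment.zone_ids if zid == z)
            assert dens[z] == pytest.approx(tally / area)


def test_conservation_and_disjoint_flags(default_city):
    """assigned + unassigned == records; old + ill <= assigned per zone."""
    from heatrisk.vulnerability import assigned_counts_per_zone

    city = default_city
    assignment = assign_points_to_zones(city.households, city.zones)
    assert assignment.assigned + assignment.unassigned == len(city.households)
    key = default_mosaic_key()
    old = count_flagged_per_zone(city.households, assignment, key, "elderly", city.zones)
    ill = count_flagged_per_zone(city.households, assignment, key, "ill", city.zones)
    totals = assigned_counts_per_zone(assignment, city.zones)
    for z in city.zones.ids:
        assert old[z] + ill[z] <= totals[z]


def test_periphery_elderly_exceed_centre(default_city):
    """Construction property: mean elderly count is higher at the periphery."""
    city = default_city
    assignment = assign_points_to_zones(city.households, city.zones)
    old = count_flagged_per_zone(
        city.households, assignment, default_mosaic_key(), "elderly", city.zones
    )
    cx, cy = city.config.centre
    cents = city.zones.centroids()
    dist = np.hypot(cents[:, 0] - cx, cents[:, 1] - cy)
    vals = np.array([old[z] for z in city.zones.ids], dtype=float)
    median = np.median(dist)
    assert vals[dist > median].mean() > vals[dist <= median].mean()
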