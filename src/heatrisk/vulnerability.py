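"""The four "exposed and vulnerable" layers.

From the household points, building footprints and the geodemographic
(Mosaic) key this module derives, per zone:

* ``old_count``  — households whose Mosaic type is flagged elderly;
* ``ill_count``  — households whose type is flagged ill-health;
* ``flats_count``— households living in high-rise buildings, defined as
  building footprints containing strictly more than ``threshold``
  (default 10) household points;
* ``density``   — assigned households per km^2 of zone area.

The default key flags the elderly types (Active Retirement 20-23 and
Elderly Needs 50-53) and the ill-health types (38, 39, 42-45, 47, 65);
the two sets are disjoint. Types present in data but absent from the key
are treated as not vulnerable, with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.strtree import STRtree

from .errors import InvalidGeometryError, ValidationError
from .geo_core import (
    MOSAIC_TYPE_MAX,
    MOSAIC_TYPE_MIN,
    BuildingSet,
    PointAssignment,
    ZoneSet,
)

logger = logging.getLogger("heatrisk")

ELDERLY_TYPES = frozenset({20, 21, 22, 23, 50, 51, 52, 53})
ILL_TYPES = frozenset({38, 39, 42, 43, 44, 45, 47, 65})

_DEFAULT_KEY_ROWS = [
    # (type, group letter, title) for the flagged types; group E = Active
    # Retirement, L = Elderly Needs; ill types span several groups.
    (20, "E", "Golden Retirement"),
    (21, "E", "Bungalow Quietude"),
    (22, "E", "Beachcombers"),
    (23, "E", "Balcony Downsizers"),
    (38, "I", "Settled Ex-Tenants"),
    (39, "I", "Choice Right to Buy"),
    (42, "J", "Worn-Out Workers"),
    (43, "J", "Streetwise Kids"),
    (44, "J", "New Parents in Need"),
    (45, "K", "Small Block Singles"),
    (47, "K", "Deprived View"),
    (50, "L", "Pensioners in Blocks"),
    (51, "L", "Sheltered Seniors"),
    (52, "L", "Meals on Wheels"),
    (53, "L", "Low Spending Elders"),
    (65, "N", "Anti-Materialists"),
]


@dataclass
class MosaicKey:
    """mosaic_type -> (group, elderly flag, ill flag); missing types are
    not vulnerable.

    ``known`` is the set of types the key covers; the built-in default
    covers the full 1-67 classification (only the flagged types carry a
    vulnerability), while a user CSV covers exactly its listed rows.
    """

    elderly: frozenset[int]
    ill: frozenset[int]
    groups: dict[int, str]
    known: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        self.known = frozenset(self.known) | self.elderly | self.ill | set(self.groups)
        if self.elderly & self.ill:
            raise ValidationError(
                f"elderly and ill type sets overlap: {sorted(self.elderly & self.ill)}"
            )

    def is_elderly(self, mosaic_type: int) -> bool:
        return mosaic_type in self.elderly

    def is_ill(self, mosaic_type: int) -> bool:
        return mosaic_type in self.ill


def default_mosaic_key() -> MosaicKey:
    return MosaicKey(
        elderly=ELDERLY_TYPES,
        ill=ILL_TYPES,
        groups={t: g for t, g, _ in _DEFAULT_KEY_ROWS},
        known=frozenset(range(MOSAIC_TYPE_MIN, MOSAIC_TYPE_MAX + 1)),
    )


def load_mosaic_key(path: str | Path | None = None) -> MosaicKey:
    """Load a Mosaic vulnerability key CSV, or the built-in default.

    CSV columns: ``mosaic_type,group,elderly,ill`` with 0/1 flags.
    Types not listed default to not-vulnerable.
    """
    if path is None:
        return default_mosaic_key()
    df = pd.read_csv(path)
    required = {"mosaic_type", "group", "elderly", "ill"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"{path}: mosaic key needs columns {sorted(required)}"
        )
    if df["mosaic_type"].duplicated().any():
        dup = df.loc[df["mosaic_type"].duplicated(), "mosaic_type"].iloc[0]
        raise ValidationError(f"{path}: duplicate mosaic_type {dup}")
    bad = ~df["mosaic_type"].between(MOSAIC_TYPE_MIN, MOSAIC_TYPE_MAX)
    if bad.any():
        raise ValidationError(
            f"{path}: mosaic_type {df.loc[bad, 'mosaic_type'].iloc[0]} out of range"
        )
    eld = frozenset(df.loc[df["elderly"].astype(bool), "mosaic_type"].astype(int))
    ill = frozenset(df.loc[df["ill"].astype(bool), "mosaic_type"].astype(int))
    groups = dict(zip(df["mosaic_type"].astype(int), df["group"].astype(str)))
    return MosaicKey(elderly=eld, ill=ill, groups=groups)


def write_mosaic_key(key: MosaicKey, path: str | Path) -> None:
    rows = sorted(set(key.groups) | key.elderly | key.ill)
    pd.DataFrame(
        {
            "mosaic_type": rows,
            "group": [key.groups.get(t, "") for t in rows],
            "elderly": [int(t in key.elderly) for t in rows],
            "ill": [int(t in key.ill) for t in rows],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Layer computations
# ---------------------------------------------------------------------------

def _zone_series(zones: ZoneSet, counts: dict[str, int]) -> dict[str, int]:
    return {zid: counts.get(zid, 0) for zid in zones.ids}


def count_flagged_per_zone(
    households: pd.DataFrame,
    assignment: PointAssignment,
    key: MosaicKey,
    flag: str,
    zones: ZoneSet,
) -> dict[str, int]:
    """Count assigned households carrying the elderly or ill flag per zone."""
    if flag == "elderly":
        flagged_types = key.elderly
    elif flag == "ill":
        flagged_types = key.ill
    else:
        raise ValidationError(f"unknown vulnerability flag {flag!r}")
    types = households["mosaic_type"].to_numpy()
    flagged = np.isin(types, list(flagged_types))
    counts: dict[str, int] = {}
    for zid, hit in zip(assignment.zone_ids, flagged):
        if zid is not None and hit:
            counts[zid] = counts.get(zid, 0) + 1
    return _zone_series(zones, counts)


def high_rise_layer(
    households: pd.DataFrame,
    buildings: BuildingSet,
    zones: ZoneSet,
    assignment: PointAssignment | None = None,
    threshold: int = 10,
) -> dict[str, int]:
    """Households in high-rise buildings, per zone.

    A building is high-rise when strictly more than ``threshold``
    household points fall within its footprint. Each qualifying
    household is attributed to a zone by its own point coordinates (not
    the building centroid), so towers straddling a boundary split
    naturally.
    """
    if threshold < 0:
        raise ValidationError("high-rise threshold must be >= 0")
    zeros = {zid: 0 for zid in zones.ids}
    if len(buildings) == 0 or len(households) == 0:
        return zeros
    pts = shapely.points(households["x"].to_numpy(), households["y"].to_numpy())
    tree = STRtree(buildings.polygons)
    p_idx, b_idx = tree.query(pts, predicate="intersects")
    if p_idx.size == 0:
        return zeros
    # households on a shared footprint boundary count toward every such
    # building for the threshold test, but are tallied into a zone once
    per_building = np.bincount(b_idx, minlength=len(buildings))
    kept_buildings = per_building > threshold
    in_kept = np.zeros(len(households), dtype=bool)
    in_kept[p_idx[kept_buildings[b_idx]]] = True

    if assignment is None:
        from .geo_core import assign_points_to_zones

        assignment = assign_points_to_zones(households, zones)
    counts: dict[str, int] = {}
    for i in np.nonzero(in_kept)[0]:
        zid = assignment.zone_ids[i]
        if zid is not None:
            counts[zid] = counts.get(zid, 0) + 1
    return _zone_series(zones, counts)


def density_layer(
    households: pd.DataFrame,
    assignment: PointAssignment,
    zones: ZoneSet,
) -> dict[str, float]:
    """Assigned households per km^2 for each zone."""
    if np.any(zones.area_km2 <= 0):
        bad = zones.ids[int(np.argmax(zones.area_km2 <= 0))]
        raise InvalidGeometryError(f"zone {bad!r} has non-positive area")
    counts: dict[str, int] = {}
    for zid in assignment.zone_ids:
        if zid is not None:
            counts[zid] = counts.get(zid, 0) + 1
    return {
        zid: counts.get(zid, 0) / area
        for zid, area in zip(zones.ids, zones.area_km2)
    }


def assigned_counts_per_zone(
    assignment: PointAssignment, zones: ZoneSet
) -> dict[str, int]:
    counts: dict[str, int] = {}
    for zid in assignment.zone_ids:
        if zid is not None:
            counts[zid] = counts.get(zid, 0) + 1
    return _zone_series(zones, counts)


def warn_unknown_types(households: pd.DataFrame, key: MosaicKey) -> int:
    """Log types present in data but absent from the key; returns count.

    Unknown types are treated as not vulnerable (graceful degradation).
    """
    present = set(households["mosaic_type"].unique().tolist())
    unknown = present - key.known
    if unknown:
        logger.warning(
            "%d mosaic type(s) absent from the key treated as not vulnerable: %s",
            len(unknown),
            sorted(unknown),
        )
    return len(unknown)


def compute_vulnerability_layers(
    households: pd.DataFrame,
    assignment: PointAssignment,
    buildings: BuildingSet,
    zones: ZoneSet,
    key: MosaicKey | None = None,
    threshold: int = 10,
) -> pd.DataFrame:
    """All four raw layers as a DataFrame indexed like the zone set.

    Columns: old_raw, ill_raw, flats_raw, density_raw.
    """
    key = key or default_mosaic_key()
    warn_unknown_types(households, key)
    old = count_flagged_per_zone(households, assignment, key, "elderly", zones)
    ill = count_flagged_per_zone(households, assignment, key, "ill", zones)
    flats = high_rise_layer(
        households, buildings, zones, assignment=assignment, threshold=threshold
    )
    dens = density_layer(households, assignment, zones)
    return pd.DataFrame(
        {
            "zone_id": zones.ids,
            "old_raw": [old[z] for z in zones.ids],
            "ill_raw": [ill[z] for z in zones.ids],
            "flats_raw": [flats[z] for z in zones.ids],
            "density_raw": [dens[z] for z in zones.ids],
        }
    )
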