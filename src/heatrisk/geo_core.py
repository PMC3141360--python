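"""Planar geometry and raster primitives plus file I/O.

Everything works in a projected planar frame with coordinates in metres
(British-National-Grid-like). There is deliberately no geographic CRS
handling: the analysis operates on projected national-grid data and
planar geometry keeps areas and containment exact.

Conventions used throughout the package:

* Areas are reported in km^2 (shoelace area / 1e6), matching the
  household-density units of the analysis.
* Points exactly on a polygon boundary count as inside.
* When zones overlap (they should not for a real census geography), the
  zone earliest in file order wins; the rule makes assignment
  deterministic.
* Zonal statistics use cell-centre containment; a sliver zone covering
  no cell centre falls back to the value of the cell centre nearest to
  the zone centroid, so every zone always receives a value.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, Polygon, mapping, shape
from shapely.strtree import STRtree

from .errors import (
    CoverageError,
    EmptyRasterError,
    InvalidGeometryError,
    ValidationError,
)

logger = logging.getLogger("heatrisk")

MOSAIC_TYPE_MIN = 1
MOSAIC_TYPE_MAX = 67

HOUSEHOLD_COLUMNS = ["hh_id", "x", "y", "mosaic_type"]


# ---------------------------------------------------------------------------
# Geometry construction and validation
# ---------------------------------------------------------------------------

def make_polygon(
    exterior: Sequence[tuple[float, float]],
    holes: Sequence[Sequence[tuple[float, float]]] = (),
) -> Polygon:
    """Build a validated shapely polygon from coordinate rings.

    Raises
    ------
    InvalidGeometryError
        If the exterior ring has fewer than 3 distinct vertices or zero
        signed area.
    """
    distinct = {(float(x), float(y)) for x, y in exterior}
    if len(distinct) < 3:
        raise InvalidGeometryError(
            f"polygon exterior needs >= 3 distinct vertices, got {len(distinct)}"
        )
    poly = Polygon(exterior, holes=[list(h) for h in holes] or None)
    if poly.area == 0.0:
        raise InvalidGeometryError("polygon exterior has zero area")
    return poly


def _check_polygon(polygon: Polygon) -> Polygon:
    if not isinstance(polygon, Polygon) or polygon.is_empty:
        raise InvalidGeometryError("expected a non-empty Polygon")
    if len(polygon.exterior.coords) < 4:  # closed ring repeats first vertex
        raise InvalidGeometryError("polygon exterior needs >= 3 distinct vertices")
    return polygon


def polygon_area(polygon: Polygon) -> float:
    """Area of a polygon in km^2 (exterior minus holes)."""
    _check_polygon(polygon)
    return polygon.area / 1e6


def point_in_polygon(x: float, y: float, polygon: Polygon) -> bool:
    """Even-odd point membership; boundary points count as inside."""
    _check_polygon(polygon)
    return bool(polygon.intersects(Point(x, y)))


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass
class ZoneSet:
    """Identified zone polygons with derived areas.

    ``ids`` keeps file order, which is also the precedence order for
    point assignment when zones overlap.
    """

    ids: list[str]
    polygons: list[Polygon]
    area_km2: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.polygons):
            raise ValidationError("zone ids and polygons differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("zone ids are not unique")
        for zid, poly in zip(self.ids, self.polygons):
            try:
                _check_polygon(poly)
            except InvalidGeometryError as exc:
                raise InvalidGeometryError(f"zone {zid!r}: {exc}") from exc
        self.area_km2 = np.array([p.area / 1e6 for p in self.polygons])

    def __len__(self) -> int:
        return len(self.ids)

    def index_of(self, zone_id: str) -> int:
        return self.ids.index(zone_id)

    def centroids(self) -> np.ndarray:
        return np.array([[p.centroid.x, p.centroid.y] for p in self.polygons])


@dataclass
class HazardRaster:
    """Regular grid of UHI magnitude (deg C) with an Esri-ASCII-style header.

    ``values`` is (nrows, ncols) with row 0 the northernmost row, as the
    ASCII grid format stores it. Cells equal to ``nodata`` are masked in
    every statistic.
    """

    ncols: int
    nrows: int
    xllcorner: float
    yllcorner: float
    cellsize: float
    nodata: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.ncols <= 0 or self.nrows <= 0:
            raise ValidationError("raster dimensions must be positive")
        if self.cellsize <= 0:
            raise ValidationError("raster cellsize must be positive")
        if self.values.shape != (self.nrows, self.ncols):
            raise ValidationError(
                f"raster values shape {self.values.shape} does not match "
                f"(nrows, ncols)=({self.nrows}, {self.ncols})"
            )

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of every cell centre, same shape as values."""
        xs = self.xllcorner + (np.arange(self.ncols) + 0.5) * self.cellsize
        ys = self.yllcorner + (np.arange(self.nrows)[::-1] + 0.5) * self.cellsize
        return np.meshgrid(xs, ys)

    def mask(self) -> np.ndarray:
        """Boolean mask, True where the cell carries data."""
        return self.values != self.nodata

    def data_range(self) -> tuple[float, float]:
        valid = self.values[self.mask()]
        if valid.size == 0:
            raise EmptyRasterError("raster contains no non-nodata cell")
        return float(valid.min()), float(valid.max())


def make_household_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise a household table.

    Required columns: hh_id (unique), x, y (metres), mosaic_type (1-67).
    Duplicate (x, y) pairs are allowed — flats share coordinates.
    """
    missing = [c for c in HOUSEHOLD_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"household table missing columns: {missing}")
    df = df[HOUSEHOLD_COLUMNS].copy()
    if df["hh_id"].duplicated().any():
        dup = df.loc[df["hh_id"].duplicated(), "hh_id"].iloc[0]
        raise ValidationError(f"duplicate household id {dup!r}")
    types = df["mosaic_type"].to_numpy()
    bad = (types < MOSAIC_TYPE_MIN) | (types > MOSAIC_TYPE_MAX)
    if bad.any():
        first = int(np.argmax(bad))
        raise ValidationError(
            f"mosaic_type {types[first]} out of range "
            f"[{MOSAIC_TYPE_MIN}, {MOSAIC_TYPE_MAX}] at row {first}"
        )
    df["mosaic_type"] = df["mosaic_type"].astype(int)
    return df.reset_index(drop=True)


@dataclass
class BuildingSet:
    """Building footprint polygons with unique ids."""

    ids: list[str]
    polygons: list[Polygon]

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("building ids are not unique")
        for poly in self.polygons:
            _check_polygon(poly)

    def __len__(self) -> int:
        return len(self.ids)


# ---------------------------------------------------------------------------
# Spatial operations
# ---------------------------------------------------------------------------

@dataclass
class PointAssignment:
    """Result of assigning point records to zones.

    ``zone_ids`` aligns with the household table rows; unassigned points
    carry None. Conservation: assigned + unassigned == len(zone_ids).
    """

    zone_ids: list[str | None]
    unassigned: int

    @property
    def assigned(self) -> int:
        return len(self.zone_ids) - self.unassigned


def assign_points_to_zones(
    households: pd.DataFrame, zones: ZoneSet
) -> PointAssignment:
    """Map each household point to at most one zone.

    Boundary points are inside; overlapping zones are resolved in favour
    of the zone earliest in file order. Points in no zone are counted and
    reported as unassigned.
    """
    if len(zones) == 0:
        raise ValidationError("zone set is empty")
    pts = shapely.points(households["x"].to_numpy(), households["y"].to_numpy())
    tree = STRtree(zones.polygons)
    p_idx, z_idx = tree.query(pts, predicate="intersects")
    best = np.full(len(households), -1, dtype=int)
    # iterate descending zone index so the smallest (earliest file order) wins
    order = np.argsort(-z_idx, kind="stable")
    best[p_idx[order]] = z_idx[order]
    zone_ids: list[str | None] = [
        zones.ids[i] if i >= 0 else None for i in best
    ]
    unassigned = int(np.sum(best < 0))
    if unassigned:
        logger.warning("%d household point(s) fall outside every zone", unassigned)
    return PointAssignment(zone_ids=zone_ids, unassigned=unassigned)


def zonal_mean(raster: HazardRaster, zones: ZoneSet) -> dict[str, float]:
    """Mean of non-nodata cell values whose centre lies in each zone.

    A zone containing no cell centre receives the value of the non-nodata
    cell centre nearest to the zone centroid (sliver fallback, logged).
    """
    mask = raster.mask()
    if not mask.any():
        raise EmptyRasterError("raster contains no non-nodata cell")
    gx, gy = raster.cell_centres()
    cx, cy, cv = gx[mask], gy[mask], raster.values[mask]

    out: dict[str, float] = {}
    fallbacks = 0
    for zid, poly in zip(zones.ids, zones.polygons):
        minx, miny, maxx, maxy = poly.bounds
        cand = (cx >= minx) & (cx <= maxx) & (cy >= miny) & (cy <= maxy)
        if cand.any():
            inside = shapely.intersects_xy(poly, cx[cand], cy[cand])
        else:
            inside = np.zeros(0, dtype=bool)
        if inside.size and inside.any():
            out[zid] = float(cv[cand][inside].mean())
        else:
            c = poly.centroid
            nearest = int(np.argmin((cx - c.x) ** 2 + (cy - c.y) ** 2))
            out[zid] = float(cv[nearest])
            fallbacks += 1
    if fallbacks:
        logger.warning(
            "%d sliver zone(s) contained no cell centre; nearest-cell fallback used",
            fallbacks,
        )
    return out


def resample_bilinear(raster: HazardRaster, factor: int) -> HazardRaster:
    """Optional bilinear upsampling of the hazard raster.

    ``factor`` is an integer >= 1; the new cellsize is cellsize/factor.
    New cells whose enclosing original cell is nodata stay nodata. The
    default pipeline does not resample (factor 1 returns the input).
    """
    if factor < 1 or int(factor) != factor:
        raise ValidationError("resample factor must be a positive integer")
    if factor == 1:
        return raster
    from scipy.interpolate import RegularGridInterpolator

    vals = np.where(raster.mask(), raster.values, np.nan)
    rows = np.arange(raster.nrows) + 0.5
    cols = np.arange(raster.ncols) + 0.5
    interp = RegularGridInterpolator(
        (rows, cols), vals, method="linear", bounds_error=False, fill_value=None
    )
    n_r, n_c = raster.nrows * factor, raster.ncols * factor
    new_rows = (np.arange(n_r) + 0.5) / factor
    new_cols = (np.arange(n_c) + 0.5) / factor
    rr, cc = np.meshgrid(new_rows, new_cols, indexing="ij")
    new_vals = interp(np.stack([rr.ravel(), cc.ravel()], axis=1)).reshape(n_r, n_c)
    new_vals = np.where(np.isnan(new_vals), raster.nodata, new_vals)
    return HazardRaster(
        ncols=n_c,
        nrows=n_r,
        xllcorner=raster.xllcorner,
        yllcorner=raster.yllcorner,
        cellsize=raster.cellsize / factor,
        nodata=raster.nodata,
        values=new_vals,
    )


# ---------------------------------------------------------------------------
# File I/O: GeoJSON, Esri ASCII grid, CSV
# ---------------------------------------------------------------------------
# All numeric output is written with >= 9 significant digits so that a
# write/read round trip is stable to 1e-9 relative.

def _polygon_from_geojson(geom: dict, context: str) -> Polygon:
    try:
        poly = shape(geom)
    except Exception as exc:
        raise ValidationError(f"{context}: malformed geometry ({exc})") from exc
    if not isinstance(poly, Polygon):
        raise ValidationError(
            f"{context}: expected Polygon geometry, got {geom.get('type')}"
        )
    return _check_polygon(poly)


def read_zones(path: str | Path) -> ZoneSet:
    """Read a ZoneSet from GeoJSON; `zone_id` (or `id`) property required."""
    with open(path) as fh:
        try:
            gj = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValidationError(f"{path}: invalid JSON ({exc})") from exc
    ids, polys = [], []
    for i, feat in enumerate(gj.get("features", [])):
        props = feat.get("properties") or {}
        zid = props.get("zone_id", props.get("id"))
        if zid is None:
            raise ValidationError(f"{path}: feature {i} has no zone_id property")
        ids.append(str(zid))
        polys.append(_polygon_from_geojson(feat.get("geometry") or {}, f"feature {i}"))
    return ZoneSet(ids=ids, polygons=polys)


def write_zones(zones: ZoneSet, path: str | Path,
                extra: Mapping[str, Mapping[str, object]] | None = None) -> None:
    """Write a ZoneSet to GeoJSON; ``extra`` adds per-zone properties."""
    feats = []
    for zid, poly in zip(zones.ids, zones.polygons):
        props: dict[str, object] = {"zone_id": zid}
        if extra is not None:
            props.update(extra.get(zid, {}))
        feats.append(
            {"type": "Feature", "properties": props, "geometry": mapping(poly)}
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def read_buildings(path: str | Path) -> BuildingSet:
    with open(path) as fh:
        gj = json.load(fh)
    ids, polys = [], []
    for i, feat in enumerate(gj.get("features", [])):
        props = feat.get("properties") or {}
        bid = props.get("building_id", props.get("id", i))
        ids.append(str(bid))
        polys.append(_polygon_from_geojson(feat.get("geometry") or {}, f"feature {i}"))
    return BuildingSet(ids=ids, polygons=polys)


def write_buildings(buildings: BuildingSet, path: str | Path) -> None:
    feats = [
        {
            "type": "Feature",
            "properties": {"building_id": bid},
            "geometry": mapping(poly),
        }
        for bid, poly in zip(buildings.ids, buildings.polygons)
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def read_households(path: str | Path) -> pd.DataFrame:
    """Read the household CSV (`hh_id,x,y,mosaic_type`) with validation."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ValidationError(f"{path}: cannot parse CSV ({exc})") from exc
    try:
        return make_household_table(df)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_households(households: pd.DataFrame, path: str | Path) -> None:
    households[HOUSEHOLD_COLUMNS].to_csv(path, index=False, float_format="%.10g")


def read_raster(path: str | Path) -> HazardRaster:
    """Read an Esri ASCII grid (.asc)."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner",
                       "cellsize", "nodata_value"}:
                if len(parts) != 2:
                    raise ValidationError(f"{path}:{lineno}: malformed header line")
                header[key] = float(parts[1])
            else:
                try:
                    rows.append([float(v) for v in parts])
                except ValueError as exc:
                    raise ValidationError(
                        f"{path}:{lineno}: non-numeric cell value"
                    ) from exc
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise ValidationError(f"{path}: missing header field {req}")
    values = np.array([v for row in rows for v in row], dtype=float)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    if values.size != ncols * nrows:
        raise ValidationError(
            f"{path}: expected {ncols * nrows} cells, found {values.size}"
        )
    return HazardRaster(
        ncols=ncols,
        nrows=nrows,
        xllcorner=header["xllcorner"],
        yllcorner=header["yllcorner"],
        cellsize=header["cellsize"],
        nodata=header.get("nodata_value", -9999.0),
        values=values.reshape(nrows, ncols),
    )


def write_raster(raster: HazardRaster, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.ncols}\n")
        fh.write(f"nrows {raster.nrows}\n")
        fh.write(f"xllcorner {raster.xllcorner:.10g}\n")
        fh.write(f"yllcorner {raster.yllcorner:.10g}\n")
        fh.write(f"cellsize {raster.cellsize:.10g}\n")
        fh.write(f"NODATA_value {raster.nodata:.10g}\n")
        for row in raster.values:
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


LAYER_TABLE_COLUMNS = [
    "zone_id",
    "uhi_raw", "old_raw", "ill_raw", "flats_raw", "density_raw",
    "uhi_std", "old_std", "ill_std", "flats_std", "density_std",
    "vulnerability_std", "risk", "risk_class",
]


def write_layer_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write the per-zone layer table CSV in the documented column order."""
    cols = [c for c in LAYER_TABLE_COLUMNS if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    table[cols].to_csv(path, index=False, float_format="%.10g")


def read_layer_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "zone_id" not in df.columns:
        raise ValidationError(f"{path}: layer table missing zone_id column")
    df["zone_id"] = df["zone_id"].astype(str)
    return df


def write_risk_geojson(
    zones: ZoneSet, table: pd.DataFrame, path: str | Path
) -> None:
    """Write zones as GeoJSON with the layer-table columns as properties."""
    props = table.set_index("zone_id").to_dict("index")
    write_zones(zones, path, extra=props)
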