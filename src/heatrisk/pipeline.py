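"""End-to-end orchestration: hazard -> vulnerability -> standardize ->
combine -> classify -> stats -> profile.

`analyse` is the in-memory pipeline over typed inputs; `run_pipeline`
adds file I/O, logging and a run manifest (input/output hashes, config
snapshot, stage counts) so reruns on identical inputs are verifiably
identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import HeatriskError, ValidationError
from .geo_core import (
    BuildingSet,
    HazardRaster,
    PointAssignment,
    ZoneSet,
    assign_points_to_zones,
    read_buildings,
    read_households,
    read_layer_table,
    read_raster,
    read_zones,
    resample_bilinear,
    write_layer_table,
    write_risk_geojson,
)
from .hazard import compute_hazard_layer
from .profiling import MosaicProfile, profile_mosaic, select_zones_by_class
from .risk import (
    RiskClassification,
    RiskWeights,
    classify_risk,
    combine_layers,
    compute_risk,
    standardize,
)
from .stats import CorrelationMatrix, correlation_matrix, write_correlation_csv
from .vulnerability import (
    MosaicKey,
    compute_vulnerability_layers,
    load_mosaic_key,
)

logger = logging.getLogger("heatrisk")


@dataclass
class PipelineConfig:
    """Run options with the documented defaults (equal weights, k=5)."""

    weights: RiskWeights = field(default_factory=RiskWeights)
    classes_k: int = 5
    highrise_threshold: int = 10
    resample_factor: int = 1
    profile_label: str = "very high"
    profile_min_count: int = 1000
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d or {})
        w = d.get("weights", {})
        vw = w.get("vulnerability", {})
        rw = w.get("risk", {})
        weights = RiskWeights(
            old=vw.get("old", 0.25),
            ill=vw.get("ill", 0.25),
            flats=vw.get("flats", 0.25),
            density=vw.get("density", 0.25),
            hazard=rw.get("hazard", 0.5),
            vulnerability=rw.get("vulnerability", 0.5),
        )
        return cls(
            weights=weights,
            classes_k=int(d.get("classes", {}).get("k", 5)),
            highrise_threshold=int(d.get("highrise", {}).get("threshold", 10)),
            resample_factor=int(d.get("resample", {}).get("factor", 1)),
            profile_label=d.get("profile", {}).get("label", "very high"),
            profile_min_count=int(d.get("profile", {}).get("min_count", 1000)),
            seed=int(d.get("seed", 0)),
        )


@dataclass
class AnalysisResult:
    table: pd.DataFrame
    classification: RiskClassification
    assignment: PointAssignment
    matrix: CorrelationMatrix
    profile: MosaicProfile


def analyse(
    zones: ZoneSet,
    raster: HazardRaster,
    households: pd.DataFrame,
    buildings: BuildingSet,
    key: MosaicKey | None = None,
    config: PipelineConfig | None = None,
) -> AnalysisResult:
    """Run the full risk assessment on in-memory inputs."""
    cfg = config or PipelineConfig()
    if cfg.resample_factor > 1:
        raster = resample_bilinear(raster, cfg.resample_factor)

    hazard = compute_hazard_layer(raster, zones)
    assignment = assign_points_to_zones(households, zones)
    table = compute_vulnerability_layers(
        households, assignment, buildings, zones,
        key=key, threshold=cfg.highrise_threshold,
    )
    table.insert(1, "uhi_raw", [hazard[z] for z in zones.ids])

    for layer in ("uhi", "old", "ill", "flats", "density"):
        table[f"{layer}_std"] = standardize(table[f"{layer}_raw"], layer)

    w = cfg.weights
    table["vulnerability_std"] = combine_layers(
        [table["old_std"], table["ill_std"], table["flats_std"],
         table["density_std"]],
        [w.old, w.ill, w.flats, w.density],
    )
    table["risk"] = compute_risk(
        table["uhi_std"], table["vulnerability_std"], [w.hazard, w.vulnerability]
    )

    classification = classify_risk(zones.ids, table["risk"].to_numpy(), cfg.classes_k)
    table["risk_class"] = classification.labels

    matrix = correlation_matrix(table)
    selected = select_zones_by_class(classification, cfg.profile_label)
    profile = profile_mosaic(
        households, assignment, selected, min_count=cfg.profile_min_count
    )
    return AnalysisResult(
        table=table, classification=classification, assignment=assignment,
        matrix=matrix, profile=profile,
    )


def run_stats_only(layer_table_path: str | Path) -> CorrelationMatrix:
    """Recompute the correlation matrix from a saved layer table CSV."""
    table = read_layer_table(layer_table_path)
    return correlation_matrix(table)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    zones_path: str | Path,
    raster_path: str | Path,
    households_path: str | Path,
    buildings_path: str | Path,
    out_dir: str | Path,
    key_path: str | Path | None = None,
    config: PipelineConfig | None = None,
) -> dict:
    """File-driven pipeline; writes the four outputs plus manifest.json.

    Returns the manifest. Reruns on identical inputs produce identical
    outputs (no hidden randomness outside the generator).
    """
    cfg = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    inputs = {
        "zones": Path(zones_path),
        "raster": Path(raster_path),
        "households": Path(households_path),
        "buildings": Path(buildings_path),
    }
    if key_path is not None:
        inputs["mosaic_key"] = Path(key_path)
    for name, p in inputs.items():
        if not p.exists():
            raise ValidationError(f"{name} file not found: {p}")

    zones = read_zones(inputs["zones"])
    raster = read_raster(inputs["raster"])
    households = read_households(inputs["households"])
    buildings = read_buildings(inputs["buildings"])
    key = load_mosaic_key(key_path)

    result = analyse(zones, raster, households, buildings, key=key, config=cfg)

    layers_csv = out / "layers.csv"
    risk_geojson = out / "risk.geojson"
    corr_csv = out / "correlations.csv"
    profile_csv = out / "profile.csv"
    write_layer_table(result.table, layers_csv)
    write_risk_geojson(zones, result.table, risk_geojson)
    write_correlation_csv(result.matrix, corr_csv)
    result.profile.to_frame().to_csv(profile_csv, index=False)

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config": {
            "weights": {
                "vulnerability": {
                    "old": cfg.weights.old, "ill": cfg.weights.ill,
                    "flats": cfg.weights.flats, "density": cfg.weights.density,
                },
                "risk": {
                    "hazard": cfg.weights.hazard,
                    "vulnerability": cfg.weights.vulnerability,
                },
            },
            "classes": {"k": cfg.classes_k},
            "highrise": {"threshold": cfg.highrise_threshold},
            "resample": {"factor": cfg.resample_factor},
            "profile": {"label": cfg.profile_label,
                        "min_count": cfg.profile_min_count},
        },
        "inputs": {name: _sha256(p) for name, p in inputs.items()},
        "counts": {
            "zones": len(zones),
            "households": len(households),
            "assigned": result.assignment.assigned,
            "unassigned": result.assignment.unassigned,
            "buildings": len(buildings),
            "selected_zones": len(result.profile.selected_zones),
            "selected_households": result.profile.selected_households,
        },
        "share_pct": result.profile.share_pct,
        "outputs": {},
    }
    for p in (layers_csv, risk_geojson, corr_csv, profile_csv):
        manifest["outputs"][p.name] = _sha256(p)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete: %s", result.profile.summary())
    return manifest
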