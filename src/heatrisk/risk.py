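"""Standardization, weighted overlay and natural-breaks classification.

The risk model follows Crichton's risk triangle: risk exists where a
hazard (the urban heat island), exposure (households) and vulnerability
(elderly, ill health, high-rise living, density) are spatially
coincident. Per zone:

1. each raw layer is standardized HDI-style — zone value divided by the
   study-area maximum — giving a [0, 1] score with max exactly 1;
2. the four vulnerability layers are combined by a weighted sum
   (defaults 25% each) into a single "exposed and vulnerable" score;
3. that score is combined with the standardized hazard (defaults 50/50)
   into the final risk score;
4. risk scores are classified into k ordinal classes (default 5,
   "very low" ... "very high") by exact Fisher-Jenks natural breaks.

Negative raw values (zones cooler than the UHI reference) are floored to
zero before the max-division so the standardized scale keeps its stated
[0, 1] range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DegenerateLayerError

_WEIGHT_TOL = 1e-9

CLASS_LABELS_5 = ["very low", "low", "medium", "high", "very high"]


def class_labels(k: int) -> list[str]:
    """Ordinal labels for k classes, ascending risk."""
    schemes = {
        1: ["medium"],
        2: ["low", "high"],
        3: ["low", "medium", "high"],
        4: ["very low", "low", "high", "very high"],
        5: CLASS_LABELS_5,
    }
    if k in schemes:
        return schemes[k]
    return [f"class {i}" for i in range(1, k + 1)]


@dataclass
class RiskWeights:
    """Overlay weights; each group must sum to 1."""

    old: float = 0.25
    ill: float = 0.25
    flats: float = 0.25
    density: float = 0.25
    hazard: float = 0.5
    vulnerability: float = 0.5

    def __post_init__(self) -> None:
        for name in ("old", "ill", "flats", "density", "hazard", "vulnerability"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"weight {name} must be >= 0")
        v = self.old + self.ill + self.flats + self.density
        if abs(v - 1.0) > _WEIGHT_TOL:
            raise ConfigurationError(f"vulnerability weights sum to {v}, expected 1")
        t = self.hazard + self.vulnerability
        if abs(t - 1.0) > _WEIGHT_TOL:
            raise ConfigurationError(f"top-level weights sum to {t}, expected 1")


def standardize(values, layer: str = "layer") -> np.ndarray:
    """Standardize a per-zone layer to [0, 1] by study-area maximum.

    Negative values are floored to 0 first; each value is then divided
    by the maximum across the study area, so the output max is exactly 1.
    """
    arr = np.asarray(values, dtype=float)
    floored = np.maximum(arr, 0.0)
    peak = floored.max() if floored.size else 0.0
    if peak <= 0.0:
        raise DegenerateLayerError(
            f"layer {layer!r} has no positive value; cannot standardize"
        )
    return floored / peak


def combine_layers(columns, weights) -> np.ndarray:
    """Weighted sum of standardized layers; stays in [0, 1]."""
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ConfigurationError("weights must be >= 0")
    if abs(w.sum() - 1.0) > _WEIGHT_TOL:
        raise ConfigurationError(f"weights sum to {w.sum()}, expected 1")
    cols = np.column_stack([np.asarray(c, dtype=float) for c in columns])
    if cols.shape[1] != w.size:
        raise ConfigurationError(
            f"{cols.shape[1]} layers but {w.size} weights"
        )
    if cols.min() < 0.0 or cols.max() > 1.0:
        raise ConfigurationError("combine_layers inputs must lie in [0, 1]")
    return cols @ w


def compute_risk(hazard_std, vulnerability_std, weights=(0.5, 0.5)) -> np.ndarray:
    """Final risk score: weighted overlay of hazard and vulnerability."""
    return combine_layers([hazard_std, vulnerability_std], weights)


# ---------------------------------------------------------------------------
# Exact Fisher-Jenks natural breaks
# ---------------------------------------------------------------------------

def _class_cost_matrix(v: np.ndarray, w: np.ndarray) -> np.ndarray:
    """cost[i, j] = weighted SSD of distinct values v[i..j] about their mean."""
    m = v.size
    cw = np.concatenate([[0.0], np.cumsum(w)])
    cwv = np.concatenate([[0.0], np.cumsum(w * v)])
    cwv2 = np.concatenate([[0.0], np.cumsum(w * v * v)])
    cost = np.full((m, m), np.inf)
    for i in range(m):
        n = cw[i + 1:] - cw[i]
        s = cwv[i + 1:] - cwv[i]
        s2 = cwv2[i + 1:] - cwv2[i]
        cost[i, i:] = np.maximum(s2 - s * s / n, 0.0)
    return cost


def jenks_breaks(values, k: int):
    """Optimal k-class partition of 1-D values minimizing within-class SSD.

    Dynamic programming over the sorted distinct values, so tied values
    are never split across classes. Among partitions with equal total
    SSD, the one whose first class is smallest wins (then the second,
    and so on), which makes the output deterministic.

    Returns
    -------
    breaks : list of float
        Ascending upper bound (maximum member) of each class; the last
        break is the data maximum.
    classes : np.ndarray of int
        0-based class index per input value, in input order.
    """
    arr = np.asarray(values, dtype=float)
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    if arr.size == 0:
        raise ConfigurationError("cannot classify an empty value set")
    distinct, counts = np.unique(arr, return_counts=True)
    m = distinct.size
    if k > m:
        raise ConfigurationError(
            f"k={k} exceeds the {m} distinct value(s) available"
        )
    cost = _class_cost_matrix(distinct, counts.astype(float))

    # suffix DP: best[i, c] = optimal SSD partitioning distinct[i:] into c classes
    best = np.full((m + 1, k + 1), np.inf)
    best[m, 0] = 0.0
    for c in range(1, k + 1):
        for i in range(m - 1, -1, -1):
            # class starting at i must leave >= c-1 distinct values after it
            ends = np.arange(i, m - (c - 1))
            if ends.size == 0:
                continue
            totals = cost[i, ends] + best[ends + 1, c - 1]
            best[i, c] = totals.min()

    # front-greedy reconstruction: earliest end index achieving the optimum
    # gives the lexicographically smallest class sizes
    breaks: list[float] = []
    classes_of_distinct = np.empty(m, dtype=int)
    i = 0
    for c in range(k, 0, -1):
        ends = np.arange(i, m - (c - 1))
        totals = cost[i, ends] + best[ends + 1, c - 1]
        end = int(ends[int(np.argmin(totals))])  # argmin takes first on ties
        classes_of_distinct[i : end + 1] = k - c
        breaks.append(float(distinct[end]))
        i = end + 1

    lookup = dict(zip(distinct.tolist(), classes_of_distinct.tolist()))
    classes = np.array([lookup[v] for v in arr.tolist()], dtype=int)
    return breaks, classes


@dataclass
class RiskClassification:
    """Per-zone ordinal risk class from Jenks breaks."""

    zone_ids: list[str]
    class_index: np.ndarray  # 1-based, ascending risk
    labels: list[str]  # per zone
    breaks: list[float]  # ascending upper bounds, one per class
    label_order: list[str] = field(default_factory=list)  # ascending classes

    def zones_with_label(self, label: str) -> list[str]:
        if label not in self.label_order:
            raise ConfigurationError(
                f"unknown class label {label!r}; valid: {self.label_order}"
            )
        return [z for z, lab in zip(self.zone_ids, self.labels) if lab == label]


def classify_risk(zone_ids, risk, k: int = 5) -> RiskClassification:
    """Label zones "very low" ... "very high" by Jenks class of risk score."""
    breaks, classes = jenks_breaks(risk, k)
    order = class_labels(k)
    return RiskClassification(
        zone_ids=list(zone_ids),
        class_index=classes + 1,
        labels=[order[c] for c in classes],
        breaks=breaks,
        label_order=order,
    )
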