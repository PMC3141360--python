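"""Household-level drill-down inside selected risk classes.

Once zones are classified, the households inside a class of interest
(typically "very high") are profiled by their geodemographic (Mosaic)
type: exact counts per type, plus the share of the whole study area's
households that fall in the selected zones. Reporting filters (count >
min_count, default 1000) apply to the report only; the full table is
retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import DegenerateDataError
from .geo_core import PointAssignment
from .risk import RiskClassification


def select_zones_by_class(
    classification: RiskClassification, label: str
) -> list[str]:
    """All and only the zone ids carrying the given class label."""
    return classification.zones_with_label(label)


@dataclass
class MosaicProfile:
    """Per-type household counts within the selected zones."""

    counts: pd.Series  # mosaic_type -> count, full table
    selected_zones: list[str]
    selected_households: int
    total_households: int
    min_count: int

    @property
    def share_pct(self) -> float:
        return share_of_households(self.selected_households, self.total_households)

    def report(self) -> pd.Series:
        """Counts filtered to those strictly above min_count."""
        return self.counts[self.counts > self.min_count]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mosaic_type": self.counts.index,
                "count": self.counts.to_numpy(),
                "in_report": (self.counts > self.min_count).to_numpy().astype(int),
            }
        )

    def summary(self) -> str:
        return (
            f"{len(self.selected_zones)} zones selected; "
            f"{self.selected_households} of {self.total_households} households "
            f"({self.share_pct:.2f}%)"
        )


def profile_mosaic(
    households: pd.DataFrame,
    assignment: PointAssignment,
    zone_ids,
    min_count: int = 1000,
) -> MosaicProfile:
    """Profile households of the selected zones by Mosaic type."""
    selected = set(zone_ids)
    in_sel = pd.Series(
        [z is not None and z in selected for z in assignment.zone_ids],
        index=households.index,
    )
    sub = households.loc[in_sel, "mosaic_type"]
    counts = sub.value_counts().sort_index()
    counts.index.name = "mosaic_type"
    return MosaicProfile(
        counts=counts,
        selected_zones=sorted(selected),
        selected_households=int(in_sel.sum()),
        total_households=len(households),
        min_count=min_count,
    )


def share_of_households(selected_count: int, total_count: int) -> float:
    """Percentage of study-area households selected, 2-decimal rounded."""
    if total_count <= 0:
        raise DegenerateDataError("total household count must be positive")
    if not 0 <= selected_count <= total_count:
        raise DegenerateDataError(
            f"selected count {selected_count} outside [0, {total_count}]"
        )
    return round(100.0 * selected_count / total_count, 2)
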