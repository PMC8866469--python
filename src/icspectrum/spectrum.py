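"""Per-eye summary of the intercapillary space spectrum.

After FAZ exclusion, an eye is reduced to the quantities analysed at the
cohort level: total space count, arithmetic means of the four
morphometric parameters, counts of spaces above fixed area thresholds
(0.01-0.05 mm^2), and the count of spaces with area/perimeter ratio
above 0.025.  All threshold counts use strict inequality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import pandas as pd

from .morphometry import SpaceTable

__all__ = [
    "GRADES",
    "EyeSpectrum",
    "summarize_eye",
    "count_above_area",
    "count_ap_above",
]

#: DR severity scale, mildest to most severe.
GRADES = (
    "nondiabetic",
    "no_apparent",
    "mild_npdr",
    "moderate_npdr",
    "severe_npdr",
    "pdr",
)

AREA_THRESHOLDS_MM2 = (0.01, 0.02, 0.03, 0.04, 0.05)
AP_RATIO_THRESHOLD = 0.025


@dataclass
class EyeSpectrum:
    """Spectrum summary of one eye (FAZ excluded from every statistic)."""

    eye_id: str
    grade: Optional[str]
    total_count: int
    mean_area_mm2: float
    mean_perimeter_mm: float
    mean_min_diameter_mm: float
    mean_max_diameter_mm: float
    counts_above_area: Dict[float, int]
    count_ap_above: int
    faz_area_mm2: float

    def __post_init__(self) -> None:
        if self.grade is not None and self.grade not in GRADES:
            raise ValueError(f"unknown severity grade {self.grade!r}")
        thresholds = sorted(self.counts_above_area)
        counts = [self.counts_above_area[t] for t in thresholds]
        if any(c > self.total_count or c < 0 for c in counts):
            raise ValueError("thresholded counts must lie in [0, total_count]")
        if any(a < b for a, b in zip(counts, counts[1:])):
            raise ValueError("counts_above_area must be non-increasing in threshold")

    def to_row(self) -> dict:
        row = {
            "eye_id": self.eye_id,
            "grade": self.grade,
            "total_count": self.total_count,
            "mean_area_mm2": self.mean_area_mm2,
            "mean_perimeter_mm": self.mean_perimeter_mm,
            "mean_min_diameter_mm": self.mean_min_diameter_mm,
            "mean_max_diameter_mm": self.mean_max_diameter_mm,
            "count_ap_above_0.025": self.count_ap_above,
            "faz_area_mm2": self.faz_area_mm2,
        }
        for t, c in sorted(self.counts_above_area.items()):
            row[f"count_area_above_{t:g}"] = c
        return row


def _non_faz(table: SpaceTable) -> pd.DataFrame:
    return table.regions[~table.regions["is_faz"]]


def count_above_area(table: SpaceTable, threshold_mm2: float) -> int:
    """Number of non-FAZ spaces with area strictly greater than threshold."""
    if threshold_mm2 <= 0:
        raise ValueError("area threshold must be positive")
    return int((_non_faz(table)["area_mm2"] > threshold_mm2).sum())


def count_ap_above(table: SpaceTable, threshold: float = AP_RATIO_THRESHOLD) -> int:
    """Number of non-FAZ spaces with area/perimeter ratio > threshold.

    The ratio carries units of mm but is conventionally reported as A.U.;
    for a disk of radius r it tends to r/2, so the 0.025 default flags
    smooth spaces wider than ~0.1 mm.
    """
    if threshold <= 0:
        raise ValueError("ratio threshold must be positive")
    return int((_non_faz(table)["ap_ratio"] > threshold).sum())


def summarize_eye(
    table: SpaceTable,
    grade: Optional[str] = None,
    area_thresholds: Sequence[float] = AREA_THRESHOLDS_MM2,
    ap_threshold: float = AP_RATIO_THRESHOLD,
) -> EyeSpectrum:
    """Reduce a SpaceTable to its per-eye spectrum summary.

    The FAZ row is excluded from every statistic; means are arithmetic
    means over the remaining regions and are NaN when no space remains.
    """
    df = _non_faz(table)
    faz = table.faz_row()
    n = len(df)
    mean = lambda col: float(df[col].mean()) if n else math.nan  # noqa: E731
    return EyeSpectrum(
        eye_id=table.eye_id,
        grade=grade,
        total_count=n,
        mean_area_mm2=mean("area_mm2"),
        mean_perimeter_mm=mean("perimeter_mm"),
        mean_min_diameter_mm=mean("min_diam_mm"),
        mean_max_diameter_mm=mean("max_diam_mm"),
        counts_above_area={
            float(t): count_above_area(table, float(t)) for t in area_thresholds
        },
        count_ap_above=count_ap_above(table, ap_threshold),
        faz_area_mm2=float(faz["area_mm2"]) if faz is not None else math.nan,
    )
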