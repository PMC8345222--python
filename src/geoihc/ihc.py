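"""Per-ROI staining metrics: intensity breakdowns, H-score, positivity, density.

The H-score collapses an ROI's intensity distribution into one number,
H = 1*(%weak) + 2*(%moderate) + 3*(%strong), ranging 0 (no staining) to 300
(every cell strong).  Percentages are over all detected cells of the
marker's slide; one stain is applied per adjacent slide, so each marker has
its own denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .types import Intensity, Marker, ROI

#: Positivity rules: 'any_stain' counts weak+moderate+strong, 'strong_only'
#: counts strong cells (the rule used for spatial analysis).
POSITIVITY_RULES = ("any_stain", "strong_only")


@dataclass
class IntensityBreakdown:
    """Counts and percentages of a marker's cells per intensity bin."""

    marker: Marker
    counts: dict[str, int]          # bin label -> count
    total: int

    @property
    def percentages(self) -> Optional[dict[str, float]]:
        if self.total == 0:
            return None
        return {k: 100.0 * v / self.total for k, v in self.counts.items()}

    @property
    def defined(self) -> bool:
        return self.total > 0


@dataclass
class MarkerMetrics:
    marker: Marker
    n_cells: int
    density: float              # positive cells / mm²
    percent_positivity: float   # %
    h_score: float              # 0-300
    positivity_rule: str


def intensity_breakdown(roi: ROI, marker: Marker) -> IntensityBreakdown:
    """Tally the marker's cells in the ROI into the four intensity bins."""
    sub = roi.marker_cells(marker)
    counts = {i.value: int((sub["intensity"] == i.value).sum()) for i in Intensity}
    return IntensityBreakdown(marker=marker, counts=counts, total=len(sub))


def h_score(b: IntensityBreakdown) -> float:
    """H = 1*(%weak) + 2*(%moderate) + 3*(%strong); NaN when no cells."""
    pct = b.percentages
    if pct is None:
        return math.nan
    return (1.0 * pct[Intensity.WEAK.value]
            + 2.0 * pct[Intensity.MODERATE.value]
            + 3.0 * pct[Intensity.STRONG.value])


def percent_positivity(b: IntensityBreakdown, rule: str = "any_stain") -> float:
    """Percentage of the marker's cells counted positive under ``rule``."""
    if rule not in POSITIVITY_RULES:
        raise ValueError(f"unknown positivity rule {rule!r}")
    pct = b.percentages
    if pct is None:
        return math.nan
    if rule == "strong_only":
        return pct[Intensity.STRONG.value]
    return (pct[Intensity.WEAK.value] + pct[Intensity.MODERATE.value]
            + pct[Intensity.STRONG.value])


def positive_count(b: IntensityBreakdown, rule: str = "any_stain") -> int:
    if rule not in POSITIVITY_RULES:
        raise ValueError(f"unknown positivity rule {rule!r}")
    if rule == "strong_only":
        return b.counts[Intensity.STRONG.value]
    return b.total - b.counts[Intensity.NEGATIVE.value]


def cell_density(roi: ROI, marker: Marker, rule: str = "any_stain") -> float:
    """Positive cells of the marker per mm² of window area."""
    b = intensity_breakdown(roi, marker)
    return positive_count(b, rule) / roi.window.area_mm2


def marker_metrics(roi: ROI, marker: Marker, rule: str = "any_stain") -> MarkerMetrics:
    b = intensity_breakdown(roi, marker)
    return MarkerMetrics(marker=marker, n_cells=b.total,
                         density=positive_count(b, rule) / roi.window.area_mm2,
                         percent_positivity=percent_positivity(b, rule),
                         h_score=h_score(b), positivity_rule=rule)


def roi_metric_table(rois: list[ROI], rule: str = "any_stain") -> pd.DataFrame:
    """Long-format per-ROI, per-marker staining metrics.

    Columns: patient_id, roi_id, marker, n_cells, per-bin counts and
    percentages, h_score, percent_positivity, density, positivity_rule.
    """
    rows = []
    for roi in rois:
        for marker in Marker:
            b = intensity_breakdown(roi, marker)
            pct = b.percentages or {i.value: math.nan for i in Intensity}
            rows.append({
                "patient_id": roi.patient_id,
                "roi_id": roi.roi_id,
                "marker": marker.value,
                "n_cells": b.total,
                **{f"n_{k}": v for k, v in b.counts.items()},
                **{f"pct_{k}": pct[k] for k in pct},
                "h_score": h_score(b),
                "percent_positivity": percent_positivity(b, rule),
                "density": positive_count(b, rule) / roi.window.area_mm2,
                "positivity_rule": rule,
            })
    return pd.DataFrame(rows)
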