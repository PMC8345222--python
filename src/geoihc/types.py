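"""Core domain types for geospatial immunohistochemistry analysis.

The unit of observation is a rectangular region of interest (ROI) cut from a
digitized, IHC-stained tumor slide.  Cell detection (performed upstream,
outside this package) yields one row per cell: the Cartesian coordinates of
its center of mass, the stain on its slide (one marker per adjacent slide),
and the staining-intensity bin assigned by the image analyst.  All geometry
in this package is in micrometres, with the ROI origin at one corner and the
window axis-aligned.  Input files may carry pixel coordinates, which are
converted on read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Optional

import numpy as np
import pandas as pd


class Marker(str, Enum):
    """IHC markers: activated fibroblasts (CAFs), proliferating cells, apoptotic cells."""

    ASMA = "aSMA"
    KI67 = "Ki67"
    CASP3 = "Casp3"


class Intensity(str, Enum):
    """Staining-intensity bins, the digital analogue of the pathologist's 0/1+/2+/3+."""

    NEGATIVE = "negative"
    WEAK = "weak"
    MODERATE = "moderate"
    STRONG = "strong"


MARKERS = tuple(Marker)
INTENSITIES = tuple(Intensity)

#: Default scanner resolution (µm per pixel) of the digitized slides.
DEFAULT_PIXEL_SIZE = 0.502
#: Default standardized ROI size in pixels (width, height).
DEFAULT_WINDOW_PX = (3426, 1379)


@dataclass(frozen=True)
class Window:
    """Axis-aligned rectangular observation window with origin at (0, 0).

    Parameters
    ----------
    width, height : float
        Side lengths in µm.  Both must be positive.
    """

    width: float
    height: float

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise ValueError(f"window sides must be positive, got {self.width} x {self.height}")

    @property
    def area(self) -> float:
        """Window area in µm²."""
        return self.width * self.height

    @property
    def area_mm2(self) -> float:
        """Window area in mm²."""
        return self.area / 1e6

    @classmethod
    def from_pixels(cls, width_px: float, height_px: float,
                    pixel_size: float = DEFAULT_PIXEL_SIZE) -> "Window":
        if pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        return cls(width_px * pixel_size, height_px * pixel_size)

    def contains(self, x, y) -> np.ndarray:
        """Vectorized closed-rectangle membership test."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= 0) & (x <= self.width) & (y >= 0) & (y <= self.height)


def default_window(pixel_size: float = DEFAULT_PIXEL_SIZE) -> Window:
    """The standardized ROI window (3426 x 1379 px) converted to µm."""
    return Window.from_pixels(*DEFAULT_WINDOW_PX, pixel_size=pixel_size)


@dataclass(frozen=True)
class MarkedCell:
    """One detected cell: position (µm), marker, and intensity bin."""

    x: float
    y: float
    marker: Marker
    intensity: Intensity

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"cell coordinates must be finite, got ({self.x}, {self.y})")


#: Column order of the tabular cell representation used throughout.
CELL_COLUMNS = ("x", "y", "marker", "intensity")


@dataclass
class ROI:
    """A region of interest: a window plus the cells detected inside it.

    Cells are held as a DataFrame with columns ``x, y, marker, intensity``
    (coordinates in µm); this is the fast path for metric computation.  Use
    :meth:`iter_cells` for typed access.
    """

    patient_id: str
    roi_id: str
    window: Window
    cells: pd.DataFrame
    pixel_size: float = DEFAULT_PIXEL_SIZE

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        missing = [c for c in CELL_COLUMNS if c not in self.cells.columns]
        if missing:
            raise ValueError(f"cells table missing columns {missing}")
        if len(self.cells):
            inside = self.window.contains(self.cells["x"].to_numpy(),
                                          self.cells["y"].to_numpy())
            if not inside.all():
                bad = int(np.flatnonzero(~inside)[0])
                row = self.cells.iloc[bad]
                raise ValueError(
                    f"cell outside window in ROI {self.patient_id}/{self.roi_id}: "
                    f"row {self.cells.index[bad]} at ({row['x']:.3f}, {row['y']:.3f}) µm, "
                    f"window {self.window.width:.2f} x {self.window.height:.2f} µm"
                )

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def iter_cells(self) -> Iterator[MarkedCell]:
        for row in self.cells.itertuples(index=False):
            yield MarkedCell(row.x, row.y, Marker(row.marker), Intensity(row.intensity))

    def marker_cells(self, marker: Marker) -> pd.DataFrame:
        return self.cells[self.cells["marker"] == marker.value]

    def point_pattern(self, marker: Marker,
                      intensities: Optional[tuple[Intensity, ...]] = None) -> "PointPattern":
        """Extract the point pattern of a marker, optionally restricted to bins."""
        sub = self.marker_cells(marker)
        if intensities is not None:
            labels = {i.value for i in intensities}
            sub = sub[sub["intensity"].isin(labels)]
        pts = sub[["x", "y"]].to_numpy(dtype=float)
        return PointPattern(points=pts, window=self.window, marker=marker)


@dataclass
class PointPattern:
    """Positive cells of one marker inside a window; the unit of spatial analysis."""

    points: np.ndarray  # (n, 2) array of µm coordinates
    window: Window
    marker: Marker

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if len(self.points):
            if not self.window.contains(self.points[:, 0], self.points[:, 1]).all():
                raise ValueError("point pattern contains points outside its window")

    @property
    def n(self) -> int:
        return len(self.points)


@dataclass
class ClinicalRecord:
    """Per-patient demographics, risk category, endpoints, and therapy exposure.

    Times are months; therapy start offsets are months from diagnosis (dates
    arrive pre-differenced).  ``first_line`` is 'IT', 'TT', or 'both'.
    """

    patient_id: str
    age: float
    imdc: str  # favorable / intermediate / poor / indeterminate
    os_months: float
    os_event: int
    first_line: Optional[str] = None
    it_start_offset_months: Optional[float] = None
    tt_start_offset_months: Optional[float] = None
    pfs_first_line_months: Optional[float] = None

    IMDC_LEVELS = ("favorable", "intermediate", "poor", "indeterminate")

    def __post_init__(self) -> None:
        if self.os_months < 0:
            raise ValueError("os_months must be >= 0")
        if self.os_event not in (0, 1):
            raise ValueError("os_event must be 0 or 1")
        if self.imdc not in self.IMDC_LEVELS:
            raise ValueError(f"unknown IMDC category {self.imdc!r}")
        for name in ("it_start_offset_months", "tt_start_offset_months",
                     "pfs_first_line_months"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")
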