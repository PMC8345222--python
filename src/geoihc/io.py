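"""Tabular readers and writers for cell-coordinate and clinical tables.

Cell tables are CSV/TSV with a header and columns ``patient_id, roi_id, x,
y, marker, intensity``.  Coordinates may be in pixels (converted to µm with
the declared pixel size) or already in µm.  The image convention (origin
top-left, y downward) is accepted as-is: every statistic downstream is
reflection-invariant, so no axis flip is performed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .types import (DEFAULT_PIXEL_SIZE, Intensity, Marker, ROI, Window,
                    default_window, ClinicalRecord)

log = logging.getLogger(__name__)

CELL_FILE_COLUMNS = ["patient_id", "roi_id", "x", "y", "marker", "intensity"]

_VALID_MARKERS = {m.value for m in Marker}
_VALID_INTENSITIES = {i.value for i in Intensity}


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    return pd.read_csv(path, sep=sep)


def read_cells(path: str | Path, pixel_size: float = DEFAULT_PIXEL_SIZE,
               units: str = "px", window: Optional[Window] = None) -> list[ROI]:
    """Read a cell table and group rows into ROI objects.

    Parameters
    ----------
    path : str or Path
        CSV (or TSV) file with columns ``patient_id, roi_id, x, y, marker,
        intensity``.
    pixel_size : float
        µm per pixel, used when ``units == 'px'``.
    units : {'px', 'µm', 'um'}
        Units of the x/y columns in the file.
    window : Window, optional
        Observation window in µm shared by all ROIs.  When absent, the
        default standardized ROI window is used if all cells fit in it,
        otherwise the per-file max extent.

    Rows with unrecognized marker or intensity labels are dropped (counted
    in the log); a cell outside the declared window raises, naming the row.
    """
    if units not in ("px", "µm", "um"):
        raise ValueError(f"units must be 'px' or 'µm', got {units!r}")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    df = _read_table(path)
    missing = [c for c in CELL_FILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cell table {path} missing columns {missing}")
    if df.empty:
        log.warning("cell table %s is empty; no ROIs read", path)
        return []

    ok = df["marker"].isin(_VALID_MARKERS) & df["intensity"].isin(_VALID_INTENSITIES)
    n_bad = int((~ok).sum())
    if n_bad:
        log.warning("dropped %d rows with unknown marker/intensity labels from %s",
                    n_bad, path)
        df = df[ok]
    if df.empty:
        return []

    df = df.copy()
    if units == "px":
        df["x"] = df["x"].astype(float) * pixel_size
        df["y"] = df["y"].astype(float) * pixel_size
    else:
        df["x"] = df["x"].astype(float)
        df["y"] = df["y"].astype(float)

    if window is None:
        win = default_window(pixel_size)
        if not win.contains(df["x"].to_numpy(), df["y"].to_numpy()).all():
            win = Window(float(df["x"].max()), float(df["y"].max()))
            log.info("cells exceed the default window; inferred window "
                     "%.2f x %.2f µm from max extent", win.width, win.height)
    else:
        win = window

    rois = []
    for (pid, rid), grp in df.groupby(["patient_id", "roi_id"], sort=True):
        cells = grp[["x", "y", "marker", "intensity"]].reset_index(drop=True)
        rois.append(ROI(patient_id=str(pid), roi_id=str(rid), window=win,
                        cells=cells, pixel_size=pixel_size))
    return rois


def write_cells(rois: list[ROI], path: str | Path) -> None:
    """Write ROIs back to a cell table (coordinates in µm)."""
    frames = []
    for roi in rois:
        out = roi.cells.copy()
        out.insert(0, "roi_id", roi.roi_id)
        out.insert(0, "patient_id", roi.patient_id)
        frames.append(out)
    if frames:
        table = pd.concat(frames, ignore_index=True)
    else:
        table = pd.DataFrame(columns=CELL_FILE_COLUMNS)
    table.to_csv(path, index=False)


CLINICAL_COLUMNS = ["patient_id", "age", "imdc", "os_months", "os_event",
                    "first_line", "it_start_offset_months",
                    "tt_start_offset_months", "pfs_first_line_months"]


def read_clinical(path: str | Path) -> list[ClinicalRecord]:
    """Read the per-patient clinical table (CSV)."""
    df = _read_table(path)
    missing = [c for c in CLINICAL_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table {path} missing columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        def opt(name):
            v = getattr(row, name, None)
            if v is None or (isinstance(v, float) and np.isnan(v)):
                return None
            return v
        records.append(ClinicalRecord(
            patient_id=str(row.patient_id),
            age=float(row.age),
            imdc=str(row.imdc),
            os_months=float(row.os_months),
            os_event=int(row.os_event),
            first_line=opt("first_line"),
            it_start_offset_months=opt("it_start_offset_months"),
            tt_start_offset_months=opt("tt_start_offset_months"),
            pfs_first_line_months=opt("pfs_first_line_months"),
        ))
    return records


def clinical_frame(records: list[ClinicalRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({c: getattr(r, c) for c in CLINICAL_COLUMNS})
    return pd.DataFrame(rows, columns=CLINICAL_COLUMNS)


def write_clinical(records: list[ClinicalRecord], path: str | Path) -> None:
    clinical_frame(records).to_csv(path, index=False)


def write_manifest(path: str | Path, seed: Optional[int], config: dict,
                   extra: Optional[dict] = None) -> None:
    """Write the JSON run manifest: seed, configuration, and its hash."""
    cfg_json = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "seed": seed,
        "config": config,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
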