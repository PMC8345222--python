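"""Pipeline orchestration: per-ROI metric tables, patient aggregation, and
the end-to-end simulate -> metrics -> spatial -> survival -> compare run."""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import compare as cmp
from . import ihc, io, spatial
from .clinical import response_by_therapy
from .config import AnalysisConfig
from .simulate import CohortSimConfig, TissueSimConfig, simulate_cohort
from .survival import SCREEN_METRICS, run_survival_screen
from .types import ClinicalRecord, Marker, ROI

log = logging.getLogger(__name__)

#: Ordered marker pairs analyzed for cross-type clustering (from -> to).
NK_PAIRS = ((Marker.ASMA, Marker.KI67), (Marker.ASMA, Marker.CASP3),
            (Marker.CASP3, Marker.KI67))
#: Directed pairs analyzed for nearest-neighbor distances.
NN_PAIRS = ((Marker.ASMA, Marker.KI67), (Marker.ASMA, Marker.CASP3),
            (Marker.KI67, Marker.CASP3))


def spatial_metric_table(rois: Sequence[ROI],
                         config: Optional[AnalysisConfig] = None) -> pd.DataFrame:
    """Per-ROI bivariate clustering metrics at the configured radii.

    One row per (ROI, ordered pair, radius).  A pair is computed only when
    both strong-cell patterns meet the eligibility threshold; otherwise the
    row carries missing values with ``eligible = False``.
    """
    config = config or AnalysisConfig()
    rows = []
    for roi in rois:
        patterns = {m: spatial.spatial_positivity(roi, m) for m in Marker}
        for frm, to in NK_PAIRS:
            pf, pt = patterns[frm], patterns[to]
            ok = (spatial.eligibility(pf, config.min_cells)
                  and spatial.eligibility(pt, config.min_cells))
            for r in config.radii:
                row = {"patient_id": roi.patient_id, "roi_id": roi.roi_id,
                       "pair": f"{frm.value}_{to.value}", "radius": r,
                       "n_from": pf.n, "n_to": pt.n, "eligible": ok,
                       "k_hat": math.nan, "nk": math.nan}
                if ok:
                    est = spatial.bivariate_k(pf, pt, r)
                    row.update({"k_hat": est.k_hat, "nk": est.nk})
                rows.append(row)
    return pd.DataFrame(rows)


def nn_distance_table(rois: Sequence[ROI],
                      config: Optional[AnalysisConfig] = None) -> pd.DataFrame:
    """Long-format directed NN distances (one row per source cell and pair)."""
    config = config or AnalysisConfig()
    frames = []
    for roi in rois:
        patterns = {m: spatial.spatial_positivity(roi, m) for m in Marker}
        for frm, to in NN_PAIRS:
            pf, pt = patterns[frm], patterns[to]
            if not (spatial.eligibility(pf, config.min_cells)
                    and spatial.eligibility(pt, config.min_cells)):
                continue
            nn = spatial.nn_distances(pf, pt)
            frames.append(pd.DataFrame({
                "patient_id": roi.patient_id, "roi_id": roi.roi_id,
                "from_marker": frm.value, "to_marker": to.value,
                "distance": nn.distances,
            }))
    if not frames:
        return pd.DataFrame(columns=["patient_id", "roi_id", "from_marker",
                                     "to_marker", "distance"])
    return pd.concat(frames, ignore_index=True)


def roi_metrics_wide(ihc_table: pd.DataFrame,
                     spatial_table: pd.DataFrame,
                     nn_table: Optional[pd.DataFrame] = None,
                     nk_radius: float = 25.0) -> pd.DataFrame:
    """Pivot per-ROI long tables into one row per ROI with metric columns."""
    h = ihc_table.pivot_table(index=["patient_id", "roi_id"], columns="marker",
                              values="h_score", aggfunc="first")
    h.columns = [f"hscore_{c}" for c in h.columns]
    d = ihc_table.pivot_table(index=["patient_id", "roi_id"], columns="marker",
                              values="density", aggfunc="first")
    d.columns = [f"density_{c}" for c in d.columns]
    sp = spatial_table[spatial_table["radius"] == nk_radius]
    k = sp.pivot_table(index=["patient_id", "roi_id"], columns="pair",
                       values="nk", aggfunc="first")
    k.columns = [f"nk{int(nk_radius)}_{c}" for c in k.columns]
    out = h.join(d, how="outer").join(k, how="outer")
    if nn_table is not None and len(nn_table):
        med = (nn_table.groupby(["patient_id", "roi_id", "from_marker",
                                 "to_marker"])["distance"].median()
               .reset_index())
        med["col"] = ("nnmed_" + med["from_marker"] + "_" + med["to_marker"])
        nn = med.pivot_table(index=["patient_id", "roi_id"], columns="col",
                             values="distance", aggfunc="first")
        out = out.join(nn, how="outer")
    return out.reset_index()


def aggregate_to_patient(roi_metrics: pd.DataFrame) -> pd.DataFrame:
    """Average 1-2 ROI rows per patient into one metric vector per patient.

    The mean is over available (non-missing) ROI values; a metric missing in
    every ROI stays missing at the patient level.  Patients contributing no
    ROIs never appear; an all-missing row would be dropped with a log entry.
    """
    if "patient_id" not in roi_metrics.columns:
        raise ValueError("roi_metrics must have a patient_id column")
    value_cols = [c for c in roi_metrics.columns
                  if c not in ("patient_id", "roi_id")
                  and pd.api.types.is_numeric_dtype(roi_metrics[c])]
    out = roi_metrics.groupby("patient_id", sort=True)[value_cols].mean()
    all_missing = out.isna().all(axis=1)
    if all_missing.any():
        log.warning("dropping %d patients with no metric values",
                    int(all_missing.sum()))
        out = out[~all_missing]
    return out.reset_index()


def response_comparisons(patient_metrics: pd.DataFrame,
                         clinical: Sequence[ClinicalRecord]) -> pd.DataFrame:
    """Welch t-tests of each screened metric between responders and resistant
    patients, per therapy line."""
    pm = patient_metrics.set_index("patient_id")
    results = []
    for therapy in ("IT", "TT"):
        classes = {rec.patient_id: response_by_therapy(rec)[therapy]
                   for rec in clinical}
        resp = [p for p, c in classes.items() if c == "responder"]
        res = [p for p, c in classes.items() if c == "resistant"]
        for name in SCREEN_METRICS:
            if name not in pm.columns:
                continue
            a = pm.reindex(resp)[name].dropna().to_numpy()
            b = pm.reindex(res)[name].dropna().to_numpy()
            if len(a) < 2 or len(b) < 2:
                log.warning("t-test skipped for %s (%s): group too small",
                            name, therapy)
                continue
            results.append(cmp.ttest_two_sample(
                a, b, label=f"{therapy}:{name}",
                group_a="responder", group_b="resistant"))
    return cmp.comparison_frame(results)


def run_pipeline(out_dir: str | Path, seed: int = 0,
                 config: Optional[AnalysisConfig] = None,
                 tissue_cfg: Optional[TissueSimConfig] = None,
                 cohort_cfg: Optional[CohortSimConfig] = None) -> dict[str, Path]:
    """Full synthetic-cohort run; writes every output table plus a manifest.

    Returns a dict of output names to paths.  Identical seeds and
    configurations produce byte-identical outputs.
    """
    config = config or AnalysisConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    sim = simulate_cohort(tissue_cfg, cohort_cfg, seed=seed, materialize=True)
    paths: dict[str, Path] = {}

    paths["cells"] = out / "cells.csv"
    io.write_cells(sim.rois, paths["cells"])
    paths["clinical"] = out / "clinical.csv"
    io.write_clinical(sim.clinical, paths["clinical"])

    ihc_table = ihc.roi_metric_table(sim.rois, rule=config.positivity_rule)
    paths["roi_metrics"] = out / "roi_metrics.csv"
    ihc_table.to_csv(paths["roi_metrics"], index=False)

    sp_table = spatial_metric_table(sim.rois, config)
    paths["spatial_metrics"] = out / "spatial_metrics.csv"
    sp_table.to_csv(paths["spatial_metrics"], index=False)

    nn_table = nn_distance_table(sim.rois, config)
    paths["nn_distances"] = out / "nn_distances.csv"
    nn_table.to_csv(paths["nn_distances"], index=False)

    wide = roi_metrics_wide(ihc_table, sp_table, nn_table,
                            nk_radius=config.analysis_radius)
    patient = aggregate_to_patient(wide)
    paths["patient_metrics"] = out / "patient_metrics.csv"
    patient.to_csv(paths["patient_metrics"], index=False)

    screen = run_survival_screen(patient, sim.clinical,
                                 min_prop=config.min_prop,
                                 cutpoint_policy=config.cutpoint_policy,
                                 fdr_scope=config.fdr_scope)
    paths["survival_results"] = out / "survival_results.csv"
    screen.to_csv(paths["survival_results"], index=False)

    comps = response_comparisons(patient, sim.clinical)
    paths["comparisons"] = out / "comparisons.csv"
    comps.to_csv(paths["comparisons"], index=False)

    corr = cmp.spearman_matrix(patient, [c for c in SCREEN_METRICS
                                         if c in patient.columns])
    paths["correlations"] = out / "correlations.csv"
    corr.r.to_csv(paths["correlations"])

    paths["manifest"] = out / "manifest.json"
    io.write_manifest(paths["manifest"], seed, config.to_dict(),
                      extra={"simulation": sim.manifest})
    return paths
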