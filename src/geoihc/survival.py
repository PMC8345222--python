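"""Survival analysis: maximally selected log-rank cut-points, Kaplan-Meier,
multivariable Cox regression, and false-discovery-rate control.

Because no standardized clinical cutoffs exist for IHC-derived metrics, each
metric is dichotomized at the cut-point that maximizes the two-group
log-rank statistic over all admissible splits (each side holding at least a
``min_prop`` share of patients).  High-vs-low groups then enter a Cox
proportional-hazards model with age and IMDC risk category as covariates;
p values across metrics are Benjamini-Hochberg adjusted.  The selection
step inflates the unadjusted Cox p values under the null; no correction for
this selection is applied, matching common practice with maximally selected
statistics (a documented caveat, not an oversight).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .clinical import ENDPOINTS, build_endpoints
from .types import ClinicalRecord

log = logging.getLogger(__name__)

DEFAULT_MIN_PROP = 0.1

#: The nine screened metrics: three H-scores, three densities, three
#: ordered-pair local clustering values nK(25).
SCREEN_METRICS = (
    "hscore_aSMA", "hscore_Ki67", "hscore_Casp3",
    "density_aSMA", "density_Ki67", "density_Casp3",
    "nk25_aSMA_Ki67", "nk25_aSMA_Casp3", "nk25_Casp3_Ki67",
)


# ---------------------------------------------------------------------------
# Log-rank
# ---------------------------------------------------------------------------

def logrank_statistic(times: np.ndarray, events: np.ndarray,
                      groups: np.ndarray) -> tuple[float, float]:
    """Unweighted two-group log-rank chi-square statistic and its p value.

    Uses the hypergeometric variance at each distinct event time; the p
    value is from a chi-square distribution with 1 df.  If the variance is
    zero (e.g. no events), the statistic is 0 and p is 1.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"log-rank requires exactly two non-empty groups, got {len(labels)}")
    g1 = (groups == labels[1]).astype(float)

    order = np.argsort(times, kind="stable")
    t, e, g = times[order], events[order], g1[order]
    n_total = len(t)
    uniq, idx = np.unique(t, return_index=True)
    # risk-set sizes just before each distinct time (times sorted ascending)
    n_at = n_total - idx
    cum_g = np.concatenate([[0.0], np.cumsum(g)])
    n1_at = g.sum() - cum_g[idx]
    # events at each distinct time, overall and in group 1
    d = np.add.reduceat(e.astype(float), idx)
    d1 = np.add.reduceat(e * g, idx)

    keep = d > 0
    n_at, n1_at, d, d1 = n_at[keep], n1_at[keep], d[keep], d1[keep]
    frac = n1_at / n_at
    o_minus_e = float(np.sum(d1 - d * frac))
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(n_at > 1,
                     d * frac * (1 - frac) * (n_at - d) / (n_at - 1), 0.0)
    var = float(np.sum(v))
    if var <= 0:
        return 0.0, 1.0
    chi2 = o_minus_e * o_minus_e / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# Optimal cut-point
# ---------------------------------------------------------------------------

@dataclass
class CutpointResult:
    metric: str
    cutoff: float
    n_high: int
    n_low: int
    statistic: float           # log-rank chi-square at the optimum
    candidates: np.ndarray     # admissible candidate cutoffs examined


def optimal_cutpoint(values: np.ndarray, times: np.ndarray, events: np.ndarray,
                     min_prop: float = DEFAULT_MIN_PROP,
                     metric: str = "") -> CutpointResult:
    """Cut-point maximizing the log-rank statistic over admissible splits.

    Candidates are midpoints between consecutive distinct metric values;
    a candidate is admissible when both induced groups hold at least
    ``min_prop`` of the patients.  Ties in the maximized statistic break
    toward the smaller cutoff.  Patients with a missing metric are excluded
    before the search.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    keep = ~np.isnan(values)
    values, times, events = values[keep], times[keep], events[keep]
    n = len(values)
    if n < 10:
        raise ValueError(f"optimal_cutpoint needs >= 10 patients, got {n}")
    if not 0 < min_prop < 0.5:
        raise ValueError("min_prop must lie in (0, 0.5)")

    distinct = np.unique(values)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    admissible = []
    for c in mids:
        n_high = int((values > c).sum())
        prop = n_high / n
        if min_prop <= prop <= 1 - min_prop:
            admissible.append(c)
    if not admissible:
        raise ValueError("no admissible cut-point satisfies the group-size constraint")

    best_c, best_stat = None, -np.inf
    for c in admissible:  # ascending: strict '>' keeps the smallest tied cutoff
        stat, _ = logrank_statistic(times, events, values > c)
        if stat > best_stat:
            best_c, best_stat = c, stat
    n_high = int((values > best_c).sum())
    return CutpointResult(metric=metric, cutoff=float(best_c), n_high=n_high,
                          n_low=n - n_high, statistic=float(best_stat),
                          candidates=np.asarray(admissible))


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def km_estimate(times: np.ndarray, events: np.ndarray,
                groups: Optional[np.ndarray] = None) -> dict:
    """Product-limit survival curves and median survival per group.

    The median is the smallest observed time with S(t) <= 0.5; NaN when
    survival never drops to 0.5.  With ``groups=None`` a single curve is
    returned under the key ``'all'``.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if groups is None:
        groups = np.zeros(len(times))
        labels = {0.0: "all"}
    else:
        groups = np.asarray(groups)
        labels = {g: g for g in np.unique(groups)}
    out = {}
    for g, name in labels.items():
        m = groups == g
        if not m.any():
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(times[m], events[m])
        sf = kmf.survival_function_.iloc[:, 0]
        below = sf[sf <= 0.5]
        median = float(below.index[0]) if len(below) else math.nan
        out[name] = {"times": sf.index.to_numpy(dtype=float),
                     "survival": sf.to_numpy(dtype=float),
                     "median": median, "n": int(m.sum())}
    return out


# ---------------------------------------------------------------------------
# Cox regression
# ---------------------------------------------------------------------------

IMDC_REFERENCE = "favorable"
IMDC_OTHER = ("intermediate", "poor", "indeterminate")


@dataclass
class CoxResult:
    metric: str
    endpoint: str
    hr: float
    ci_low: float
    ci_high: float
    p: float
    coef: float
    covariates: dict[str, float] = field(default_factory=dict)
    median_high: float = math.nan
    median_low: float = math.nan
    fdr_p: float = math.nan


def _imdc_design(imdc: Sequence[str]) -> pd.DataFrame:
    """Treatment-coded IMDC dummies with 'favorable' as the reference level."""
    s = pd.Series(imdc, dtype=str)
    unknown = set(s.unique()) - set(ClinicalRecord.IMDC_LEVELS)
    if unknown:
        raise ValueError(f"unknown IMDC categories: {sorted(unknown)}")
    return pd.DataFrame({f"imdc_{lvl}": (s == lvl).astype(float).to_numpy()
                         for lvl in IMDC_OTHER})


def cox_fit(times: np.ndarray, events: np.ndarray, exposure: np.ndarray,
            age: np.ndarray, imdc: Sequence[str], *,
            exposure_name: str = "group_high", metric: str = "",
            endpoint: str = "OS") -> CoxResult:
    """Multivariable Cox PH fit of an exposure adjusted for age and IMDC.

    ``exposure`` may be a binary high/low indicator (the screen's use) or a
    continuous covariate; the returned HR, Wald 95% CI, and p refer to its
    coefficient.  Ties are handled by Efron's method (lifelines' default).
    Constant covariate columns are dropped with a warning; non-convergence
    propagates as an error with lifelines' diagnostics attached.
    """
    df = pd.DataFrame({
        "time": np.asarray(times, dtype=float),
        "event": np.asarray(events, dtype=int),
        exposure_name: np.asarray(exposure, dtype=float),
        "age": np.asarray(age, dtype=float),
    })
    df = pd.concat([df, _imdc_design(imdc)], axis=1)
    if df["event"].sum() < 1:
        raise ValueError("Cox fit requires at least one event")
    for col in list(df.columns[2:]):
        if df[col].nunique() <= 1:
            if col == exposure_name:
                raise ValueError(f"exposure {exposure_name!r} is constant")
            log.warning("dropping constant covariate %r from Cox model", col)
            df = df.drop(columns=[col])

    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="time", event_col="event")
    summary = cph.summary
    row = summary.loc[exposure_name]
    covariates = {name: float(summary.loc[name, "coef"])
                  for name in summary.index if name != exposure_name}
    res = CoxResult(metric=metric, endpoint=endpoint,
                    hr=float(row["exp(coef)"]),
                    ci_low=float(row["exp(coef) lower 95%"]),
                    ci_high=float(row["exp(coef) upper 95%"]),
                    p=float(row["p"]), coef=float(row["coef"]),
                    covariates=covariates)
    exp_vals = df[exposure_name]
    if set(exp_vals.unique()) <= {0.0, 1.0}:
        km = km_estimate(df["time"].to_numpy(), df["event"].to_numpy(),
                         exp_vals.to_numpy())
        if 1.0 in km:
            res.median_high = km[1.0]["median"]
        if 0.0 in km:
            res.median_low = km[0.0]["median"]
    return res


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------

def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaNs pass through untouched."""
    p = np.asarray(p_values, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p values must lie in [0, 1]")
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# Full screen
# ---------------------------------------------------------------------------

def _endpoint_frame(clinical: Sequence[ClinicalRecord], endpoint: str) -> pd.DataFrame:
    rows = []
    for rec in clinical:
        eps = build_endpoints(rec)
        if endpoint in eps:
            t, e = eps[endpoint]
            rows.append({"patient_id": rec.patient_id, "time": t, "event": e,
                         "age": rec.age, "imdc": rec.imdc})
    return pd.DataFrame(rows)


def run_survival_screen(metrics: pd.DataFrame, clinical: Sequence[ClinicalRecord],
                        endpoints: Sequence[str] = ENDPOINTS,
                        metric_names: Sequence[str] = SCREEN_METRICS,
                        min_prop: float = DEFAULT_MIN_PROP,
                        cutpoint_policy: str = "per_endpoint",
                        fdr_scope: str = "within_endpoint") -> pd.DataFrame:
    """Screen every metric against every endpoint; one row per combination.

    ``metrics`` is the patient-level table (one row per patient, metric
    columns as in :data:`SCREEN_METRICS`, indexed or keyed by patient_id).
    ``cutpoint_policy`` selects whether cut-points are re-derived on each
    endpoint's treated subset ('per_endpoint', default) or determined once
    on OS and reused ('os').  Metrics with too few eligible patients yield
    a row of missing estimates rather than an error.
    """
    if cutpoint_policy not in ("per_endpoint", "os"):
        raise ValueError(f"unknown cutpoint_policy {cutpoint_policy!r}")
    if fdr_scope not in ("within_endpoint", "global"):
        raise ValueError(f"unknown fdr_scope {fdr_scope!r}")
    metrics = metrics.set_index("patient_id") if "patient_id" in metrics.columns else metrics

    os_frame = _endpoint_frame(clinical, "OS")
    rows = []
    for endpoint in endpoints:
        ep = _endpoint_frame(clinical, endpoint)
        for name in metric_names:
            row = {"metric": name, "endpoint": endpoint, "cutoff": math.nan,
                   "n_high": np.nan, "n_low": np.nan,
                   "median_high": math.nan, "median_low": math.nan,
                   "hr": math.nan, "ci_low": math.nan, "ci_high": math.nan,
                   "p": math.nan, "logrank_stat": math.nan}
            try:
                cut_frame = ep if cutpoint_policy == "per_endpoint" else os_frame
                vals = metrics.reindex(cut_frame["patient_id"])[name].to_numpy(dtype=float)
                cp = optimal_cutpoint(vals, cut_frame["time"].to_numpy(),
                                      cut_frame["event"].to_numpy(),
                                      min_prop=min_prop, metric=name)
                ep_vals = metrics.reindex(ep["patient_id"])[name].to_numpy(dtype=float)
                keep = ~np.isnan(ep_vals)
                sub = ep[keep]
                high = (ep_vals[keep] > cp.cutoff).astype(float)
                res = cox_fit(sub["time"].to_numpy(), sub["event"].to_numpy(),
                              high, sub["age"].to_numpy(), sub["imdc"].tolist(),
                              metric=name, endpoint=endpoint)
                row.update({"cutoff": cp.cutoff, "n_high": int(high.sum()),
                            "n_low": int(len(high) - high.sum()),
                            "median_high": res.median_high,
                            "median_low": res.median_low,
                            "hr": res.hr, "ci_low": res.ci_low,
                            "ci_high": res.ci_high, "p": res.p,
                            "logrank_stat": cp.statistic})
            except (ValueError, KeyError) as err:
                log.warning("survival screen: %s / %s skipped (%s)", name,
                            endpoint, err)
            rows.append(row)
    table = pd.DataFrame(rows)
    if fdr_scope == "within_endpoint":
        table["fdr_p"] = np.nan
        for endpoint in endpoints:
            m = table["endpoint"] == endpoint
            table.loc[m, "fdr_p"] = fdr_adjust(table.loc[m, "p"].to_numpy())
    else:
        table["fdr_p"] = fdr_adjust(table["p"].to_numpy())
    return table
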