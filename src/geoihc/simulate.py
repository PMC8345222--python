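"""Synthetic tissue and cohort generator.

Because per-cell and clinical patient data of this kind are rarely shareable,
every pipeline stage here is exercised against simulated data whose
statistical structure matches what the analysis assumes:

* **Tissue**: per ROI, fibroblast (aSMA) cells follow a homogeneous Poisson
  process; proliferating (Ki67) cells are Thomas-type offspring of the
  fibroblast parents (Poisson number per parent, isotropic Gaussian
  displacement, window-clipped by re-drawing) plus an independent Poisson
  background, producing controllable cross-type clustering measurable by
  nK(25); apoptotic (Casp3) cells are a weighted subsample of a uniform
  candidate pool with retention probability increasing with distance to the
  nearest fibroblast, emulating apoptosis far from the fibroblast niche.
  Intensity bins are drawn i.i.d. per marker, so the strong-only patterns
  used for spatial analysis are independent thinnings that inherit the
  second-order structure.

* **Cohort**: per-patient tissue parameters are jittered around cohort-level
  values; survival times follow an exponential proportional-hazards model
  whose linear predictor combines configured log-hazard coefficients on the
  standardized true metrics with age and IMDC effects; censoring is
  independent; first-line therapy assignment and progression-free survival
  are drawn so that configured responder / resistant / indeterminate
  fractions are met in expectation.  The ground truth (per-patient true
  metrics and the generating coefficients) is returned for recovery tests.

Everything is deterministic given a seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import (ClinicalRecord, Intensity, Marker, PointPattern, ROI,
                    Window, default_window)

log = logging.getLogger(__name__)

_BIN_LABELS = [i.value for i in Intensity]


# ---------------------------------------------------------------------------
# Tissue configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkerSimSpec:
    """Expected detected-cell count for a marker's slide and its intensity mix."""

    expected_count: float
    bin_probs: tuple[float, float, float, float]  # negative, weak, moderate, strong

    def __post_init__(self) -> None:
        if self.expected_count <= 0:
            raise ValueError("expected_count must be positive")
        if abs(sum(self.bin_probs) - 1.0) > 1e-9 or min(self.bin_probs) < 0:
            raise ValueError("bin_probs must be non-negative and sum to 1")

    @property
    def h_score_true(self) -> float:
        _, w, m, s = self.bin_probs
        return 100.0 * (w + 2.0 * m + 3.0 * s)

    @property
    def positive_fraction(self) -> float:
        return 1.0 - self.bin_probs[0]


@dataclass(frozen=True)
class AttractionSpec:
    """Thomas-type cross-type clustering: offspring placed around parents.

    The offspring marker's total expected count stays at its MarkerSimSpec
    value; the Poisson background rate is the remainder after the expected
    parent offspring, so marginal counts are invariant to the attraction
    strength.
    """

    parent: Marker = Marker.ASMA
    offspring: Marker = Marker.KI67
    mean_offspring: float = 1.0   # Poisson mean per parent
    sigma: float = 15.0           # isotropic Gaussian dispersion, µm

    def __post_init__(self) -> None:
        if self.mean_offspring < 0:
            raise ValueError("mean_offspring must be >= 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass(frozen=True)
class RepulsionSpec:
    """Distance-dependent placement of a target type away from a reference type.

    A uniform candidate pool of ``overgen`` times the target count is drawn
    and the target cells are sampled without replacement with probability
    proportional to 1 - exp(-d / scale), d being the distance to the nearest
    reference cell.  Larger ``scale`` pushes the target farther out.
    """

    reference: Marker = Marker.ASMA
    target: Marker = Marker.CASP3
    scale: float = 20.0     # µm
    overgen: float = 3.0

    def __post_init__(self) -> None:
        if self.scale <= 0 or self.overgen <= 1:
            raise ValueError("scale must be > 0 and overgen > 1")


def _default_markers() -> dict[Marker, MarkerSimSpec]:
    # Chosen to land near the reported cohort medians for the fibroblast
    # compartment (H-score ~35, any-stain density ~1900/mm²) while keeping
    # the marker ordering aSMA > Ki67 > Casp3 in both H-score and density
    # and >= 10 expected strong cells per marker for spatial eligibility.
    return {
        Marker.ASMA: MarkerSimSpec(7500, (0.700, 0.260, 0.025, 0.015)),
        Marker.KI67: MarkerSimSpec(9000, (0.950, 0.033, 0.010, 0.007)),
        Marker.CASP3: MarkerSimSpec(6000, (0.990, 0.0045, 0.003, 0.0025)),
    }


@dataclass(frozen=True)
class TissueSimConfig:
    """Generative parameters for one ROI."""

    window: Window = field(default_factory=default_window)
    markers: dict[Marker, MarkerSimSpec] = field(default_factory=_default_markers)
    attraction: Optional[AttractionSpec] = field(default_factory=AttractionSpec)
    repulsion: Optional[RepulsionSpec] = field(default_factory=RepulsionSpec)

    def background_rate(self) -> float:
        """Poisson background count of the offspring marker."""
        if self.attraction is None:
            return self.markers[Marker.KI67].expected_count
        bg = (self.markers[self.attraction.offspring].expected_count
              - self.attraction.mean_offspring
              * self.markers[self.attraction.parent].expected_count)
        if bg < 0:
            raise ValueError(
                "attraction mean_offspring x parent count exceeds the offspring "
                "marker's expected count; no non-negative background exists")
        return bg

    def scaled(self, factor: float) -> "TissueSimConfig":
        """Same structure at ``factor`` times the cellularity (for small runs)."""
        markers = {m: replace(s, expected_count=s.expected_count * factor)
                   for m, s in self.markers.items()}
        return replace(self, markers=markers)


# ---------------------------------------------------------------------------
# ROI simulation
# ---------------------------------------------------------------------------

def _uniform_points(n: int, window: Window, rng: np.random.Generator) -> np.ndarray:
    pts = rng.random((n, 2))
    pts[:, 0] *= window.width
    pts[:, 1] *= window.height
    return pts


def _offspring_points(parents: np.ndarray, mu: float, sigma: float,
                      window: Window, rng: np.random.Generator,
                      max_redraws: int = 1000) -> np.ndarray:
    counts = rng.poisson(mu, size=len(parents))
    centers = np.repeat(parents, counts, axis=0)
    if len(centers) == 0:
        return np.empty((0, 2))
    pts = centers + rng.normal(scale=sigma, size=centers.shape)
    total_draws = len(pts)
    for _ in range(max_redraws):
        outside = ~window.contains(pts[:, 0], pts[:, 1])
        n_out = int(outside.sum())
        if n_out == 0:
            break
        total_draws += n_out
        pts[outside] = (centers[outside]
                        + rng.normal(scale=sigma, size=(n_out, 2)))
    else:
        raise RuntimeError("offspring rejection sampling did not converge; "
                           "dispersion too large for the window")
    if total_draws > 100 * len(pts):
        raise RuntimeError("offspring rejection rate > 99%; window too small "
                           "for the requested dispersion")
    return pts


def simulate_roi(cfg: TissueSimConfig, rng: np.random.Generator,
                 patient_id: str = "P1", roi_id: str = "R1") -> ROI:
    """Draw one ROI from the generative tissue model (deterministic per rng state)."""
    window = cfg.window
    positions: dict[Marker, np.ndarray] = {}

    # fibroblasts: homogeneous Poisson
    n_par = rng.poisson(cfg.markers[Marker.ASMA].expected_count)
    parents = _uniform_points(n_par, window, rng)
    positions[Marker.ASMA] = parents

    # proliferating cells: Thomas offspring + Poisson background
    if cfg.attraction is not None:
        off = _offspring_points(parents, cfg.attraction.mean_offspring,
                                cfg.attraction.sigma, window, rng)
        n_bg = rng.poisson(cfg.background_rate())
        bg = _uniform_points(n_bg, window, rng)
        positions[Marker.KI67] = np.vstack([off, bg])
    else:
        n_k = rng.poisson(cfg.markers[Marker.KI67].expected_count)
        positions[Marker.KI67] = _uniform_points(n_k, window, rng)

    # apoptotic cells: distance-weighted subsample of a uniform pool
    casp_target = cfg.markers[Marker.CASP3].expected_count
    if cfg.repulsion is not None:
        n_pool = rng.poisson(casp_target * cfg.repulsion.overgen)
        pool = _uniform_points(n_pool, window, rng)
        n_c = rng.poisson(casp_target)
        if n_c > n_pool:
            log.warning("candidate pool smaller than target Casp3 count; clamping")
            n_c = n_pool
        if n_par > 0 and n_pool > 0:
            from scipy.spatial import cKDTree
            d, _ = cKDTree(parents).query(pool, k=1)
            w = 1.0 - np.exp(-d / cfg.repulsion.scale)
            if w.sum() <= 0:
                w = np.ones(n_pool)
        else:
            w = np.ones(max(n_pool, 1))[:n_pool]
        idx = rng.choice(n_pool, size=n_c, replace=False, p=w / w.sum()) \
            if n_pool else np.empty(0, dtype=int)
        positions[Marker.CASP3] = pool[np.sort(idx)]
    else:
        n_c = rng.poisson(casp_target)
        positions[Marker.CASP3] = _uniform_points(n_c, window, rng)

    frames = []
    for marker in Marker:
        pts = positions[marker]
        bins = rng.choice(4, size=len(pts), p=cfg.markers[marker].bin_probs)
        frames.append(pd.DataFrame({
            "x": pts[:, 0], "y": pts[:, 1],
            "marker": marker.value,
            "intensity": [_BIN_LABELS[b] for b in bins],
        }))
    cells = pd.concat(frames, ignore_index=True)
    return ROI(patient_id=patient_id, roi_id=roi_id, window=window, cells=cells)


def csr_pattern(n: int, window: Window, rng: np.random.Generator,
                marker: Marker = Marker.ASMA) -> PointPattern:
    """A binomial (fixed-n CSR) point pattern, for calibration studies."""
    return PointPattern(points=_uniform_points(n, window, rng), window=window,
                        marker=marker)


# ---------------------------------------------------------------------------
# Cohort configuration
# ---------------------------------------------------------------------------

def _default_coefficients() -> dict[str, float]:
    # log hazard ratios per SD of the true metric; nonzero entries mirror the
    # qualitative finding pattern (proliferation strongest, fibroblast and
    # apoptosis H-scores weaker, clustering metrics null)
    return {
        "hscore_Ki67": math.log(1.8),
        "hscore_aSMA": math.log(1.45),
        "hscore_Casp3": math.log(1.33),
        "density_Ki67": math.log(1.3),
    }


@dataclass(frozen=True)
class CohortSimConfig:
    """Generative parameters for a patient cohort."""

    n_patients: int = 96
    rois_per_patient: int = 2
    coefficients: dict[str, float] = field(default_factory=_default_coefficients)
    baseline_median: float = 48.0        # months, exponential baseline
    censor_mean: float = 90.0            # months, exponential censoring
    admin_cap: float = 200.0             # months, administrative censoring
    age_mean: float = 59.0
    age_sd: float = 9.0
    age_range: tuple[float, float] = (33.0, 87.0)
    age_coef: float = 0.02               # log hazard per year above the mean
    imdc_probs: tuple[float, float, float, float] = (0.21, 0.58, 0.09, 0.12)
    imdc_coefs: dict[str, float] = field(default_factory=lambda: {
        "intermediate": 0.4, "poor": 0.9, "indeterminate": 0.2})
    first_line_probs: tuple[float, float, float] = (0.53, 0.44, 0.03)  # IT, TT, both
    later_line_prob: float = 0.30        # chance of also receiving the other therapy
    # responder / resistant / indeterminate fractions among treated patients
    it_response_fracs: tuple[float, float, float] = (0.35, 0.49, 0.16)
    tt_response_fracs: tuple[float, float, float] = (0.64, 0.21, 0.15)
    count_jitter_sd: float = 0.25        # lognormal sigma on expected counts
    bin_concentration: float = 300.0     # Dirichlet concentration for bin probs
    attraction_jitter_sd: float = 0.30   # lognormal sigma on mean_offspring
    repulsion_jitter_sd: float = 0.30    # lognormal sigma on repulsion scale
    metric_noise_cv: float = 0.05        # measurement noise on observed metrics

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        for name in ("it_response_fracs", "tt_response_fracs"):
            fr = getattr(self, name)
            if min(fr) < 0 or abs(sum(fr) - 1.0) > 1e-6:
                raise ValueError(f"{name} must be non-negative and sum to 1")
        if abs(sum(self.imdc_probs) - 1.0) > 1e-6:
            raise ValueError("imdc_probs must sum to 1")
        if abs(sum(self.first_line_probs) - 1.0) > 1e-6:
            raise ValueError("first_line_probs must sum to 1")


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

_IMDC_LEVELS = ("favorable", "intermediate", "poor", "indeterminate")

METRIC_NAMES = (
    "hscore_aSMA", "hscore_Ki67", "hscore_Casp3",
    "density_aSMA", "density_Ki67", "density_Casp3",
    "nk25_aSMA_Ki67", "nk25_aSMA_Casp3", "nk25_Casp3_Ki67",
)


def _jitter_tissue(base: TissueSimConfig, cohort: CohortSimConfig,
                   rng: np.random.Generator) -> TissueSimConfig:
    markers = {}
    for m, spec in base.markers.items():
        count = spec.expected_count * rng.lognormal(0.0, cohort.count_jitter_sd)
        probs = rng.dirichlet(np.asarray(spec.bin_probs) * cohort.bin_concentration)
        markers[m] = MarkerSimSpec(count, tuple(probs))
    attraction = base.attraction
    if attraction is not None:
        mu = attraction.mean_offspring * rng.lognormal(0.0, cohort.attraction_jitter_sd)
        # cap so the offspring background stays non-negative
        cap = markers[attraction.offspring].expected_count / \
            markers[attraction.parent].expected_count
        attraction = replace(attraction, mean_offspring=min(mu, cap))
    repulsion = base.repulsion
    if repulsion is not None:
        repulsion = replace(repulsion, scale=repulsion.scale
                            * rng.lognormal(0.0, cohort.repulsion_jitter_sd))
    return replace(base, markers=markers, attraction=attraction,
                   repulsion=repulsion)


def _true_metrics(cfg: TissueSimConfig, rng: np.random.Generator,
                  r: float = 25.0) -> dict[str, float]:
    """Analytic patient-level metric values implied by a tissue configuration."""
    area_mm2 = cfg.window.area_mm2
    out: dict[str, float] = {}
    for m, label in ((Marker.ASMA, "aSMA"), (Marker.KI67, "Ki67"),
                     (Marker.CASP3, "Casp3")):
        spec = cfg.markers[m]
        out[f"hscore_{label}"] = spec.h_score_true
        out[f"density_{label}"] = spec.expected_count * spec.positive_fraction / area_mm2
    # Thomas cross-clustering: expected extra offspring within r of a parent
    if cfg.attraction is not None:
        att = cfg.attraction
        lam_off = cfg.markers[att.offspring].expected_count / cfg.window.area
        p_within = 1.0 - math.exp(-r * r / (2.0 * att.sigma ** 2))
        out["nk25_aSMA_Ki67"] = 1.0 + att.mean_offspring * p_within / \
            (lam_off * math.pi * r * r)
    else:
        out["nk25_aSMA_Ki67"] = 1.0
    # distance-thinned placement induces mild dispersion around the reference
    scale = cfg.repulsion.scale if cfg.repulsion is not None else 0.0
    out["nk25_aSMA_Casp3"] = 1.0 / (1.0 + scale / 100.0)
    out["nk25_Casp3_Ki67"] = 1.0 / (1.0 + scale / 200.0)
    # idiosyncratic patient-level variation beyond the structural parameters
    for k in ("nk25_aSMA_Casp3", "nk25_Casp3_Ki67"):
        out[k] *= rng.lognormal(0.0, 0.05)
    return out


@dataclass
class CohortSim:
    """A simulated cohort with its generating ground truth."""

    clinical: list[ClinicalRecord]
    metrics_true: pd.DataFrame        # patient_id + true metric values
    metrics_observed: pd.DataFrame    # true values with measurement noise
    tissue_configs: dict[str, TissueSimConfig]
    rois: Optional[list[ROI]]
    manifest: dict


def simulate_cohort(tissue_cfg: Optional[TissueSimConfig] = None,
                    cohort_cfg: Optional[CohortSimConfig] = None,
                    seed: int | np.random.Generator = 0,
                    materialize: bool = False) -> CohortSim:
    """Simulate a cohort of patients with known metric-survival coupling.

    With ``materialize=True`` the per-patient ROIs are generated as cell
    tables (so the full measurement pipeline can run on them); otherwise
    only the clinical records and the metric tables are produced, which is
    what the survival-machinery recovery tests need.
    """
    tissue_cfg = tissue_cfg or TissueSimConfig()
    cohort_cfg = cohort_cfg or CohortSimConfig()
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))

    patient_ids = [f"P{i + 1:03d}" for i in range(cohort_cfg.n_patients)]
    tissue_configs: dict[str, TissueSimConfig] = {}
    truth_rows = []
    for pid in patient_ids:
        cfg_i = _jitter_tissue(tissue_cfg, cohort_cfg, rng)
        tissue_configs[pid] = cfg_i
        truth_rows.append({"patient_id": pid, **_true_metrics(cfg_i, rng)})
    truths = pd.DataFrame(truth_rows)

    # linear predictor on standardized true metrics
    lp = np.zeros(len(truths))
    z_info = {}
    for name, coef in cohort_cfg.coefficients.items():
        if coef == 0.0 or name not in truths.columns:
            continue
        v = truths[name].to_numpy(dtype=float)
        mu, sd = float(v.mean()), float(v.std(ddof=0))
        if sd <= 0:
            raise ValueError(f"metric {name} is constant; cannot standardize")
        lp += coef * (v - mu) / sd
        z_info[name] = {"mean": mu, "sd": sd, "coef": coef}

    ages = np.clip(rng.normal(cohort_cfg.age_mean, cohort_cfg.age_sd,
                              len(truths)), *cohort_cfg.age_range)
    imdc = rng.choice(len(_IMDC_LEVELS), size=len(truths),
                      p=cohort_cfg.imdc_probs)
    imdc_labels = [_IMDC_LEVELS[i] for i in imdc]
    lp = lp + cohort_cfg.age_coef * (ages - cohort_cfg.age_mean)
    lp = lp + np.array([cohort_cfg.imdc_coefs.get(l, 0.0) for l in imdc_labels])

    base_rate = math.log(2.0) / cohort_cfg.baseline_median
    t_event = rng.exponential(1.0 / (base_rate * np.exp(lp)))
    t_cens = np.minimum(rng.exponential(cohort_cfg.censor_mean, len(truths)),
                        cohort_cfg.admin_cap)
    os_months = np.minimum(t_event, t_cens)
    os_event = (t_event <= t_cens).astype(int)

    first_line = rng.choice(3, size=len(truths), p=cohort_cfg.first_line_probs)
    fl_labels = ["IT", "TT", "both"]

    records: list[ClinicalRecord] = []
    for i, pid in enumerate(patient_ids):
        fl = fl_labels[first_line[i]]
        it_off = tt_off = None
        horizon = os_months[i]
        if fl in ("IT", "both"):
            it_off = float(rng.uniform(0.0, min(3.0, horizon)))
        if fl in ("TT", "both"):
            tt_off = float(rng.uniform(0.0, min(3.0, horizon)))
        # the other therapy may be received in a later line
        if fl == "IT" and tt_off is None and rng.random() < cohort_cfg.later_line_prob:
            tt_off = float(rng.uniform(0.0, 0.8 * horizon)) if horizon > 0 else 0.0
        if fl == "TT" and it_off is None and rng.random() < cohort_cfg.later_line_prob:
            it_off = float(rng.uniform(0.0, 0.8 * horizon)) if horizon > 0 else 0.0

        fracs = (cohort_cfg.it_response_fracs if fl in ("IT", "both")
                 else cohort_cfg.tt_response_fracs)
        cls = rng.choice(3, p=fracs)  # 0 responder, 1 resistant, 2 indeterminate
        if cls == 0:
            pfs = 9.0 + float(rng.exponential(6.0))
        elif cls == 1:
            pfs = float(rng.uniform(0.5, 6.0))
        else:
            pfs = float(rng.uniform(6.0, 9.0))

        records.append(ClinicalRecord(
            patient_id=pid, age=float(ages[i]), imdc=imdc_labels[i],
            os_months=float(os_months[i]), os_event=int(os_event[i]),
            first_line=fl, it_start_offset_months=it_off,
            tt_start_offset_months=tt_off, pfs_first_line_months=pfs))

    observed = truths.copy()
    if cohort_cfg.metric_noise_cv > 0:
        for c in METRIC_NAMES:
            noise = rng.lognormal(0.0, cohort_cfg.metric_noise_cv, len(observed))
            observed[c] = observed[c] * noise

    rois: Optional[list[ROI]] = None
    if materialize:
        rois = []
        for pid in patient_ids:
            for j in range(cohort_cfg.rois_per_patient):
                rois.append(simulate_roi(tissue_configs[pid], rng,
                                         patient_id=pid, roi_id=f"R{j + 1}"))

    manifest = {
        "n_patients": cohort_cfg.n_patients,
        "rois_per_patient": cohort_cfg.rois_per_patient,
        "coefficients": dict(cohort_cfg.coefficients),
        "standardization": z_info,
        "baseline_median_months": cohort_cfg.baseline_median,
        "age_coef": cohort_cfg.age_coef,
        "imdc_coefs": dict(cohort_cfg.imdc_coefs),
    }
    return CohortSim(clinical=records, metrics_true=truths,
                     metrics_observed=observed, tissue_configs=tissue_configs,
                     rois=rois, manifest=manifest)
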