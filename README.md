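# geoihc

Geospatial analysis of immunohistochemistry (IHC)-derived cell coordinates
in tumor regions of interest, with downstream survival and treatment-
response analysis.

The package is written for translational researchers who have digitized,
IHC-stained slides, run cell detection upstream (e.g. in a commercial
digital-pathology platform), and now hold per-cell tables: coordinates of
each cell's center of mass, its marker (one stain per adjacent slide), and
a staining-intensity bin (negative / weak / moderate / strong).  The
canonical use case is the tumor microenvironment of clear cell renal cell
carcinoma, with αSMA marking cancer-associated fibroblasts (CAFs), Ki-67
marking proliferating cells, and cleaved caspase-3 marking apoptotic cells
— but nothing in the code is specific to those stains beyond the labels.

## What it computes

**Staining metrics, per ROI and marker**

- intensity breakdown over the four bins, and the H-score
  `H = 1·(%weak) + 2·(%moderate) + 3·(%strong)` ∈ [0, 300];
- percent positivity (any-stain or strong-only rule);
- cell density (positive cells / mm²).

**Spatial statistics, per ROI and ordered marker pair** (strong-intensity
cells only; a pattern enters spatial analysis only with ≥ 10 cells)

- bivariate Ripley's K with isotropic edge correction, normalized as
  `nK(r) = K̂(r) / (πr²)`, so that complete spatial randomness gives
  nK = 1, clustering nK > 1, dispersion nK < 1.  The estimator is

  `K̂(r) = A / (n₁n₂) · Σᵢⱼ 1(dᵢⱼ ≤ r) / wᵢⱼ`,

  where `wᵢⱼ` is the fraction of the circle through cell *j* centered at
  cell *i* that lies inside the rectangular window (computed in closed
  form), and `A` is the window area.  Default radii: 25 and 125 µm, with
  downstream analysis at 25 µm.
- directed nearest-neighbor (NN) distances with per-pair medians, and
  scaled 2D kernel-density summaries of joint NN distances (peak = 1.0).

**Survival and cohort analysis, per patient** (ROI values averaged so each
patient has one value per metric)

- optimal cut-points maximizing the two-group log-rank statistic over all
  admissible splits (each group ≥ 10% of patients);
- multivariable Cox proportional-hazards models of each dichotomized
  metric, adjusted for age and IMDC risk category, with Benjamini–Hochberg
  FDR control across metrics, for three endpoints: overall survival from
  diagnosis (OS) and from initiation of immunotherapy (OS-IT) or targeted
  therapy (OS-TT);
- Kaplan–Meier curves and median survival per group;
- Wilcoxon rank-sum and Welch t-test group comparisons, and the Spearman
  correlation matrix between metrics.

A synthetic tissue-and-cohort generator (Poisson fibroblasts, Thomas-type
clustered proliferating cells, distance-thinned apoptotic cells; an
exponential proportional-hazards cohort with known coefficients) stands in
for patient data, so the entire pipeline is testable end to end.

## Worked example

```python
import numpy as np
import geoihc as g

rng = np.random.default_rng(0)
roi = g.simulate_roi(g.TissueSimConfig(), rng)        # one synthetic ROI

caf  = g.spatial_positivity(roi, g.Marker.ASMA)       # strong aSMA+ cells
ki67 = g.spatial_positivity(roi, g.Marker.KI67)
print(g.bivariate_k(caf, ki67, 25.0).nk)              # 1.211
print(g.nn_distances(caf, ki67).median)               # 73.1 (µm)

mm = g.marker_metrics(roi, g.Marker.ASMA)
print(mm.h_score, mm.density)                         # 35.6, 1902 cells/mm²
```

`nK(25) = 1.211` means there are ~21% more strong Ki-67⁺ cells within
25 µm of a typical CAF than expected if the two populations were spatially
independent.  The median NN distance is large here because only
strong-intensity cells (121 and 68 of ~22,600 in this ROI) enter the
spatial analysis.

The survival screen on a simulated 96-patient cohort:

```python
sim = g.simulate_cohort(seed=1)                       # known ground truth
screen = g.run_survival_screen(sim.metrics_observed, sim.clinical)
print(screen[screen.endpoint == "OS"].head(3).round(3))
```

```
       metric endpoint  cutoff  n_high  n_low     hr  ci_low  ci_high      p  fdr_p
  hscore_aSMA       OS  35.810      34     62  1.806   1.060    3.076  0.030  0.045
  hscore_Ki67       OS   9.923      14     82  6.557   3.245   13.253  0.000  0.000
 hscore_Casp3       OS   3.286      15     81  2.505   1.278    4.907  0.007  0.017
```

One row per metric × endpoint (27 rows total): the selected cut-point,
group sizes, the age- and IMDC-adjusted hazard ratio of the high group
with its Wald 95% CI, and raw and FDR-adjusted p values.  In this cohort
the generator plants its strongest hazard on the Ki-67 H-score, and the
screen ranks it first.

A `geoihc` command-line interface wraps the same steps
(`simulate`, `metrics`, `spatial`, `survival`, `compare`, `report`), with
global `--seed`, `--config` (YAML), and `--out` options.

## Layout

```
src/geoihc/
  types.py      domain types (Window, ROI, PointPattern, ClinicalRecord)
  io.py         cell/clinical table readers and writers, run manifest
  config.py     YAML-loadable analysis configuration
  ihc.py        intensity breakdowns, H-score, positivity, density
  spatial.py    edge-corrected Ripley's K, nK(r), NN distances, 2D KDE
  clinical.py   endpoint construction, therapy-response classification
  survival.py   log-rank, optimal cut-points, Cox, KM, FDR, the screen
  compare.py    Wilcoxon / Welch tests, Spearman matrix, NN comparisons
  simulate.py   synthetic tissue and cohort generator
  pipeline.py   metric tables, patient aggregation, end-to-end run
  plots.py      KM curves, correlation heatmap, scaled KDE panels
  cli.py        command-line interface
```

See `docs/methods.md` for the statistical methods, modeling assumptions,
and numerical conventions.
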