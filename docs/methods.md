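# Methods

This note documents the statistical procedures implemented in `geoihc`,
the assumptions behind them, and the conventions fixed where the
literature leaves choices open.

## Input model

The unit of observation is a rectangular region of interest (ROI) selected
from the tumor core of a digitized IHC-stained slide.  Upstream cell
detection provides one row per cell: Cartesian coordinates of the cell's
center of mass, the marker of its slide (one stain per adjacent slide, so
markers have disjoint cell populations), and one of four intensity bins
(negative, weak, moderate, strong) assigned by an analyst-calibrated
threshold — the digital counterpart of the pathologist's 0/1+/2+/3+
grading.  The standardized ROI geometry is 3426 × 1379 pixels at
0.502 µm/pixel (1719.85 × 692.26 µm, 1.1906 mm²), overridable in the
configuration.  Coordinates arriving in pixels are converted to µm on
read.  Image-convention input (origin top-left, y downward) is accepted
unflipped: every statistic computed here is invariant under reflection.

Two ROIs per patient is the default design; patient-level metrics are the
arithmetic mean of the available (non-missing) ROI values, so a metric
eligible in only one ROI uses that single value, and a metric missing in
both stays missing.

## Staining metrics

For each ROI and marker the four-bin tally yields percentages over all
detected cells of that marker's slide.  The H-score is the intensity-
weighted summary `1·(%weak) + 2·(%moderate) + 3·(%strong)`, spanning 0 (no
staining) to 300 (all cells strong).  Percent positivity and cell density
(positive cells per mm² of window) depend on a positivity rule:
*any-stain* (weak + moderate + strong, the default for density) or
*strong-only*.  Spatial analysis always uses strong-only positivity; the
rule in force is recorded in the run manifest.

## Spatial statistics

**Normalized bivariate Ripley's K.**  For ordered marker pair (1 → 2) with
point counts n₁, n₂ in a window of area A,

    K̂(r) = A / (n₁ n₂) · Σ_{i∈1, j∈2, 0 < d_ij ≤ r} 1 / w_ij,

with isotropic edge correction: w_ij is the fraction of the circumference
of the circle centered at point i through point j that lies inside the
window.  For an axis-aligned rectangle this fraction has a closed form:
each edge nearer than d removes an arc of half-angle arccos(e/d), and
when the circle encloses a corner the overlap of the two adjacent edge
arcs, `arccos(e₁/d) + arccos(e₂/d) − π/2`, is restored.  The normalization
`nK(r) = K̂(r)/(πr²)` makes nK an observed-over-expected ratio: 1 under
complete spatial randomness (CSR), above 1 for clustering, below 1 for
dispersion.  `nK(25) = 1.30` reads "30% more type-2 cells within 25 µm of
a typical type-1 cell than expected at random".

Conventions fixed for reproducibility: pairs at exactly d = r count
(closed ball); cross-type pairs at d = 0 (coincident centroids of distinct
cells) count with the limiting interior weight w = 1; for the univariate
case self-pairs and coincident duplicates are excluded and the denominator
is n(n−1), the standard unbiased estimator.  Edge weights are uncapped; a
warning (not an error) is emitted when r exceeds a quarter of the shorter
window side, since the default radii (25 and 125 µm) are small relative to
the default window.  The two radii provide local and global views of
clustering; they are strongly rank-correlated on tissue with a shared
clustering mechanism, and downstream analysis uses 25 µm (about twice a
tumor-cell radius, i.e. the immediate cell vicinity).

**Eligibility.**  A pattern enters spatial analysis only with ≥ 10
strong-positive cells; a bivariate statistic requires both patterns
eligible, and ineligible metrics are recorded as missing rather than
computed on sparse patterns.  The threshold is a consensus convention, not
a validated standard.

**Nearest-neighbor distances.**  Directed Euclidean NN distances, one per
source cell, excluding self-matches for same-type queries; medians are
the per-ROI summary.  Joint NN-distance distributions (distance to the
nearest proliferating cell vs. nearest apoptotic cell, per fibroblast)
are summarized by a product-Gaussian kernel density on a 128 × 128 grid
over [0, max] per axis with the normal-reference (Scott) bandwidth
`σ̂ · n^(−1/6)` per axis, and scaled by the grid maximum so the peak is
exactly 1.0; per-axis medians are carried for annotation.  A degenerate
axis (zero variance) falls back to a nominal 1%-of-scale bandwidth so the
density concentrates at the observed value.

## Survival analysis

**Endpoints.**  Overall survival from metastatic diagnosis (OS), and OS
re-anchored at first receipt of immunotherapy (OS-IT) or targeted therapy
(OS-TT), derived by subtracting pre-differenced therapy-start offsets;
event indicators pass through.  All times are months.  Therapy response is
classified from first-line progression-free survival: responder > 9
months, resistant < 6 months, indeterminate between (inclusive), with
missing PFS for a treated patient classified indeterminate with a warning.

**Optimal cut-points.**  Since no standardized cutoffs exist for these
metrics, each is dichotomized at the maximally selected log-rank
cut-point: candidates are midpoints between consecutive distinct observed
values whose induced split leaves at least `min_prop = 0.1` of patients on
each side, the unweighted log-rank chi-square (hypergeometric variance) is
evaluated at each, and ties break toward the smaller cutoff.  Cut-points
are re-derived on each endpoint's contributing subset by default
(`cutpoint_policy = "per_endpoint"`); determining them once on OS and
reusing them is available as a configuration switch.

**Cox models.**  Each dichotomized metric enters a multivariable Cox
proportional-hazards model with age (years at diagnosis) and IMDC risk
category as covariates.  IMDC is treatment-coded with *favorable* as the
reference; patients with indeterminate IMDC form a fourth category level
rather than being dropped.  Ties are handled by Efron's method and
intervals are Wald 95% CIs — the dominant defaults in survival practice.
Constant covariate columns are dropped with a warning; non-convergence
propagates with diagnostics.  Median survival per group is the smallest
observed time at which the product-limit curve reaches 0.5.

**Multiplicity.**  Benjamini–Hochberg FDR adjustment is applied to the
nine metric p values within each endpoint (default); pooling across all
27 tests is a configuration switch.

**Known caveat.**  The cut-point selection maximizes the very statistic
the subsequent model tests, so the *unadjusted* Cox p values of the screen
are anti-conservative under the null.  No selection correction is applied,
matching common practice with maximally selected statistics; the
recovery and calibration tests of the survival machinery therefore fit the
generating (continuous-covariate) model, where type-I error is nominal.

## Group comparisons and correlations

Wilcoxon rank-sum tests compare NN-distance distributions, treating cells
as observations (acknowledged within-patient pseudo-replication; a
patient-level alternative is to compare per-patient medians).  Exact
enumeration is used for small samples (both n ≤ 50, no cross-group ties),
otherwise the continuity-corrected normal approximation.  Responder-vs-
resistant metric comparisons use Welch's unequal-variance t-test.
Spearman correlations between metrics use pairwise deletion (≥ 3 complete
pairs) and are labeled weak (0.2–0.4), moderate (0.4–0.6), or strong
(0.6–1.0), with −0.4–0.2 reported as none/weak-negative.  All tests are
two-tailed at α = 0.05.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
not the imaging process (no pixel-level rendering, no segmentation error
model).

**Tissue.**  Fibroblast (aSMA) cells follow a homogeneous Poisson process
in the window.  Proliferating (Ki67) cells are Thomas-type offspring:
each fibroblast spawns Poisson(µ) offspring displaced by an isotropic
Gaussian (σ, default 15 µm), re-drawn until inside the window, plus an
independent Poisson background sized so the marker's total expected count
is invariant to µ.  This is the minimal generative mechanism with
controllable cross-type clustering and known moments: the implied
cross-pair expectation is
`nK(r) = 1 + µ·(1 − exp(−r²/2σ²)) / (λ₂ π r²)`.
Apoptotic (Casp3) cells are sampled without replacement from a uniform
candidate pool (3× oversized) with probability ∝ 1 − exp(−d/scale), d the
distance to the nearest fibroblast (scale default 20 µm), reproducing
longer fibroblast→apoptotic NN distances without claiming a biological
mechanism.  Intensity bins are drawn i.i.d. per marker, so strong-only
patterns are independent thinnings that inherit the second-order
structure.  Defaults (per-slide expected counts 7500 / 9000 / 6000 and
bin mixes) put the fibroblast compartment near an H-score of 35 and an
any-stain density of ~1900 cells/mm², preserve the marker ordering
aSMA > Ki67 > Casp3 in both H-score and density, and leave ~15 expected
strong Casp3 cells per ROI — so occasional spatial-eligibility failures
occur by design, as they do in real cohorts.  The H-score cannot fall
below the any-stain positivity percentage (all weights ≥ 1), so jointly
matching very low H-scores and high positive densities at realistic
cellularity is impossible; where a trade-off was needed the defaults favor
the fibroblast compartment's values and the cross-marker ordering.

**Cohort.**  Per patient, tissue parameters are jittered around the
cohort-level values (lognormal on counts and attraction/repulsion
strengths, Dirichlet on bin probabilities), defining per-patient *true*
metrics analytically.  Survival times are exponential with hazard
`h₀ · exp(Σ βₖ zₖ + 0.02·(age − 59) + IMDC effect)`, where zₖ are the
standardized true metrics and h₀ gives a 48-month baseline median;
censoring is independent exponential (mean 90 months) with an
administrative cap at 200 months, yielding ~40% censoring.  Demographics
mirror a typical metastatic ccRCC cohort: age ≈ N(59, 9) clipped to
[33, 87]; IMDC favorable/intermediate/poor/indeterminate at
21/58/9/12%; first-line therapy IT/TT/both at 53/44/3%.  Default nonzero
coefficients plant the strongest hazard on the Ki-67 H-score (log 1.8 per
SD), weaker effects on the aSMA and caspase-3 H-scores and the Ki-67
density, and none on the clustering metrics.  PFS is drawn within the
class bands (responder 9 + Exp(6), resistant U(0.5, 6), indeterminate
U(6, 9)) after class assignment at configured fractions.  The *observed*
metric table adds 5% lognormal measurement noise to the truths; with
`materialize=True` the per-patient ROIs are generated as cell tables so
the full measurement pipeline runs instead.  The returned manifest records
the coefficients and standardization for recovery tests.

What the generator does **not** emulate: spatially varying cell intensity
(staining gradients), correlation between intensity bin and position,
slide-alignment error between adjacent sections, segmentation
false-positives/negatives, informative censoring, and treatment effects on
the hazard.  Passing tests therefore demonstrate that the estimators and
the screen behave correctly under the stated model, not that the model
captures every feature of real tissue.

## Numerical choices and problem sizes

- Arc fractions are closed-form with arccos arguments clipped to [0, 1];
  a circle with no arc inside the window raises (cannot occur for centers
  inside the window at the radii used, guarded anyway).
- The KDE grid is 128 × 128 by default; bandwidths are per-axis Scott.
- Candidate cut-points are exhaustively enumerated (no grid
  approximation), so the search equals brute force by construction.
- Verification sizes, chosen to make Monte-Carlo error small relative to
  the tolerance being checked: CSR calibration uses 500 replicate pattern
  pairs at 200 points per type (band ±0.02 around 1.0); edge-correction
  geometry is checked against dense angular sampling (10⁶ base angles
  with bisection-refined crossings) on 1000 random cases; hazard-ratio
  recovery uses 50 replicates of 500-patient cohorts; null calibration
  pools 540 metric tests.
- All randomness flows through `numpy.random.Generator` seeds; identical
  seeds give byte-identical pipeline outputs.

## Limitations

- Cut-point-selected Cox p values are anti-conservative (see above).
- Cell-level Wilcoxon tests ignore within-patient clustering.
- The bivariate K estimator assumes first-order homogeneity within the
  ROI; inhomogeneous variants, pair-correlation functions, and envelope
  tests are out of scope.
- The generator's analytic nK truths for the repulsion-linked pairs are
  monotone proxies of the thinning scale, adequate for coupling survival
  to structure but not moment-exact like the Thomas attraction formula.
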