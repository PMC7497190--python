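# Methods

## Scene model and conventions

**Depth semantics.** Depth values are perpendicular (z-axis) distances in
metres, as reported by time-of-flight depth streams. File storage follows the
common depth-PNG convention: 16-bit grayscale, millimetre values, 0 as the
invalid sentinel; whitespace-delimited text matrices (metres) are accepted
interchangeably. Valid readings are restricted to the device working range
(default ≤ 4.5 m).

**Frame averaging.** Repeated captures of the static scene (≥ 5 frames at
the default) are superimposed per pixel over the frames in which that pixel
holds a valid reading; a pixel valid in no frame stays invalid. The per-pixel
frame count is kept as provenance.

**Calibration.** The camera sits a nominal 0.50 m behind the eye on the line
of sight. Calibration subtracts the constant `centre depth − tape-measured
viewing distance` from every valid pixel, making the map eye-referenced with
the centre pixel exact. A uniform additive offset is the plain reading of a
central-pixel correction; the small-angle error it introduces off-axis is
accepted. Pixels driven ≤ 0 become invalid. If the centre pixel itself is
unreadable (e.g. a window covers it), `calibrate` raises; the scene
*pipeline* instead falls back to the configured nominal offset and sets the
target vergence from the tape measurement, recording the fallback in
provenance.

**Defocus map.** `F(p) = 1/d(p) − V_t` with `V_t` the centre-pixel vergence;
positive = hyperopic (nearer than target), negative = myopic (farther).
Invalid pixels are filled with `−V_t` (the no-vergence rule: no usable depth
is treated as optically at infinity), so every pixel is finite and the map
needs no masking downstream.

**Pixel-to-angle mapping.** Ideal pinhole: `θx = atan((u−u0)/fx)`,
`θy = atan((v0−v)/fy)` (positive up), with focal lengths from the configured
field of view (default 70.6° × 60° at 512 × 434 px, both configurable; the
implementation is resolution-agnostic).

**Eccentricity.** Defined as the radial coordinate of the planar-angle chart,
`ε = √(θx² + θy²)`. This makes the 30° analysis field an exact circle of
area π·30² deg² in the coordinates over which dioptric volumes are
integrated, so the uniform-disc closed form holds exactly in the limit. It
deviates from the true ray-to-axis angle by < 1.5° at the field edge (the
two agree to first order); with equal angular sampling it is exactly
radially symmetric in the angle chart, only approximately so in pixel
radius.

## Metrics

**Dioptric volume.** Trapezoidal double integration over the separable
`(θx, θy)` grid in degrees (`numpy.trapezoid` applied per axis), giving
D·deg² literally. The integrand is the defocus map zero-filled outside the
region mask; since the rings (5°-wide annuli, half-open, outermost closed at
30°) and the quadrants (90° wedges bounded by the ±45° diagonals, assigned
through a single shared modular index so float rounding cannot drop diagonal
pixels) partition the disc, and trapezoidal integration is linear, regional
volumes are exactly additive (observed ≲ 1e-13 relative). A pixel is in or
out of a region by its centre's eccentricity; no partial-pixel weighting.
The double-myopic variant doubles negative values before integration, so
`DV_2M = DV + ∫min(F,0)` holds as an identity and pure-hyperopic scenes are
unaffected.

**Scale.** No area normalisation is applied; a whole-scene DV is of order
10²–10³ D·deg² for realistic desk scenes. A `mean_defocus` convenience field
(DV divided by the integrated mask area) is emitted alongside. **SD_D** is
the unweighted sample (n−1) standard deviation of `F` over the mask pixels,
in dioptres; no solid-angle weighting.

**Coverage.** The default camera's vertical half-field (30.0°) only just
spans the disc, so the gridded mask covers ≈ 99.96% of π·30²; the coverage
fraction is reported, and a map whose grid cannot reach 30° triggers a
warning.

## Synthetic scenes

Ideal planes ray-cast through the pinhole: a desk plane through the on-axis
book point at `working_distance + camera_offset`, tipped by `desk_tilt` about
the horizontal axis (0° = fronto-parallel; positive tilts the upper image
away, so a noise-free 0°-tilt scene at the book distance yields `F ≡ 0`
inside the mask after calibration — the pipeline's null case); a
fronto-parallel wall; rectangular clutter at fixed distances (nearest surface
wins); an optional window rectangle emitting no return. Additive Gaussian
depth noise (default SD 4 mm) per pixel per frame, clipped at zero; readings
beyond the working range become invalid, matching the single no-vergence
rule. No infrared physics, inter-reflection, occlusion by the subject's own
body, or colour imagery is modelled — the geometry suffices to exercise
averaging, calibration, conversion and integration. Defaults (book at
0.30 m, 0.50 m camera offset, 25° tilt, wall at 2.5 m, 5 frames) describe a
typical child's desk; real scenes' DV/SD_D distributions are only loosely
matched, so passing tests demonstrate correctness of the computations, not
realism of any particular scene.

## Synthetic cohorts

Covariates are drawn to match the reference cohort descriptives: age
N(9.3, 1.2²) years (untruncated — the 7–12 recruitment band is documentation,
not a clip, so sample means are unbiased for the specified means), baseline
M N(−1.51, 2.02²) D (cylinder ≤ 0 drawn separately and sphere derived so
`M = S + C/2` holds exactly), working distance N(0.297, 0.06²) m, desk time
log-normal(median 2 h/day, σ = 0.7), outdoor time log-normal(median 2 h/week,
σ = 1.0), home-size groups with probabilities (0.32, 0.34, 0.34) over the
three published floor-area bands, parental myopia with probabilities
(0.12, 0.42, 0.46).

Regional volumes are shifted log-normals; ring DVs sum to DV, quadrant DVs
are a Dirichlet split of DV, and the double-myopic variants subtract a
positive log-normal myopic part so `DV_2M ≤ DV` always. The 15–20° ring is
calibrated to SD ≈ 1.07 D·deg² so that, with slope −0.18 D per transformed
unit, its standardized effect on ΔM is ≈ −0.43 at the reference total SD.

The refraction change is `ΔM = −1.49 + 0.12·age + 0.05·M − 0.18·tDV20 + ε`,
ε ~ N(0, 0.36²); the intercept and residual SD are chosen once so the
population mean and SD of ΔM are ≈ −0.56 and ≈ 0.45 D. `tDV20` is produced
by the *same* two-step transform the analysis applies, so refitting the
analysis model on generated data is exact-model OLS and coefficient recovery
is a clean check (retention of the term and ~95% CI coverage). All remaining
covariates are generated null, giving stepwise selection something to
correctly discard. Cross-correlations present in real data (e.g. working
distance vs DV) are *not* emulated.

## Statistics

- **Two-step transform**: mean-tie fractional ranks `(r − c)/(n + 1 − 2c)`
  with the Blom constant c = 3/8 (configurable), inverse-normal scores,
  rescaled linearly to the input's sample mean and (n−1) SD. Strictly
  rank-preserving, hence Spearman correlations with any third variable are
  unchanged. Constant input or n < 3 raises.
- **Partial Spearman**: rank all three variables, apply the first-order
  partial-correlation formula on the ranks, p from the t approximation with
  n − 3 df (n − 2 without a control). Matches pingouin's
  `partial_corr(method="spearman")` to ~1e-10. A control perfectly
  rank-correlated with either variable raises.
- **Backward stepwise OLS**: fit all terms plus intercept; repeatedly drop
  the single term with the largest p ≥ 0.05 (exact ties: the later column,
  recorded in the removal trace) and refit; stop when all remaining p < 0.05
  or none remain. Standardized coefficients come from refitting on z-scored
  variables (response included, indicators included, the convention of
  mainstream stats packages), so `std B = B·SD(x)/SD(y)` holds. VIF per
  retained term via statsmodels; singular designs are rejected up front with
  the offending columns named via pivot diagnostics. Under a pure-noise
  response with k near-orthogonal predictors the all-removed rate is ≈
  (1 − α)^k — the survivor of the elimination ladder is effectively the
  minimum of k null p-values.
- **Group tests**: one-way ANOVA (and Kruskal–Wallis for the skewed scene
  metrics) across home-size tertiles — ranked split with sizes n//3 plus the
  remainder assigned to the larger-home groups (16/17/17 at n = 50), explicit
  cut points optionally overriding; exact Bonferroni (p × number of pairs,
  capped at 1) for pairwise tests; classical pooled independent t-tests for
  the 2 h/day desk-time and 2 h/week outdoor-time Low/High splits (Welch
  available by configuration). Any group with fewer than 2 observations
  raises; the cohort pipeline catches this and reports the error in the
  univariate section rather than voiding the whole document.

The four regression blocks (ring/quadrant × single/double myopic potency)
each offer the full covariate set — age, baseline M, working distance,
Low/High desk and outdoor indicators, parental-myopia and home-size
indicators (references: no myopic parent, Small home, Low time), transformed
SD_D — plus the block's transformed regional volumes.

## Problem sizes and tolerances

Closed-form and oracle checks use grids up to 512²; additivity is asserted at
1e-10 relative tolerance (observed ~1e-13); integration and partial-Spearman
oracles at 1e-12. Simulation-based checks use 200 transform samples, 1000
stepwise-null replicates at n = 50, and 100 recovery replicates at n = 500 —
sizes at which the Monte-Carlo error is comfortably below the asserted
margins while the whole suite runs in well under a minute of compute.

## Known limitations

Single-time-point scenes (no temporal integration of defocus), no eye-fixation
data (scene defocus is not mapped through eye optics to retinal defocus), no
lens-distortion correction or multi-view registration, and an additive-only
central calibration (a multiplicative alternative is not implemented). The
synthetic cohort's null covariates and missing cross-correlations mean
passing recovery tests validate the estimator, not epidemiological realism.
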