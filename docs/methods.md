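# Methods

`canopyage` implements a chronosequence analysis of post-fire canopy
structure for semi-arid, fire-killed (obligate-seeder) woodlands: structural
metrics are computed from 1 m canopy height models (CHMs), their recovery
trajectories over stand age are fitted with additive smooth models, and the
relationship is inverted to predict stand age from structure.  Because the
package ships no field data, a calibrated synthetic generator stands in for
the plot network; this note records the model, its parameters, and the design
choices that were genuinely open.

## Structural metrics

For a CHM with valid (non-nodata) pixels:

* **H_max** — the 98th-percentile pixel height (linear-interpolation
  quantile, ground zeros included).  A robust top-of-canopy height that
  ignores isolated spikes.
* **Cover_5m** — the percentage of valid pixels *strictly* above 5 m.  The
  5 m threshold separates live canopy from low regrowth; it is configurable.
* **H_cv** — coefficient of variation (sample sd over mean, n−1 convention)
  of pixel heights **above the cover threshold**.  Computing the CV over
  canopy pixels only keeps it bounded and interpretable as canopy-height
  heterogeneity; including ground zeros would let the mean approach zero and
  the CV diverge in sparse stands.  Fewer than two canopy pixels yields NaN
  (an undefined result, logged), not an exception.
* **Rumple_norm** — 3D canopy surface area over ground-projected area,
  divided by H_max (units m⁻¹).  The surface is triangulated on the
  pixel-center grid with a fixed lower-left→upper-right diagonal per cell;
  cells touching a nodata pixel are excluded from both surface and ground
  area.  A flat canopy of height *h* gives exactly 1/*h*; an inclined plane
  of slope *s* gives √(1+s²)/H_max.

Cropping uses pixel-center membership in a half-open box (min edge
inclusive), which makes cropping idempotent and unambiguous at edges.

## Truth trajectories and their calibration

Each attribute follows a parametric curve of stand age *t* (years) whose free
shape parameter is solved at construction so the curve passes through the
study system's anchor values; the curve families themselves are package
choices:

| attribute | form | anchors enforced |
|---|---|---|
| Cover_5m (%) | gamma hump 48·(t/120)^a·e^{a(1−t/120)} | peak 48 % at 120 yr; 20 % at 450 yr (a ≈ 0.613) |
| H_max (m) | monomolecular 15.5·(1−e^{−t/65}) | ~15 m plateau; ~0.9 m decade⁻¹ rise over 150 yr |
| density (ha⁻¹) | 20 + 5980·e^{−t/45} | >4000 ha⁻¹ young; ~20 ha⁻¹ at 450 yr |
| basal area (m² ha⁻¹) | lognormal hump, peak 15 at 160 yr | 10 m² ha⁻¹ at 420 yr (σ ≈ 1.072) |
| H_cv (–) | 0.25 + 0.45·e^{−t/τ} + 0.35·(t/450)^1.5 | minimum at 75 yr (τ ≈ 19.3) |
| Rumple_norm (m⁻¹) | gamma hump, peak 0.35 at 60 yr | 0.15 at 450 yr |

The high young-stand H_cv component (amplitude 0.45, ~19-yr timescale)
represents standing dead trees: many stems die upright in the fire and decay
over decades, leaving tall thin spikes over an otherwise low canopy.

Rainfall enters linearly, centred at 290 mm/yr (the gradient midpoint), and
is scaled so the wet-vs-dry contrast over 260→302 mm/yr equals +1.2 m
(H_max), +7 pp (Cover_5m), +0.02 m⁻¹ (Rumple_norm) additively, and −10 %
relative (H_cv, multiplicative).  Plot size enters as coefficient·ln(area/4.4 ha)
for the three scale-dependent metrics (H_max 0.4, H_cv 0.02, Rumple 0.01);
cover, basal area and density carry no plot-size or rainfall effect.

## Tier A generator (plot tables)

Defaults emulate the study design: 250 plots; ages uniform on [1, 450] yr;
rainfall uniform on [250, 330] mm/yr, independent of age by default (a
Gaussian-copula rank correlation of −0.57 is available to reproduce the
study's confounding); plot areas lognormal with mean 4.4 and sd 2.0 ha;
coordinates uniform on a 600 × 600 km region.  Ages are sampled uniformly
because the real age distribution is unknown beyond its range.  Per-metric
Gaussian noise (sd: H_max 1.2 m, cover 7 pp, H_cv 0.07, rumple 0.05 ≈ 15 %
of its peak, basal area 2.5 m² ha⁻¹, and 0.15 on log₁₀ density) is sized so
that 250-plot fits show realistic scatter while recovering the anchors;
noisy values are truncated to their valid ranges (cover ∈ [0, 100], heights
and CV ≥ 0), and density noise acts on the log scale so density stays
positive.  Everything is reproducible from a single integer seed.

What Tier A does **not** emulate: spatial autocorrelation (coordinates are
pure noise), platform differences, age-estimation error in the
chronosequence itself, and non-Gaussian metric error.  Passing tests
therefore demonstrate that the estimators recover known trajectories under
clean sampling assumptions — not that they would do so on field data.

## Tier B generator (stand scenes → CHMs)

Live canopy trees are placed by a homogeneous Poisson process.  The Boolean
model gives the covered fraction of intensity-λ random disks with mean area
A as 1 − e^{−λA}, so λ = −ln(1 − c)/A hits a target cover c.  Two
refinements make the rasterized scene quantitatively consistent with the
truth curves:

1. the calibration uses the mean crown area **above the 5 m threshold**
   (crown edges of short trees dip below it), and
2. the centre of the tree-height distribution (Normal, sd 1.5 m, truncated
   above 5 m) is solved so the Boolean-model-implied pixel-height 98th
   percentile equals the truth top height — the raw p98 of a stand whose
   *mean* height is the target would overshoot by sampling the tall tail.

Crowns are spherical caps (height drop of one crown radius at the edge,
radius 0.18·height) rasterized by max-compositing over pixel centers; cones
are available.  Snags are near-zero-crown spikes (radius 0.25 m) with
heights drawn around the pre-fire top height and density
200·2^{−age/20 yr} ha⁻¹.  Stands younger than 5 yr (the canopy
establishment age) carry only sub-5 m regrowth, so a 1-yr-old scene without
snags has zero cover above 5 m.

Known internal tension, by construction: at age 10 the truth cover anchor
(~18 % above 5 m) and the truth top height (~2 m) cannot both be realized by
any physical scene — any canopy above the threshold forces the CHM p98 above
5 m.  Tier consistency is therefore asserted for cover at all probe ages but
for H_max only at ages ≥ 75; snags intentionally add further young-age H_max
inflation (that is the H_cv mechanism).

## Additive smooth models

Trajectories are fitted as Y = β₀ + f₁(age) + f₂(rainfall) + f₃(area) by
penalized least squares: cubic B-spline bases (dimension 10 per smooth,
interior knots at predictor quantiles), an exact ∫f″² curvature penalty
(Gram matrix by Gauss–Legendre; correct for uneven knots, with the linear
functions unpenalized), and smooths centred over the training data for
identifiability.  Smoothing parameters minimize the generalized
cross-validation score n·RSS/(n − γ·edf)² with γ = 1.4, the standard
inflation that counters GCV's tendency to undersmooth when its profile is
flat; optimization is a coarse common-λ grid followed by Nelder–Mead on
log λ.  GCV was chosen over REML to avoid carrying mixed-model machinery;
a one-smooth cross-check against mgcv's REML fit is part of the test suite.
Tree density is fitted on the natural-log scale and back-transformed with
the naive exponential (no smearing correction) — predictions estimate the
conditional median.  Effective degrees of freedom are the hat-matrix trace;
adjusted R² is 1 − (1 − R²)(n − 1)/(n − edf − 1).

Fitted curves are evaluated at the training-mean rainfall and plot area
(conditional, not marginal, predictions).  Evaluation outside the sampled
age range raises unless explicitly allowed, in which case covariates are
clipped to the boundary.  Rates of change are central finite differences of
the fitted curve (grid step ≤ 5 yr), reported per decade; extrema are grid
arg-extrema refined by a local quadratic, with boundary extrema flagged
rather than rejected.  No age × rainfall interaction is fitted.

Boundary behaviour is the known weak spot of any k≈10 smooth here: the cover
curve's curvature at ages < 20 yr exceeds what the basis can follow (sup
error up to ~1.5 pp even with zero noise; mgcv behaves comparably), and
curve features read off at the extreme old-age boundary carry extra
variance.

## Age inversion and validation

Age models flip the formula: age = Σ f(metricᵢ) + f(rainfall) + f(area),
for a suite of 11 metric subsets (4 singles, 6 pairs, full set).  Hold-out
validation stratifies over 11 equal-length age classes spanning the
*observed* range (the class count is taken as primary; a fixed 35-yr width
cannot tile 1–450), reserving ⌈10 %⌉ of each class (≥1 when the class has
≥2 members; singletons stay in training).  Per repetition, RMSE and
R² = 1 − SSE/SST (about the validation mean; negative values permitted) are
computed on the hold-out; repetitions draw independent substreams of one
seed, so the first repetition is identical whatever the repetition count.
Predictions are clamped to the training age range to prevent spline
extrapolation blow-ups.  Per-age-class bias (mean/median/IQR of predicted −
observed) and an empirical semivariogram γ(h) of residuals complete the
diagnostics.

The structure–age map is not injective: young stands combine low cover with
snag-driven high H_cv, mimicking old growth.  On default synthetic data an
H_cv-only model regularly assigns ages > 300 yr to plots younger than 35 yr;
the test suite asserts this failure mode is reproducible.

## Problem sizes and numerical choices

Tests and the acceptance script use the study-scale design (250 plots, 10
seeds) for trajectory recovery, 50 repetitions for validation orderings
(500 is the reference setting for real analyses), and 20-seed Monte-Carlo
averages on ~2 ha scenes for tier consistency.  Degenerate inputs are
handled explicitly: all-nodata rasters and unsolvable anchors raise;
sub-threshold canopies yield NaN metrics that propagate as missing values;
validation-fit failures are skipped and counted, with >10 % failures an
error.  Read heights in [−0.01, 0) m are clamped to zero; lower values are
rejected as corrupt.
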