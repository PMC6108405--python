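# Methods

## Scan model and conventions

A scan is a population of pulses emitted from one instrument position over
a zenith × azimuth grid.  Zenith is measured from the vertical (0° = up,
90° = the horizontal optical plane, values to 180° permitted for
downward-looking rows); azimuth counterclockwise from +x viewed from
above — all metaproperties are rotation-invariant, so the azimuth origin is
arbitrary.  Coordinates are sensor-relative (origin at the optical centre,
z up); the mounting height is carried as instrument metadata only.
Spherical to Cartesian: x = d·sinθ·cosφ, y = d·sinθ·sinφ, z = d·cosθ.

Each pulse records at most two returns (distance, relative intensity in
[0, 1]), sorted by ascending distance.  Intensity units of real
instruments are uncalibrated and scale-dependent, so regression
coefficients against any particular instrument's intensity scale are not
comparable across data sources; the package normalizes to [0, 1].

Zenith bands are closed intervals.  Real scans sample discrete zenith
rows, so the "optical plane" subset (θ = 90°) is implemented as a ±0.5°
tolerance band (configurable), capturing the row nearest the plane.

## Metaproperties: numerical choices

* **Pulse metrics** (mean distance, mean intensity, 1st:2nd returns) are
  computed over the closed band [0°, 90°]; pulses without returns
  contribute nothing.  A scan with first returns but zero second returns
  yields an infinite 1st:2nd ratio: the value is carried as a flagged
  sentinel, is never log-transformed, and makes the row unusable for
  regression (listwise deletion with a count in the results).
* **OPA** orders vertices by azimuth (ties broken by ascending distance),
  closes the polygon, and takes the absolute shoelace sum over 2.
  Optical-plane pulses without returns are skipped, not interpolated, so
  the OPA of open scenes underestimates the sight-line envelope.  For
  star-shaped scenes (every real single-position scan) the polygon is
  simple.
* **Rugosity** triangulates the (x, y) projections of first returns in
  [0°, 30°] (scipy's Delaunay), lifts each triangle to its vertices' z
  values, and divides the summed 3-D area by the area of the convex hull
  of the projected points.  The hull equals the triangulated footprint,
  which guarantees rugosity ≥ 1, exactly 1 for a flat surface, and
  invariance to a constant z offset.  No sliver-triangle filtering is
  applied.  Fewer than 3 points, or a collinear projection, is reported
  as not-computable rather than imputed.

## Classification workflow

* **Separation.**  A variable completely separates the classes when the
  two class ranges do not overlap (non-finite values excluded).  The
  standard logistic MLE then has no finite maximizer; the workflow
  switches to Firth's bias-reduced fit, which maximizes
  l(β) + ½·log det I(β) (Jeffreys prior).  The Firth solver is a damped
  Newton iteration on the modified score U*(β) = Xᵀ(y − p + h∘(½ − p))
  with hat-matrix leverages h, step-halving on the penalized
  log-likelihood, convergence at step < 1e-8, cap 100 iterations.
  Standard errors come from the inverse Fisher information at the
  optimum; the model-level p-value is the penalized likelihood-ratio test
  against the intercept-only Firth fit.
* **Standard fit.**  statsmodels' Newton/IRLS solver.  A fit is flagged
  non-converged when the solver reports failure, a coefficient passes a
  divergence guard (|β| > 1000), or the Hessian becomes singular along a
  diverging path; in the singular case the fit is returned with missing
  coefficients rather than aborting the workflow.
* **"Wald statistic"** is reported as the two-sided Wald p-value of
  β/SE against the standard normal; model-level significance is the
  likelihood-ratio test against intercept-only.
* **Power analysis** sizes the testing set as
  n = ⌈N·x / ((N−1)·E² + x)⌉, x = Z²·r·(100−r), with r and E on the
  percent scale (Z = 1.96, E = 5 by default; r = 50 gives the familiar
  n → 385 asymptote).  Rounding is up.
* **Stratified split**: per-class testing counts are the
  largest-remainder rounding of proportional allocation (they always sum
  to the requested size and never deviate from proportionality by ≥ 1);
  rows are drawn without replacement with a seeded generator.
* **Model reduction** keeps a full model whose likelihood-ratio p is
  below α even when individual coefficients are non-significant (an
  overfitting guard); otherwise it iteratively removes the
  highest-Wald-p predictor and refits on the same training data.  A
  diverging fit flattens every Wald p to ≈ 1, making the ordering
  uninformative; in that case the reduction removes separating variables
  (the cause of the divergence) first.  The removal sequence is recorded.
* **Influence diagnostics**: standardized Pearson residuals
  r/√(1−h) (default threshold 3) and Cook's distances
  r²·h/(k(1−h)) (default threshold 1.5).  An observation may be both an
  outlier and influential; the lists are reported separately and the
  thresholds are configuration.
* **Evaluation.**  Classification threshold 0.5 on the predicted
  probability (the linear predictor is clipped before the inverse logit,
  so extreme penalized fits cannot overflow).  Chance accuracy is
  100·Σ(nᵢ/N)² over the population class counts.  The goodness-of-fit χ²
  compares predicted-class totals against true-class totals with
  df = k − 1; note that published χ² values for this workflow are
  construction-ambiguous, so only the formula is contractual here.  ROC
  AUC is the trapezoid rule (equal to the tie-aware Mann–Whitney pair
  statistic); PR AUC is average precision.  Confidence intervals are
  seeded stratified percentile bootstraps (default 2000 resamples) —
  the method is a package choice, as no standard is implied by the
  workflow definition.

## Simulator

The simulator is a statistical stand-in, not a radiative-transfer model:
beam divergence is not ray-sampled, and partial interception is a
Bernoulli draw (`second_return_prob`) rather than a waveform computation.
What it emulates is the population-level contrast structure of real
scenes; what it does not emulate is instrument-specific intensity
calibration, multiple scattering, topography, or motion artifacts —
so passing tests demonstrate the pipeline's correctness and the
*direction* and *separability* of the scene contrasts, not calibrated
agreement with any particular instrument's coefficient magnitudes.

* **Rooms**: an axis-aligned enclosing box (defaults 8 × 10 m footprint,
  ceiling 2 m above and floor 1.3 m below the optical centre — an
  ordinary room with a tripod-mounted sensor).  Exact first-return
  distances come from the slab-method ray–box exit distance; every pulse
  returns.  Reflectance ~ clipped Gaussian(0.75, 0.05) — bright hard
  surfaces.  `second_return_prob` defaults to 0.01 (edge effects only).
* **Forests**: canopy layer between 12 and 18 m; a skyward pulse escapes
  through a gap with probability 0.25 (the gap fraction of a moderately
  open canopy); otherwise the first interception is the nearest of a
  trunk cylinder (12 trunks of 0.25 m radius in a 30 m stand), an
  exponential understory free path (0.05 interceptors/m — a sparse
  understory with ~20 m mean free path), the canopy base plus a short
  exponential penetration depth, or the ground.  Interceptions beyond
  40 m are recorded as no-returns (the range clip).  Reflectance
  ~ Gaussian(0.35, 0.08) — absorption by foliage.  A returned pulse
  yields a second return with probability 0.25, placed a short free path
  behind the first.
* **Range noise** is Gaussian with σ = 0.05 m on all returns, reading a
  ±50 mm instrument range-error figure as a 1-σ scale; this is the
  mechanism that gives even a flat ceiling a rugosity well above 1.
* **Grids**: the default pattern is 131 zenith rows (0–130°, 1°) × 80
  azimuth columns (4.5°) ≈ 10⁴ pulses — desk-scale rather than the
  4–8 × 10⁵ pulses of a field instrument, chosen so that a full
  88-scan experiment runs in seconds; counts are configurable.  The grid
  always contains a row at exactly 90° and full coverage of the 0–30°
  and 30–35° bands.
* **Datasets**: per-scan seeds are spawned from a base seed
  (deterministic); per-scan jitter (canopy heights ±10%, gap probability
  ±20%, room dimensions ±20%, reflectance ±8–10%) creates within-class
  variance.  The temperate/tropical/coastal/inland presets shipped as
  YAML are illustrative structural variants, not calibrated scenes.

## Design choices where the design was open

* The rugosity footprint is the convex hull of the projected points
  (not the azimuth-ordered polygon): it matches the triangulated region
  and guarantees the ≥ 1 invariant.
* The 1st:2nd returns direction is asserted only as *separation*, not
  sign: the package's synthetic rooms have the higher ratio (solid
  surfaces produce few second returns), but the workflow never assumes a
  direction.
* Proof-of-concept experiments exclude the two completely separating
  ratio metaproperties by name and run in full-population mode
  (train = test = all scans); in synthetic scenes the remaining four
  metrics may themselves separate, in which case the workflow's own
  separation rule selects the Firth fit.
* When dropping separating variables would leave no predictors, the
  variables are retained and the penalized fit used instead.

## Problem sizes

The test suite uses a coarse 2,120-pulse grid for sweeps and a shared
10 + 14 scan dataset; the acceptance script simulates ten independent
32 + 56 scan datasets at the full ~10⁴-pulse default grid and reports the
minimum accuracy across seeds.  These sizes are the package's chosen
desk-scale study conditions; every quantity is recomputed at run time.

## Known limitations

* Only binary classification is implemented (the workflow is defined for
  the binomial case; other response families would substitute at the
  regression stage).
* The simulator's second-return placement is geometric, not physical;
  first:second ratios near 1/q are a design property, not a prediction.
* OPA of scenes with no-return optical-plane pulses underestimates the
  open-space envelope (skipped vertices).
* Standard-error-based Wald p-values under the Firth penalty are known to
  be conservative near separation; profile-likelihood intervals are not
  implemented.
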