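# Methods

This note documents the models and procedures implemented in
`planktransect`, the assumptions behind them, the defaults that matter, and
what the synthetic-data generators do and do not emulate.

## Segmentation

**Flat-fielding.** A towed line-scan shadowgraph camera has illumination
that varies along the scan line but is stable from frame to frame.  The
background is therefore estimated as a per-column mean intensity over a
trailing window of frames (default 100, updated causally) and divided out;
corrected intensities are clipped to [0, 1.5].  A frame identical to its
background maps to all ones.  Division by a non-positive background column
is an error that names the column, since it indicates a dead sensor column
rather than data.

**K-harmonic means (KHM).** Foreground detection clusters pixel
intensities with KHM, which minimises

    KHM(X, C) = Σᵢ k / Σⱼ ‖xᵢ − cⱼ‖⁻ᵖ,

the harmonic mean of point-to-center distances.  Unlike k-means, points far
from *all* centers dominate the objective, so a center is pulled onto the
small dark-organism mode even when it holds a fraction of a percent of the
pixels — the property that makes KHM suitable for shadowgraph frames.
Defaults: k = 2 (foreground/background), p = 3.5 (a common literature
choice; p > 2 is required for the update weights to exist), intensity-only
feature space.  The raw fixed-point recursion can overshoot and raise the
objective; each update is therefore backtracked (step halved toward the
current centers until the objective does not increase), which guarantees a
monotone non-increasing objective trace while preserving the standard
update direction.  Centers are estimated on a random subsample of at most
20 000 pixels and all pixels are then assigned to the nearest center; the
cluster with the lowest center is foreground.  8-connected components with
area ≥ 25 px (≈ organisms larger than ~0.33 mm at 66 μm/px) become ROIs.
Identical input values collapse the centers together, which is reported
rather than hidden.

## Classifier post-processing

The classifier emits, per vignette, a probability vector over fine classes
whose argmax is the predicted class.  Fine classes are mapped onto broader
ecological groups by a total mapping; the group label `"unknown"` is
reserved for filtered vignettes and can never be a mapping target.

**Metrics.** Group-level confusion counts give precision P = TP/(TP+FP),
recall R = TP/(TP+FN), F1 = 2PR/(P+R).  Weighted averages weight groups by
true-label support; groups with undefined precision (never predicted) are
excluded from the weighted mean rather than imputed.

**Threshold filtering.** For each fine class, the precision of its group —
restricted to that class's vignettes — is recomputed over a grid of
probability cut-offs t ∈ {0, 0.01, …, 0.99}, keeping vignettes with
`max_prob > t`.  The precision-vs-t curve is smoothed by local (lowess)
regression with span 0.5, and the threshold is the smallest t at which the
smoothed curve reaches the target precision (default 0.90).  The response
smoothed is the precision of the kept set at each cut-off (not a cumulative
variant); this is documented because either reading is defensible and the
choice affects thresholds only marginally on smooth curves.  Grid step and
span are configuration, not science: they were fixed a priori at values
fine enough to resolve the Beta-shaped confidence distributions.  If the
target is never reached the class is flagged unattainable and its threshold
is set to its maximum observed confidence, so the strict keep rule
(`max_prob > threshold`; a vignette exactly at its threshold becomes
unknown) filters every such vignette.  Classes with fewer than 20 predicted
test vignettes inherit their group's pooled threshold with a logged
warning.

**Correction factors.** Counts of a group classified with precision P and
recall R are biased by R/P relative to truth, so CF = P/R corrects them in
expectation when the confusion structure is homogeneous across the survey.
CF is computed once from the labelled test set and applied globally; groups
with zero recall are flagged uncorrectable and passed through.

## Concentrations and kriging

Vignettes are merged with the tow's sensor stream and binned into 1-m
half-open depth strata [d, d+1) per profile (one monotone leg of the
undulating tow).  The imaged volume of a stratum crossing is
`volume_rate × residence time`; the default rate of 0.168 m³ s⁻¹ sits
within the instrument's stated 150–185 L s⁻¹ envelope and is configurable.
Concentration = count / imaged volume × CF(group), in ind m⁻³.

Binned values are interpolated onto a regular grid (500 m along-track ×
1 m depth; cell centers at 250 m + k·500 m and 0.5 m + k·1 m) by ordinary
kriging.  Anisotropy is handled by scaling coordinates by the target
resolution before variogram fitting and kriging, so one isotropic variogram
acts in scaled space — a pragmatic choice that ties the anisotropy ratio to
the output grid rather than estimating a separate anisotropy model.  The
semivariogram is estimated on 15 lag bins up to half the maximum
separation (points subsampled to ≤ 3000 for the pair computation) and a
spherical model (exponential and gaussian available) is fitted by weighted
least squares with Cressie weights N(h)/γ²(h).  Constant fields return a
zero-sill model and nugget-dominated fits are flagged as weak structure.
The kriging system enforces Σλ = 1 via a Lagrange multiplier; with zero
nugget the predictor interpolates the data exactly.  Singular systems are
retried once with a 10⁻¹⁰ diagonal jitter.  Negative concentration
predictions are clipped to zero with a logged count.  Correction factors
are applied to the binned concentrations before kriging.

## Water masses

Speed and flow-toward direction come from the zonal/meridional components:
speed = √(u²+v²), direction = atan2(u, v) in degrees clockwise from north
(0° = northward flow).  This is the oceanographic convention — the
direction the water flows toward, not the meteorological "from" convention.

K-means clustering runs on standardized (|u|, |v|, speed) features
(signed u, v available behind a flag), 25 initialisations, fixed seed, for
k = 2…8; the elbow of the total within-cluster sum of squares (maximum
second difference) selects k, overridable to k = 3.  Clusters are ranked by
mean current speed: slowest → eddy water (ED), fastest → boundary-current
water (FC), intermediate → interface (IF).  Ranking by a physical quantity
makes the labels invariant to k-means index permutation.  Variance
explained = 1 − within-SS / total-SS on the standardized features.

Distance-to-FC is the minimum Euclidean distance from each grid cell to
any FC cell, computed in (along-track km, depth km); the vertical term is
retained but negligible at transect scales.  Mixed layer depth uses the
density-threshold criterion: the shallowest depth below a 5-m reference
where σ_t exceeds the reference value by 0.125 kg m⁻³, linearly
interpolated between samples; profiles that never cross are capped at the
deepest sample and flagged.  Anomalies remove the per-depth-level
along-track mean.

## Driver models

Per-taxon one-way ANOVA across water masses, with Tukey HSD pairwise
comparisons (family-wise adjusted p-values) where the ANOVA is significant
at α = 0.05.  Concentrations enter untransformed by default (log1p behind
a flag).  Water masses with fewer than two observations are dropped from
the comparison and noted.

The random-forest regression grows 500 trees with 14 candidate predictors
per split by default (both configurable; an mtry exceeding the design width
is an error, not silently capped — except in ablation refits, below).
Variance explained is out-of-bag: 1 − MSE_OOB / Var(y).  The categorical
water-mass predictor is one-hot encoded because the tree backend has no
native categorical support; its importance is summed over the indicator
columns so tables report one row per original predictor.  Two importance
measures are reported: total impurity ("node purity") decrease, and the
mean squared error increase under predictor permutation; rankings order by
MSE increase with node purity as tie-break.

**ALE.** For a continuous predictor, quantile bin boundaries span the
observed range (20 bins by default; duplicate quantiles merge empty bins);
within each bin the prediction difference between the predictor set to the
bin's upper vs lower boundary — all other variables untouched — is
averaged over the bin's observations, local effects are accumulated across
bins, and the curve is centered so the data-weighted mean effect is zero.
For a categorical predictor, levels are ordered by similarity of the other
covariates' distributions (mean two-sample Kolmogorov distance,
nearest-neighbour chained from the most extreme level) and consecutive-level
prediction differences are accumulated and centered by level frequency.
Because effects are estimated from *local* differences, correlated
predictors do not inflate each other's curves, which the tests verify
against closed-form and numerical oracles.

**Ablation.** A predictor's contribution is the drop in OOB variance
explained when the model is refitted without it under identical settings
and seed; mtry is capped at the reduced design width so the refit is
well-posed.

## Synthetic data: what it emulates, and what it does not

The generators produce every pipeline input with known ground truth, under
a single top-level seed split per sub-generator (fixed seed ⇒ bit-identical
output).

**Frames.** Dark elliptical blobs (Gaussian edge blur, contrast 0.4–0.5)
on a bright background (0.85) under a smooth multiplicative illumination
ramp (20 % peak-to-peak) with additive Gaussian pixel noise (σ = 0.02–0.03
grayscale units).  Planted boxes lie fully inside frames.  Not emulated:
real organism morphology, motion blur, overlapping transparent bodies,
depth-of-field effects — so segmentation tests demonstrate the correctness
of the flat-field/KHM/labelling chain, not field-grade detection rates.

**Classifier tables.** True fine classes are drawn from specified
abundances, predictions from a row-stochastic confusion matrix, and the
winning-class confidence from one of two Beta distributions — mode ≈ 0.89
for correct and 0.6 for incorrect predictions.  Real CNN confidence
calibration is undescribed for this class of model; the Beta model is an
explicit assumption chosen to make threshold filtering non-trivially
effective, and the uninformative-confidence case (identical distributions)
is covered by tests as the unattainable regime.  Expected per-group
precision/recall follow from the confusion matrix in closed form, which
serves as the oracle for the empirical metrics.

**Transect scenario.** A zonal section (60 km × 80 m at 500 m × 1 m
default resolution) crossing a cyclonic eddy (solid-body rotation, rim
speed 0.3 m s⁻¹, radius 12 km) embedded in a boundary current (1 m s⁻¹
toward 20°).  The blend weight between the two flows plateaus at ½ across
a 6-km interface band, making the interface a genuine third flow regime —
the construction that "three significant current clusters" describes; truth
labels are assigned by nearest regime (blend weight < ¼, ¼–¾, > ¾).
Hydrography carries linear stratification with an isopycnal-shoaling bump
at the interface; chlorophyll a subsurface maximum sits at the interface
with oxygen tracking it.  Taxa respond additively on log-concentration to
water-mass label, current speed, distance-to-FC and optionally
log1p(prey concentration), with lognormal noise (σ = 0.2) — so
random-forest/ALE recovery targets have known shapes and the prey-coupling
coefficient is a planted causal link that ablation should (and does)
detect.  The flow is barotropic (labels constant over depth) and the
transect is one-dimensional in space; fully 3-D eddy structure, inertial
motion, and tides are out of scope.

**Tow sampling.** An undulating path (ship 2.5 m s⁻¹, vertical
0.2 m s⁻¹, 3–79 m) crosses 1-m strata; per-taxon counts are Poisson with
mean concentration × imaged volume, and group-level misclassification
scatters counts through a confusion matrix multinomially.

## Problem sizes and numerical choices

Tests and the acceptance script use: classifier tables of n = 100 000 (the
scale at which empirical confusion converges to spec within 0.02 max-norm
and corrected counts recover truth within 5 %); 8 frames of 256² px;
transect grids of 120 × 80 cells; kriging on ≤ 2500 data points (random
subsample above that, dense-matrix OK being O(n³)); random forests of
200–500 trees on 300–1200 rows.  These sizes were chosen so each stage's
statistical claim is testable with comfortable margins while the whole
suite stays quick on one CPU.  Tolerances follow the source of error:
exact linear-algebra identities at 10⁻⁸, construction oracles at bin or
grid resolution, stochastic recoveries at 2–5 % with seeded generators.

## Known limitations

- Field-scale performance figures (per-transect concentrations,
  variance-explained percentages) depend on real cruise data and are not
  claims this package makes; synthetic recoveries bound correctness, not
  oceanographic realism.
- The lowess-smoothed precision curve can cross the target slightly before
  the raw curve does; held-out evaluation (the property actually tested)
  absorbs this.
- Ordinary kriging is stationary and isotropic in scaled coordinates; no
  trend (universal kriging) or kriging-variance maps beyond the optional
  weights output.
- KHM is run on intensities only; a positional feature space is possible
  behind the subsampling interface but untested against truth.
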