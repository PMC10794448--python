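# Methods

This note documents the models, estimators and numerical choices behind
`plaquetrend`, and what the synthetic cohorts do and do not establish about
behaviour on real data.

## Geometry of one frame

A frame carries two simple closed polygons in mm, lumen and vessel, in the
image coordinate system whose origin is the catheter. Polygons are
normalized counter-clockwise on load; self-intersecting or sub-3-vertex
inputs are rejected. Areas use the shoelace formula, centroids the polygon
area centroid, and the best-fit circle a Kasa algebraic least-squares fit.

Two diameter conventions coexist deliberately:

- ξ (diameter ratio) measures shape *relative to the catheter*: chords are
  cast through the image origin at 360 uniform directions, each chord being
  the sum of the outermost boundary crossings on the two sides.
- ψ (eccentricity) measures *intrinsic* shape: the same chord construction
  through the contour's own centroid. ξ_P normalizes the lumen–vessel
  centroid offset by the mean lumen diameter taken through the lumen
  centroid (this convention is fixed by the worked example: offset 0.5 for
  a unit-radius lumen gives ξ_P = 0.25).

Plaque-thickness features (ρ, ϱ) parameterize the plaque by rays from the
lumen centroid at 360 uniform angles: thickness(θ) is the vessel-hit minus
lumen-hit distance. Rays must cross each boundary exactly once per side;
multiple distinct crossings raise a geometry-inconsistency error rather
than silently picking one. An alternative parameterization by boundary
normals was rejected: normal fields of annotated polygons are noisy, and
the centroid-ray family is deterministic and self-consistent across frames.
When a frame has no plaque at all, ϱ (max/mean thickness) is defined as 1,
the value a vanishing uniform layer attains, keeping signals finite.

Curvature is estimated on a copy of the contour resampled to N = 256 points
equally spaced in arclength, which decouples the estimate from the
annotation vertex density. The tangent angle at each resampled vertex is the
angle of the central position difference; curvature is the central
difference of the unwrapped tangent angle over arclength, with the
wrap-around step closing the total turning of 2π. Δl is the constant
arclength step, so Σ Δl equals the perimeter exactly, and the roughness of
a circle, √((r/2π)·Σϰ²Δl), equals 1 to O(1/N²). Two accuracy caveats are
measured by the test suite: (a) the estimator sees the *polygon*, so when
the annotation has fewer vertices than N the resampling manufactures flat
runs and corner spikes, inflating τ and (slightly) κ — synthetic cohort
contours use 96 vertices for speed and carry this bias as a benign feature
property; (b) τ = max ϰ − min ϰ converges slowly in N because the central
differences smooth curvature extrema over a window of 4·P/N. Against exact
boundaries, τ and κ agree with analytic oracles to <1 % once the annotation
density exceeds N.

## Longitudinal signals and registration

Frame-wise features are linearly interpolated onto a uniform grid of
60 frames/mm starting at the first annotated position, with no
extrapolation past the last. The baseline and follow-up pullbacks are
aligned by an integer grid shift; the automated surrogate for the manual
procedure maximizes the mean Pearson correlation of the plaque-burden and
vessel-area signals over the overlap, searching all shifts that leave at
least 300 frames (5 mm) of overlap, ties broken toward zero shift.
`manual_shift` preserves the operator-driven workflow. Derivatives use
central differences (one-sided at the endpoints, which are first-order but
affect only two frames); no smoothing is applied before differentiation,
though a moving-average filter is available and off by default.

## Regions of interest and targets

ChPAV forms maximal sign-pure runs of PB_FU − PB_BL; frames with exactly
zero difference break runs. Runs shorter than 15 interpolated frames
(0.25 mm) are discarded, as are runs whose *peak* |difference| is below
0.5 % — the run-level peak reading of the discard rule; a mean-based
variant is exposed via `amplitude_mode`. PBR bins baseline PB into
[0,30), [30,60), [60,100], bin edges going to the upper bin. Windowed
criteria tile fixed windows at stride = window size, repeated at the
standard offsets and pooled (overlap across offsets is accepted; trailing
partial windows are dropped because the fixed window size is
definitional).

Volumes integrate area signals by the trapezoidal rule at 1/60 mm spacing
over the continuous interval [start, end), including the boundary sample at
`end` when it exists; this makes TAV/TVV of any disjoint exhaustive
partition sum exactly to the full-pullback values. ΔPAV = 0 is assigned to
the regression class so the two classes partition outcomes.

## Condensation and feature sets

Each ROI condenses the 36 baseline signals (18 features + 18 derivatives)
by median, IQR (P75−P25), central-80 % range (P90−P10), Shannon entropy,
and first-harmonic magnitude/phase. Entropy uses 16 equal-width bins over
the segment's own range (configurable); a segment constant to rounding has
zero entropy. The Fourier magnitude is normalized by 2/N so a
unit-amplitude single-cycle sinusoid has magnitude 1; the phase of a
zero-magnitude harmonic is defined as 0. Follow-up data never enters the
features — only the target (and the ChPAV partition).

`Sb` is `Sa` plus the four baseline ROI volumetrics (TLV, TVV, TAV, PAV),
which is the composition consistent with the 242-feature total of `Sd`
(20 + 4 + 6·36 + 2). The artery label is the only categorical feature; it
is one-hot expanded by the model stage and exempt from standardization.

## Model and evaluation protocol

The regressor is XGBoost with 256 estimators, maximum depth 12 and
squared-error loss; remaining hyperparameters are the library defaults,
frozen in `ExperimentConfig`. Folds are formed at the pullback level
(grouping by patient is available via `group_by`), stratified by the sign
of the pullback-level ΔPAV; 5 folds × 20 repeats yield 100 models, and
every ROI appears in exactly 20 test sets. Standardization
(mean/population-std; zero-variance columns map to 0) and the k-best
mutual-information selection (nearest-neighbour MI estimator against the
binary progression label, ties broken by column order) are fitted on the
training side only — a negative-control test verifies that refitting on
train∪test would change the parameters. Degenerate denominators define
MCC = r = 0 and per-class F1 = 0.

SHAP attributions are computed by an exact float64 TreeSHAP over the fitted
booster's dumped trees (path-dependent weighting by training cover), so
per-sample attributions plus the base value reproduce the float64 ensemble
margin to round-off; split thresholds and inputs are routed through float32
to match the booster's own comparisons, and the implementation is
cross-checked in tests against a brute-force Shapley enumeration and
against the booster's native float32 `pred_contribs`. Feature impact is
summarized as selection ratio × Σ of per-model mean |SHAP|, exactly 0 for
never-selected features.

## Synthetic cohorts

The generator encodes the statistical structure the analysis assumes, not
plaque biophysics. Per artery, the baseline plaque-burden field is a sum of
Gaussian bumps (σ 0.8–2 mm, every ≈2 mm) on a base level drawn from
42–58 %, clipped to 20–80 %; vessel area is a smooth field from 12–18 mm²;
lumen area follows from PB. The follow-up field adds focal signed Gaussian
bumps whose amplitude is `pb_slope·(PB_BL − 50) − statin_effect·STA +
N(0, noise_sd²)` with defaults slope 0.5 and noise 4.0, chosen so the
region-level ΔPAV is a monotone function of the regional median baseline PB
with R² ≈ 0.5 — a moderate, noise-dominated-but-detectable signal. Frames
are annotated at 0.3–0.5 mm spacing (mean 0.4); both phases share the
anatomical annotation grid, and an optional planted integer-frame shift
delays the follow-up content for registration tests. Contours are
star-shaped polar polygons around the catheter origin with smoothly varying
harmonic shape tracks; lumen polygons are radially rescaled and the
vessel-wall thickness scale solved from a quadratic so that polygon areas
equal the field values exactly, which guarantees lumen ⊂ vessel and makes
the generated PB recoverable bit-exactly from the rendered contours.
Clinical covariates are drawn independently from marginals typical of a
secondary-prevention IVUS trial population (e.g. age ~ N(58.6, 9.9²),
93 % male).

What passing tests on these cohorts show: every pipeline stage is
internally consistent, leak-free, deterministic, and able to recover a
planted regional progression signal of realistic strength (mean test MCC
≥ 0.5 with R² ≈ 0.5 planted, ≈ 0 under permuted targets). What they do not
show: performance on real IVUS data, where contour annotation error,
non-Gaussian progression patterns, catheter obliquity, and correlations
between clinical covariates and progression are all absent from the
generator.

## Problem sizes used by the shipped tests

The recovery experiment uses 96 arteries from 48 patients (25–45 mm
pullbacks, ≈540 ChPAV ROIs) — a deliberately scaled cohort that keeps the
full 100-model protocol intact. The geometry oracle suite uses 100 random
frames (dense-annotation frames for the curvature statistics);
reproducibility is checked by byte-comparing two complete CLI runs on a
6-pullback cohort.
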