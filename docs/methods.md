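# Methods

## Scope and data model

The package processes dynamic fluorescence recordings of an indocyanine-green
bolus into ROI kinetics curves and severity summaries. Two containers carry
the state: `FrameStack` (a T×H×W stack with strictly increasing timestamps,
field kind, optional working distance, and an append-only provenance list)
and `KineticsCurve` (a time/intensity series with ROI label, a normalization
tag set at most once, provenance, and an optional artifact mask). Every
operation returns a new object with exactly one provenance entry appended, so
a features table can always be traced back to the processing that produced
it.

Conventions used throughout: pixel coordinates are 0-based and row-major;
time windows are half-open `[t0, t1)`; trailing partial groups in temporal
binning and partial tiles in spatial downsampling are dropped rather than
padded, so every retained bin is an unbiased mean. Timestamps default to
`i / frame_rate` but explicit per-frame times always win. Composite-frame
layouts (white light / fluorescence / overlay tiled into one frame) are
supplied by configuration, not auto-detected, because they are
device-specific.

## Corrections

**Baseline subtraction** removes the pre-injection background by subtracting
the mean of the first `n_baseline` frames (default 10; at 5 fps that is the
first 2 s). Negative values are preserved — clipping is a consumer decision
(see MTT below).

**Flat-field correction (FFC).** A flat image `IF` (uniform fluorescent
scene) and a dark image `IB` correct a raw frame `IR` as
`IC = (IR − IB)/(IF − IB) · MFB` with `MFB = mean(IF − IB)`. Pixels where
`|IF − IB| ≤ 1e-6·MFB` are masked NaN; a calibration with more than half its
pixels unusable is rejected. Two variants are selectable: the as-typeset
form with `IR − IF` in the numerator, and a gain-only form `IR/(IF − IB)·MFB`
for stacks whose additive offset was already removed. The orchestrated
pipeline uses the gain-only form after baseline subtraction, because the
temporal baseline already contains the dark/ambient level; subtracting `IB`
again would introduce a spatially varying offset `−IB·MFB/(IF − IB)` that
biases ROIs in dim corners of the field.

**Working-distance correction.** For a flat surface imaged at distance `D`,
a pixel at object-plane offset `(x, y)` cm from the principal point lies at
`sqrt(D² + x² + y²)` from the camera, and isotropic emission gives an
inverse-square intensity falloff. Referring a recording to a standard
distance `Ds` multiplies each pixel by `(D² + x² + y²)/(Ds² + x² + y²)`.
Only this ratio form is implemented; absolute emitted power is never
estimated, and surface topography (per-pixel z) is out of scope — the
pixel pitch at the object plane and the principal point are required
configuration because they cannot be recovered from the frames.

## Kinetics

**ROI extraction** averages the pixels whose centers fall inside the ROI
disk (no partial-area weighting — membership is testable by enumeration);
masked pixels are excluded, and a fully masked disk is an error.

**Motion artifacts.** Subject motion and breathing contaminate curves with
spikes far faster than the few-second dye kinetics. Detection flags samples
whose deviation from the windowed median exceeds `mad_k` times the windowed
MAD (per-window `median(|window − median(window)|)`, floored at machine
epsilon so constant segments produce no flags). Defaults: window 11 samples,
`mad_k` 5 — breathing spikes are large and isolated, so the band can be
generous. Correction offers removal (times stay irregular; refusing to leave
fewer than 10 samples), a centered moving average (default width 5 samples =
1 s at 5 fps, short against the kinetics timescale), and local median
replacement of flagged samples only. PCA-based filtering is out of scope.

**Normalization.** Constant modes divide by the maximum or mean of a
normal-tissue reference curve — a pure rescaling. SBR is the pointwise ratio
`B(t)/N(t)` (zeros in the reference masked); CBR is
`(B(t) − N(t))/std[N(t)]` with the sample standard deviation (ddof 1,
configurable) over the full analysis window — the window is not specified in
the field's usage, so whole-window is the default with a switch. SBR/CBR
require a shared time grid; resampling is never implicit, a linear
`resample_to_reference` must be called explicitly so interpolation shows up
in provenance. nAUC divides a curve by its own trapezoidal AUC over the
whole analysis window, making curves unit-area; the trapezoidal rule is used
for every AUC because it is standard for irregular sampling and exact on
piecewise-linear fixtures. A curve can be normalized exactly once.

## Landmarks and features

Landmark detection assumes a baseline-subtracted curve with at least 20
samples. The uptake start `t0` is the first time with `m = 3` consecutive
samples above `k = 3` baseline standard deviations (baseline statistics from
the first 10 samples; for noiseless fixtures the threshold falls back to a
negligible fraction of the dynamic range). The peak `tP` is the global
maximum of the curve smoothed with a width-3 moving average (smoothing is
used only to locate the peak). The washout inflection `tInf` is the sample
breakpoint of the best continuous two-segment linear fit over `[tP, end]`
(exhaustive search over candidate breakpoints, least squares with basis
`{1, t − tb, (t − tb)₊}`); fewer than 4 post-peak samples censor it.

Features: IMAX is the value at the detected peak. AUCs are trapezoidal over
`[t0, end]` (total), `[t0, tInf]` (perfusion), `[tInf, end]` (permeability)
and `[tP, end]` (residual rAUC — the peak-to-end integral is the most
literal residual-decay window; configurable). MTT and V are the
intensity-weighted first and second central moments of the sample times,
computed as plain sums with negative samples clipped to zero *only inside
these sums* (the weights must be nonnegative; clipping elsewhere would bias
slopes and AUCs) and over `[t0, end]` by default (the pre-injection baseline
carries no transit information; a full-window option remains). FWHM finds
the half-of-IMAX crossings by linear interpolation — the last up-crossing
before the peak and the first down-crossing after it; a curve still above
the half level at the end of the recording is censored, with the width
measured to the last sample and a flag set. Slopes are ordinary least
squares over the three dynamic segments; the ingress fit is restricted to
samples between 10% and 90% of IMAX to avoid baseline and peak curvature;
segments with fewer than 3 samples yield a flagged None, not an exception.

Scaling a curve by `c > 0` scales IMAX, rAUC, s1, s2 by `c` and leaves tP,
MTT, FWHM, V unchanged — this homogeneity is what makes timing features
robust to processing choices, and it is enforced by the test suite exactly
(up to ~1 ulp floating-point effects in interpolated quantities).

## Group analysis and spider orientation

Pipeline variants toggle FFC and nAUC (NP, nAUC, FFC, FFC+nAUC);
motion-artifact correction is applied per curve when the detected artifact
fraction exceeds 2% — selective application needs an explicit rule, and 2%
separates clean curves from visibly contaminated ones on the synthetic
fixtures. Relative features divide by the median over the normal-tissue
ROIs (or over all ROIs, for variability studies). Group differences use the
two-sided Mann–Whitney U: the exact null when `n1·n2 ≤ 400` with no ties,
otherwise the normal approximation with tie correction; significance tiers
at p < 0.05 and p < 0.01 with no multiplicity correction by default
(Holm–Bonferroni is available).

The six relative features of a class, drawn as a radar hexagon (vertices at
`90° − k·60°`, first feature at the top, then clockwise; slope radii in
absolute value since radar radii must be positive), are summarized by the
ellipse through the six vertices: a direct least-squares conic fit
constrained to ellipses, with the second-central-moment principal axes as a
fallback for degenerate conics. The orientation is the signed angle of the
major axis from the vertical, mapped to (−90°, 90°], positive
counterclockwise (a configurable flip accommodates the opposite convention).
A near-circular fit (`a/b − 1 < 0.02`) is flagged degenerate and reported as
0° — the normal-tissue convention. The default feature order
`(IMAX, FWHM, s1, rAUC, s2, MTT)` was chosen once, on the frozen synthetic
severity classes, so that hyperperfused classes tilt positive and
hypoperfused classes negative; the order is crucial to the summary and fully
configurable.

## Synthetic ground truth

The curve model is a gamma-variate inflow anchored to a bi-exponential
washout: baseline `b` until onset `t0`; then
`b + A·(Δ/tp)^α·exp(α(1 − Δ/tp))` with `tp = α·β`, handing over at the
analytic peak to `b + A·[(1−ρ)e^{−λf(Δ−tp)} + ρe^{−λs(Δ−tp)}]`. This is the
minimal four-phase indicator-dilution shape with closed-form peak time
(`t0 + αβ`) and height (`A` above baseline), so every truth record is exact.
Noise is seeded Gaussian (sd as a fraction of `A`, optionally scaled by
`sqrt(value/A)` for a shot-noise-like profile); zero-noise output is
deterministic regardless of seed, and all generators are reproducible
bit-for-bit from (config, seed).

Severity presets (A, α, β, λ_fast, ρ, λ_slow, t0):

| class       | A   | α | β   | λ_fast | ρ    | λ_slow | t0 |
|-------------|-----|---|-----|--------|------|--------|----|
| normal      | 100 | 3 | 3.0 | 0.080  | 0.35 | 0.005  | 10 |
| superficial | 170 | 3 | 1.5 | 0.100  | 0.25 | 0.004  |  8 |
| deep        |  45 | 3 | 5.0 | 0.045  | 0.28 | 0.006  | 14 |

They encode hyperperfusion (higher, earlier, narrower bolus with steeper
slopes) versus vascular destruction (lower, later, broader) and were
calibrated once against the directionality self-test
(`preset_directionality`: after nAUC, superficial has relative IMAX, rAUC,
s1, |s2| above 1 and MTT, FWHM below 1; deep reverses all six), then frozen.

Phantom stacks compose a vignetting field (radial Gaussian by default, cos⁴
available), the inverse-square working-distance falloff
`D²/(D² + x² + y²)`, the per-region curve, a dark level and optional noise,
and emit a matching flat/dark calibration pair and truth ROIs. Breathing
artifacts are one-sample positive spikes at a fixed period (amplitude a
fraction of the local value, jittered by at most one sample).

The standard synthetic study uses 120 s at 5 fps (600 samples), 5 ROIs per
class, and 64×80-pixel phantom frames; the statistical-calibration check
uses 1000 replicates of 5-vs-5 groups. These sizes keep every check
comfortably fast while leaving discretization (one 0.2 s sample) well below
the tolerances tested.

What the generator does *not* emulate: biophysical skin optics, compartment
pharmacokinetics, spatially heterogeneous kinetics inside one ROI, camera
saturation, and non-spike motion (drift, rotation). Passing tests therefore
demonstrate the correctness of the pipeline's algebra and its qualitative
severity separation on curves of the documented shape — not clinical
accuracy on animal or human recordings.

## Known limitations

* Landmark detection assumes a single-bolus curve; recirculation humps or
  double injections can misplace `tInf`.
* The distance correction models a flat surface only; curved surfaces would
  need per-pixel depth, which a 2D recording cannot provide.
* Whole-recording windows are used for `std[N(t)]` (CBR) and the nAUC
  integral; both are configurable but results depend on the choice.
* The spider orientation depends on the feature order by construction; the
  shipped default is a calibrated convention, not a canonical one, and
  orientations are comparable only within one convention.
* With 5 ROIs per group the exact Mann–Whitney test can reject at most at
  its achievable level (~0.032 at the nominal 0.05), which bounds the
  attainable significance of any single comparison.
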