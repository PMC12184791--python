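# icga

Processing and analysis of indocyanine-green angiography (ICGA) kinetics for
the assessment of indeterminate burn wounds.

After an intravenous ICG bolus, dynamic near-infrared fluorescence imaging
records a time–intensity curve in every tissue region: a flat baseline, a
rapid dye uptake to a peak, a fast washout, and a slow residual washout.
Burn severity changes the shape of this curve — superficial (hyperperfused)
burns rise higher and faster and wash out more steeply than normal tissue,
while deep burns with vascular destruction are lower, later and broader.
Raw intensities, however, are confounded by non-uniform illumination,
working distance, motion and injection variability, so the curves must be
corrected and normalized before their features mean anything.

This package implements the full pipeline for researchers working with
dynamic fluorescence recordings of burns (or any bolus-transit study):

* **ingest** — load multi-page TIFF stacks, directories of frames or curve
  CSVs; split composite white-light/fluorescence frames; select time
  windows; temporal binning and spatial downsampling.
* **correction** — baseline subtraction; flat-field correction
  `IC = (IR − IB)/(IF − IB)·MFB` from a flat/dark calibration pair;
  working-distance correction `I·(D² + x² + y²)/(Ds² + x² + y²)` for a flat
  surface at distance `D` referred to a standard distance `Ds`.
* **kinetics** — mean-ROI curve extraction, spike detection against a
  rolling median/MAD band, motion-artifact correction (removal, moving
  average, local replacement), and four normalizations: constants from a
  reference curve, SBR `B(t)/N(t)`, CBR `(B(t) − N(t))/std[N(t)]`, and nAUC
  (each curve divided by its own area under the curve).
* **features** — landmarks (uptake start t0, peak tP, washout inflection)
  and the feature families: intensity (IMAX, total/perfusion/permeability
  AUCs, residual rAUC), timing (tP, FWHM, mean transit time
  `MTT = Σ Fᵢtᵢ / Σ Fᵢ` and its variance `V = Σ Fᵢtᵢ²/Σ Fᵢ − MTT²`), and
  mixed (ingress slope s1, fast egress s2, residual egress s3).
* **analysis** — the four pipeline variants (NP, nAUC, FFC, FFC+nAUC),
  relative features against the normal-tissue median, two-sided
  Mann–Whitney U comparisons with significance tiers, and the spider-chart
  summary: the six relative features drawn as a radar hexagon, an ellipse
  fitted through its vertices, and the tilt of its major axis from the
  vertical reported in (−90°, 90°] — positive for hyperperfused
  (superficial), negative for hypoperfused (deep), degenerate (0°) for
  normal tissue.
* **synthetic** — ground-truth generators: a gamma-variate/bi-exponential
  four-phase curve model with frozen severity presets, phantom frame stacks
  with vignetting, inverse-square distance falloff and matching calibration
  images, and periodic breathing-spike injection.

## Worked example

Render a phantom with five ROIs per tissue class under a vignetted
illumination field, run the strictest pipeline variant, and summarize each
class by its spider-chart orientation:

```python
from icga import (
    ROI, SceneConfig, simulate_stack, PipelineVariant, run_pipeline,
    relative_features, class_spider_orientations,
)

regions = []
for j, cls in enumerate(["normal", "superficial", "deep"]):
    for i in range(5):
        regions.append(
            (ROI(label=f"{cls}_{i}", cx=14 + 13 * i, cy=12 + 20 * j, radius=5), cls)
        )
scene = SceneConfig(shape=(64, 80), regions=tuple(regions), seed=1, duration=120.0)
stack, rois, flat_field, truth = simulate_stack(scene)

table = run_pipeline(
    stack, rois, PipelineVariant.from_name("FFC+nAUC"), flat_field=flat_field
)
table["tissue_class"] = [label.rsplit("_", 1)[0] for label in table["roi_label"]]

rel = relative_features(table, reference_class="normal")
print(rel.groupby("tissue_class")[["imax", "rauc", "mtt_s", "fwhm_s", "s1", "s2"]]
      .median().round(2))
for cls, ori in class_spider_orientations(rel).items():
    print(f"{cls:12s} orientation {ori.orientation_deg:+6.1f} deg"
          f"  (degenerate: {ori.degenerate})")
```

Output:

```
              imax  rauc  mtt_s  fwhm_s    s1    s2
tissue_class
deep          0.94  0.93   1.03    1.47  0.57  0.71
normal        1.00  1.00   1.00    1.00  1.00  1.00
superficial   1.28  1.05   0.93    0.62  2.54  1.70
deep         orientation  -58.6 deg  (degenerate: False)
normal       orientation   +0.0 deg  (degenerate: True)
superficial  orientation  +73.3 deg  (degenerate: False)
```

Each row holds the class-median features divided by the normal-tissue
median. The superficial class raises the peak, residual area and both
slopes while narrowing MTT and FWHM; the deep class reverses every
direction. The hexagons built from these rows tilt the fitted ellipse
clockwise for deep burns (negative angle) and counterclockwise for
superficial ones (positive angle), while normal tissue stays a near-perfect
hexagon flagged degenerate at 0°.

A command-line interface mirrors the stages; see `icga --help`
(`simulate`, `ingest`, `correct`, `curves`, `features`, `analyze`).

## Documentation

The model, parameter defaults, numerical choices and known limitations are
documented in `docs/methods.md`.
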