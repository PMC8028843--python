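# riceyield

Yield-class prediction for rice breeding lines from UAV hyperspectral
imagery: reflectance calibration, spectral-angle-mapper (SAM) background
removal, correlation-justified band aggregation, a 41-index vegetation
bank, lodging-feature fusion, and the intraline/interline evaluation
design that measures what the lodging index adds — together with a
synthetic hyperspectral field generator so the whole pipeline runs and
is testable with no field data.

## Who this is for

Crop-phenotyping and remote-sensing researchers who want a tested,
reusable implementation of the classification workflow: 13 japonica rice
lines in triplicate on a 3-row × 13-cell grid, imaged by a 176-band
(400–1000 nm) camera, labelled A/B/C by measured grain yield
(A > 750 kg·mu⁻¹, 700 ≤ B ≤ 750, C < 700), with per-line lodging scored
0–3 as the count of lodged replicates.

The core quantities:

* SAM angle: `θ(x, r) = arccos(⟨x, r⟩ / (‖x‖‖r‖))`; a pixel is background
  iff its angle to the mean soil spectrum is no larger than its angle to
  the mean rice spectrum.
* Calibration: `ρ = ρ_panel · (raw − dark) / (white − dark)` per band,
  `ρ_panel = 0.34`.
* Features per sampled pixel: 22 means of consecutive 8-band groups,
  41 vegetation indices (e.g. NDVI = (R₈₀₀ − R₆₇₀)/(R₈₀₀ + R₆₇₀)), and
  optionally the line's lodging index.
* Evaluation: gradient-boosted trees (objective regularized by
  γ·T + ½λ‖w‖²) selected by grid search, scored by 3×3 confusion
  matrices with per-class precision/recall over leave-one-replicate-out
  ("intraline") and hold-one-line-per-class-out ("interline", 2×7×4 = 56
  plans) splits, with/without/only the lodging feature.

## Worked example

```python
import riceyield as ry

# a synthetic field with known ground truth (13 lines x 3 replicates)
scene, fieldmap, frames = ry.simulate_field(seed=1)

# raw counts -> reflectance -> background-free plot samples
raw = ry.encode_raw(scene.cube, frames)
cube = ry.calibrate_reflectance(raw, frames)
library = ry.ReferenceSpectraLibrary.from_truth(scene)
mask = ry.sam_classify(cube, library)
rois = ry.select_plot_rois(mask, fieldmap, margin_px=2)
samples = ry.sample_pixels(rois, cube, fieldmap, n=30, seed=1)

# fused features and the lodging ablation over all 56 interline plans
res = ry.run_interline_ablation(seed=1)
for cond, m in res["summary"].items():
    print(f"{cond}: precision_A={m['precision_A']:.3f} "
          f"recall_A={m['recall_A']:.3f} accuracy={m['accuracy']:.3f}")
```

prints

```
interline_with_lodging: precision_A=1.000 recall_A=1.000 accuracy=0.825
interline_without_lodging: precision_A=0.972 recall_A=0.779 accuracy=0.740
interline_lodging_only: precision_A=1.000 recall_A=1.000 accuracy=0.667
```

Read: with the lodging index fused in, every one of the 56 held-out-line
evaluations identifies class-A pixels perfectly; dropping the index
leaves the stem-mixed spectra of lodged class-B lines confusable with
class A, so precision falls; the lodging index alone nails class A (its
value 3 occurs only there) but cannot separate B from C, capping its
accuracy at 2/3. The same pipeline stages are available from a shell:

```sh
riceyield simulate --seed 42 --out scene/
riceyield preprocess --scene scene/ --margin 2 --n-samples 100 --seed 7 --out samples.csv
riceyield features --samples samples.csv --fieldmap scene/fieldmap.json --with-lodging --out feats.csv
riceyield evaluate --features feats.csv --fieldmap scene/fieldmap.json --mode interline --out report/
```

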