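# Methods

`riceyield` re-implements, end to end, a UAV-hyperspectral workflow for
sorting japonica rice lines into yield classes, and couples it to a
synthetic scene generator so every stage can be verified against known
ground truth without any flight data.

## The problem and the design

Thirteen rice lines are grown in triplicate on a 3-row × 13-cell grid
(one replicate of every line per row, order permuted per row). Each line's
manually measured grain yield (kg·mu⁻¹, 1 mu ≈ 666.7 m²) assigns it a
class: **A** above 750, **B** between 700 and 750 (inclusive at both
boundaries), **C** below 700. A 176-band hyperspectral camera
(400–1000 nm) images the field; the question is whether a classifier over
per-pixel spectral features can recognize the high-yield class A,
especially for *unseen* lines.

Two split designs probe different generalization questions:

* **intraline** — train on two replicates of every line, test on the
  held-out replicate. Implemented as all three leave-one-replicate-out
  plans rather than one random two-of-three draw: deterministic, and a
  superset of any single draw.
* **interline** — hold out one whole line per class (all replicates),
  train on the remaining lines. The plans are the Cartesian product over
  classes of held-out lines; with class sizes (2, 7, 4) that is 56 plans,
  all of which are evaluated.

Lodging (stems bending over, exposing them to the sensor) is scored per
line as the count of lodged replicates (0–3) and can be fused into the
feature table. The central analysis is an ablation: the same learner and
the same hyperparameter space, with and without the lodging index, plus a
lodging-only baseline.

## Processing stages

1. **Reflectance calibration.** `reflectance = panel · (raw − dark) /
   (white − dark)` per band, with `panel = 0.34` (the white reference is a
   34% diffuse panel). Output is clipped to [0, 1]; values above the white
   panel are treated as sensor saturation. Lens-distortion correction is
   vendor-specific and not modelled; simulated scenes are distortion-free.
2. **Background removal.** Spectral angle mapper (SAM): each pixel is
   compared with mean rice and mean soil reference spectra by
   `arccos(⟨x, r⟩ / (‖x‖‖r‖))`, which is invariant to illumination
   scaling. A pixel is background iff its soil angle is smaller than its
   rice angle; ties go to background so rice samples are never
   contaminated by soil.
3. **ROI selection and sampling.** Each plot rectangle is shrunk by an
   edge margin (default 2 px; the width of the edge strip removed in the
   field protocol is not documented) and intersected with the rice mask.
   Pixels are drawn uniformly without replacement (default 300 per plot at
   field scale); pixels with any zero-valued band are excluded as removed
   background.
4. **Dimension reduction.** The 176 bands are averaged in consecutive
   groups of 8 adjacent bands → 22 channels. The group size is justified
   by band–band redundancy: the per-band "run length" diagnostic reports,
   for every band, the longest contiguous interval whose members all
   correlate with it above r = 0.9. The diagnostic is reported, not
   auto-applied; group boundaries are fixed consecutive blocks. A PCA
   alternative (22 components) is provided for comparison.
5. **Vegetation indices.** A registry of 41 literature indices (NDVI,
   GNDVI, SAVI, OSAVI, EVI2, PRI, PSRI, CI variants, …) is evaluated per
   pixel on the full-resolution spectra, each index defined by wavelength
   anchors resolved to the nearest band center and an arithmetic
   expression (+ − × ÷, parentheses, `sqrt`). The registry is
   user-replaceable via JSON; all default denominators are positive on
   strictly positive spectra, so the default bank is finite on real canopy
   reflectance. Indices are computed per pixel before band aggregation,
   at full spectral resolution, so every anchor resolves to a true band
   center.
6. **Fusion and labels.** 22 band means + 41 indices (+ lodging index when
   enabled) per sampled pixel, labelled with the plot's yield class.
   Texture maps (local range/std over 3×3, local entropy over 9×9,
   reflective padding) are available but excluded from the default feature
   set, since they did not help classification at field scale.
7. **Training and metrics.** The boosted-tree classifier (regularized by
   γ·T + ½λ‖w‖², with T the leaf count and w the leaf scores) and all
   baseline learners (linear/RBF SVM, random forest, naive Bayes, LDA,
   AdaBoost) are delegated to xgboost / scikit-learn. Model selection is a
   grid search by stratified 3-fold cross-validation on training rows
   only, refit at the best point; a single-point grid skips the inner CV.
   The default grid is depth {3,5,7} × learning rate {0.05,0.1,0.3} ×
   trees {100,300} × γ {0,1} × λ {1,10}. Metrics are 3×3 confusion
   matrices with per-class precision (column-wise; 0 when nothing is
   predicted as the class) and recall (row-wise). Pixel-level metrics are
   canonical; plot-level majority-vote aggregation is available.

## The synthetic scene generator

The generator reproduces the statistical structure the analysis relies
on, not radiative-transfer realism:

* **Endmembers.** Rice canopy: low visible reflectance with a green bump
  at 550 nm, chlorophyll dip at 670 nm, red edge near 715 nm, NIR plateau
  ≈ 0.45. Soil: gentle monotone slope. Stem: intermediate, with a weak
  red edge and low NIR.
* **Hierarchical variation.** Each line carries a smooth random relative
  spectral perturbation (three Gaussian bumps, amplitude sd 2.5%); each
  plot adds a smaller plot-level perturbation (sd 1.5%) representing
  replicate-to-replicate field heterogeneity; each pixel adds independent
  Gaussian band noise (sd 0.01 reflectance), so within-plot band
  histograms are normal by construction.
* **Class structure.** Classes scale the canopy multiplicatively
  (A +3%, B 0, C −3%) — deliberately comparable to the line-level
  variation, so spectra alone identify a line's class only partly.
* **Lodging.** A lodged plot's canopy is mixed with the stem endmember,
  `(1−α)·canopy + α·stem`, α = 0.4 by default (the real perturbation
  strength is undocumented; α is a free parameter). Class-A lines lodge in
  all replicates (index 3); the first two class-B lines lodge partially
  (indices 2 and 1); others never lodge. This creates the lodging–class
  association the analysis exploits while keeping the *spectral* lodging
  signature ambiguous between A and lodged B lines — only the lodging
  index, whose value 3 is unique to class A, resolves the ambiguity. That
  is precisely the mechanism behind the ablation result.
* **Sensor model.** Raw counts are an affine per-band map,
  `raw = dark + gain · reflectance / panel`, with the white frame defined
  as the panel's own raw image; reflectance calibration inverts it to
  float precision, giving a closed-loop test.
* **Determinism.** All randomness flows from one seed, split into a
  structure stream and a noise stream, so the field layout is identical
  across noise settings and every output is bit-reproducible.

What the generator does **not** emulate: atmospheric and illumination
drift, orthomosaic geometry, mixed border pixels, weeds, spatially
correlated pixel noise, growth-stage differences between flights.
Passing tests therefore demonstrate the pipeline's correctness and the
internal consistency of the evaluation design — not field-scale accuracy
on real imagery.

## Problem sizes

Desk-scale studies use 16×16-pixel plots (scene 64×264×176), a 2-pixel
margin, 30 sampled pixels per plot (1 170 samples; the trimmed interior
holds 144 eligible pixels, so the field-scale 300 is not representable),
and a single-point boosted-tree configuration (depth 2, learning rate
0.3, 150 trees; `shallow_grid()`). Shallow trees rely on cleanly
separating features rather than memorizing line-specific spectral
signatures, which is the behaviour the interline design probes. The
ablation study in `scripts/acceptance.py` and the acceptance test runs 20
independently seeded fields over all 56 interline plans and three
conditions.

## Numerical choices and edge cases

* Ties in SAM go to background; zero spectra are rejected for angle
  computation (undefined direction).
* Yield-class boundaries: 750 → B, 700 → B ("between 750 and 700" read
  inclusively; "more than 750" strict).
* Band counts not divisible by the group size leave a final short group
  (the default 176/8 is exact).
* Zero-variance bands have undefined correlations; they are reported and
  excluded from run-length scans.
* Undefined vegetation-index values (zero denominators on degenerate
  inputs) are flagged as NaN and rejected at fusion time.
* Empty ROIs (excessive margins) and sampling deficits raise errors
  naming the plot and the deficit rather than silently shrinking.

## Known limitations

* Different labs use different 41-index rosters; the default registry is
  a standard literature bank and is replaceable via JSON without touching
  the evaluation engine.
* Intraline results on real data depend on which two replicates are
  drawn for training; the leave-one-replicate-out enumeration used here
  is deterministic but not identical to a single random draw.
* Precision/recall can be reported per pixel or per plot (majority
  vote); both are computed, pixel-level is the default.
* The lodging mixing weight and the lodged-line roster are generator
  conventions, chosen once to make the lodging–class association
  recoverable; they are not field measurements.
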