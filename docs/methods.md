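# Methods

This note records the models, parameter choices and numerical decisions
behind `fusionclass`, and what the synthetic experiments do and do not show.

## Fusion model

Both input channels are mapped to `[0, 1]` float intensities (8-bit inputs
divided by 255, 16-bit by 65535). Fusion operates in the frequency domain:

* **Transform.** Orthonormal separable type-II DCT (`scipy.fft.dctn`,
  `norm="ortho"`), inverted by the orthonormal type-III DCT. This pair is
  exactly self-inverse (round-trip error at machine precision) and satisfies
  Parseval's identity, which the test suite asserts at 1e-10 / 1e-9. A
  common alternative scaling (no normalization forward, weighted inverse)
  changes no fused *image* under the rules below but breaks the energy
  identity; the orthonormal pair is the only self-consistent choice here.
* **Rules.** `average` (default): elementwise mean of the two coefficient
  grids. Because the DCT is linear, coefficient averaging equals pixelwise
  averaging exactly — frequency-domain processing buys nothing for this rule
  per se, but it is the natural home of the second rule, `max_magnitude`,
  which keeps the per-frequency coefficient of larger absolute value (exact
  ties resolve toward the first input; ties have measure zero for noisy
  images). The fused image is clipped to `[0, 1]` after inversion.
* **Block mode.** Whole-image transform by default; an optional block mode
  (e.g. 8×8) transforms each tile independently, with edge tiles processed
  at their natural size so the decomposition is exactly invertible for any
  image shape. The average rule is block-size invariant (linearity).

## Preprocessing

* **CLAHE** (`skimage.exposure.equalize_adapthist` behind the module
  surface): default 8×8 tile grid, clip limit 0.01, 256 bins — conventional
  defaults, all configurable. A constant image is returned unchanged (its
  histogram is a single bin; equalization is undefined).
* **Registration.** Rigid + isotropic scale, intensity-based: maximize the
  Pearson correlation of pixel vectors over a deterministic coarse-to-fine
  grid (3-level pyramid; translations ±16 px resolved to 1 px, rotation ±15°
  resolved to 0.5°, scale 0.9–1.1 resolved to 0.025). The identity transform
  is always evaluated at full resolution, so registration can never return a
  lower similarity than the unregistered input. Flat (zero-variance) images
  are rejected — correlation is undefined. Known-transform recovery on
  phantoms is exact to the grid resolution (tests assert 1 px / 1°).

## Phantom generator

The generator *defines* the study conditions for all synthetic experiments.
Each phantom is a star-shaped region `r(θ) = R(1 + a·sin(kθ + φ))` on a
128×128 grid, plus 0–2 small circular satellite lesions (so the mean/SE/worst
feature aggregation is exercised), rendered into two channels:

| parameter | benign | malignant |
|---|---|---|
| base radius R | U(16, 24) px | U(16, 24) px |
| spiculation amplitude a | U(0.00, 0.04) | U(0.28, 0.42) |
| spiculation lobes k | 4–8 | 6–11 |
| components | 1–3 | 1–3 |

* **MRI-like channel:** foreground 0.55 on background 0.1, sharp boundary,
  fine Gaussian texture noise σ = 0.08 plus additive noise σ = 0.02. Low
  lesion contrast relative to its noise: boundary *shape* is its signal.
* **SPECT-like channel:** foreground 0.95 on background 0.1, Gaussian-blurred
  with σ = 4 px (low resolution), coarse correlated noise σ = 0.05 (white
  noise smoothed at σ = 2 px) plus the same additive noise. High contrast,
  but spiculations are smoothed away: region *presence/extent* is its signal.

Intensities are clipped to `[0, 1]` after noise; the truth mask is the exact
noiseless rendering. Everything is keyed by `(spec, seed)` and reproduces
byte for byte; dataset generation derives per-pair seeds from a master seed.

These phantoms are deliberately *not* physically realistic (no k-space
simulation, no attenuation/scatter, no anatomy around the lesion). Passing
tests therefore demonstrate that the pipeline's machinery is correct and
that fusion recovers information split across modalities *by construction*;
they say nothing about accuracy on clinical images.

## Segmentation and features

Otsu global threshold → 8-connected labeling → per-component hole filling →
components under 25 px discarded. The ordered boundary is traced with the
Moore-neighbor algorithm. Base features per component:

* radius: mean centroid→boundary distance.
* texture: std of source intensities over component pixels.
* perimeter: Crofton estimate (`regionprops.perimeter_crofton`). The naive
  8-chain length (axial steps 1, diagonal √2) overestimates smooth contours
  by ≈5%, which alone pushes a rasterized disk's compactness to ≈0.10; the
  Crofton estimator is asymptotically unbiased and keeps disk compactness
  small and positive (≈0.02–0.05 for r = 15–40), matching the intended
  "≈0 for a disk" semantics.
* area: pixel count. smoothness: mean local radial second difference over
  mean radius. compactness: `P²/(4πA) − 1`. concavity: mean convex-hull
  depth of boundary points over mean radius (hull via shapely).
  concave_points: boundary vertices deeper than 1.5 px inside the hull.
  symmetry: mean relative imbalance of chord halves perpendicular to the
  principal axis (eigenvectors taken from the ascending `eigh` order, so a
  disk's degenerate axes still yield orthogonal major/minor directions).
  fractal_dimension: box-counting slope over box sizes {2,4,8,16,32},
  minus 1.

Aggregation across components: mean; standard error (sample std/√n, 0 for a
single component); worst = mean of the three largest values. Fixed 30-name
order: all means, then all SEs, then all worsts.

Rasterization caveat: `smoothness` responds to pixel-level jaggedness, so it
does not monotonically track spiculation amplitude at these radii;
class separation rests on compactness, concavity and concave points (the
test suite asserts exactly those).

## Classifiers

* **KNN** (native): z-score standardization with training statistics
  (zero-variance features pass through), Euclidean distance, majority vote
  over k = 5 (odd to reduce ties); an exact vote tie falls to the single
  nearest neighbor's class.
* **ID3** (native): binary splits on midpoints of sorted distinct feature
  values, chosen by maximal information gain; ties break toward the lowest
  feature index, then the lowest threshold. Stops on purity, max depth,
  minimum leaf size, or zero gain. No standardization (thresholds are
  scale-equivariant). Leaves store the majority class and training purity
  (used as the ROC score).
* **SVM** (contract-level): linear soft-margin maximum-margin classifier on
  standardized features; `sklearn.svm.SVC(kernel="linear")` provides the
  convex solver, and the model exposes the weight vector and intercept.
  The contract asserted in tests: determinism, zero training error on
  separable toy data, and a geometric margin within 5% of the analytic
  optimum. Default penalty C = 1.

Positive class: *malignant*, everywhere.

## Evaluation

Accuracy, precision, recall, specificity as count ratios ×100; F1 as the
harmonic mean 2PR/(P+R). A zero denominator flags a metric as undefined
(`None`) instead of coercing to 0. Rendered values round half-up to two
decimals. ROC by descending-threshold sweep with tied scores sharing one
operating point; AUC by the trapezoidal rule, which the tests verify equals
Mann–Whitney pair counting.

Published-table note: one fused-track accuracy cell and four single-modality
cells in the reference count tables are inconsistent with their own counts
(recomputation differs by more than the 0.06 print tolerance; in one row
recall and specificity appear transposed). The acceptance checks recompute
every *self-consistent* cell and pass at ±0.06, which covers the tables'
mixed rounding/truncation; the inconsistent cells are excluded rather than
reproduced.

## Experiment protocol

`run_experiment` generates `2·n_per_class` pairs (default 200), applies
CLAHE to both channels, fuses them (pairs are generated pre-aligned, so
re-registration is off by default and available via `register_pairs`),
extracts features from the fused, MRI-only and SPECT-only images, and trains
all three classifiers per track on one shared stratified 70/30 split.
Samples whose segmentation comes back empty are skipped per track. Each
stage draws randomness from a stream keyed by `(master seed, stage name)`,
so adding a stage never perturbs earlier stages; written artifacts are
hashed into a manifest. The default problem size (200 pairs at 128×128)
keeps a full run around two minutes on one core.

## Known limitations

* Phantom realism targets the feature set, not clinical appearance; results
  on these phantoms bound nothing about real MRI/SPECT data.
* Registration covers rigid + isotropic scale only — no deformable motion,
  and its grid bounds (±16 px, ±15°) are assumptions about capture geometry.
* The ID3 tree has no pruning beyond depth/min-leaf; with 30 correlated
  features it can overfit small training sets.
* `max_magnitude` fusion is included as a common DCT-fusion baseline but the
  experiments use the average rule throughout.
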