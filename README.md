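# fusionclass

Multimodal medical-image **fusion** and benign/malignant **tumor
classification**, built as a tested, reusable Python library.

Anatomical imaging (MRI-like) and functional imaging (SPECT-like) carry
complementary information about the same lesion: the anatomical channel has
sharp boundaries but modest lesion contrast, the functional channel has
strong lesion contrast but low spatial resolution. `fusionclass` combines a
registered pair into a single image in the frequency domain and asks a
concrete, measurable question: *does classifying from the fused image beat
classifying from either modality alone?*

The pipeline:

1. **Preprocess** — CLAHE (contrast-limited adaptive histogram equalization)
   on each channel; rigid registration `T* = argmax_T ρ(I_ref, T(I_target))`
   with ρ = normalized cross-correlation, found by a deterministic
   coarse-to-fine grid search over translation, rotation and isotropic scale.
2. **Fuse** — orthonormal 2-D type-II DCT of both images,

   `X(k₁,k₂) = Σₙ₁Σₙ₂ x(n₁,n₂) cos[π(2n₁+1)k₁ / 2M] cos[π(2n₂+1)k₂ / 2N]`

   (orthonormal scaling), an *averaging rule* on the coefficients
   (optionally max-magnitude), inverse DCT, clip to [0, 1].
3. **Features** — Otsu segmentation of the fused image, then a 30-value
   vector: the {mean, standard error, worst} of 10 per-component features
   (radius, texture, perimeter, area, smoothness, compactness, concavity,
   concave points, symmetry, fractal dimension).
4. **Classify** — native KNN (Euclidean distance, majority vote), native ID3
   decision tree (information-gain splits on midpoint thresholds), and a
   linear soft-margin SVM.
5. **Evaluate** — confusion matrix; accuracy, precision, recall,
   specificity, F1 = 2PR/(P+R) as percentages; ROC/AUC by threshold sweep.

Because clinical image collections are rarely redistributable, the package
ships a **synthetic phantom generator**: paired MRI-like/SPECT-like images
of star-shaped lesions `r(θ) = R(1 + a·sin(kθ + φ))` whose boundary
morphology separates the classes (benign ≈ circular, `a ≤ 0.05`; malignant
spiculated, `a ≥ 0.25`), with exact ground-truth masks. Every stage of the
pipeline is testable end to end with no downloads.

## Worked example

```sh
python examples/04_full_experiment.py
```

runs the three-track experiment on 40 phantom pairs (seed 42) and prints,
among others:

```
=== fused track ===
classifier  TP  FP  TN  FN  accuracy  precision  recall  specificity     f1
       svm   6   0   6   0    100.00      100.0  100.00        100.0 100.00
       knn   6   0   6   0    100.00      100.0  100.00        100.0 100.00
      tree   5   0   6   1     91.67      100.0   83.33        100.0  90.91

mean accuracy per track: {'fused': 97.22, 'mri': 69.44, 'spect': 86.11}
```

Each row is one classifier evaluated on the held-out 30% of one feature
track. The fused track's mean accuracy (97.22%) exceeds both the MRI-only
(69.44%) and SPECT-only (86.11%) tracks: neither modality alone carries all
the class-separating information, and DCT-domain averaging recovers it.

The other examples cover phantom generation (`01`), fusion quality scores
(`02`), registration recovery of a known misalignment (`03`), and metric
arithmetic from raw confusion-matrix counts (`05`). The same functionality
is available from the shell via the thin `fusionclass` CLI
(`fusionclass phantom | preprocess | fuse | quality | features | train-eval
| run | metrics-from-counts`).

## Layout

```
src/fusionclass/
  phantoms.py     synthetic paired-modality phantom generator
  preprocess.py   grayscale, CLAHE, rigid NCC registration
  fusion.py       orthonormal 2-D DCT pair + fusion rules
  quality.py      PSNR / SSIM / NC diagnostics
  features.py     segmentation + 30-value feature vector
  classifiers.py  native KNN and ID3, linear SVM contract
  evaluation.py   confusion matrix, metrics, ROC/AUC, report tables
  pipeline.py     end-to-end experiment with manifest + per-stage seeding
  cli.py          thin click wrapper
docs/methods.md   model, parameter and design notes
examples/         one short narrative script per capability
tests/            pytest suite (unit, property, acceptance)
```
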