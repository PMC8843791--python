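"""Run the full three-track experiment on a small synthetic dataset.

Forty phantom pairs are generated, CLAHE-enhanced and fused; the 30-value
feature vector is extracted from the fused, MRI-only and SPECT-only images;
SVM, KNN and ID3 are trained on each track with the same stratified 70/30
split; and the per-track comparison tables are printed.
"""

from fusionclass import ExperimentConfig, run_experiment

result = run_experiment(ExperimentConfig(n_per_class=20, seed=42))
for track in ("fused", "mri", "spect"):
    print(f"\n=== {track} track ===")
    print(result.tracks[track].report.to_string(index=False))

print("\nmean accuracy per track:",
      {t: round(tr.mean_accuracy, 2) for t, tr in result.tracks.items()})
# Fusing the modalities should give the highest mean accuracy: each channel
# carries only part of the class-separating information (the MRI channel the
# sharp boundary shape, the SPECT channel the clean high-contrast region).
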