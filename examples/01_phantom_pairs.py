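"""Generate one benign and one malignant phantom pair and inspect them.

Each pair is an MRI-like channel (sharp boundary, fine texture noise) and a
SPECT-like channel (blurred, high-contrast activity blob) of the same
tumor-like region, plus the exact ground-truth mask.
"""

import numpy as np

from fusionclass import PhantomSpec, generate_pair

for label, amp in (("benign", 0.02), ("malignant", 0.35)):
    spec = PhantomSpec(label=label, spiculation_amplitude=amp,
                       spiculation_lobes=7, n_components=2)
    pair = generate_pair(spec, seed=11)
    print(f"{label:10s} mask={int(pair.truth_mask.sum())} px  "
          f"mri range [{pair.mri.min():.2f}, {pair.mri.max():.2f}]  "
          f"spect range [{pair.spect.min():.2f}, {pair.spect.max():.2f}]")

# The mask pixel count is the lesion area; a malignant phantom of the same
# base radius covers a similar area but with a far more irregular boundary.
print("identical reruns are bit-identical:",
      np.array_equal(generate_pair(spec, 11).mri, pair.mri))
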