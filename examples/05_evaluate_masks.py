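"""Segmentation metric suite and inter-rater agreement.

Shows the full per-case report (Dice, precision, recall, ASSD, MSSD, HD,
HD95) on a constructed pair of masks, and the ICC(2,1) agreement statistic
on paired per-case scores.
"""

import numpy as np

from fkmeans.metrics import evaluate_masks, icc

truth = np.zeros((32, 32, 16), dtype=bool)
truth[8:20, 8:20, 4:10] = True
pred = np.zeros_like(truth)
pred[10:22, 8:20, 4:10] = True  # same block shifted 2 voxels along x

report = evaluate_masks(pred, truth, spacing=(1.25, 1.25, 2.5))
for key, value in report.as_dict().items():
    print(f"{key:10s}: {value:8.4f}" if isinstance(value, float) else
          f"{key:10s}: {value}")
# The 2-voxel shift appears directly in the surface distances (2 x 1.25 mm
# Hausdorff) and as a symmetric drop in precision and recall.

rater_a = np.array([0.71, 0.80, 0.62, 0.90, 0.75, 0.84])
rater_b = np.array([0.69, 0.83, 0.60, 0.88, 0.79, 0.82])
print(f"\nICC(2,1) of two raters' Dice scores: {icc(rater_a, rater_b):.3f}")
# Values above ~0.75 indicate good absolute agreement between the raters.
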