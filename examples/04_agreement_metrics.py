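"""The evaluation metrics on small worked examples.

Shows Dice, 95% Hausdorff distance with anisotropic voxels, voxelwise AUC,
ICC(2,1) between parallel volume measurements, and Bland-Altman limits.
"""

import numpy as np

from plexseg import auc_voxelwise, bland_altman, dice, hausdorff95, icc
from plexseg.grids import LabelMask

a = np.zeros((12, 12, 12), int); a[4:8, 4:8, 4:8] = 1
b = np.zeros((12, 12, 12), int); b[5:9, 4:8, 4:8] = 1
iso = np.eye(4)
print(f"Dice of two offset cubes: {dice(LabelMask(a, iso), LabelMask(b, iso)):.3f}")
print(f"HD95 (1 mm iso): {hausdorff95(LabelMask(a, iso), LabelMask(b, iso)):.2f} mm")
thick = np.diag([4.0, 1.0, 1.0, 1.0])  # 4 mm slices along the offset axis
print(f"HD95 (4 mm slices): "
      f"{hausdorff95(LabelMask(a, thick), LabelMask(b, thick)):.2f} mm")

rng = np.random.default_rng(0)
scores = rng.normal(0, 1, size=a.shape) + 2.0 * a  # informative but noisy
print(f"voxelwise AUC of noisy scores: {auc_voxelwise(scores, a):.3f}")

# three 'methods' measuring the same 8 subjects' volumes
truth = rng.uniform(2, 5, size=8)
table = np.column_stack([truth + rng.normal(0, 0.15, 8) for _ in range(3)])
print(f"ICC(2,1) across methods: {icc(table):.3f}")
bias, lo, hi = bland_altman(table[:, 0], table[:, 1])
print(f"Bland-Altman method 1 vs 2: bias {bias:+.3f} cm^3, "
      f"limits [{lo:+.3f}, {hi:+.3f}]")
# High ICC and narrow limits of agreement mean volumes from the different
# methods can be used interchangeably.
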