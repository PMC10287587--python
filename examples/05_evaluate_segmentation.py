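"""Evaluate a predicted mask with the full metric suite.

DSC, sensitivity and specificity are voxel-overlap ratios; HD95 is the
95th percentile of boundary-to-boundary distances in mm (robust to a few
stray voxels, sensitive to contour errors); the voxelwise ROC AUC measures
how well the probability map ranks tumor above background.
"""

import numpy as np

from slseg.core import SegmentationMask
from slseg.metrics import evaluate_exam, summarize_by_location

spacing = (5.0, 1.0, 1.0)  # dz, dy, dx in mm
ref = np.zeros((4, 32, 32), dtype=np.uint8)
ref[1:3, 10:22, 8:24] = 1

# a prediction that slightly under-segments and adds a small false blob
pmap = np.zeros((4, 32, 32))
pmap[1:3, 11:21, 9:23] = 0.9
pmap[0, 2:4, 2:4] = 0.8
pred = (pmap >= 0.5).astype(np.uint8)

report = evaluate_exam(
    SegmentationMask(pred, spacing, "demo"),
    SegmentationMask(ref, spacing, "demo"),
    pmap,
)
print(f"DSC          {report.dsc:.3f}   (overlap agreement, 1 = perfect)")
print(f"sensitivity  {report.sensitivity:.3f}   (fraction of tumor recovered)")
print(f"specificity  {report.specificity:.3f}   (fraction of background kept)")
print(f"HD95         {report.hd95_mm:.2f} mm (boundary discrepancy)")
print(f"AUC          {report.auc:.3f}   (probability-map discrimination)")

table = summarize_by_location([report], {"demo": "PUL"})
print("\nper-location summary table:")
print(table[["location", "group", "dsc", "hd95_mm", "n_exams"]].to_string(index=False))
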