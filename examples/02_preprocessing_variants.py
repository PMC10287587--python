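"""Apply the preprocessing variants that define the ensemble's base learners.

Each variant is bias-field correction (optional) followed by one of four
intensity maps: z-score, volume min-max, per-slice min-max, or Nyul
histogram standardization.
"""

import numpy as np

from slseg.phantom import PhantomConfig, generate_cohort
from slseg.preprocess import (
    PreprocessSpec,
    apply_preprocess,
    nyul_train,
)

cohort = generate_cohort(PhantomConfig(n_exams=4, seed=7))
exam = cohort[0]

# Nyul standardization needs a standard scale learned from a training cohort
scale = nyul_train([e.image for e in cohort[1:]])
print("Nyul standard scale (percentile -> standard intensity):")
for p, s in zip(scale.percentiles, scale.standard_values):
    print(f"  {p:5.1f} -> {s:7.2f}")

specs = [
    PreprocessSpec("zscore", bias_correct=False),
    PreprocessSpec("zscore", bias_correct=True),
    PreprocessSpec("minmax_volume", bias_correct=True),
    PreprocessSpec("minmax_slice", bias_correct=True),
    PreprocessSpec("nyul", bias_correct=True, nyul_scale=scale),
]

print(f"\ninput intensities: mean {exam.image.voxels.mean():.1f}, "
      f"sd {exam.image.voxels.std():.1f}")
for spec in specs:
    out = apply_preprocess(exam, spec)
    v = out.image.voxels
    print(f"{spec.name:18s} -> mean {v.mean():8.3f}  sd {v.std():7.3f}  "
          f"range [{v.min():8.3f}, {v.max():8.3f}]")
# Each variant lands the same anatomy on a different intensity scale; the
# networks trained on them make different mistakes, which is exactly the
# diversity the Super Learner exploits.
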