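"""Fit Super Learner weights on a toy probability stack.

Four 'base learners' predict tumor probabilities for the same voxels; one
of them is nearly perfect, the rest are noise.  Minimizing the stacked
cross-entropy on held-out truth concentrates the simplex weights on the
good learner, and the optimized combination beats every single learner.
"""

import numpy as np

from slseg.ensemble import (
    EnsembleWeights,
    ProbabilityStack,
    fit_weights,
    sl_loss,
)

rng = np.random.default_rng(0)
truth = (rng.random((6, 16, 16)) > 0.7).astype(np.float32)
good = np.clip(truth, 0.05, 0.95)
stack = ProbabilityStack(
    np.stack([rng.random(truth.shape), good,
              rng.random(truth.shape), rng.random(truth.shape)]
             ).astype(np.float32),
    learner_ids=("noise-a", "good", "noise-b", "noise-c"),
)

fit = fit_weights(stack, truth, epochs=600, seed=0)
print("fitted simplex weights:")
for lid, w in zip(stack.learner_ids, fit.weights.w):
    print(f"  {lid:8s} {w:8.4f}")
print(f"(sum = {fit.weights.w.sum():.6f}, converged after "
      f"{fit.epochs_run} epochs)")

n_vox = truth.size
print(f"\nper-voxel stacked cross-entropy (lower is better):")
print(f"  optimized weights: {sl_loss(fit.weights, stack, truth)/n_vox:.4f}")
print(f"  uniform weights:   "
      f"{sl_loss(EnsembleWeights.uniform(4), stack, truth)/n_vox:.4f}")
for j, lid in enumerate(stack.learner_ids):
    vertex = np.zeros(4)
    vertex[j] = 1.0
    loss = sl_loss(EnsembleWeights(vertex), stack, truth) / n_vox
    print(f"  {lid} alone:      {loss:.4f}")
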