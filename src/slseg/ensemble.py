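"""The Super Learner: simplex-constrained stacking of base-learner maps.

Given per-voxel tumor probabilities :math:`p_{ji}` from :math:`m` base
learners, the Super Learner forms the convex combination
:math:`p_{SL,i} = \\sum_j w_j p_{ji}` with weights on the probability
simplex (:math:`w_j \\in [0,1]`, :math:`\\sum_j w_j = 1`).  The weights are
fit on a held-out tuning set by minimizing the cross-entropy of the
combined probability against the reference masks:

.. math::

   L(\\vec w) = -\\sum_i \\Big[ y_i \\log \\sum_j w_j p_{ji}
                 + (1 - y_i) \\log \\big(1 - \\sum_j w_j p_{ji}\\big) \\Big].

Feasibility is guaranteed at every optimization step by a softmax
reparameterization of the weights.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

from .core import SegmentationMask

log = logging.getLogger(__name__)

#: clipping bound applied to the combined probability before taking logs
CLIP = 1e-7


@dataclass(frozen=True)
class ProbabilityStack:
    """Per-voxel probabilities from m base learners over the same voxels.

    ``probs`` has shape ``(m, ...)`` where the trailing axes are any
    consistent voxel layout (typically slices x rows x cols, possibly
    concatenated over exams).
    """

    probs: np.ndarray
    learner_ids: tuple[str, ...] = ()
    exam_ids: tuple[str, ...] = ()

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=np.float32)
        if p.ndim < 2 or p.shape[0] < 1:
            raise ValueError("probs must be (m, ...) with m >= 1")
        if p.min() < 0 or p.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")
        ids = tuple(self.learner_ids) or tuple(f"learner{j}" for j in range(p.shape[0]))
        if len(ids) != p.shape[0]:
            raise ValueError("learner_ids length must equal m")
        object.__setattr__(self, "probs", p)
        object.__setattr__(self, "learner_ids", ids)
        object.__setattr__(self, "exam_ids", tuple(self.exam_ids))

    @property
    def m(self) -> int:
        return self.probs.shape[0]


@dataclass(frozen=True)
class EnsembleWeights:
    """Length-m vector on the probability simplex."""

    w: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.w, dtype=np.float64)
        if w.ndim != 1 or w.size < 1:
            raise ValueError("weights must be a 1D vector")
        if w.min() < -1e-9 or w.max() > 1 + 1e-9:
            raise ValueError("each weight must lie in [0, 1]")
        if abs(w.sum() - 1.0) > 1e-6:
            raise ValueError(f"weights must sum to 1, got {w.sum()}")
        object.__setattr__(self, "w", np.clip(w, 0.0, 1.0))

    @classmethod
    def uniform(cls, m: int) -> "EnsembleWeights":
        return cls(np.full(m, 1.0 / m))


@dataclass(frozen=True)
class SLFitResult:
    weights: EnsembleWeights
    loss_trajectory: tuple[float, ...]
    epochs_run: int


def _check_congruent(stack: ProbabilityStack, truth: np.ndarray) -> np.ndarray:
    y = np.asarray(truth, dtype=np.float32)
    if y.shape != stack.probs.shape[1:]:
        raise ValueError(
            f"truth shape {y.shape} does not match stack {stack.probs.shape[1:]}")
    return y


def sl_loss(weights: EnsembleWeights, stack: ProbabilityStack, truth) -> float:
    """Cross-entropy of the weighted combination, summed over all voxels."""
    y = _check_congruent(stack, truth)
    if weights.w.size != stack.m:
        raise ValueError("weight length does not match number of learners")
    p = np.tensordot(weights.w, stack.probs.astype(np.float64), axes=(0, 0))
    p = np.clip(p, CLIP, 1.0 - CLIP)
    return float(-(y * np.log(p) + (1.0 - y) * np.log1p(-p)).sum())


def combine(stack: ProbabilityStack, weights: EnsembleWeights) -> np.ndarray:
    """The Super Learner probability map: per-voxel convex combination."""
    if weights.w.size != stack.m:
        raise ValueError("weight length does not match number of learners")
    p = np.tensordot(weights.w, stack.probs.astype(np.float64), axes=(0, 0))
    return np.clip(p, 0.0, 1.0).astype(np.float32)


def binarize(pmap: np.ndarray, threshold: float = 0.5,
             spacing=(1.0, 1.0, 1.0), exam_id: str = "") -> SegmentationMask:
    """Threshold a probability map; ties (p == threshold) map to tumor."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0,1), got {threshold}")
    vox = (np.asarray(pmap) >= threshold).astype(np.uint8)
    return SegmentationMask(vox, spacing, exam_id)


def fit_weights(stack: ProbabilityStack, truth, epochs: int = 200,
                seed: int = 0, lr: float = 0.05, patience: int = 10,
                min_improve: float = 1e-8) -> SLFitResult:
    """Optimize the ensemble weights on the simplex by Adam on the SL loss.

    Weights are parameterized as a softmax over unconstrained logits
    initialized to zero, so the starting point is the uniform 1/m vector and
    every iterate is feasible.  Optimization stops early once the per-voxel
    loss improves by less than ``min_improve`` for ``patience`` consecutive
    epochs.  Degenerate truth (single-class everywhere) leaves the weights
    uniform with a warning, as the loss then carries no ranking signal for
    calibrated learners.
    """
    y = _check_congruent(stack, truth).astype(np.float64).reshape(-1)
    m = stack.m
    p = stack.probs.astype(np.float64).reshape(m, -1)
    n_vox = y.size
    if y.min() == y.max():
        log.warning("degenerate truth (all %g): weights remain uniform", y.min())
        w0 = EnsembleWeights.uniform(m)
        return SLFitResult(w0, (sl_loss(w0, stack, truth),), 0)

    logits = np.zeros(m)
    madam = np.zeros(m)
    vadam = np.zeros(m)
    b1, b2, eps = 0.9, 0.999, 1e-8
    traj = []
    stall = 0
    for t in range(1, epochs + 1):
        z = logits - logits.max()
        ez = np.exp(z)
        w = ez / ez.sum()
        comb = w @ p
        comb_c = np.clip(comb, CLIP, 1.0 - CLIP)
        loss = float(-(y * np.log(comb_c) + (1.0 - y) * np.log1p(-comb_c)).sum())
        traj.append(loss)
        # d(loss)/d(comb), zero where clipping is active
        dcomb = np.where((comb > CLIP) & (comb < 1.0 - CLIP),
                         (comb_c - y) / (comb_c * (1.0 - comb_c)), 0.0)
        dw = p @ dcomb
        dlogits = w * (dw - float(w @ dw))
        madam = b1 * madam + (1 - b1) * dlogits
        vadam = b2 * vadam + (1 - b2) * dlogits ** 2
        logits -= lr * (madam / (1 - b1 ** t)) / (np.sqrt(vadam / (1 - b2 ** t)) + eps)
        if len(traj) > 1 and traj[-2] - traj[-1] < min_improve * n_vox:
            stall += 1
            if stall >= patience:
                break
        else:
            stall = 0
    z = logits - logits.max()
    ez = np.exp(z)
    w = ez / ez.sum()
    w = w / w.sum()  # exact renormalization at output
    result = SLFitResult(EnsembleWeights(w), tuple(traj), len(traj))
    if traj and traj[-1] > traj[0] + 1e-9:
        # never return something worse than the uniform start
        log.warning("SL loss increased during fit; reverting to uniform weights")
        result = SLFitResult(EnsembleWeights.uniform(m), tuple(traj), len(traj))
    return result


def save_weights(result: SLFitResult, stack_ids, path: str) -> None:
    with open(path, "w") as fh:
        json.dump({"learner_ids": list(stack_ids),
                   "w": [float(x) for x in result.weights.w],
                   "final_loss": result.loss_trajectory[-1],
                   "epochs_run": result.epochs_run}, fh, indent=1)


def load_weights(path: str) -> tuple[EnsembleWeights, list[str]]:
    with open(path) as fh:
        d = json.load(fh)
    return EnsembleWeights(np.asarray(d["w"])), list(d["learner_ids"])
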