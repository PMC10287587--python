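"""Config-driven orchestration of the full ensemble pipeline.

Stages: cohort -> single train/tune/test split -> per-variant preprocessing
-> K-fold cross-validated training of all base learners -> base-learner
probability maps on the tuning split -> Super Learner weight fit -> combined
prediction + thresholding on the test split -> per-learner and Super Learner
metric reports and per-location summary tables.  One global seed expands
deterministically into per-stage seeds, so re-running a config reproduces
the splits and weights.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np

from . import ensemble as ens
from . import metrics as met
from .core import Exam, split_cohort
from .models import (
    AugmentationSpec,
    TrainedLearner,
    UNetConfig,
    default_variants,
    predict_slices,
    preprocess_exams,
    save_learner,
    train_cv,
)
from .phantom import PhantomConfig, generate_cohort
from .preprocess import PreprocessSpec

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs."""

    variants: list = field(default_factory=default_variants)
    fractions: tuple[float, float, float] = (0.80, 0.09, 0.11)
    k: int = 5
    epochs: int = 8
    batch_size: int = 16
    lr: float = 1e-3
    sl_epochs: int = 200
    threshold: float = 0.5
    seed: int = 0
    augmentation: AugmentationSpec = field(default_factory=AugmentationSpec)
    phantom: PhantomConfig | None = field(default_factory=PhantomConfig)
    out_dir: str = "slseg_run"
    save_learners: bool = False

    def __post_init__(self):
        if not self.variants:
            raise ValueError("variant list must be nonempty")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in ("k", "epochs", "batch_size", "lr", "sl_epochs",
                    "threshold", "seed", "out_dir", "save_learners"):
            if key in raw:
                kwargs[key] = raw[key]
        if "fractions" in raw:
            kwargs["fractions"] = tuple(raw["fractions"])
        if "phantom" in raw:
            kwargs["phantom"] = PhantomConfig(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in raw["phantom"].items()})
        if "augmentation" in raw:
            aug = dict(raw["augmentation"])
            if "scale_range" in aug:
                aug["scale_range"] = tuple(aug["scale_range"])
            kwargs["augmentation"] = AugmentationSpec(**aug)
        if "variants" in raw:
            kwargs["variants"] = [
                (UNetConfig(**v.get("unet", {})),
                 PreprocessSpec(v["method"], v.get("bias_correct", True)))
                for v in raw["variants"]]
        return cls(**kwargs)


@dataclass
class PipelineResult:
    run_dir: str
    split: object
    learners: list
    weights: ens.SLFitResult
    sl_reports: list
    base_reports: list        # flat: one report per (learner, test exam)
    equal_reports: list       # equal-weight ensemble, for comparison
    summary: object           # per-location DataFrame


def _stage_seeds(seed: int) -> dict:
    names = ("split", "cv", "sl")
    ss = np.random.SeedSequence(seed)
    return {n: int(c.generate_state(1)[0] % 2 ** 31)
            for n, c in zip(names, ss.spawn(len(names)))}


def _stack_exams(maps: list[np.ndarray]) -> np.ndarray:
    """Concatenate per-exam 3D maps along the slice axis."""
    return np.concatenate(maps, axis=0)


def run_pipeline(config: PipelineConfig, exams: list[Exam] | None = None) -> PipelineResult:
    """Run the full ensemble workflow and persist every artifact.

    ``exams`` overrides the phantom cohort (e.g. exams read from disk).
    Test-split exams are never seen by training or the weight fit; this is
    enforced by exam-id bookkeeping and checked before prediction.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    if exams is None:
        if config.phantom is None:
            raise ValueError("no cohort: provide exams or a phantom config")
        log.info("stage=phantom generating %d exams", config.phantom.n_exams)
        exams = generate_cohort(config.phantom)
    by_id = {e.exam_id: e for e in exams}

    # --- split ------------------------------------------------------------
    split = split_cohort(list(by_id), config.fractions, seed=seeds["split"])
    with open(os.path.join(config.out_dir, "splits.json"), "w") as fh:
        json.dump({"train": list(split.train_ids), "tune": list(split.tune_ids),
                   "test": list(split.test_ids), "seed": config.seed}, fh, indent=1)
    log.info("stage=split train=%d tune=%d test=%d", len(split.train_ids),
             len(split.tune_ids), len(split.test_ids))

    # --- cross-validated training ------------------------------------------
    train_exams = [by_id[i] for i in split.train_ids]
    bias_cache: dict = {}
    learners = train_cv(train_exams, config.k, config.variants,
                        epochs=config.epochs, batch_size=config.batch_size,
                        seed=seeds["cv"], lr=config.lr,
                        augmentation=config.augmentation, bias_cache=bias_cache)
    if config.save_learners:
        for lrn in learners:
            save_learner(lrn, os.path.join(config.out_dir, "learners", lrn.learner_id))

    # --- base-learner maps on tune and test --------------------------------
    def predict_stack(ids):
        assert not set(ids) & set(split.train_ids), "leakage: train ids in stack"
        maps = []
        for lrn in learners:
            per_exam = [predict_slices(lrn, by_id[i], bias_cache=bias_cache)
                        for i in ids]
            maps.append(_stack_exams(per_exam))
        return np.stack(maps), [by_id[i] for i in ids]

    log.info("stage=predict tune split (%d exams x %d learners)",
             len(split.tune_ids), len(learners))
    tune_probs, tune_exams = predict_stack(split.tune_ids)
    tune_truth = _stack_exams([e.mask.voxels for e in tune_exams])
    stack = ens.ProbabilityStack(tune_probs,
                                 learner_ids=tuple(l.learner_id for l in learners))

    # --- Super Learner fit (tuning split only) ------------------------------
    fit = ens.fit_weights(stack, tune_truth, epochs=config.sl_epochs,
                          seed=seeds["sl"])
    ens.save_weights(fit, stack.learner_ids,
                     os.path.join(config.out_dir, "weights.json"))
    log.info("stage=sl_fit epochs_run=%d final_loss=%.4f", fit.epochs_run,
             fit.loss_trajectory[-1])

    # --- final evaluation on the test split ---------------------------------
    log.info("stage=predict test split (%d exams)", len(split.test_ids))
    sl_reports, base_reports, equal_reports = [], [], []
    eq = ens.EnsembleWeights.uniform(len(learners))
    for exam_id in split.test_ids:
        exam = by_id[exam_id]
        per_learner = np.stack([
            predict_slices(lrn, exam, bias_cache=bias_cache) for lrn in learners])
        exam_stack = ens.ProbabilityStack(
            per_learner, learner_ids=stack.learner_ids)
        spacing = exam.mask.spacing
        for j, lrn in enumerate(learners):
            pred = ens.binarize(per_learner[j], config.threshold, spacing, exam_id)
            base_reports.append(met.evaluate_exam(pred, exam.mask, per_learner[j]))
        p_sl = ens.combine(exam_stack, fit.weights)
        sl_reports.append(met.evaluate_exam(
            ens.binarize(p_sl, config.threshold, spacing, exam_id),
            exam.mask, p_sl))
        p_eq = ens.combine(exam_stack, eq)
        equal_reports.append(met.evaluate_exam(
            ens.binarize(p_eq, config.threshold, spacing, exam_id),
            exam.mask, p_eq))

    labels = {e.exam_id: e.location_label for e in exams}
    summary = met.summarize_by_location(sl_reports, labels, base_reports)
    _write_reports(config.out_dir, sl_reports, base_reports, equal_reports, summary)
    sl_mean = np.mean([r.dsc for r in sl_reports])
    base_mean = np.mean([r.dsc for r in base_reports])
    log.info("stage=evaluate sl_mean_dsc=%.3f base_mean_dsc=%.3f equal_mean_dsc=%.3f",
             sl_mean, base_mean, np.mean([r.dsc for r in equal_reports]))
    return PipelineResult(run_dir=config.out_dir, split=split, learners=learners,
                          weights=fit, sl_reports=sl_reports,
                          base_reports=base_reports, equal_reports=equal_reports,
                          summary=summary)


def _write_reports(out_dir, sl_reports, base_reports, equal_reports, summary):
    import pandas as pd

    rep_dir = os.path.join(out_dir, "reports")
    os.makedirs(rep_dir, exist_ok=True)
    rows = ([{"group": "super_learner", **r.as_row()} for r in sl_reports]
            + [{"group": "equal_weights", **r.as_row()} for r in equal_reports]
            + [{"group": "individual", **r.as_row()} for r in base_reports])
    pd.DataFrame(rows).to_csv(os.path.join(rep_dir, "per_exam.tsv"),
                              sep="\t", index=False)
    summary.to_csv(os.path.join(rep_dir, "summary_by_location.tsv"),
                   sep="\t", index=False)
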