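"""Base learners: U-Net construction, dice loss, augmentation, training.

A *base learner* is one trained network identified by its architecture
(U-Net or attention U-Net), its preprocessing variant, and the
cross-validation fold it was trained on.  ``train_cv`` produces the full
grid of ``k x len(variants)`` learners whose per-voxel probability maps the
Super Learner later combines.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import Exam, make_folds
from .nn.optim import Adam
from .nn.unet import UNet2D
from .preprocess import (
    NyulStandardScale,
    PreprocessSpec,
    apply_preprocess,
    bias_correct,
    normalize_minmax_slice,
    normalize_minmax_volume,
    normalize_zscore,
    nyul_apply,
    nyul_train,
)

log = logging.getLogger(__name__)

DICE_EPS = 1e-6


@dataclass(frozen=True)
class UNetConfig:
    levels: int = 5
    root_features: int = 32
    in_channels: int = 1
    out_channels: int = 1
    attention: bool = False

    def __post_init__(self):
        if self.levels < 1 or self.root_features < 1:
            raise ValueError("levels and root_features must be >= 1")

    def to_dict(self) -> dict:
        return {"levels": self.levels, "root_features": self.root_features,
                "in_channels": self.in_channels, "out_channels": self.out_channels,
                "attention": self.attention}

    @classmethod
    def from_dict(cls, d: dict) -> "UNetConfig":
        return cls(**d)


#: desk-scale configuration used throughout the test pipeline
TINY_UNET = UNetConfig(levels=3, root_features=4)
#: the architecture at publication scale (constructible, not exercised in CI)
PAPER_UNET = UNetConfig(levels=5, root_features=32)


@dataclass(frozen=True)
class AugmentationSpec:
    rotation_max_deg: float = 15.0
    scale_range: tuple[float, float] = (0.9, 1.1)
    flip_h_prob: float = 0.5
    flip_v_prob: float = 0.5

    def __post_init__(self):
        if not (0 <= self.flip_h_prob <= 1 and 0 <= self.flip_v_prob <= 1):
            raise ValueError("flip probabilities must be in [0,1]")
        if self.scale_range[0] <= 0 or self.scale_range[0] > self.scale_range[1]:
            raise ValueError("scale_range must be positive and ordered")


def build_unet(config: UNetConfig, seed: int = 0) -> UNet2D:
    """Instantiate the network described by ``config`` with seeded init."""
    return UNet2D(config.levels, config.root_features, config.in_channels,
                  config.out_channels, config.attention, seed=seed)


def count_parameters(config: UNetConfig) -> int:
    """Exact trainable-parameter count of :func:`build_unet` output.

    Counts convolution weights+biases, batch-norm scale+shift and (when
    enabled) the attention gates' three 1x1 projections.  Running batch-norm
    statistics are buffers, not trainable, and are excluded.
    """
    feats = [config.root_features * 2 ** i for i in range(config.levels)]

    def double_conv(in_ch: int, out_ch: int) -> int:
        conv1 = in_ch * out_ch * 9 + out_ch
        conv2 = out_ch * out_ch * 9 + out_ch
        bn = 2 * out_ch
        return conv1 + conv2 + 2 * bn

    total = 0
    for i in range(config.levels):
        total += double_conv(config.in_channels if i == 0 else feats[i - 1], feats[i])
    for i in range(config.levels - 1):
        total += feats[i + 1] * feats[i] * 4 + feats[i]          # transposed conv
        total += double_conv(2 * feats[i], feats[i])             # decoder block
        if config.attention:
            inter = feats[i]
            total += feats[i] * inter + inter                    # theta_x
            total += feats[i + 1] * inter + inter                # phi_g
            total += inter * 1 + 1                               # psi
    total += feats[0] * config.out_channels + config.out_channels  # final 1x1
    return total


# ---------------------------------------------------------------------------
# Dice loss


def dice_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """1 - (2*sum(p*y) + eps) / (sum(p) + sum(y) + eps) over the whole batch."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {target.shape}")
    inter = float((pred * target).sum())
    denom = float(pred.sum() + target.sum())
    return 1.0 - (2.0 * inter + DICE_EPS) / (denom + DICE_EPS)


def _dice_loss_grad(pred: np.ndarray, target: np.ndarray) -> np.ndarray:
    """d(dice_loss)/d(pred), same shape as pred."""
    inter = float((pred.astype(np.float64) * target).sum())
    denom = float(pred.sum(dtype=np.float64) + target.sum(dtype=np.float64)) + DICE_EPS
    num = 2.0 * inter + DICE_EPS
    return ((num / denom ** 2) - (2.0 / denom) * target).astype(np.float32)


# ---------------------------------------------------------------------------
# Augmentation


def augment(image_slice: np.ndarray, mask_slice: np.ndarray,
            spec: AugmentationSpec, rng: np.random.Generator):
    """One random rotation + isotropic scale + flips, identically on both.

    The zoom is about the slice center and the result is cropped/padded back
    to the input size implicitly by resampling on the original grid.  The
    image is interpolated bilinearly, the mask by nearest neighbor so it
    stays binary.
    """
    if image_slice.shape != mask_slice.shape:
        raise ValueError("image and mask slices must be congruent")
    img, msk = image_slice, mask_slice
    if rng.random() < spec.flip_h_prob:
        img, msk = img[:, ::-1], msk[:, ::-1]
    if rng.random() < spec.flip_v_prob:
        img, msk = img[::-1, :], msk[::-1, :]
    theta = np.deg2rad(rng.uniform(-spec.rotation_max_deg, spec.rotation_max_deg))
    scale = rng.uniform(*spec.scale_range)
    if abs(theta) > 1e-12 or abs(scale - 1.0) > 1e-12:
        c, s = np.cos(theta), np.sin(theta)
        # inverse mapping (output -> input): rotate by -theta, divide by scale
        mat = np.array([[c, -s], [s, c]]) / scale
        center = (np.asarray(img.shape) - 1) / 2.0
        offset = center - mat @ center
        img = ndimage.affine_transform(img, mat, offset=offset, order=1,
                                       mode="constant", cval=float(img.min()))
        msk = ndimage.affine_transform(msk, mat, offset=offset, order=0,
                                       mode="constant", cval=0)
    return (np.ascontiguousarray(img, dtype=np.float32),
            np.ascontiguousarray(msk, dtype=np.uint8))


# ---------------------------------------------------------------------------
# Training


@dataclass
class TrainedLearner:
    """A base learner: network state plus everything needed to re-apply it."""

    network: UNet2D
    config: UNetConfig
    preprocess: PreprocessSpec
    fold_index: int = 0
    training_log: list = field(default_factory=list)
    seed: int = 0
    learner_id: str = ""

    def __post_init__(self):
        if not self.learner_id:
            self.learner_id = (f"{'attn-unet' if self.config.attention else 'unet'}"
                               f"_{self.preprocess.name}_fold{self.fold_index}")


def _stack_slices(exams: list[Exam]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Pool all 2D slices of all exams into (N,1,H,W) arrays."""
    xs, ys, ids = [], [], []
    for ex in exams:
        for z in range(ex.image.shape[0]):
            xs.append(ex.image.voxels[z])
            ys.append(ex.mask.voxels[z])
            ids.append(ex.exam_id)
    x = np.asarray(xs, dtype=np.float32)[:, None]
    y = np.asarray(ys, dtype=np.float32)[:, None]
    return x, y, ids


def preprocess_exams(exams: list[Exam], spec: PreprocessSpec,
                     bias_cache: dict | None = None) -> list[Exam]:
    """Apply one preprocessing variant to a list of exams.

    ``bias_cache`` maps exam_id -> bias-corrected ImageVolume so the costly
    N4 step is shared between variants and folds.
    """
    from dataclasses import replace as _replace

    out = []
    for ex in exams:
        img = ex.image
        if spec.bias_correct:
            if bias_cache is not None and ex.exam_id in bias_cache:
                img = bias_cache[ex.exam_id]
            else:
                img = bias_correct(img)
                if bias_cache is not None:
                    bias_cache[ex.exam_id] = img
        if spec.method == "zscore":
            img = normalize_zscore(img)
        elif spec.method == "minmax_volume":
            img = normalize_minmax_volume(img)
        elif spec.method == "minmax_slice":
            img = normalize_minmax_slice(img)
        else:
            if spec.nyul_scale is None:
                raise ValueError("nyul method requires a trained scale")
            img = nyul_apply(img, spec.nyul_scale)
        out.append(_replace(ex, image=img))
    return out


def train_learner(train: list[Exam], val: list[Exam], config: UNetConfig,
                  spec: PreprocessSpec, epochs: int = 120, batch_size: int = 16,
                  seed: int = 0, lr: float = 1e-3,
                  augmentation: AugmentationSpec | None = None,
                  fold_index: int = 0,
                  bias_cache: dict | None = None,
                  preprocessed: bool = False) -> TrainedLearner:
    """Train one base learner on pooled, augmented 2D slices.

    Slices from the (preprocessed) training exams are pooled, shuffled each
    epoch, augmented on the fly and optimized with Adam on the dice loss.
    Per-epoch training loss and validation dice are recorded.  With
    ``preprocessed=True`` the exams are taken as already preprocessed.
    """
    if not train:
        raise ValueError("empty training set")
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    if augmentation is None:
        augmentation = AugmentationSpec()
    if not preprocessed:
        train = preprocess_exams(train, spec, bias_cache)
        val = preprocess_exams(val, spec, bias_cache)
    x_train, y_train, _ = _stack_slices(train)
    if x_train.size == 0:
        raise ValueError("empty training slice pool")
    x_val, y_val, _ = _stack_slices(val) if val else (None, None, None)

    rng = np.random.default_rng(seed)
    net = build_unet(config, seed=seed)
    net.check_input(x_train.shape[2], x_train.shape[3])
    opt = Adam(net.parameters(), lr=lr)
    n = x_train.shape[0]
    training_log = []
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            xb = np.empty_like(x_train[idx])
            yb = np.empty_like(y_train[idx])
            for j, i in enumerate(idx):
                xi, yi = augment(x_train[i, 0], y_train[i, 0], augmentation, rng)
                xb[j, 0], yb[j, 0] = xi, yi
            p = net.forward(xb, train=True)
            losses.append(dice_loss(p, yb))
            opt.zero_grad()
            net.backward(_dice_loss_grad(p, yb))
            opt.step()
        entry = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if x_val is not None:
            pv = _predict_array(net, x_val, batch_size)
            entry["val_dice"] = 1.0 - dice_loss((pv >= 0.5).astype(np.float32), y_val)
        training_log.append(entry)
        log.debug("learner fold=%d epoch=%d loss=%.4f val=%s", fold_index,
                  epoch, entry["train_loss"], entry.get("val_dice"))
    return TrainedLearner(network=net, config=config, preprocess=spec,
                          fold_index=fold_index, training_log=training_log,
                          seed=seed)


def _predict_array(net: UNet2D, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float32)
    for start in range(0, x.shape[0], batch_size):
        out[start:start + batch_size] = net.forward(x[start:start + batch_size],
                                                    train=False)
    return out


def predict_slices(learner: TrainedLearner, exam: Exam,
                   preprocessed: bool = False,
                   bias_cache: dict | None = None) -> np.ndarray:
    """Per-voxel tumor probabilities for one exam, slice by slice.

    The learner's recorded preprocessing variant is re-applied first (unless
    the caller already did), so inference always sees the distribution the
    network was trained on.
    """
    if not preprocessed:
        exam = preprocess_exams([exam], learner.preprocess, bias_cache)[0]
    learner.network.check_input(exam.image.shape[1], exam.image.shape[2])
    x = exam.image.voxels[:, None].astype(np.float32)
    return _predict_array(learner.network, x)[:, 0]


def default_variants(attention_variant: bool = True) -> list[tuple[UNetConfig, PreprocessSpec]]:
    """The six base-learner variants: z-score without bias correction and the
    four normalizations with bias correction on the U-Net, plus z-score with
    bias correction on the attention U-Net."""
    unet = UNetConfig(levels=TINY_UNET.levels, root_features=TINY_UNET.root_features)
    variants = [
        (unet, PreprocessSpec("zscore", bias_correct=False)),
        (unet, PreprocessSpec("zscore", bias_correct=True)),
        (unet, PreprocessSpec("minmax_volume", bias_correct=True)),
        (unet, PreprocessSpec("minmax_slice", bias_correct=True)),
        (unet, PreprocessSpec("nyul", bias_correct=True)),
    ]
    if attention_variant:
        attn = UNetConfig(levels=TINY_UNET.levels, root_features=TINY_UNET.root_features,
                          attention=True)
        variants.append((attn, PreprocessSpec("zscore", bias_correct=True)))
    return variants


def train_cv(train_exams: list[Exam], k: int,
             variants: list[tuple[UNetConfig, PreprocessSpec]],
             epochs: int = 120, batch_size: int = 16, seed: int = 0,
             lr: float = 1e-3, augmentation: AugmentationSpec | None = None,
             bias_cache: dict | None = None) -> list[TrainedLearner]:
    """K-fold cross-validated training of every variant.

    Each fold serves as validation once, with the remaining folds as
    training data, yielding ``k * len(variants)`` base learners.  Nyul
    standard scales are learned from that fold's *training* exams only, on
    the same (bias-corrected or raw) intensities the normalization will see.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if not variants:
        raise ValueError("need at least one variant")
    ids = [e.exam_id for e in train_exams]
    by_id = {e.exam_id: e for e in train_exams}
    ss = np.random.SeedSequence(seed)
    fold_seed, *learner_seeds = [int(s.generate_state(1)[0] % 2 ** 31)
                                 for s in ss.spawn(1 + k * len(variants))]
    folds = make_folds(ids, k, seed=fold_seed)
    if bias_cache is None:
        bias_cache = {}
    learners = []
    si = 0
    for config, spec in variants:
        for f in range(k):
            tr_ids, va_ids = folds.train_val(f)
            tr = [by_id[i] for i in tr_ids]
            va = [by_id[i] for i in va_ids]
            fold_spec = spec
            if spec.method == "nyul":
                # landmarks learned on the intensities normalization will see
                if spec.bias_correct:
                    for e in tr:
                        if e.exam_id not in bias_cache:
                            bias_cache[e.exam_id] = bias_correct(e.image)
                    vols = [bias_cache[e.exam_id] for e in tr]
                else:
                    vols = [e.image for e in tr]
                fold_spec = spec.with_scale(nyul_train(vols))
            learner = train_learner(tr, va, config, fold_spec, epochs=epochs,
                                    batch_size=batch_size, seed=learner_seeds[si],
                                    lr=lr, augmentation=augmentation,
                                    fold_index=f, bias_cache=bias_cache)
            learners.append(learner)
            si += 1
            log.info("trained %s (%d/%d)", learner.learner_id, si, k * len(variants))
    return learners


# ---------------------------------------------------------------------------
# Serialization


def save_learner(learner: TrainedLearner, directory: str) -> None:
    """One directory per learner: parameter state + JSON sidecar."""
    os.makedirs(directory, exist_ok=True)
    np.savez(os.path.join(directory, "state.npz"), **learner.network.get_state())
    meta = {
        "learner_id": learner.learner_id,
        "config": learner.config.to_dict(),
        "preprocess": {
            "method": learner.preprocess.method,
            "bias_correct": learner.preprocess.bias_correct,
            "nyul_scale": (learner.preprocess.nyul_scale.to_dict()
                           if learner.preprocess.nyul_scale else None),
        },
        "fold_index": learner.fold_index,
        "seed": learner.seed,
        "training_log": learner.training_log,
    }
    with open(os.path.join(directory, "learner.json"), "w") as fh:
        json.dump(meta, fh, indent=1)


def load_learner(directory: str) -> TrainedLearner:
    with open(os.path.join(directory, "learner.json")) as fh:
        meta = json.load(fh)
    config = UNetConfig.from_dict(meta["config"])
    pp = meta["preprocess"]
    scale = (NyulStandardScale.from_dict(pp["nyul_scale"])
             if pp.get("nyul_scale") else None)
    spec = PreprocessSpec(pp["method"], pp["bias_correct"], scale)
    net = build_unet(config, seed=meta["seed"])
    with np.load(os.path.join(directory, "state.npz")) as arrays:
        net.set_state(dict(arrays))
    return TrainedLearner(network=net, config=config, preprocess=spec,
                          fold_index=meta["fold_index"],
                          training_log=meta["training_log"],
                          seed=meta["seed"], learner_id=meta["learner_id"])
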