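"""Bias-field correction and intensity normalization/standardization.

Heterogeneous multicenter MR data carry two nuisances the segmentation
networks must not have to learn: a smooth multiplicative bias field from
coil/field inhomogeneity, and site-dependent intensity conventions (the raw
numbers mean different things on different scanners).  This module provides
N4 bias correction plus the four per-exam intensity maps that, combined with
the two network architectures, define the ensemble's base-learner variants:

* ``zscore``          — (x - mean) / sd over the whole 3D volume;
* ``minmax_volume``   — (x - min) / (max - min) over the whole 3D volume;
* ``minmax_slice``    — the min-max map applied to each 2D slice independently;
* ``nyul``            — Nyul histogram-landmark standardization (two-phase:
  learn a standard scale from a training cohort, then piecewise-linearly map
  each volume's own landmarks onto it).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .core import Exam, ImageVolume

log = logging.getLogger(__name__)

NORMALIZATION_METHODS = ("zscore", "minmax_volume", "minmax_slice", "nyul")

#: Default histogram landmarks: deciles with robust 1/99 percentile anchors.
DEFAULT_PERCENTILES = (1.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 90.0, 99.0)
DEFAULT_STANDARD_RANGE = (0.0, 100.0)


@dataclass(frozen=True)
class NyulStandardScale:
    """Learned landmark percentiles and their standard-scale intensities."""

    percentiles: tuple[float, ...]
    standard_values: tuple[float, ...]

    def __post_init__(self):
        p = tuple(float(x) for x in self.percentiles)
        s = tuple(float(x) for x in self.standard_values)
        if len(p) != len(s) or len(p) < 2:
            raise ValueError("percentiles and standard_values must have equal length >= 2")
        if not all(a < b for a, b in zip(p, p[1:])):
            raise ValueError("percentiles must be strictly increasing")
        if not all(a < b for a, b in zip(s, s[1:])):
            raise ValueError("standard_values must be strictly increasing")
        if p[0] <= 0 or p[-1] >= 100:
            raise ValueError("percentiles must lie strictly inside (0, 100)")
        object.__setattr__(self, "percentiles", p)
        object.__setattr__(self, "standard_values", s)

    def to_dict(self) -> dict:
        return {"percentiles": list(self.percentiles),
                "standard_values": list(self.standard_values)}

    @classmethod
    def from_dict(cls, d: dict) -> "NyulStandardScale":
        return cls(tuple(d["percentiles"]), tuple(d["standard_values"]))


@dataclass(frozen=True)
class PreprocessSpec:
    """One preprocessing variant: optional N4 correction then a normalization."""

    method: str = "zscore"
    bias_correct: bool = True
    nyul_scale: NyulStandardScale | None = None

    def __post_init__(self):
        if self.method not in NORMALIZATION_METHODS:
            raise ValueError(f"unknown method {self.method!r}; "
                             f"choose from {NORMALIZATION_METHODS}")

    @property
    def name(self) -> str:
        return ("n4+" if self.bias_correct else "") + self.method

    def with_scale(self, scale: NyulStandardScale) -> "PreprocessSpec":
        return replace(self, nyul_scale=scale)


# ---------------------------------------------------------------------------
# Bias-field correction


#: histogram settings for the mode-sharpening step
_HIST_BINS = 128
_HIST_SMOOTH_BINS = 1.5
_PEAK_PROMINENCE = 0.005


def _sharpen_modes(t: np.ndarray) -> np.ndarray:
    """Map every voxel's log-intensity to its nearest histogram mode.

    The smoothed log-intensity histogram is searched for peaks (tissue
    classes); each voxel is assigned the mean log-intensity of its class.
    This is the sharpening step of the correction: the residual
    ``t - sharpened`` is what remains after explaining the image by
    piecewise-constant tissue classes, i.e. noise plus the bias field.
    """
    from scipy import signal

    lo, hi = np.percentile(t, [0.1, 99.9])
    if hi - lo < 1e-9:
        return np.full_like(t, t.mean())
    hist, edges = np.histogram(t, bins=_HIST_BINS, range=(lo, hi))
    hs = ndimage.gaussian_filter1d(hist.astype(np.float64), _HIST_SMOOTH_BINS)
    peaks, _ = signal.find_peaks(hs, prominence=_PEAK_PROMINENCE * hs.max())
    if peaks.size == 0:
        peaks = np.array([int(np.argmax(hs))])
    centers = (edges[peaks] + edges[peaks + 1]) / 2.0
    mids = (centers[:-1] + centers[1:]) / 2.0
    lab = np.digitize(t, mids)
    centers = np.array([t[lab == j].mean() if (lab == j).any() else centers[j]
                        for j in range(centers.size)])
    return centers[lab]


def _smooth_field_fit(resid: np.ndarray, cells: list[int]) -> np.ndarray:
    """Robust smooth-field fit: per-cell medians, cubic B-spline upsampling."""
    from skimage.transform import resize

    bounds = [np.array_split(np.arange(s), c) for s, c in zip(resid.shape, cells)]
    coarse = np.empty(cells, dtype=np.float64)
    for a, za in enumerate(bounds[0]):
        for b, yb in enumerate(bounds[1]):
            for c, xb in enumerate(bounds[2]):
                coarse[a, b, c] = np.median(resid[np.ix_(za, yb, xb)])
    return resize(coarse, resid.shape, order=3, mode="edge", anti_aliasing=False)


def bias_correct(volume: ImageVolume, max_iterations: int = 50,
                 spline_scale_mm: float | None = None,
                 tol: float = 1e-4) -> ImageVolume:
    """Remove a smooth multiplicative bias field, N4-style.

    Works in the log domain: each iteration sharpens the current
    intensity histogram onto its tissue-class modes, and fits a smooth
    field (cell medians of the residual on a coarse control grid, cubic
    B-spline upsampled) to what the classes cannot explain.  Iterations
    stop when the field estimate changes by less than ``tol`` in log
    units.  The field has unit geometric mean, so global intensity scale
    is preserved; output is non-negative, finite and deterministic.

    Parameters
    ----------
    max_iterations : refit iterations (usually converges in < 10).
    spline_scale_mm : control-cell extent of the smooth field in mm;
        defaults to 1/3 of the larger in-plane field of view, coarse
        enough that anatomy is not absorbed into the field.
    """
    v = volume.voxels.astype(np.float64)
    if not np.all(np.isfinite(v)):
        raise ValueError(f"{volume.exam_id}: non-finite input")
    if np.all(v == 0):
        raise ValueError(f"{volume.exam_id}: all-zero volume")
    if max_iterations < 1:
        raise ValueError("max_iterations must be >= 1")
    if v.min() < 0:
        v = v - v.min()
    dz, dy, dx = volume.spacing
    if spline_scale_mm is None:
        spline_scale_mm = max(v.shape[1] * dy, v.shape[2] * dx) / 3.0
    extent = (v.shape[0] * dz, v.shape[1] * dy, v.shape[2] * dx)
    cells = [max(1, int(round(e / spline_scale_mm))) for e in extent]

    delta = 1e-3 * v[v > 0].mean()
    l = np.log(v + delta)
    log_field = np.zeros_like(l)
    for _ in range(max_iterations):
        resid = l - _sharpen_modes(l - log_field)
        new = _smooth_field_fit(resid, cells)
        new -= new.mean()
        if np.max(np.abs(new - log_field)) < tol:
            log_field = new
            break
        log_field = new
    corrected = np.clip(np.exp(l - log_field) - delta, 0.0, None)
    return ImageVolume(corrected.astype(np.float32), volume.spacing, volume.exam_id)


# ---------------------------------------------------------------------------
# Normalizations


def _check_finite(volume: ImageVolume) -> np.ndarray:
    v = volume.voxels
    if not np.all(np.isfinite(v)):
        raise ValueError(f"{volume.exam_id}: non-finite input")
    return v.astype(np.float64)


def normalize_zscore(volume: ImageVolume) -> ImageVolume:
    """Standardize to zero mean / unit population sd over the whole volume."""
    v = _check_finite(volume)
    if v.size < 2:
        raise ValueError("z-score needs at least 2 voxels")
    sd = v.std()
    if sd < 1e-12:
        log.warning("%s: constant volume, z-score output set to zeros", volume.exam_id)
        out = np.zeros_like(v)
    else:
        out = (v - v.mean()) / sd
    return ImageVolume(out.astype(np.float32), volume.spacing, volume.exam_id)


def normalize_minmax_volume(volume: ImageVolume) -> ImageVolume:
    """Rescale the whole 3D volume linearly onto [0, 1]."""
    v = _check_finite(volume)
    lo, hi = v.min(), v.max()
    if hi - lo < 1e-12:
        log.warning("%s: constant volume, min-max output set to zeros", volume.exam_id)
        out = np.zeros_like(v)
    else:
        out = (v - lo) / (hi - lo)
    return ImageVolume(out.astype(np.float32), volume.spacing, volume.exam_id)


def normalize_minmax_slice(volume: ImageVolume) -> ImageVolume:
    """Apply the min-max map to each 2D slice independently."""
    v = _check_finite(volume)
    lo = v.min(axis=(1, 2), keepdims=True)
    hi = v.max(axis=(1, 2), keepdims=True)
    rng = hi - lo
    flat = rng[:, 0, 0] < 1e-12
    if flat.any():
        log.warning("%s: %d constant slice(s) set to zeros", volume.exam_id,
                    int(flat.sum()))
    rng = np.where(rng < 1e-12, 1.0, rng)
    out = (v - lo) / rng
    out[flat] = 0.0
    return ImageVolume(out.astype(np.float32), volume.spacing, volume.exam_id)


# ---------------------------------------------------------------------------
# Nyul histogram standardization


def _foreground(v: np.ndarray) -> np.ndarray:
    """Foreground voxels: intensity above the mean of the nonzero voxels."""
    nz = v[v != 0]
    thr = nz.mean() if nz.size else 0.0
    fg = v[v > thr]
    return fg if fg.size else v.reshape(-1)


def _landmarks(v: np.ndarray, percentiles) -> np.ndarray:
    return np.percentile(_foreground(v), percentiles)


def nyul_train(volumes, percentiles=DEFAULT_PERCENTILES,
               standard_range=DEFAULT_STANDARD_RANGE) -> NyulStandardScale:
    """Learn a standard intensity scale from a training cohort.

    For each volume, landmark intensities at the given percentiles of the
    foreground histogram are mapped by the affine transform that sends the
    low/high anchor landmarks to the standard range; the standard scale is
    the across-cohort mean of the mapped landmarks.
    """
    volumes = list(volumes)
    if not volumes:
        raise ValueError("nyul_train needs at least one volume")
    p = np.asarray(percentiles, dtype=float)
    if p.ndim != 1 or len(p) < 3 or not np.all(np.diff(p) > 0):
        raise ValueError("percentiles must be >= 3 strictly increasing values")
    s_min, s_max = (float(x) for x in standard_range)
    if s_max <= s_min:
        raise ValueError("standard_range must be increasing")
    mapped = []
    for vol in volumes:
        lm = _landmarks(_check_finite(vol), p)
        if not np.all(np.diff(lm) > 0):
            raise ValueError(
                f"{vol.exam_id}: degenerate (non-increasing) landmarks")
        a = (s_max - s_min) / (lm[-1] - lm[0])
        mapped.append(s_min + a * (lm - lm[0]))
    standard = np.mean(mapped, axis=0)
    return NyulStandardScale(tuple(p), tuple(standard))


def nyul_apply(volume: ImageVolume, scale: NyulStandardScale) -> ImageVolume:
    """Map a volume onto the standard scale by piecewise-linear interpolation.

    The volume's own landmark intensities are sent to ``standard_values``;
    between landmarks the map is linear, and beyond the anchor landmarks it
    extrapolates linearly with the end-segment slopes.  The map is monotone
    non-decreasing, so intensity ordering is preserved.
    """
    v = _check_finite(volume)
    lm = _landmarks(v, scale.percentiles)
    if not np.all(np.diff(lm) > 0):
        raise ValueError(f"{volume.exam_id}: degenerate (non-increasing) landmarks")
    sv = np.asarray(scale.standard_values)
    out = np.interp(v, lm, sv)
    # linear extrapolation beyond the anchors (np.interp clamps)
    lo_slope = (sv[1] - sv[0]) / (lm[1] - lm[0])
    hi_slope = (sv[-1] - sv[-2]) / (lm[-1] - lm[-2])
    below = v < lm[0]
    above = v > lm[-1]
    out[below] = sv[0] + lo_slope * (v[below] - lm[0])
    out[above] = sv[-1] + hi_slope * (v[above] - lm[-1])
    return ImageVolume(out.astype(np.float32), volume.spacing, volume.exam_id)


# ---------------------------------------------------------------------------
# Composition


def apply_preprocess(exam: Exam, spec: PreprocessSpec) -> Exam:
    """Apply one preprocessing variant to an exam's image; the mask is untouched."""
    if spec.method == "nyul" and spec.nyul_scale is None:
        raise ValueError("nyul method requires a trained NyulStandardScale")
    img = exam.image
    if spec.bias_correct:
        img = bias_correct(img)
    if spec.method == "zscore":
        img = normalize_zscore(img)
    elif spec.method == "minmax_volume":
        img = normalize_minmax_volume(img)
    elif spec.method == "minmax_slice":
        img = normalize_minmax_slice(img)
    else:
        img = nyul_apply(img, spec.nyul_scale)
    return replace(exam, image=img)
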