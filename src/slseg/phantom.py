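"""Seeded generator of synthetic MR-like exams.

Multicenter musculoskeletal MR data are heterogeneous in ways that matter to
a segmentation ensemble: smooth multiplicative bias fields, site-dependent
intensity offsets/scales/gamma, variable tumor size, contrast and position,
and additive noise.  This module builds small 3D phantoms with exactly that
statistical structure — a dim muscle-like background, a bright fat band,
and a lobulated ellipsoidal "lipomatous tumor" whose intensity sits at a
configurable contrast to fat — so every downstream stage (preprocessing,
training, ensembling, evaluation) is testable without any data download.

Everything is a pure function of ``(config.seed, exam index)``; two calls
with equal arguments return bit-identical exams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import Exam, ImageVolume, SegmentationMask

#: intensity of the fat band on the phantom's native scale
FAT_INTENSITY = 1.0
#: intensity of the muscle-like background
MUSCLE_INTENSITY = 0.35


@dataclass(frozen=True)
class PhantomConfig:
    """Cohort-level description of the synthetic study conditions."""

    n_exams: int = 60
    shape: tuple[int, int, int] = (8, 64, 64)
    tumor_radius_range: tuple[float, float] = (7.0, 14.0)
    tumor_contrast_range: tuple[float, float] = (1.4, 1.9)
    bias_amplitude: float = 0.3
    bias_smoothness: float = 16.0
    noise_sd: float = 0.03
    site_styles: tuple[tuple[float, float, float], ...] = (
        (0.0, 1.0, 1.0),      # reference scanner
        (20.0, 160.0, 0.9),   # offset + wide dynamic range, mild gamma
        (5.0, 620.0, 1.15),   # high-gain protocol
    )
    location_labels: tuple[str, ...] = ("DUL", "DLL", "PUL", "PLL", "T")
    max_lobes: int = 3
    spacing: tuple[float, float, float] = (5.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_exams < 1:
            raise ValueError("n_exams must be >= 1")
        if any(s < 1 for s in self.shape):
            raise ValueError("non-positive shape")
        for rng_ in (self.tumor_radius_range, self.tumor_contrast_range):
            if rng_[0] > rng_[1]:
                raise ValueError(f"range out of order: {rng_}")
        if self.noise_sd < 0 or self.bias_amplitude < 0:
            raise ValueError("noise_sd and bias_amplitude must be >= 0")
        if not self.site_styles:
            raise ValueError("need at least one site style")


def make_bias_field(shape, amplitude: float, smoothness: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Strictly positive smooth multiplicative field with mean ~1.

    Low-pass filtered white noise, scaled to the requested peak amplitude in
    the log domain, exponentiated, then normalized to unit mean.  With
    ``amplitude == 0`` the field is exactly 1 everywhere.
    """
    if any(s < 1 for s in shape):
        raise ValueError(f"non-positive shape {shape}")
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if amplitude == 0:
        return np.ones(shape, dtype=np.float64)
    noise = rng.standard_normal(shape)
    # in-plane correlation length `smoothness`; weaker smoothing across slices
    sigma = (max(1.0, smoothness / 4.0), smoothness, smoothness)
    smooth = ndimage.gaussian_filter(noise, sigma=sigma, mode="nearest")
    peak = np.abs(smooth).max()
    if peak < 1e-12:
        return np.ones(shape, dtype=np.float64)
    log_field = smooth / peak * np.log1p(amplitude)
    field = np.exp(log_field)
    return field / field.mean()


def _ellipsoid(shape, center, radii, rot_deg: float) -> np.ndarray:
    """Boolean ellipsoid with in-plane rotation, radii = (rz, ry, rx) voxels."""
    zz, yy, xx = np.meshgrid(*(np.arange(s, dtype=np.float64) for s in shape),
                             indexing="ij")
    zz, yy, xx = zz - center[0], yy - center[1], xx - center[2]
    th = np.deg2rad(rot_deg)
    yr = yy * np.cos(th) - xx * np.sin(th)
    xr = yy * np.sin(th) + xx * np.cos(th)
    return (zz / radii[0]) ** 2 + (yr / radii[1]) ** 2 + (xr / radii[2]) ** 2 <= 1.0


def generate_exam(config: PhantomConfig, index: int) -> Exam:
    """Generate one phantom exam, fully determined by ``(config.seed, index)``."""
    if not 0 <= index < config.n_exams:
        raise ValueError(f"index {index} outside [0, {config.n_exams})")
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, index)))
    nz, ny, nx = config.shape

    # --- anatomy: muscle background with a sharp-edged fat band -----------
    # piecewise-constant tissue classes, as in real limbs where subcutaneous
    # fat meets muscle at a crisp fascia boundary
    vol = np.full(config.shape, MUSCLE_INTENSITY, dtype=np.float64)
    band_center = rng.uniform(0.25, 0.75) * ny
    band_width = rng.uniform(0.10, 0.18) * ny
    rows = np.abs(np.arange(ny) - band_center) < band_width
    vol[:, rows, :] = FAT_INTENSITY

    # --- tumor: 1..max_lobes overlapping ellipsoids -----------------------
    r_lo, r_hi = config.tumor_radius_range
    if 2 * r_hi + 2 > min(ny, nx):
        raise ValueError(
            f"tumor radius range {config.tumor_radius_range} cannot fit "
            f"inside in-plane shape {(ny, nx)}")
    contrast = rng.uniform(*config.tumor_contrast_range)
    n_lobes = int(rng.integers(1, config.max_lobes + 1))
    r_main = rng.uniform(r_lo, r_hi)
    rz_main = max(1.0, min(nz / 2.0 - 1.0, rng.uniform(0.25, 0.45) * nz))
    margin_y = r_hi + 1
    center = np.array([
        rng.uniform(rz_main + 0.5, nz - rz_main - 0.5) if nz > 2 * rz_main + 1
        else nz / 2.0,
        rng.uniform(margin_y, ny - margin_y),
        rng.uniform(margin_y, nx - margin_y),
    ])
    mask = _ellipsoid(config.shape, center,
                      (rz_main, r_main, r_main * rng.uniform(0.7, 1.0)),
                      rng.uniform(0, 180))
    for _ in range(n_lobes - 1):
        off = rng.uniform(-0.5, 0.5, size=3) * np.array([rz_main, r_main, r_main])
        r_lobe = r_main * rng.uniform(0.4, 0.8)
        rz_lobe = max(1.0, rz_main * rng.uniform(0.5, 0.9))
        lobe_center = center + off
        lobe = _ellipsoid(config.shape, lobe_center,
                          (rz_lobe, r_lobe, r_lobe * rng.uniform(0.7, 1.0)),
                          rng.uniform(0, 180))
        # keep lobes strictly inside the grid
        lobe[0, :, :] = lobe[-1, :, :] = False
        lobe[:, 0, :] = lobe[:, -1, :] = False
        lobe[:, :, 0] = lobe[:, :, -1] = False
        mask |= lobe
    vol[mask] = FAT_INTENSITY * contrast

    # --- acquisition: bias field, site style, noise -----------------------
    bias = make_bias_field(config.shape, config.bias_amplitude,
                           config.bias_smoothness, rng)
    vol = vol * bias
    offset, scale, gamma = config.site_styles[index % len(config.site_styles)]
    vol = offset + scale * np.power(np.clip(vol, 0, None), gamma)
    if config.noise_sd > 0:
        vol = vol + rng.normal(0.0, config.noise_sd * scale, size=config.shape)

    exam_id = f"phantom-{config.seed:04d}-{index:03d}"
    image = ImageVolume(vol.astype(np.float32), config.spacing, exam_id)
    seg = SegmentationMask(mask.astype(np.uint8), config.spacing, exam_id)
    label = config.location_labels[index % len(config.location_labels)]
    return Exam(image, seg, location_label=label,
                site_tag=f"site{index % len(config.site_styles)}")


def generate_cohort(config: PhantomConfig) -> list[Exam]:
    """All ``n_exams`` phantoms; site styles and location labels cycle."""
    return [generate_exam(config, i) for i in range(config.n_exams)]


def easy_config(n_exams: int = 20, seed: int = 0, shape=(8, 64, 64)) -> PhantomConfig:
    """Homogeneous, noise-free conditions: tumors are constant-intensity
    ellipsoids brighter than everything else, segmentable by thresholding.
    Used as a perfect-DSC oracle regime in end-to-end tests."""
    return PhantomConfig(
        n_exams=n_exams, shape=shape, seed=seed,
        tumor_contrast_range=(1.6, 1.9), bias_amplitude=0.0,
        noise_sd=0.0, site_styles=((0.0, 1.0, 1.0),),
    )
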