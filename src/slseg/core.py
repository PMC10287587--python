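"""Domain types, volume/mask I/O, grid resampling and cohort splitting.

Conventions used throughout the package:

* volumes are ``float32`` arrays indexed ``(slice, row, col)``;
* voxel spacing is ``(dz, dy, dx)`` in mm, matching the array axes;
* masks are ``uint8`` arrays with 1 = tumor, 0 = background;
* all physical distances are computed in mm via the spacing.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np

LOCATION_LABELS = ("DUL", "DLL", "PUL", "PLL", "T", "UNKNOWN")


@dataclass(frozen=True)
class ImageVolume:
    """A 3D scalar MR intensity grid with per-axis voxel spacing in mm."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    exam_id: str

    def __post_init__(self):
        v = np.asarray(self.voxels, dtype=np.float32)
        if v.ndim != 3 or v.shape[0] < 1:
            raise ValueError(f"expected a 3D volume, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"{self.exam_id}: non-finite intensities")
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError(f"spacing must be 3 positive lengths, got {self.spacing}")
        object.__setattr__(self, "voxels", v)
        object.__setattr__(self, "spacing", sp)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass(frozen=True)
class SegmentationMask:
    """Binary grid congruent with an :class:`ImageVolume` (1 = tumor)."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    exam_id: str

    def __post_init__(self):
        v = np.asarray(self.voxels)
        vals = np.unique(v)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(
                f"{self.exam_id}: mask values must be in {{0,1}}, found {vals[:8]}"
            )
        object.__setattr__(self, "voxels", v.astype(np.uint8))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass(frozen=True)
class Exam:
    """An image/mask pair plus location and site metadata."""

    image: ImageVolume
    mask: SegmentationMask
    location_label: str = "UNKNOWN"
    site_tag: str = ""

    def __post_init__(self):
        if self.image.shape != self.mask.shape:
            raise ValueError(
                f"{self.exam_id}: image shape {self.image.shape} "
                f"!= mask shape {self.mask.shape}"
            )
        if not np.allclose(self.image.spacing, self.mask.spacing):
            raise ValueError(f"{self.exam_id}: image/mask spacing mismatch")
        if self.location_label not in LOCATION_LABELS:
            raise ValueError(f"unknown location label {self.location_label!r}")

    @property
    def exam_id(self) -> str:
        return self.image.exam_id


@dataclass(frozen=True)
class DataSplit:
    """Disjoint train / tune / test exam-id lists."""

    train_ids: tuple[str, ...]
    tune_ids: tuple[str, ...]
    test_ids: tuple[str, ...]

    def __post_init__(self):
        groups = (set(self.train_ids), set(self.tune_ids), set(self.test_ids))
        n = sum(len(g) for g in groups)
        if len(groups[0] | groups[1] | groups[2]) != n:
            raise ValueError("split groups are not pairwise disjoint")

    @property
    def all_ids(self) -> tuple[str, ...]:
        return self.train_ids + self.tune_ids + self.test_ids


@dataclass(frozen=True)
class FoldAssignment:
    """Map exam-id -> fold index in [0, k)."""

    fold_of: dict
    k: int

    def fold_ids(self, fold: int) -> tuple[str, ...]:
        return tuple(e for e, f in self.fold_of.items() if f == fold)

    def train_val(self, fold: int) -> tuple[tuple[str, ...], tuple[str, ...]]:
        """Training ids (all other folds) and validation ids for one fold."""
        val = self.fold_ids(fold)
        train = tuple(e for e, f in self.fold_of.items() if f != fold)
        return train, val


# ---------------------------------------------------------------------------
# I/O


def _read_volume_any(path: str) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a NIfTI file or a DICOM series directory into (slice,row,col) order."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if os.path.isdir(path):
        import SimpleITK as sitk

        reader = sitk.ImageSeriesReader()
        files = reader.GetGDCMSeriesFileNames(path)
        if not files:
            raise FileNotFoundError(f"no DICOM series found in {path}")
        reader.SetFileNames(files)
        img = reader.Execute()
        arr = sitk.GetArrayFromImage(img)  # (z, y, x)
        spacing = tuple(reversed(img.GetSpacing()))  # (dz, dy, dx)
        return np.asarray(arr, dtype=np.float32), spacing
    import nibabel as nib

    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3D data, got shape {data.shape}")
    # nibabel axes are (x, y, z) = (col, row, slice); transpose to (z, y, x)
    zooms = img.header.get_zooms()[:3]
    return np.ascontiguousarray(data.T, dtype=np.float32), tuple(float(z) for z in reversed(zooms))


def read_exam(image_path: str, mask_path: str, *, location_label: str = "UNKNOWN",
              site_tag: str = "", exam_id: str | None = None) -> Exam:
    """Read an image/mask pair (NIfTI file or DICOM series directory).

    The mask is binarized at > 0.5; values other than {0, 1} in the raw mask
    are rejected so silent label-set errors cannot pass through.
    """
    img_vox, img_sp = _read_volume_any(image_path)
    msk_vox, msk_sp = _read_volume_any(mask_path)
    if img_vox.shape != msk_vox.shape:
        raise ValueError(
            f"image shape {img_vox.shape} != mask shape {msk_vox.shape}"
        )
    if not np.allclose(img_sp, msk_sp, rtol=1e-4):
        raise ValueError(f"image spacing {img_sp} != mask spacing {msk_sp}")
    vals = np.unique(msk_vox)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"mask contains values outside {{0,1}}: {vals[:8]}")
    if exam_id is None:
        exam_id = os.path.splitext(os.path.basename(image_path))[0]
        if exam_id.endswith(".nii"):
            exam_id = exam_id[:-4]
    image = ImageVolume(img_vox, img_sp, exam_id)
    mask = SegmentationMask((msk_vox > 0.5).astype(np.uint8), img_sp, exam_id)
    return Exam(image, mask, location_label=location_label, site_tag=site_tag)


def write_exam(exam: Exam, image_path: str, mask_path: str) -> None:
    """Write an exam as a pair of NIfTI files (float32 image, uint8 mask)."""
    import nibabel as nib

    dz, dy, dx = exam.image.spacing
    affine = np.diag([dx, dy, dz, 1.0])
    for arr, path in ((exam.image.voxels, image_path), (exam.mask.voxels, mask_path)):
        img = nib.Nifti1Image(np.ascontiguousarray(arr.T), affine)
        img.header.set_zooms((dx, dy, dz))
        nib.save(img, path)


def write_raw_cache(exam: Exam, out_dir: str) -> str:
    """Persist an exam as raw 32-bit little-endian floats + a text sidecar."""
    os.makedirs(out_dir, exist_ok=True)
    base = os.path.join(out_dir, exam.exam_id)
    exam.image.voxels.astype("<f4").tofile(base + ".img.raw")
    exam.mask.voxels.astype("<f4").tofile(base + ".msk.raw")
    with open(base + ".hdr", "w") as fh:
        s = exam.image.shape
        sp = exam.image.spacing
        fh.write(f"exam_id\t{exam.exam_id}\n")
        fh.write(f"shape\t{s[0]}\t{s[1]}\t{s[2]}\n")
        fh.write(f"spacing\t{sp[0]!r}\t{sp[1]!r}\t{sp[2]!r}\n")
        fh.write(f"location\t{exam.location_label}\n")
        fh.write(f"site\t{exam.site_tag}\n")
    return base


def read_raw_cache(base: str) -> Exam:
    """Read an exam written by :func:`write_raw_cache` (path without suffix)."""
    meta = {}
    with open(base + ".hdr") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            meta[parts[0]] = parts[1:]
    shape = tuple(int(x) for x in meta["shape"])
    spacing = tuple(float(x) for x in meta["spacing"])
    exam_id = meta["exam_id"][0]
    img = np.fromfile(base + ".img.raw", dtype="<f4").reshape(shape)
    msk = np.fromfile(base + ".msk.raw", dtype="<f4").reshape(shape)
    return Exam(
        ImageVolume(img, spacing, exam_id),
        SegmentationMask((msk > 0.5).astype(np.uint8), spacing, exam_id),
        location_label=meta.get("location", ["UNKNOWN"])[0] or "UNKNOWN",
        site_tag=meta.get("site", [""])[0],
    )


# ---------------------------------------------------------------------------
# Resampling


def resample_to_grid(exam: Exam, target: int = 512) -> Exam:
    """Resample every slice to ``target`` x ``target`` preserving aspect ratio.

    The larger in-plane dimension is scaled isotropically to ``target``
    (bilinear for the image, nearest-neighbor for the mask) and the remainder
    is symmetrically zero-padded.  In-plane spacing is divided by the scale
    factor; the slice axis is untouched (the networks are 2D slice-wise).
    """
    if target <= 0:
        raise ValueError(f"target must be positive, got {target}")
    from skimage.transform import resize

    nz, ny, nx = exam.image.shape
    if (ny, nx) == (target, target):
        return exam
    scale = target / max(ny, nx)
    new_y = int(round(ny * scale))
    new_x = int(round(nx * scale))
    dz, dy, dx = exam.image.spacing
    new_spacing = (dz, dy / scale, dx / scale)

    img = np.empty((nz, new_y, new_x), dtype=np.float32)
    msk = np.empty((nz, new_y, new_x), dtype=np.uint8)
    for z in range(nz):
        img[z] = resize(exam.image.voxels[z], (new_y, new_x), order=1,
                        anti_aliasing=False, preserve_range=True)
        msk[z] = resize(exam.mask.voxels[z], (new_y, new_x), order=0,
                        anti_aliasing=False, preserve_range=True)

    pad_y, pad_x = target - new_y, target - new_x
    pads = ((0, 0), (pad_y // 2, pad_y - pad_y // 2), (pad_x // 2, pad_x - pad_x // 2))
    img = np.pad(img, pads)
    msk = np.pad(msk, pads)
    image = ImageVolume(img, new_spacing, exam.exam_id)
    mask = SegmentationMask(msk, new_spacing, exam.exam_id)
    return replace(exam, image=image, mask=mask)


# ---------------------------------------------------------------------------
# Splitting


def largest_remainder_sizes(n: int, fractions) -> list[int]:
    """Apportion ``n`` items to groups by the largest-remainder method."""
    fractions = np.asarray(fractions, dtype=float)
    quotas = n * fractions
    sizes = np.floor(quotas).astype(int)
    remainder = n - sizes.sum()
    # ties broken by group order, matching a stable descending sort
    order = np.argsort(-(quotas - sizes), kind="stable")
    sizes[order[:remainder]] += 1
    return sizes.tolist()


def split_cohort(exam_ids, fractions=(0.80, 0.09, 0.11), seed: int = 0) -> DataSplit:
    """Single seeded split into train / tune / test by largest-remainder sizes."""
    ids = list(exam_ids)
    if not ids:
        raise ValueError("empty cohort")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate exam ids")
    fr = tuple(float(f) for f in fractions)
    if len(fr) != 3 or any(f < 0 for f in fr):
        raise ValueError(f"need 3 non-negative fractions, got {fractions}")
    if abs(sum(fr) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fr)}")
    rng = np.random.default_rng(seed)
    perm = [ids[i] for i in rng.permutation(len(ids))]
    n_train, n_tune, _ = largest_remainder_sizes(len(ids), fr)
    return DataSplit(
        train_ids=tuple(perm[:n_train]),
        tune_ids=tuple(perm[n_train:n_train + n_tune]),
        test_ids=tuple(perm[n_train + n_tune:]),
    )


def make_folds(train_ids, k: int, seed: int = 0) -> FoldAssignment:
    """Seeded K-fold assignment with fold sizes differing by at most one."""
    ids = list(train_ids)
    n = len(ids)
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k > n:
        raise ValueError(f"k={k} exceeds number of exams {n}")
    rng = np.random.default_rng(seed)
    perm = [ids[i] for i in rng.permutation(n)]
    base, extra = divmod(n, k)
    fold_of = {}
    pos = 0
    for f in range(k):
        size = base + (1 if f < extra else 0)
        for e in perm[pos:pos + size]:
            fold_of[e] = f
        pos += size
    return FoldAssignment(fold_of=fold_of, k=k)
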