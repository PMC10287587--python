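"""Overlap- and boundary-based evaluation of predicted segmentations.

Overlap metrics (DSC, sensitivity, specificity) are voxel-count ratios;
HD95 is the 95th percentile of nearest-boundary Euclidean distances in mm
(pooled over both directions, honoring anisotropic voxel spacing); the ROC
analysis treats every voxel's predicted probability as a score for the
tumor class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from scipy.spatial import cKDTree

from .core import SegmentationMask


@dataclass(frozen=True)
class MetricsReport:
    exam_id: str
    dsc: float
    sensitivity: float
    specificity: float
    hd95_mm: float | None = None
    auc: float | None = None

    def as_row(self) -> dict:
        return {"exam_id": self.exam_id, "dsc": self.dsc,
                "sensitivity": self.sensitivity, "specificity": self.specificity,
                "hd95_mm": self.hd95_mm, "auc": self.auc}


def _as_bool(mask) -> np.ndarray:
    if isinstance(mask, SegmentationMask):
        return mask.voxels.astype(bool)
    return np.asarray(mask).astype(bool)


def confusion_counts(pred, ref) -> tuple[int, int, int, int]:
    """Voxelwise (TP, FP, TN, FN)."""
    p, r = _as_bool(pred), _as_bool(ref)
    if p.shape != r.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {r.shape}")
    tp = int(np.count_nonzero(p & r))
    fp = int(np.count_nonzero(p & ~r))
    fn = int(np.count_nonzero(~p & r))
    tn = p.size - tp - fp - fn
    return tp, fp, tn, fn


def dsc(pred, ref) -> float:
    """Dice-similarity coefficient 2TP/(2TP+FP+FN); 1.0 if both masks empty."""
    tp, fp, tn, fn = confusion_counts(pred, ref)
    if tp + fp + fn == 0:
        import logging
        logging.getLogger(__name__).warning("both masks empty: DSC defined as 1.0")
        return 1.0
    return 2.0 * tp / (2.0 * tp + fp + fn)


def sensitivity(pred, ref) -> float:
    """TP/(TP+FN); NaN if the reference is empty."""
    tp, fp, tn, fn = confusion_counts(pred, ref)
    if tp + fn == 0:
        return float("nan")
    return tp / (tp + fn)


def specificity(pred, ref) -> float:
    """TN/(TN+FP); NaN if the reference covers everything."""
    tp, fp, tn, fn = confusion_counts(pred, ref)
    if tn + fp == 0:
        return float("nan")
    return tn / (tn + fp)


# ---------------------------------------------------------------------------
# HD95


def boundary_voxels(mask) -> np.ndarray:
    """Indices (k,3) of mask voxels with >= 1 face-adjacent background neighbor."""
    m = _as_bool(mask)
    structure = ndimage.generate_binary_structure(m.ndim, 1)  # faces only
    interior = ndimage.binary_erosion(m, structure=structure, border_value=0)
    return np.argwhere(m & ~interior)


def hd95(pred, ref, spacing=None, slicewise: bool = False) -> float | None:
    """95th percentile of pooled bidirectional nearest-boundary distances (mm).

    Returns ``None`` when either mask is empty (the distance set is then
    undefined).  With ``slicewise=True`` the distances are computed per 2D
    slice within the slices where both masks are present, mirroring
    slice-by-slice delineation; the default is fully volumetric 3D.
    """
    p, r = _as_bool(pred), _as_bool(ref)
    if p.shape != r.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {r.shape}")
    if spacing is None:
        spacing = (pred.spacing if isinstance(pred, SegmentationMask)
                   else (1.0,) * p.ndim)
    spacing = np.asarray(spacing, dtype=float)
    if not p.any() or not r.any():
        return None
    if slicewise:
        dists = []
        for z in range(p.shape[0]):
            if p[z].any() and r[z].any():
                dists.append(_directed_distances(p[z], r[z], spacing[1:]))
        if not dists:
            return None
        return float(np.percentile(np.concatenate(dists), 95))
    return float(np.percentile(_directed_distances(p, r, spacing), 95))


def _directed_distances(p: np.ndarray, r: np.ndarray, spacing) -> np.ndarray:
    bp = boundary_voxels(p) * spacing
    br = boundary_voxels(r) * spacing
    tree_r = cKDTree(br)
    tree_p = cKDTree(bp)
    d_pr, _ = tree_r.query(bp)
    d_rp, _ = tree_p.query(br)
    return np.concatenate([d_pr, d_rp])


# ---------------------------------------------------------------------------
# ROC


def roc_auc(pmap, ref) -> tuple[np.ndarray, float | None]:
    """Voxelwise ROC curve points (fpr, tpr) and tie-aware AUC.

    AUC is the normalized rank-sum (Mann-Whitney) statistic, identical to
    the trapezoid rule over the tie-grouped ROC curve; a single-class
    reference yields ``(empty curve, None)``.
    """
    scores = np.asarray(pmap, dtype=np.float64).reshape(-1)
    y = _as_bool(ref).reshape(-1)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        return np.empty((0, 2)), None
    ranks = stats.rankdata(scores)
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(y.astype(int), scores)
    return np.column_stack([fpr, tpr]), float(auc)


# ---------------------------------------------------------------------------
# Per-exam and per-location reporting


def evaluate_exam(pred: SegmentationMask, ref: SegmentationMask,
                  pmap=None) -> MetricsReport:
    """All metrics for one exam; AUC included when a probability map is given."""
    auc = None
    if pmap is not None:
        _, auc = roc_auc(pmap, ref)
    return MetricsReport(
        exam_id=ref.exam_id,
        dsc=dsc(pred, ref),
        sensitivity=sensitivity(pred, ref),
        specificity=specificity(pred, ref),
        hd95_mm=hd95(pred, ref),
        auc=auc,
    )


_METRIC_COLS = ("dsc", "sensitivity", "specificity", "hd95_mm", "auc")


def _mean_metrics(reports) -> dict:
    out = {}
    for colm in _METRIC_COLS:
        vals = [getattr(r, colm) for r in reports]
        vals = [v for v in vals if v is not None and np.isfinite(v)]
        out[colm] = float(np.mean(vals)) if vals else None
        out[f"n_{colm}"] = len(vals)
    out["n_exams"] = len(reports)
    return out


def summarize_by_location(sl_reports, labels: dict,
                          individual_reports=None):
    """Per-location and overall metric means, with improvement rows.

    ``labels`` maps exam_id -> location label.  When per-exam reports of the
    individual base learners are supplied (a flat list, several rows per
    exam), the summary adds the individual means and improvement rows:
    the signed difference (SL - individual) for the overlap metrics, and
    the percent reduction ``(individual - SL) / individual * 100`` for HD95.
    Undefined HD95 entries are excluded from the means, with the count of
    contributing exams reported.
    """
    import pandas as pd

    for r in sl_reports:
        if r.exam_id not in labels:
            raise ValueError(f"exam {r.exam_id} has no location label")
    locations = sorted({labels[r.exam_id] for r in sl_reports})
    rows = []
    for loc in locations + ["ALL"]:
        sel = [r for r in sl_reports
               if loc == "ALL" or labels[r.exam_id] == loc]
        row = {"location": loc, "group": "super_learner", **_mean_metrics(sel)}
        rows.append(row)
        if individual_reports is not None:
            sel_ind = [r for r in individual_reports
                       if loc == "ALL" or labels.get(r.exam_id) == loc]
            ind_row = {"location": loc, "group": "individual",
                       **_mean_metrics(sel_ind)}
            rows.append(ind_row)
            rows.append({"location": loc, "group": "improvement",
                         **improvement_row(ind_row, row)})
    return pd.DataFrame(rows)


def improvement_row(individual: dict, sl: dict) -> dict:
    """Improvement of SL over the individual mean, per metric.

    Overlap metrics and AUC are bounded in [0,1], so the signed difference
    SL - individual is reported directly; HD95 is an unbounded distance, so
    the improvement is the percent reduction (individual - SL)/individual.
    """
    out = {}
    for colm in ("dsc", "sensitivity", "specificity", "auc"):
        a, b = individual.get(colm), sl.get(colm)
        out[colm] = None if a is None or b is None else b - a
    a, b = individual.get("hd95_mm"), sl.get("hd95_mm")
    if a is None or b is None or a == 0:
        out["hd95_mm"] = None
    else:
        out["hd95_mm"] = (a - b) / a * 100.0
    return out
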