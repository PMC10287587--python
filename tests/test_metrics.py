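"""Overlap metrics, HD95 and ROC against independent brute-force oracles."""

import numpy as np
import pytest

from slseg.core import SegmentationMask
from slseg.metrics import (
    MetricsReport,
    confusion_counts,
    dsc,
    evaluate_exam,
    hd95,
    improvement_row,
    roc_auc,
    sensitivity,
    specificity,
    summarize_by_location,
)


def brute_confusion(pred, ref):
    """Independent oracle: explicit per-voxel Python loop."""
    tp = fp = tn = fn = 0
    for p, r in zip(np.asarray(pred).ravel(), np.asarray(ref).ravel()):
        if p and r:
            tp += 1
        elif p and not r:
            fp += 1
        elif not p and r:
            fn += 1
        else:
            tn += 1
    return tp, fp, tn, fn


def brute_boundary(mask):
    """Mask voxels with a face neighbor outside the mask (grid edge counts)."""
    m = np.asarray(mask).astype(bool)
    out = []
    for idx in np.argwhere(m):
        for ax in range(3):
            for d in (-1, 1):
                nb = idx.copy()
                nb[ax] += d
                if (nb < 0).any() or (nb >= m.shape).any() or not m[tuple(nb)]:
                    out.append(idx)
                    break
            else:
                continue
            break
    return np.array(out).reshape(-1, 3)


def brute_hd95(pred, ref, spacing):
    from scipy.spatial.distance import cdist

    bp = brute_boundary(pred) * np.asarray(spacing)
    br = brute_boundary(ref) * np.asarray(spacing)
    d = cdist(bp, br)
    pooled = np.concatenate([d.min(axis=1), d.min(axis=0)])
    return float(np.percentile(pooled, 95))


class TestConfusion:
    def test_identical_masks(self, rng):
        m = (rng.random((3, 6, 6)) > 0.5).astype(np.uint8)
        tp, fp, tn, fn = confusion_counts(m, m)
        assert fp == 0 and fn == 0 and tp == m.sum()

    def test_complementary_masks(self, rng):
        m = (rng.random((3, 6, 6)) > 0.5).astype(np.uint8)
        tp, fp, tn, fn = confusion_counts(1 - m, m)
        assert tp == 0 and tn == 0

    def test_two_by_two_toy(self):
        ref = np.array([[[1, 1], [0, 0]]])
        pred = np.array([[[0, 1], [0, 1]]])
        assert confusion_counts(pred, ref) == (1, 1, 1, 1)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_counts(np.zeros((1, 2, 2)), np.zeros((1, 2, 3)))


class TestOverlapMetrics:
    def test_identical_nonempty_masks_all_one(self, rng):
        m = (rng.random((2, 5, 5)) > 0.4).astype(np.uint8)
        assert dsc(m, m) == 1.0
        assert sensitivity(m, m) == 1.0
        assert specificity(m, m) == 1.0

    def test_two_by_two_toy_values(self):
        ref = np.array([[[1, 1], [0, 0]]])
        pred = np.array([[[0, 1], [0, 1]]])
        assert dsc(pred, ref) == 0.5
        assert sensitivity(pred, ref) == 0.5
        assert specificity(pred, ref) == 0.5

    def test_disjoint_masks(self):
        a = np.zeros((1, 4, 4), dtype=np.uint8)
        b = np.zeros((1, 4, 4), dtype=np.uint8)
        a[0, 0, 0] = 1
        b[0, 3, 3] = 1
        assert dsc(a, b) == 0.0
        assert sensitivity(a, b) == 0.0

    def test_both_empty_dsc_is_one_with_warning(self, caplog):
        z = np.zeros((1, 3, 3), dtype=np.uint8)
        with caplog.at_level("WARNING"):
            assert dsc(z, z) == 1.0
        assert "empty" in caplog.text

    def test_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            pred = (rng.random((16, 16)) > rng.uniform(0.3, 0.7)).astype(np.uint8)
            ref = (rng.random((16, 16)) > rng.uniform(0.3, 0.7)).astype(np.uint8)
            tp, fp, tn, fn = brute_confusion(pred, ref)
            assert confusion_counts(pred, ref) == (tp, fp, tn, fn)
            if tp + fp + fn:
                assert dsc(pred, ref) == 2 * tp / (2 * tp + fp + fn)
            if tp + fn:
                assert sensitivity(pred, ref) == tp / (tp + fn)
            if tn + fp:
                assert specificity(pred, ref) == tn / (tn + fp)


class TestHD95:
    def test_identical_masks_zero(self, rng):
        m = np.zeros((3, 8, 8), dtype=np.uint8)
        m[1, 2:5, 2:5] = 1
        assert hd95(m, m, spacing=(1, 1, 1)) == 0.0

    def test_two_single_voxels_three_apart(self):
        a = np.zeros((1, 8, 8), dtype=np.uint8)
        b = np.zeros((1, 8, 8), dtype=np.uint8)
        a[0, 2, 2] = 1
        b[0, 2, 5] = 1
        assert hd95(a, b, spacing=(1.0, 1.0, 1.0)) == pytest.approx(3.0)

    def test_anisotropic_spacing_honored(self):
        a = np.zeros((3, 4, 4), dtype=np.uint8)
        b = np.zeros((3, 4, 4), dtype=np.uint8)
        a[0, 1, 1] = 1
        b[2, 1, 1] = 1  # two slices apart at dz = 5 mm
        assert hd95(a, b, spacing=(5.0, 1.0, 1.0)) == pytest.approx(10.0)

    def test_empty_mask_returns_undefined(self):
        m = np.zeros((1, 4, 4), dtype=np.uint8)
        n = m.copy()
        n[0, 1, 1] = 1
        assert hd95(m, n, spacing=(1, 1, 1)) is None
        assert hd95(n, m, spacing=(1, 1, 1)) is None

    def test_symmetric_in_arguments(self, rng):
        a = (rng.random((4, 10, 10)) > 0.6).astype(np.uint8)
        b = (rng.random((4, 10, 10)) > 0.6).astype(np.uint8)
        sp = (2.0, 0.7, 0.7)
        assert hd95(a, b, sp) == pytest.approx(hd95(b, a, sp))

    def test_matches_all_pairs_brute_force(self):
        rng = np.random.default_rng(7)
        spacing = (3.0, 0.9, 0.9)
        checked = 0
        while checked < 50:
            pred = (rng.random((4, 16, 16)) > rng.uniform(0.5, 0.9)).astype(np.uint8)
            ref = (rng.random((4, 16, 16)) > rng.uniform(0.5, 0.9)).astype(np.uint8)
            if not pred.any() or not ref.any():
                continue
            got = hd95(pred, ref, spacing)
            want = brute_hd95(pred, ref, spacing)
            assert got == pytest.approx(want, abs=1e-9)
            checked += 1

    def test_slicewise_option_on_shared_slices(self):
        a = np.zeros((2, 8, 8), dtype=np.uint8)
        b = np.zeros((2, 8, 8), dtype=np.uint8)
        a[0, 2, 2] = 1
        b[0, 2, 6] = 1
        b[1, 4, 4] = 1  # no pred on slice 1: excluded from slicewise pooling
        assert hd95(a, b, spacing=(10.0, 1.0, 1.0), slicewise=True) \
            == pytest.approx(4.0)


class TestROC:
    def test_perfect_separation(self):
        ref = np.array([[[0, 0, 1, 1]]], dtype=np.uint8)
        pmap = np.array([[[0.1, 0.2, 0.8, 0.9]]])
        _, auc = roc_auc(pmap, ref)
        assert auc == 1.0

    def test_constant_map_gives_half(self):
        ref = np.array([[[0, 1, 0, 1]]], dtype=np.uint8)
        _, auc = roc_auc(np.full((1, 1, 4), 0.5), ref)
        assert auc == 0.5

    def test_rank_sum_hand_example(self):
        y = np.array([0, 0, 1, 1], dtype=np.uint8)
        p = np.array([0.1, 0.4, 0.35, 0.8])
        _, auc = roc_auc(p, y)
        assert auc == pytest.approx(0.75)

    def test_single_class_reference_undefined(self):
        curve, auc = roc_auc(np.random.default_rng(0).random((1, 3, 3)),
                             np.zeros((1, 3, 3), dtype=np.uint8))
        assert auc is None and curve.size == 0

    def test_invariant_under_monotone_transform(self, rng):
        ref = (rng.random((2, 8, 8)) > 0.7).astype(np.uint8)
        p = rng.random((2, 8, 8))
        _, a1 = roc_auc(p, ref)
        _, a2 = roc_auc(np.sqrt(p) * 3 + 2, ref)
        assert a1 == pytest.approx(a2)

    def test_matches_sklearn_on_random_maps(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(10):
            ref = (rng.random((2, 8, 8)) > 0.6).astype(np.uint8)
            if ref.min() == ref.max():
                continue
            p = np.round(rng.random((2, 8, 8)), 1)  # coarse: force ties
            _, auc = roc_auc(p, ref)
            assert auc == pytest.approx(
                roc_auc_score(ref.ravel(), p.ravel()), abs=1e-12)


class TestSummaries:
    @staticmethod
    def _report(eid, **kw):
        base = dict(dsc=0.8, sensitivity=0.7, specificity=0.99,
                    hd95_mm=5.0, auc=0.95)
        base.update(kw)
        return MetricsReport(exam_id=eid, **base)

    def test_single_location_means_equal_report(self):
        reports = [self._report("a"), self._report("b")]
        table = summarize_by_location(reports, {"a": "PUL", "b": "PUL"})
        row = table[(table.location == "PUL")].iloc[0]
        assert row["dsc"] == pytest.approx(0.8)
        assert row["hd95_mm"] == pytest.approx(5.0)

    def test_overlap_improvement_is_signed_difference(self):
        sl = [self._report("a", dsc=0.857)]
        ind = [self._report("a", dsc=0.752)]
        table = summarize_by_location(sl, {"a": "DUL"}, ind)
        imp = table[(table.location == "DUL")
                    & (table.group == "improvement")].iloc[0]
        assert imp["dsc"] == pytest.approx(0.105)

    def test_hd95_improvement_is_percent_reduction(self):
        # the distal-upper-limb numbers: 11.5 mm down to 1.7 mm = 85.2 %
        sl = [self._report("a", hd95_mm=1.7)]
        ind = [self._report("a", hd95_mm=11.5)]
        table = summarize_by_location(sl, {"a": "DUL"}, ind)
        imp = table[(table.location == "DUL")
                    & (table.group == "improvement")].iloc[0]
        assert round(imp["hd95_mm"], 1) == 85.2

    def test_undefined_hd95_excluded_with_count(self):
        reports = [self._report("a"), self._report("b", hd95_mm=None)]
        table = summarize_by_location(reports, {"a": "T", "b": "T"})
        row = table[table.location == "T"].iloc[0]
        assert row["hd95_mm"] == pytest.approx(5.0)
        assert row["n_hd95_mm"] == 1 and row["n_exams"] == 2

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="label"):
            summarize_by_location([self._report("a")], {})

    def test_improvement_row_handles_missing(self):
        out = improvement_row({"dsc": None, "hd95_mm": 0.0},
                              {"dsc": 0.9, "hd95_mm": 1.0})
        assert out["dsc"] is None and out["hd95_mm"] is None


class TestEvaluateExam:
    def test_full_report_fields(self, rng):
        ref = np.zeros((2, 8, 8), dtype=np.uint8)
        ref[0, 2:5, 2:5] = 1
        pmap = rng.random((2, 8, 8)) * 0.3
        pmap[0, 2:5, 2:5] = 0.9
        pred = SegmentationMask((pmap >= 0.5).astype(np.uint8), (1, 1, 1), "e")
        refm = SegmentationMask(ref, (1, 1, 1), "e")
        rep = evaluate_exam(pred, refm, pmap)
        assert rep.dsc == 1.0 and rep.auc == 1.0 and rep.hd95_mm == 0.0

    def test_dice_loss_consistency_with_dsc(self, rng):
        from slseg.models import dice_loss

        pred = (rng.random((2, 8, 8)) > 0.5).astype(np.uint8)
        ref = (rng.random((2, 8, 8)) > 0.5).astype(np.uint8)
        assert dsc(pred, ref) == pytest.approx(
            1.0 - dice_loss(pred.astype(float), ref.astype(float)), abs=1e-5)
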