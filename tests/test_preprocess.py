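"""Bias correction and the four intensity normalization methods."""

import numpy as np
import pytest

from slseg.core import ImageVolume
from slseg.phantom import PhantomConfig, generate_exam, make_bias_field
from slseg.preprocess import (
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
from conftest import make_exam


def vol(arr, spacing=(1.0, 1.0, 1.0), exam_id="v"):
    return ImageVolume(np.asarray(arr, dtype=np.float32), spacing, exam_id)


class TestZscore:
    def test_hand_computed_values(self):
        out = normalize_zscore(vol([[[1.0, 2.0, 3.0]]]))
        np.testing.assert_allclose(
            out.voxels.ravel(), [-1.2247449, 0.0, 1.2247449], atol=1e-6)

    def test_output_mean_zero_sd_one(self, rng):
        out = normalize_zscore(vol(rng.random((4, 8, 8)) * 100 + 17))
        assert abs(out.voxels.mean()) < 1e-6
        assert abs(out.voxels.std() - 1.0) < 1e-6

    def test_constant_volume_returns_zeros_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            out = normalize_zscore(vol(np.full((2, 3, 3), 5.0)))
        assert np.all(out.voxels == 0)
        assert "constant" in caplog.text

    def test_affine_invariance(self, rng):
        x = rng.random((3, 6, 6)) * 40
        a = normalize_zscore(vol(x)).voxels
        b = normalize_zscore(vol(2.5 * x + 13.0)).voxels
        np.testing.assert_allclose(a, b, atol=1e-5)

    def test_non_finite_rejected(self):
        bad = np.ones((2, 3, 3), dtype=np.float32)
        v = ImageVolume(bad, (1, 1, 1), "x")
        object.__setattr__(v, "voxels", bad * np.inf)
        with pytest.raises(ValueError, match="non-finite"):
            normalize_zscore(v)


class TestMinMax:
    def test_volume_defining_formula(self):
        out = normalize_minmax_volume(vol([[[2.0, 4.0, 6.0]]]))
        np.testing.assert_allclose(out.voxels.ravel(), [0.0, 0.5, 1.0], atol=1e-7)

    def test_volume_attains_bounds(self, rng):
        out = normalize_minmax_volume(vol(rng.random((3, 5, 5)) * 9 - 4))
        assert out.voxels.min() == 0.0 and out.voxels.max() == 1.0

    def test_slice_independence(self):
        two = np.stack([np.array([[0.0, 2.0]]), np.array([[5.0, 15.0]])])
        out = normalize_minmax_slice(vol(two))
        np.testing.assert_allclose(out.voxels[:, 0], [[0.0, 1.0], [0.0, 1.0]])

    def test_every_nonconstant_slice_attains_bounds(self, rng):
        out = normalize_minmax_slice(vol(rng.random((4, 6, 6)) * 50))
        assert np.allclose(out.voxels.min(axis=(1, 2)), 0.0)
        assert np.allclose(out.voxels.max(axis=(1, 2)), 1.0)

    def test_single_slice_matches_volume_normalization(self, rng):
        x = rng.random((1, 7, 7)) * 12
        np.testing.assert_allclose(normalize_minmax_slice(vol(x)).voxels,
                                   normalize_minmax_volume(vol(x)).voxels)

    def test_constant_slice_zeroed(self, caplog):
        x = np.stack([np.full((2, 2), 3.0), np.array([[0.0, 1.0], [2.0, 3.0]])])
        with caplog.at_level("WARNING"):
            out = normalize_minmax_slice(vol(x))
        assert np.all(out.voxels[0] == 0)
        assert out.voxels[1].max() == 1.0


class TestNyul:
    percentiles = (1, 25, 50, 75, 99)

    def _training_vol(self, rng, lo=0.0, hi=100.0):
        return vol(rng.gamma(3.0, 7.0, size=(4, 16, 16)) + lo, exam_id="tv")

    def test_identical_training_volumes_give_their_landmarks(self, rng):
        v = self._training_vol(rng)
        scale = nyul_train([v, v, v], self.percentiles, (0.0, 100.0))
        single = nyul_train([v], self.percentiles, (0.0, 100.0))
        np.testing.assert_allclose(scale.standard_values, single.standard_values)

    def test_affine_intensity_change_is_invisible(self, rng):
        x = rng.gamma(3.0, 7.0, size=(4, 16, 16)) + 5.0
        a = nyul_train([vol(x)], self.percentiles, (0.0, 100.0))
        b = nyul_train([vol(3.0 * x + 11.0)], self.percentiles, (0.0, 100.0))
        np.testing.assert_allclose(a.standard_values, b.standard_values, rtol=1e-5)

    def test_standard_values_strictly_increasing(self, rng):
        vols = [self._training_vol(np.random.default_rng(s)) for s in range(5)]
        scale = nyul_train(vols)
        assert np.all(np.diff(scale.standard_values) > 0)

    def test_apply_is_identity_on_matching_landmarks(self, rng):
        v = self._training_vol(rng)
        scale = nyul_train([v], self.percentiles,
                           standard_range=(0.0, 1.0))
        # map the standard range so the anchors coincide with v's landmarks
        from slseg.preprocess import _landmarks

        lm = _landmarks(v.voxels.astype(np.float64), self.percentiles)
        scale = NyulStandardScale(self.percentiles, tuple(lm))
        out = nyul_apply(v, scale)
        np.testing.assert_allclose(out.voxels, v.voxels, atol=1e-4)

    def test_monotone_in_input_intensity(self, rng):
        v = self._training_vol(rng)
        scale = nyul_train([self._training_vol(np.random.default_rng(9))])
        out = nyul_apply(v, scale)
        x = v.voxels.ravel()
        y = out.voxels.ravel()
        order = np.argsort(x, kind="stable")
        assert np.all(np.diff(y[order]) >= -1e-5)

    def test_linear_ramp_two_landmark_exact_affine(self):
        ramp = np.linspace(10.0, 20.0, 256).reshape(1, 16, 16)
        scale = NyulStandardScale((1.0, 99.0), (0.0, 100.0))
        out = nyul_apply(vol(ramp), scale)
        lo, hi = np.percentile(ramp[ramp > ramp[ramp != 0].mean()], [1, 99])
        expected = (ramp - lo) / (hi - lo) * 100.0
        np.testing.assert_allclose(out.voxels, expected, atol=1e-3)

    def test_transformed_landmarks_match_standard_scale(self, rng):
        # the map must send each volume's own landmarks onto the standard
        # values (landmarks evaluated over the same foreground voxel set)
        vols = [vol(np.random.default_rng(s).gamma(3.0, 7.0, (4, 16, 16)))
                for s in range(4)]
        scale = nyul_train(vols)
        srange = scale.standard_values[-1] - scale.standard_values[0]
        for v in vols:
            out = nyul_apply(v, scale)
            x = v.voxels.astype(np.float64)
            fg = x > x[x != 0].mean()
            got = np.percentile(out.voxels[fg], scale.percentiles)
            np.testing.assert_allclose(got, scale.standard_values,
                                       atol=0.01 * srange)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            nyul_train([])

    def test_scale_invariants_enforced(self):
        with pytest.raises(ValueError):
            NyulStandardScale((1, 50, 99), (0.0, 0.0, 100.0))
        with pytest.raises(ValueError):
            NyulStandardScale((1, 99), (0.0, 50.0, 100.0))


class TestBiasCorrect:
    def test_constant_volume_passes_through(self):
        out = bias_correct(vol(np.full((4, 16, 16), 7.0)))
        np.testing.assert_allclose(out.voxels, 7.0, rtol=1e-5)

    def test_output_non_negative(self, rng):
        out = bias_correct(vol(rng.random((4, 16, 16)) * 10 - 2))
        assert out.voxels.min() >= 0.0

    def test_deterministic(self, default_cohort_small):
        img = default_cohort_small[0].image
        a = bias_correct(img)
        b = bias_correct(img)
        np.testing.assert_array_equal(a.voxels, b.voxels)

    def test_all_zero_volume_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            bias_correct(vol(np.zeros((2, 8, 8))))

    def test_restores_known_multiplicative_phantom(self):
        # I = B * T with known smooth B: corrected must track T more closely
        cfg = PhantomConfig(n_exams=5, seed=21, bias_amplitude=0.0,
                            noise_sd=0.02, site_styles=((0.0, 1.0, 1.0),))
        wins = 0
        for i in range(5):
            exam = generate_exam(cfg, i)
            truth = exam.image.voxels.astype(np.float64)
            field = make_bias_field(truth.shape, 1.0, 16.0,
                                    np.random.default_rng(500 + i))
            biased = vol(np.clip(truth, 0.01, None) * field,
                         spacing=exam.image.spacing)
            corrected = bias_correct(biased)
            r_raw = np.corrcoef(biased.voxels.ravel(), truth.ravel())[0, 1]
            r_cor = np.corrcoef(corrected.voxels.ravel(), truth.ravel())[0, 1]
            wins += r_cor > r_raw
        assert wins == 5


class TestApplyPreprocess:
    def test_composition_without_bias_equals_normalization(self, rng):
        exam = make_exam(rng.random((2, 8, 8)) * 30, np.zeros((2, 8, 8)))
        spec = PreprocessSpec("zscore", bias_correct=False)
        out = apply_preprocess(exam, spec)
        np.testing.assert_allclose(
            out.image.voxels, normalize_zscore(exam.image).voxels)

    def test_nyul_without_scale_rejected(self, rng):
        exam = make_exam(rng.random((2, 8, 8)), np.zeros((2, 8, 8)))
        with pytest.raises(ValueError, match="Scale"):
            apply_preprocess(exam, PreprocessSpec("nyul", bias_correct=False))

    def test_mask_untouched(self, default_cohort_small):
        exam = default_cohort_small[0]
        out = apply_preprocess(exam, PreprocessSpec("minmax_slice",
                                                    bias_correct=True))
        np.testing.assert_array_equal(out.mask.voxels, exam.mask.voxels)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown method"):
            PreprocessSpec("histogram_eq")


class TestOrderInvariance:
    """All four normalizations are pure per-intensity maps given their
    statistics: permuting voxels and normalizing commutes with normalizing
    and permuting."""

    @pytest.mark.parametrize("fn", [normalize_zscore, normalize_minmax_volume])
    def test_volume_statistics_maps(self, fn, rng):
        x = rng.random((2, 6, 6)) * 20
        perm = rng.permutation(x.size)
        direct = fn(vol(x)).voxels.ravel()[perm]
        permuted = fn(vol(x.ravel()[perm].reshape(x.shape))).voxels.ravel()
        np.testing.assert_allclose(direct, permuted, atol=1e-6)
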