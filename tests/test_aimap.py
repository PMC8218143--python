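"""SUV computation, asymmetry-index mapping, Z standardization, thresholding
and hypometabolic ROI extraction."""

import numpy as np
import pytest
from scipy import integrate, optimize, special

from petdti.aimap import (AIThreshold, SUVParams, apply_gm_mask, compute_ai,
                          compute_suv, compute_zai, critical_value,
                          extract_roi, normalize_cerebellum)
from petdti.volume import BinaryMask, Volume3D

from conftest import centered_affine


def vol(data, spacing=2.0):
    data = np.asarray(data, dtype=float)
    return Volume3D(data, centered_affine(data.shape, spacing))


class TestSUV:
    def test_direct_formula(self):
        activity = vol(np.full((4, 4, 4), 10_000.0))
        params = SUVParams(body_weight_g=70_000, injected_dose_bq=1.9e8)
        suv = compute_suv(activity, params)
        assert suv.data[0, 0, 0] == pytest.approx(3.684, abs=5e-4)

    def test_zero_activity(self):
        suv = compute_suv(vol(np.zeros((3, 3, 3))),
                          SUVParams(70_000, 1.9e8))
        assert np.all(suv.data == 0)

    def test_dose_linearity(self, rng):
        activity = vol(rng.random((4, 4, 4)) * 1e4)
        s1 = compute_suv(activity, SUVParams(70_000, 1e8))
        s2 = compute_suv(activity, SUVParams(70_000, 2e8))
        np.testing.assert_allclose(s2.data, s1.data / 2.0)

    @pytest.mark.parametrize("kwargs", [
        dict(body_weight_g=0, injected_dose_bq=1e8),
        dict(body_weight_g=70_000, injected_dose_bq=-1.0),
        dict(body_weight_g=70_000, injected_dose_bq=1e8, gm_fraction_threshold=1.2),
    ])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SUVParams(**kwargs)


class TestGMMask:
    def test_boundary_inclusive(self):
        gm = vol(np.array([[[0.29, 0.30, 0.31]]]))
        mask = apply_gm_mask(gm, 0.30)
        assert mask.data.tolist() == [[[False, True, True]]]

    def test_zero_probability_empty(self):
        assert apply_gm_mask(vol(np.zeros((3, 3, 3))), 0.3).count == 0

    def test_zero_threshold_includes_all(self):
        assert apply_gm_mask(vol(np.zeros((3, 3, 3))), 0.0).count == 27

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            apply_gm_mask(vol(np.zeros((2, 2, 2))), 1.5)


class TestCerebellumNormalization:
    def _masks(self, shape):
        gm = BinaryMask(np.ones(shape, dtype=bool), centered_affine(shape))
        cereb = gm.like(np.zeros(shape, dtype=bool))
        cereb.data[0] = True
        return gm, cereb

    def test_uniform_suv_gives_unity(self):
        suv = vol(np.full((4, 4, 4), 5.0))
        gm, cereb = self._masks(suv.shape)
        out = normalize_cerebellum(suv, gm, cereb)
        np.testing.assert_allclose(out.data, 1.0)

    def test_reference_scaling(self):
        suv = vol(np.full((4, 4, 4), 3.0))
        suv.data[0] = 2.0  # reference region mean = 2
        gm, cereb = self._masks(suv.shape)
        out = normalize_cerebellum(suv, gm, cereb)
        assert out.data[1, 0, 0] == pytest.approx(1.5)

    def test_global_scale_invariance(self, rng):
        suv = vol(rng.random((4, 4, 4)) + 0.5)
        gm, cereb = self._masks(suv.shape)
        a = normalize_cerebellum(suv, gm, cereb)
        b = normalize_cerebellum(vol(suv.data * 7.3), gm, cereb)
        np.testing.assert_allclose(a.data, b.data, rtol=1e-12)

    def test_empty_reference_rejected(self):
        suv = vol(np.ones((3, 3, 3)))
        gm = BinaryMask(np.ones(suv.shape, dtype=bool), suv.affine)
        empty = gm.like(np.zeros(suv.shape, dtype=bool))
        with pytest.raises(ValueError, match="empty"):
            normalize_cerebellum(suv, gm, empty)


class TestAI:
    def test_symmetric_template_has_zero_ai(self, rng):
        # cross-module invariant: the symmetrized template of any volume is
        # its own mirror, so its AI map vanishes identically
        from petdti.volume import make_symmetric_template
        raw = vol(rng.random((8, 6, 6)) + 0.5)
        tmpl = make_symmetric_template(raw, 0.0)
        ai = compute_ai(tmpl, 0.0)
        np.testing.assert_allclose(ai.data, 0.0, atol=1e-10)

    def test_symmetric_image_gives_zero(self, rng):
        half = rng.random((4, 6, 6)) + 1.0
        suvr = vol(np.concatenate([half, half[::-1]], axis=0))
        ai = compute_ai(suvr, 0.0)
        np.testing.assert_allclose(ai.data, 0.0, atol=1e-12)

    def test_direct_formula_and_antisymmetry(self):
        # voxel pair (I, fI) = (1.2, 0.8) across the midline
        data = np.ones((8, 4, 4))
        data[1, 2, 2] = 1.2
        data[6, 2, 2] = 0.8  # mirror voxel
        ai = compute_ai(vol(data), 0.0)
        assert ai.data[1, 2, 2] == pytest.approx(10.0)
        assert ai.data[6, 2, 2] == pytest.approx(-10.0)

    def test_antisymmetry_everywhere(self, rng):
        suvr = vol(rng.random((8, 6, 6)) + 0.5)
        ai = compute_ai(suvr, 0.0)
        np.testing.assert_allclose(ai.data, -ai.data[::-1], atol=1e-10)

    def test_zero_denominator_undefined(self):
        data = np.zeros((4, 4, 4))
        ai = compute_ai(vol(data), 0.0)
        assert np.isnan(ai.data).all()

    def test_bounded_for_positive_images(self, rng):
        ai = compute_ai(vol(rng.random((8, 6, 6)) + 1e-3), 0.0)
        assert np.nanmax(np.abs(ai.data)) < 50.0


class TestZAI:
    def test_hand_computed_population_sd(self):
        # AI values {-2, 0, 2} over GM; X = 2 -> Z = 2 / sqrt(8/3) = 1.2247
        ai = vol(np.array([[[-2.0, 0.0, 2.0]]]))
        gm = BinaryMask(np.ones((1, 1, 3), dtype=bool), ai.affine)
        z = compute_zai(ai, gm)
        assert z.data[0, 0, 2] == pytest.approx(1.224745, abs=1e-6)
        assert z.data[0, 0, 0] == pytest.approx(-1.224745, abs=1e-6)

    def test_mean_voxel_maps_to_zero(self, rng):
        ai = vol(rng.normal(size=(5, 5, 5)))
        gm = BinaryMask(np.ones(ai.shape, dtype=bool), ai.affine)
        z = compute_zai(ai, gm)
        assert abs(z.data[gm.data].mean()) < 1e-12
        assert z.data[gm.data].std() == pytest.approx(1.0)

    def test_location_invariance(self, rng):
        ai = vol(rng.normal(size=(5, 5, 5)))
        gm = BinaryMask(np.ones(ai.shape, dtype=bool), ai.affine)
        z1 = compute_zai(ai, gm)
        z2 = compute_zai(vol(ai.data + 3.7), gm)
        np.testing.assert_allclose(z1.data, z2.data, atol=1e-10)

    def test_zero_sd_rejected(self):
        ai = vol(np.ones((3, 3, 3)))
        gm = BinaryMask(np.ones(ai.shape, dtype=bool), ai.affine)
        with pytest.raises(ValueError, match="standard deviation"):
            compute_zai(ai, gm)


def _t_quantile_oracle(alpha, df):
    """Lower-tail t quantile by numerical integration of the density
    (independent of scipy.stats.t)."""
    const = (special.gamma((df + 1) / 2)
             / (np.sqrt(df * np.pi) * special.gamma(df / 2)))

    def pdf(x):
        return const * (1 + x ** 2 / df) ** (-(df + 1) / 2)

    def cdf(x):
        val, _ = integrate.quad(pdf, -np.inf, x)
        return val

    return optimize.brentq(lambda x: cdf(x) - alpha, -1e3, 0.0, xtol=1e-10)


class TestCriticalValue:
    def test_cohort_of_14_reproduces_printed_threshold(self):
        thr = AIThreshold(n_subjects=14, alpha=0.05)
        assert thr.df == 13
        assert round(critical_value(thr), 2) == -1.77

    def test_normal_limit(self):
        z = critical_value(AIThreshold(n_subjects=100_001, alpha=0.05))
        assert z == pytest.approx(-1.645, abs=5e-4)

    def test_single_df(self):
        assert round(critical_value(AIThreshold(n_subjects=2, alpha=0.05)), 2) == -6.31

    @pytest.mark.parametrize("df", [1, 2, 5, 13, 50, 200])
    def test_matches_numerical_integration_oracle(self, df):
        got = critical_value(AIThreshold(n_subjects=df + 1, alpha=0.05))
        assert got == pytest.approx(_t_quantile_oracle(0.05, df), abs=1e-4)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            AIThreshold(n_subjects=1)
        with pytest.raises(ValueError):
            AIThreshold(n_subjects=14, alpha=0.7)


class TestExtractROI:
    def _zai_with_clusters(self):
        shape = (16, 12, 12)
        z = np.zeros(shape)
        gm = np.ones(shape, dtype=bool)
        z[2:7, 2:4, 2:6] = -3.0     # 40-voxel cluster, left hemisphere
        z[12:14, 8:10, 8:11] = -3.0  # 12-voxel cluster
        return (Volume3D(z, centered_affine(shape)),
                BinaryMask(gm, centered_affine(shape)))

    def test_largest_cluster_wins(self):
        zai, gm = self._zai_with_clusters()
        roi = extract_roi(zai, gm, -1.77, min_cluster_mm3=8.0)
        assert roi.voxel_count == 40
        assert roi.hemisphere == "left"
        assert roi.secondary_cluster_sizes[0] == 12

    def test_no_suprathreshold_voxels(self):
        zai, gm = self._zai_with_clusters()
        roi = extract_roi(Volume3D(np.zeros(zai.shape), zai.affine), gm, -1.77)
        assert roi.empty
        assert roi.summary()["status"] == "no significant hypometabolism"

    def test_focality_criterion_filters_small_clusters(self):
        zai, gm = self._zai_with_clusters()
        # both clusters are below 80 voxels; require an absurdly large focus
        roi = extract_roi(zai, gm, -1.77, min_cluster_mm3=50 * 8.0)
        assert roi.empty

    def test_positive_critical_z_rejected(self):
        zai, gm = self._zai_with_clusters()
        with pytest.raises(ValueError):
            extract_roi(zai, gm, 1.77)
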