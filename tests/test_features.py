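"""Feature extractors against brute-force oracles and closed-form cases."""

import numpy as np
import pandas as pd
import pytest

import _oracles as oracle
from subtyperad.features import (
    FEATURE_SCHEMA,
    RETAINED_LBP_BINS,
    drop_invalid_columns,
    extract_all,
    glcm_features,
    kinetic_pixelwise,
    kinetic_whole,
    lbp_code,
    lbp_histogram,
    morphology_features,
    stats_features,
)
from subtyperad.features import _direction_glcm, _glcm_stats
from subtyperad.phantom import ShapeProfile, generate_lesion_shape


class TestSchema:
    def test_schema_has_146_unique_ordered_labels(self):
        assert len(FEATURE_SCHEMA) == 146
        assert len(set(FEATURE_SCHEMA)) == 146
        assert FEATURE_SCHEMA[0] == "F1"
        assert FEATURE_SCHEMA[15] == "F16_1"
        assert FEATURE_SCHEMA[-1] == "M7"
        assert len(RETAINED_LBP_BINS) == 31

    def test_extract_all_emits_full_finite_vector(self, phantom_case):
        vec = extract_all(phantom_case.phases, phantom_case.truth_mask)
        assert list(vec.index) == list(FEATURE_SCHEMA)
        assert np.isfinite(vec.to_numpy()).all()

    def test_extract_all_deterministic(self, phantom_case):
        a = extract_all(phantom_case.phases, phantom_case.truth_mask)
        b = extract_all(phantom_case.phases, phantom_case.truth_mask)
        assert a.equals(b)

    def test_enhancement_absorption_consistency(self, phantom_case):
        vec = extract_all(phantom_case.phases, phantom_case.truth_mask)
        assert vec["T11"] == pytest.approx((vec["T10"] - 1) * 100, abs=1e-12)
        assert vec["T13"] == pytest.approx((vec["T12"] - 1) * 100, abs=1e-12)

    def test_translation_invariance_of_texture_and_stats(self, phantom_case):
        phases = phantom_case.phases
        mask = phantom_case.truth_mask
        shifted_phases = np.roll(phases, (5, -7), axis=(1, 2))
        shifted_mask = np.roll(mask, (5, -7), axis=(0, 1))
        a = extract_all(phases, mask)
        b = extract_all(shifted_phases, shifted_mask)
        texture_stats = [l for l in FEATURE_SCHEMA if not l.startswith("M")]
        assert np.allclose(a[texture_stats], b[texture_stats])
        # morphology invariant too (same mask, just translated)
        assert np.allclose(a[[f"M{i}" for i in range(1, 8)]],
                           b[[f"M{i}" for i in range(1, 8)]])


class TestGLCM:
    def test_constant_lesion_degeneracy(self):
        image = np.full((6, 6), 37.0)
        mask = np.ones((6, 6), bool)
        energy, contrast, corr, entropy, deficit = glcm_features(image, mask)
        assert (energy, contrast, corr, entropy, deficit) == (1.0, 0.0, 0.0, 0.0, 1.0)

    def test_checkerboard_direction_zero(self):
        levels = 16
        image = np.indices((6, 6)).sum(axis=0) % 2 * 255.0
        mask = np.ones((6, 6), bool)
        q = np.where(image > 0, levels - 1, 0)
        P = _direction_glcm(q, mask, 0, 1, levels)
        energy, contrast, *_ = _glcm_stats(P)
        assert contrast == pytest.approx((levels - 1) ** 2)
        assert energy == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_pair_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        image, mask = oracle.random_lesion(rng, max_side=8)
        got = glcm_features(image, mask)
        want = oracle.glcm_averaged(image, mask)
        assert np.allclose(got, want, atol=1e-10)

    def test_probabilities_and_ranges(self, phantom_case):
        energy, contrast, corr, entropy, deficit = glcm_features(
            phantom_case.phases[1], phantom_case.truth_mask
        )
        assert 0 < energy <= 1
        assert entropy >= 0
        assert 0 < deficit <= 1
        assert -1 <= corr <= 1


class TestLBP:
    def test_flat_neighbourhood_codes_255(self):
        assert lbp_code(5, [5] * 8) == 255

    def test_dominant_center_codes_0(self):
        assert lbp_code(9, [1, 2, 3, 4, 5, 6, 7, 8]) == 0

    def test_two_set_bits(self):
        assert lbp_code(5, (6, 4, 4, 4, 4, 4, 4, 6)) == 129

    def test_uniform_lesion_all_mass_at_255(self):
        image = np.full((8, 8), 50.0)
        mask = np.zeros((8, 8), bool)
        mask[2:6, 2:6] = True
        hist = lbp_histogram(image, mask)
        assert hist[list(RETAINED_LBP_BINS).index(255)] == 1.0
        assert hist.sum() == 1.0

    def test_border_only_mask_warns_and_zeroes(self):
        image = np.arange(25.0).reshape(5, 5)
        mask = np.zeros((5, 5), bool)
        mask[0, 2] = True
        with pytest.warns(UserWarning):
            hist = lbp_histogram(image, mask)
        assert not hist.any()

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_per_pixel_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        image, mask = oracle.random_lesion(rng)
        got = lbp_histogram(image, mask)
        rows, cols = image.shape
        interior = mask.copy()
        interior[0, :] = interior[-1, :] = interior[:, 0] = interior[:, -1] = False
        if not interior.any():
            return
        want = oracle.lbp_retained_hist(image, mask)
        assert np.allclose(got, want)


class TestKinetics:
    def test_null_enhancement(self):
        assert kinetic_whole(100, 100, 100) == (1.0, 0.0, 1.0, 0.0)

    def test_direct_arithmetic(self):
        er1, ar1, er2, ar2 = kinetic_whole(100, 180, 150)
        assert (er1, ar1) == (1.8, 80.0)
        assert (er2, ar2) == (1.5, 50.0)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            kinetic_whole(0, 10, 10)

    def test_identical_phases_zero_rates(self):
        img = np.random.default_rng(0).integers(1, 255, (6, 6)).astype(float)
        mask = np.ones((6, 6), bool)
        assert kinetic_pixelwise(img, img, mask) == (0.0, 0.0, 0.0)

    def test_single_pixel_rate(self):
        a = np.array([[75.0]])
        b = np.array([[50.0]])
        mask = np.ones((1, 1), bool)
        assert kinetic_pixelwise(a, b, mask) == (0.0, 0.5, 0.5)

    def test_zero_reference_pixels_excluded(self):
        a = np.array([[10.0, 20.0]])
        b = np.array([[0.0, 10.0]])
        mask = np.ones((1, 2), bool)
        std, mean, mx = kinetic_pixelwise(a, b, mask)
        assert (std, mean, mx) == (0.0, 1.0, 1.0)

    def test_all_zero_reference_raises(self):
        mask = np.ones((2, 2), bool)
        with pytest.raises(ValueError):
            kinetic_pixelwise(np.ones((2, 2)), np.zeros((2, 2)), mask)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_pixel_oracle(self, seed):
        rng = np.random.default_rng(200 + seed)
        a, mask = oracle.random_lesion(rng)
        b = rng.integers(0, 256, a.shape).astype(float)
        got = kinetic_pixelwise(a, b, mask)
        want = oracle.pixelwise_rate_stats(a, b, mask)
        assert np.allclose(got, want)


class TestStats:
    def test_constant_region_conventions(self):
        image = np.full((5, 5), 42.0)
        mask = np.ones((5, 5), bool)
        assert stats_features(image, mask) == (42.0, 0.0, 0.0, 42.0, 0.0, 0.0)

    def test_symmetric_two_level(self):
        image = np.array([[0.0, 100.0]] * 4)
        mask = np.ones((4, 2), bool)
        mean, std, entropy, mx, bias, peak = stats_features(image, mask)
        assert (mean, std, entropy, mx, bias) == (50.0, 50.0, 1.0, 100.0, 0.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_moment_oracle(self, seed):
        rng = np.random.default_rng(300 + seed)
        image, mask = oracle.random_lesion(rng)
        got = stats_features(image, mask)
        want = oracle.first_order_stats(image, mask)
        assert np.allclose(got, want)

    def test_skew_kurtosis_match_scipy(self):
        from scipy import stats as sps

        rng = np.random.default_rng(4)
        image = rng.integers(0, 256, (9, 9)).astype(float)
        mask = rng.random((9, 9)) < 0.7
        _, _, _, _, bias, peak = stats_features(image, mask)
        vals = image[mask]
        assert bias == pytest.approx(sps.skew(vals))
        assert peak == pytest.approx(sps.kurtosis(vals))


class TestMorphology:
    def test_disk_is_round_and_smooth(self):
        rr, cc = np.mgrid[0:64, 0:64]
        mask = (rr - 32) ** 2 + (cc - 32) ** 2 <= 20**2
        m1, m2, m3, m4, m5, m6, m7 = morphology_features(mask)
        assert 0.9 <= m6 <= 1.1
        assert m2 <= 0.05
        assert m4 <= 0.02
        assert m3 >= 1.0 / 1.1          # tightness ~ 1/roundness

    def test_square_area_is_side_squared(self):
        mask = np.zeros((20, 20), bool)
        mask[4:14, 4:14] = True
        assert morphology_features(mask)[6] == 100.0

    def test_perturbed_blob_is_rougher_than_base(self):
        base = generate_lesion_shape(ShapeProfile(16, 0.0), np.random.default_rng(5))
        pert = generate_lesion_shape(ShapeProfile(16, 0.25, 5), np.random.default_rng(5))
        assert morphology_features(pert)[3] > morphology_features(base)[3]

    def test_tiny_boundary_rejected(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        with pytest.raises(ValueError):
            morphology_features(mask)


class TestDropInvalidColumns:
    def test_all_zero_column_removed(self):
        t = pd.DataFrame({"a": [1.0, 2.0], "b": [0.0, 0.0], "label": ["A", "B"]})
        out = drop_invalid_columns(t)
        assert list(out.columns) == ["a", "label"]

    def test_no_zero_column_identity(self):
        t = pd.DataFrame({"a": [1.0, 0.0], "b": [0.0, 2.0]})
        assert drop_invalid_columns(t).equals(t)

    def test_removal_matches_column_scan(self, phantom_case):
        vec = extract_all(phantom_case.phases, phantom_case.truth_mask)
        table = pd.DataFrame([vec.to_dict(), vec.to_dict()])
        expected = [c for c in table.columns if (table[c] == 0).all()]
        out = drop_invalid_columns(table)
        assert sorted(set(table.columns) - set(out.columns)) == sorted(expected)
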