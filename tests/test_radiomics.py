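"""Quantization, texture matrices, feature maps, and oracle equivalence."""

import numpy as np
import pytest

from dcesom.radiomics import (
    DIRECTIONS,
    compute_feature_maps,
    load_registry,
    normalize_series,
    quantize_fbn,
    window_features,
)
from dcesom.radiomics.features import glcm_compact, glcm_features, glcm_matrix
from dcesom.radiomics.registry import EXPECTED_COUNTS

from radiomics_oracle import oracle_all_features


class TestNormalizeSeries:
    def test_unit_tail_mean_leaves_profiles_unchanged(self):
        rng = np.random.default_rng(0)
        e1 = rng.uniform(0.5, 1.5, (4, 4, 1, 30))
        e1[..., -10:] = 1.0
        e2 = rng.uniform(0.5, 1.5, (4, 4, 1, 30))
        mask = np.ones((4, 4, 1), bool)
        n1, n2, valid = normalize_series(e1, e2, mask)
        np.testing.assert_allclose(n1, e1)
        np.testing.assert_allclose(n2, e2)
        assert valid.all()

    def test_first_echo_tail_mean_is_one_after_normalization(self):
        rng = np.random.default_rng(1)
        e1 = rng.uniform(1, 5, (5, 5, 1, 40))
        e2 = rng.uniform(1, 5, (5, 5, 1, 40))
        n1, _n2, _ = normalize_series(e1, e2, np.ones((5, 5, 1), bool))
        np.testing.assert_allclose(n1[..., -10:].mean(axis=-1), 1.0)

    def test_second_echo_divided_by_first_echo_factor(self):
        # echo2 tail is twice echo1's: after normalization its tail mean is 2
        e1 = np.full((2, 2, 1, 20), 3.0)
        e2 = np.full((2, 2, 1, 20), 6.0)
        _n1, n2, _ = normalize_series(e1, e2, np.ones((2, 2, 1), bool))
        np.testing.assert_allclose(n2[..., -10:].mean(axis=-1), 2.0)

    def test_nonpositive_tail_flags_voxel(self):
        e1 = np.full((2, 1, 1, 20), 1.0)
        e1[0] = -1.0
        _n1, _n2, valid = normalize_series(e1, e1.copy(), np.ones((2, 1, 1), bool))
        assert not valid[0, 0, 0] and valid[1, 0, 0]


class TestQuantizeFBN:
    def test_three_values_four_bins_example(self):
        img = np.array([[0.0, 0.5, 1.0]])
        q = quantize_fbn(img, 4, np.ones_like(img, bool))
        np.testing.assert_array_equal(q, [[1, 3, 4]])

    def test_constant_image_maps_to_level_one(self):
        img = np.full((3, 3), 2.5)
        q = quantize_fbn(img, 128, np.ones_like(img, bool))
        assert (q == 1).all()

    def test_random_input_stays_within_levels(self):
        rng = np.random.default_rng(2)
        img = rng.normal(size=(16, 16))
        q = quantize_fbn(img, 128, np.ones_like(img, bool))
        assert q.min() >= 1 and q.max() <= 128


class TestTextureMatrices:
    def test_toy_pair_matrix_and_dissimilarity(self):
        # rows [1,2;1,2]: horizontal pairs are always (1,2)
        patch = np.array([[1, 2], [1, 2]])
        p = glcm_matrix(patch, (0, 1), 2)
        assert p[0, 1] == pytest.approx(0.5)
        assert p[1, 0] == pytest.approx(0.5)
        lv, pc = glcm_compact(patch, (0, 1))
        feats = glcm_features(lv, pc, 2)
        assert feats["glcm_dissimilarity"] == pytest.approx(1.0)

    def test_constant_patch_mass_on_diagonal_zero_dissimilarity(self):
        patch = np.full((5, 5), 3)
        for d in DIRECTIONS:
            p = glcm_matrix(patch, d, 8)
            assert p[2, 2] == pytest.approx(1.0)
        feats = window_features(patch, patch.astype(float), 8)
        assert feats["glcm_dissimilarity"] == 0.0
        assert feats["ibs_variance"] == 0.0

    def test_matrices_normalize_to_unit_mass(self):
        rng = np.random.default_rng(3)
        patch = rng.integers(1, 9, (5, 5))
        for d in DIRECTIONS:
            assert glcm_matrix(patch, d, 8).sum() == pytest.approx(1.0)


class TestRegistry:
    def test_category_counts_match_design(self):
        registry = load_registry()
        assert len(registry) == 133
        counts = {}
        for spec in registry:
            counts[spec.category] = counts.get(spec.category, 0) + 1
        assert counts == EXPECTED_COUNTS

    def test_window_features_covers_exactly_the_registry(self):
        rng = np.random.default_rng(4)
        feats = window_features(rng.integers(1, 9, (5, 5)), rng.uniform(0, 1, (5, 5)), 8)
        assert set(feats) == {spec.feature_id for spec in load_registry()}


@pytest.mark.parametrize("case", range(8))
def test_all_133_features_match_brute_force_oracle(case):
    """Every feature equals the straight-from-definition oracle to 1e-9."""
    rng = np.random.default_rng(100 + case)
    if case < 4:
        ng = [8, 128, 128, 16][case]
        hi = [8, 128, 10, 16][case]
        win = rng.integers(1, hi + 1, (5, 5))
    elif case == 4:
        ng, win = 128, np.full((5, 5), 17)  # constant window
    elif case == 5:
        ng = 16
        win = np.full((5, 5), 3)
        win[2, 2] = 9  # single outlier zone
    elif case == 6:
        ng = 4
        win = np.tile([[1, 2], [2, 1]], (3, 3))[:5, :5]  # checkerboard
    else:
        ng = 128
        win = np.sort(rng.integers(1, 129, (5, 5)), axis=None).reshape(5, 5)
    raw = rng.uniform(0.2, 1.8, (5, 5))
    impl = window_features(win, raw, ng)
    orac = oracle_all_features(win.tolist(), raw.tolist(), ng)
    assert set(impl) == set(orac)
    for key in impl:
        assert impl[key] == pytest.approx(orac[key], rel=1e-9, abs=1e-9), key


class TestFeatureMaps:
    def test_translation_invariance_of_feature_maps(self):
        rng = np.random.default_rng(5)
        img = rng.uniform(0, 1, (14, 14, 1, 2))
        mask = np.zeros((14, 14, 1), bool)
        mask[1:11, 1:11, 0] = True
        ids = ["glcm_dissimilarity", "ih_entropy"]
        a = compute_feature_maps(img, mask, ids, ng=16)
        img_s = np.roll(img, (2, 3), axis=(0, 1))
        mask_s = np.roll(mask, (2, 3), axis=(0, 1))
        b = compute_feature_maps(img_s, mask_s, ids, ng=16)
        for fid in ids:
            np.testing.assert_allclose(
                np.roll(a.maps[fid], (2, 3), axis=(0, 1)), b.maps[fid], atol=1e-12
            )

    def test_maps_reproducible_bit_identically(self):
        rng = np.random.default_rng(6)
        img = rng.uniform(0, 1, (12, 12, 1, 3))
        mask = np.ones((12, 12, 1), bool)
        a = compute_feature_maps(img, mask, ["ngtdm_contrast"], ng=16)
        b = compute_feature_maps(img, mask, ["ngtdm_contrast"], ng=16)
        np.testing.assert_array_equal(a.maps["ngtdm_contrast"], b.maps["ngtdm_contrast"])

    def test_percentage_features_stay_in_analytic_range(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            win = rng.integers(1, 17, (5, 5))
            feats = window_features(win, win.astype(float), 16)
            assert 0 < feats["glrlm_percentage"] <= 1
            assert 0 < feats["glszm_percentage"] <= 1
            assert feats["ngldm_dependence_count_percentage"] == pytest.approx(1.0)

    def test_only_full_window_centers_are_valid(self):
        mask = np.zeros((9, 9, 1), bool)
        mask[1:8, 1:8, 0] = True  # 7x7 region -> 3x3 valid centers
        img = np.random.default_rng(8).uniform(0, 1, (9, 9, 1, 1))
        stack = compute_feature_maps(img, mask, ["ih_mean"], ng=8)
        assert stack.valid.sum() == 9
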