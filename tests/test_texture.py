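"""Texture features against brute-force oracles and closed forms."""

import numpy as np
import pandas as pd
import pytest

from ostex.image_roi import InputError, QuantizedROI, quantize
from ostex.texture import (
    DEFAULT_REGISTRY,
    GLCM_FEATURES,
    TextureConfig,
    aggregate_feature,
    aggregate_slices,
    analysis_matrix,
    build_feature_table,
    compute_glcm,
    compute_rlm,
    distribution_moments,
    glcm_features,
    gradient_features,
    histogram_features,
    rlm_features,
    roi_feature_vector,
)
from oracles import (
    glcm_counts_oracle,
    gradient_oracle,
    haralick_oracle,
    moments_oracle,
    quantize_oracle,
    rlm_features_oracle,
    rlm_runs_oracle,
)

DIRECTIONS = (0, 45, 90, 135)


def qroi_from_grid(grid, mask, bits=3):
    return QuantizedROI(grid=np.where(mask, grid, 0).astype(np.int16),
                        mask=mask.astype(bool), bits=bits)


def checkerboard(n=4):
    """Two-level checkerboard as a 1-bit quantized ROI (levels 1, 2)."""
    grid = (np.indices((n, n)).sum(axis=0) % 2) + 1
    return qroi_from_grid(grid, np.ones((n, n), bool), bits=1)


class TestHistogram:
    def test_two_point_symmetric(self):
        m, deg = distribution_moments([1, 1, 3, 3])
        assert m == {"mean": 2.0, "variance": 1.0, "skewness": 0.0, "kurtosis": -2.0}
        assert not deg

    def test_constant_flags_degenerate(self):
        m, deg = distribution_moments(np.full(10, 5.0))
        assert deg and m["variance"] == 0.0 and m["skewness"] == 0.0

    def test_skewed_sample_matches_direct_summation(self, rng):
        x = rng.choice([0.0, 1.0, 5.0], size=1000, p=[0.6, 0.3, 0.1])
        m, _ = distribution_moments(x)
        expected = moments_oracle(list(x))
        for k, v in expected.items():
            assert m[k] == pytest.approx(v, abs=1e-12)

    def test_minmax_normalization_rescales_mean(self, rng):
        img = rng.random((10, 10)) * 100 + 50
        mask = np.ones((10, 10), bool)
        m_norm, _ = histogram_features(img, mask, normalize="minmax")
        m_raw, _ = histogram_features(img, mask, normalize="none")
        assert 0.0 <= m_norm["mean"] <= 1.0
        assert m_raw["skewness"] == pytest.approx(m_norm["skewness"], abs=1e-9)


class TestGradient:
    def test_constant_image_zero_gradient(self):
        img = np.full((10, 10), 3.0)
        feats, deg = gradient_features(img, np.ones((10, 10), bool))
        assert feats["gr_mean"] == 0.0 and feats["gr_nonzeros"] == 0.0
        assert deg

    def test_two_band_image_hand_enumeration(self):
        # levels a|b split down the middle: interior pixels at one column on
        # either side of the boundary see |a-b| via the horizontal difference
        img = np.zeros((8, 8))
        img[:, 4:] = 15.0
        mask = np.ones((8, 8), bool)
        feats, _ = gradient_features(img, mask, bits=4)
        grads = gradient_oracle(quantize(img, mask, 4).grid, mask)
        boundary = [g for g in grads if g > 0]
        assert all(g == 15.0 for g in boundary)  # quantized levels 1 and 16
        assert feats["gr_nonzeros"] == pytest.approx(len(boundary) / len(grads))
        assert feats["gr_mean"] == pytest.approx(np.mean(grads), abs=1e-12)

    def test_random_roi_matches_per_pixel_oracle(self, rng):
        img = rng.random((8, 8)) * 200
        mask = rng.random((8, 8)) < 0.9
        mask[2:6, 2:6] = True
        feats, _ = gradient_features(img, mask, bits=4)
        grads = gradient_oracle(quantize(img, mask, 4).grid, mask)
        expected = moments_oracle(grads)
        assert feats["gr_mean"] == pytest.approx(expected["mean"], abs=1e-10)
        assert feats["gr_variance"] == pytest.approx(expected["variance"], abs=1e-10)
        assert feats["gr_skewness"] == pytest.approx(expected["skewness"], abs=1e-10)
        assert feats["gr_kurtosis"] == pytest.approx(expected["kurtosis"], abs=1e-10)
        assert feats["gr_nonzeros"] == pytest.approx(
            np.mean([g > 0 for g in grads]), abs=1e-12
        )

    def test_too_thin_roi_raises(self):
        mask = np.zeros((10, 10), bool)
        mask[5, :] = True  # one-pixel-thick line has no interior
        with pytest.raises(InputError, match="too thin"):
            gradient_features(np.random.default_rng(0).random((10, 10)), mask)


class TestGLCM:
    def test_constant_roi_single_diagonal_cell(self):
        q = qroi_from_grid(np.full((4, 4), 3), np.ones((4, 4), bool))
        g = compute_glcm(q, 0, 1)
        assert g.probabilities[2, 2] == 1.0
        f = glcm_features(g)
        assert f["asm"] == 1.0 and f["contrast"] == 0.0
        assert f["entropy"] == 0.0 and f["inverse_difference_moment"] == 1.0

    def test_checkerboard_cross_level_pairs_only(self):
        g = compute_glcm(checkerboard(), 0, 1)
        P = g.probabilities
        assert P[0, 1] == 0.5 and P[1, 0] == 0.5 and P[0, 0] == 0.0
        f = glcm_features(g)
        assert f["contrast"] == pytest.approx(1.0)
        assert f["asm"] == pytest.approx(0.5)
        assert f["entropy"] == pytest.approx(np.log(2))

    @pytest.mark.parametrize("direction", DIRECTIONS)
    @pytest.mark.parametrize("offset", [1, 2, 3])
    def test_random_masked_counts_equal_pair_enumeration(
        self, direction, offset, random_masked_roi
    ):
        grid, mask = random_masked_roi(size=6, levels=5)
        q = qroi_from_grid(grid, mask)
        got = compute_glcm(q, direction, offset).counts
        expected = glcm_counts_oracle(grid, mask, direction, offset, q.n_levels)
        np.testing.assert_array_equal(got, expected)

    def test_probabilities_sum_to_one_and_symmetric(self, random_masked_roi):
        grid, mask = random_masked_roi(size=9, levels=7)
        q = qroi_from_grid(grid, mask)
        for d in DIRECTIONS:
            P = compute_glcm(q, d, 1).probabilities
            assert P.sum() == pytest.approx(1.0, abs=1e-12)
            np.testing.assert_allclose(P, P.T)

    def test_features_match_direct_summation(self, rng):
        counts = rng.integers(0, 20, size=(8, 8))
        counts = counts + counts.T  # symmetric, as produced by accumulation
        P = counts / counts.sum()
        q = qroi_from_grid(np.ones((4, 4), int), np.ones((4, 4), bool))
        from ostex.texture import glcm_features_stack

        feats, _ = glcm_features_stack(P[None])
        expected = haralick_oracle(P)
        for name in GLCM_FEATURES:
            assert feats[name][0] == pytest.approx(expected[name], abs=1e-12), name

    def test_agrees_with_skimage_on_full_mask(self, rng):
        """On an unmasked image our masked accumulation must reduce to
        skimage's graycomatrix (symmetric, unnormalized)."""
        from skimage.feature import graycomatrix

        levels = rng.integers(0, 8, size=(12, 12)).astype(np.uint8)
        q = qroi_from_grid(levels + 1, np.ones((12, 12), bool))
        for direction, angle in ((0, 0.0), (90, np.pi / 2)):
            for offset in (1, 2):
                ours = compute_glcm(q, direction, offset).counts
                ref = graycomatrix(levels, [offset], [angle], levels=8,
                                   symmetric=True)[:, :, 0, 0]
                np.testing.assert_array_equal(ours, ref)

    def test_degenerate_correlation_reported_zero(self):
        q = qroi_from_grid(np.full((4, 4), 2), np.ones((4, 4), bool))
        f = glcm_features(compute_glcm(q, 0, 1))
        assert f["correlation"] == 0.0


class TestRLM:
    def test_constant_grid_horizontal(self):
        q = qroi_from_grid(np.full((4, 4), 2), np.ones((4, 4), bool))
        rlm = compute_rlm(q, 0)
        assert rlm.total_runs == 4
        f = rlm_features(rlm)
        assert f["short_run_emphasis"] == pytest.approx(1 / 16)
        assert f["long_run_emphasis"] == pytest.approx(16.0)
        assert f["fraction_in_runs"] == pytest.approx(0.25)
        assert f["grey_level_nonuniformity"] == pytest.approx(4.0)
        assert f["run_length_nonuniformity"] == pytest.approx(4.0)

    def test_checkerboard_all_runs_length_one(self):
        f = rlm_features(compute_rlm(checkerboard(), 0))
        assert f["short_run_emphasis"] == 1.0
        assert f["long_run_emphasis"] == 1.0
        assert f["fraction_in_runs"] == 1.0

    @pytest.mark.parametrize("direction", DIRECTIONS)
    def test_masked_hole_splits_runs_like_scanline_oracle(self, direction):
        grid = np.array(
            [[1, 1, 1, 2, 2],
             [1, 1, 2, 2, 2],
             [3, 1, 1, 1, 1],
             [3, 3, 2, 1, 1],
             [1, 2, 2, 2, 1]]
        )
        mask = np.ones((5, 5), bool)
        mask[1:3, 2] = False  # hole
        q = qroi_from_grid(grid, mask)
        got = rlm_features(compute_rlm(q, direction))
        runs = rlm_runs_oracle(grid, mask, direction)
        expected = rlm_features_oracle(runs, int(mask.sum()))
        for k, v in expected.items():
            assert got[k] == pytest.approx(v, abs=1e-12), k

    @pytest.mark.parametrize("direction", DIRECTIONS)
    def test_pixel_conservation(self, direction, random_masked_roi):
        """Every in-mask pixel belongs to exactly one maximal run."""
        grid, mask = random_masked_roi(size=10, levels=4)
        q = qroi_from_grid(grid, mask)
        rlm = compute_rlm(q, direction)
        r = np.arange(1, rlm.counts.shape[1] + 1)
        assert (rlm.counts * r).sum() == mask.sum()


class TestOracleEquivalenceSweep:
    def test_all_feature_classes_match_oracles_on_random_instances(self):
        """Feature classes vs exhaustive oracles across random masked grids."""
        rng = np.random.default_rng(77)
        for trial in range(25):
            size = int(rng.integers(5, 11))
            levels = int(rng.integers(2, 9))
            grid = rng.integers(1, levels + 1, size=(size, size))
            mask = rng.random((size, size)) < 0.8
            if mask.sum() < 4:
                continue
            q = qroi_from_grid(grid, mask, bits=3)
            for d in DIRECTIONS:
                got = rlm_features(compute_rlm(q, d))
                exp = rlm_features_oracle(
                    rlm_runs_oracle(grid, mask, d), int(mask.sum())
                )
                for k in exp:
                    assert got[k] == pytest.approx(exp[k], abs=1e-10)
                offset = int(rng.integers(1, 4))
                glcm = compute_glcm(q, d, offset)
                np.testing.assert_array_equal(
                    glcm.counts,
                    glcm_counts_oracle(grid, mask, d, offset, q.n_levels),
                )
                if glcm.counts.sum() > 0:
                    gotf = glcm_features(glcm)
                    expf = haralick_oracle(glcm.probabilities)
                    for k in expf:
                        assert gotf[k] == pytest.approx(expf[k], abs=1e-10)


class TestAggregation:
    def test_identical_configs_mean_is_identity(self):
        assert aggregate_feature([0.4] * 20) == pytest.approx(0.4)

    def test_four_direction_mean(self):
        assert aggregate_feature([1, 2, 3, 4]) == pytest.approx(2.5)

    def test_skipped_config_excluded_from_mean(self):
        values = [float(i) for i in range(1, 20)] + [np.nan]
        assert aggregate_feature(values) == pytest.approx(np.mean(range(1, 20)))

    def test_no_valid_configs_raises(self):
        with pytest.raises(InputError):
            aggregate_feature([np.nan, np.nan])

    def test_slice_mean_and_completeness_flag(self):
        full = [{"a": 0.0}, {"a": 0.0}, {"a": 0.0}, {"a": 0.0}, {"a": 5.0}]
        agg, complete = aggregate_slices(full)
        assert agg["a"] == pytest.approx(1.0) and complete
        partial = [{"a": 1.0, "b": 2.0}, {"a": 3.0}]
        agg, complete = aggregate_slices(partial)
        assert agg == {"a": 2.0, "b": 2.0} and not complete


class TestInvariances:
    def test_transposition_invariance_with_averaged_directions(self, rng):
        """The 4-direction set is closed under transposition, so averaged
        RLM/GLCM features must be unchanged when the image is transposed."""
        img = rng.random((20, 20)) * 300
        mask = rng.random((20, 20)) < 0.9
        mask[4:16, 4:16] = True
        cfg = TextureConfig()
        f1 = roi_feature_vector(img, mask, cfg)
        f2 = roi_feature_vector(img.T, mask.T, cfg)
        for k in f1:
            assert f1[k] == pytest.approx(f2[k], rel=1e-9), k

    def test_affine_intensity_invariance_of_features(self, rng):
        img = rng.random((20, 20)) * 120 + 30
        mask = np.ones((20, 20), bool)
        f1 = roi_feature_vector(img, mask)
        f2 = roi_feature_vector(2.7 * img + 11.0, mask)
        for k in f1:
            assert f1[k] == pytest.approx(f2[k], rel=1e-9), k

    def test_entropy_rises_and_organization_falls_with_finer_texture(self):
        """Shorter correlation length => higher GLCM entropy, lower ASM and
        long-run emphasis (rank correlation across seeds)."""
        from scipy.stats import wilcoxon

        from ostex.synthetic import TextureParams, make_trabecular_slice

        fine, coarse = [], []
        for seed in range(50):
            rows = {}
            for ell, store in ((2.0, fine), (8.0, coarse)):
                tp = TextureParams(image_size=64, slice_count=1, roi_depth_px=10,
                                   correlation_length=ell, noise_sigma=0.0)
                img, masks = make_trabecular_slice(tp, seed)
                feats = roi_feature_vector(img.pixels, masks["medial_tibia"].mask)
                store.append(feats)
        ent_f = np.array([f["entropy"] for f in fine])
        ent_c = np.array([f["entropy"] for f in coarse])
        asm_f = np.array([f["asm"] for f in fine])
        asm_c = np.array([f["asm"] for f in coarse])
        lre_f = np.array([f["long_run_emphasis"] for f in fine])
        lre_c = np.array([f["long_run_emphasis"] for f in coarse])
        assert wilcoxon(ent_f - ent_c, alternative="greater").pvalue < 0.01
        assert wilcoxon(asm_c - asm_f, alternative="greater").pvalue < 0.01
        assert wilcoxon(lre_c - lre_f, alternative="greater").pvalue < 0.01


class TestFeatureTable:
    @staticmethod
    def _vectors():
        rng = np.random.default_rng(5)
        vecs = {}
        for sid in ("S1", "S2"):
            for region in ("medial_tibia", "medial_femur"):
                for tp in ("initial", "followup"):
                    vecs[(sid, region, tp)] = {
                        f: float(rng.random()) for f in DEFAULT_REGISTRY
                    }
        return vecs

    def test_shape_and_change_columns(self):
        table = build_feature_table(self._vectors())
        assert len(table) == 8
        change_cols = [c for c in table.columns if c.startswith("change_")]
        assert len(change_cols) == len(DEFAULT_REGISTRY) == 19

    def test_change_is_followup_minus_initial(self):
        vecs = self._vectors()
        table = build_feature_table(vecs)
        row = table[(table.subject_id == "S1") & (table.region == "medial_tibia")
                    & (table.timepoint == "followup")].iloc[0]
        key_i = ("S1", "medial_tibia", "initial")
        key_f = ("S1", "medial_tibia", "followup")
        for f in DEFAULT_REGISTRY:
            assert row[f"change_{f}"] == pytest.approx(vecs[key_f][f] - vecs[key_i][f])

    def test_missing_followup_leaves_change_absent(self):
        vecs = self._vectors()
        del vecs[("S2", "medial_tibia", "followup")]
        del vecs[("S2", "medial_femur", "followup")]
        table = build_feature_table(vecs)
        assert len(table) == 6
        mat = analysis_matrix(table, "tibial", "change")
        assert list(mat.index) == ["S1"]

    def test_duplicate_key_rejected(self):
        pairs = list(self._vectors().items())
        with pytest.raises(InputError, match="duplicate"):
            build_feature_table(pairs + pairs[:1])

    def test_combined_matrix_prefixes_regions(self):
        table = build_feature_table(self._vectors())
        comb = analysis_matrix(table, "combined", "initial")
        assert comb.shape == (2, 38)
        assert any(c.startswith("T_") for c in comb.columns)
        assert any(c.startswith("F_") for c in comb.columns)
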