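"""Texture-matrix builders vs brute-force oracles, plus closed forms."""

import numpy as np
import pandas as pd
import pytest

from deltarad import texture
from deltarad.preprocessing import quantize_roi
from deltarad.io import ImageVolume, ROIMask

from _helpers import make_quantized, random_quantized
from _oracles import (
    glcm_counts_bruteforce,
    glrlm_counts_bruteforce,
    glszm_zones_bruteforce,
    ngtdm_bruteforce,
    zones_to_matrix,
)


def _pad_to(a, shape):
    return np.pad(a, [(0, s - n) for s, n in zip(shape, a.shape)])


def assert_matrices_match(q, distance=1):
    """All four builders agree with their independent oracles on one ROI."""
    g = texture.build_glcm(q, distance=distance)
    np.testing.assert_array_equal(
        g.counts, glcm_counts_bruteforce(q.levels, q.mask, q.ng, distance)
    )

    r = texture.build_glrlm(q)
    oracle_r = glrlm_counts_bruteforce(q.levels, q.mask, q.ng)
    width = max(r.counts.shape[1], oracle_r.shape[1])
    np.testing.assert_array_equal(
        _pad_to(r.counts, (q.ng, width)), _pad_to(oracle_r, (q.ng, width))
    )

    z = texture.build_glszm(q)
    oracle_z = zones_to_matrix(glszm_zones_bruteforce(q.levels, q.mask, q.ng), q.ng)
    width = max(z.counts.shape[1], oracle_z.shape[1])
    np.testing.assert_array_equal(
        _pad_to(z.counts, (q.ng, width)), _pad_to(oracle_z, (q.ng, width))
    )

    t = texture.build_ngtdm(q)
    s_oracle, n_oracle = ngtdm_bruteforce(q.levels, q.mask, q.ng)
    np.testing.assert_allclose(t.s, s_oracle, atol=1e-9)
    np.testing.assert_array_equal(t.n, n_oracle)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(50))
    def test_random_rois_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        q = random_quantized(rng, max_shape=(8, 8, 4), ng=8)
        assert_matrices_match(q)

    @pytest.mark.parametrize("seed", [100, 101, 102])
    def test_distance_two_glcm(self, seed):
        rng = np.random.default_rng(seed)
        q = random_quantized(rng, max_shape=(7, 7, 4), ng=6)
        assert_matrices_match(q, distance=2)


class TestGLCM:
    def test_constant_roi_single_cell(self):
        q = make_quantized(np.ones((3, 3, 2), int), ng=4)
        g = texture.build_glcm(q)
        assert g.p[0, 0] == 1.0 and g.p.sum() == 1.0
        assert texture.glcm_energy(g) == 1.0

    def test_line_alternating_levels_hand_enumeration(self):
        # 1x1x4 ROI, levels 1,2,1,2: three adjacent pairs, symmetrized
        q = make_quantized(np.array([[[1, 2, 1, 2]]]), ng=2)
        g = texture.build_glcm(q)
        expected = np.array([[0.0, 0.5], [0.5, 0.0]])
        np.testing.assert_allclose(g.p, expected)
        assert texture.glcm_energy(g) == pytest.approx(0.5)

    def test_symmetry_and_normalization(self, rng):
        q = random_quantized(rng, ng=6)
        g = texture.build_glcm(q)
        np.testing.assert_allclose(g.p, g.p.T)
        assert g.p.sum() == pytest.approx(1.0)
        assert np.all(g.p >= 0)

    def test_energy_uniform_over_k_cells(self):
        # levels 1,2 alternating in a line of 8 -> off-diagonal mass 0.5/0.5
        q = make_quantized(np.array([[[1, 2] * 4]]), ng=2)
        assert texture.glcm_energy(texture.build_glcm(q)) == pytest.approx(0.5)

    def test_energy_bounds(self, rng):
        for seed in range(5):
            q = random_quantized(np.random.default_rng(seed), ng=8)
            e = texture.glcm_energy(texture.build_glcm(q))
            assert 0.0 < e <= 1.0

    def test_invalid_distance(self, rng):
        q = random_quantized(rng)
        with pytest.raises(ValueError):
            texture.build_glcm(q, distance=0)

    def test_averaged_aggregation_defined(self, rng):
        q = random_quantized(rng, ng=4)
        g = texture.build_glcm(q, aggregation="averaged")
        e = texture.glcm_energy(g)
        assert 0.0 < e <= 1.0
        assert len(g.p_by_direction) == 13


class TestGLSZM:
    def test_constant_connected_roi_single_zone(self):
        q = make_quantized(np.ones((4, 3, 2), int), ng=2)
        z = texture.build_glszm(q)
        assert z.n_zones == 1
        assert z.counts[0, 23] == 1  # one zone of size 24
        assert texture.glszm_large_zone_emphasis(z) == 24**2

    def test_all_distinct_levels_singleton_zones(self):
        levels = np.arange(1, 9).reshape(2, 2, 2)
        q = make_quantized(levels, ng=8)
        z = texture.build_glszm(q)
        assert z.n_zones == 8
        assert texture.glszm_large_zone_emphasis(z) == 1.0

    def test_lze_direct_formula(self):
        # zones of sizes 1, 2, 3 -> (1 + 4 + 9)/3
        levels = np.zeros((7, 1, 1), int)
        levels[0, 0, 0] = 1
        levels[2:4, 0, 0] = 2
        levels[5:7, 0, 0] = 3
        levels[4, 0, 0] = 3  # sizes: level1:1, level2:2, level3:3
        q = make_quantized(levels, ng=3)
        z = texture.build_glszm(q)
        assert texture.glszm_large_zone_emphasis(z) == pytest.approx(14 / 3)

    def test_mass_conservation(self, rng):
        for seed in range(5):
            q = random_quantized(np.random.default_rng(seed), ng=6)
            z = texture.build_glszm(q)
            s = np.arange(1, z.counts.shape[1] + 1)
            assert np.sum(z.counts * s) == q.n_voxels


class TestGLRLM:
    def test_single_line_single_run(self):
        q = make_quantized(np.full((1, 1, 5), 3, int), ng=4)
        r = texture.build_glrlm(q)
        # z-direction: 1 run of length 5; the other 12 directions: 5 runs of 1
        assert r.counts[2, 4] == 1
        assert r.counts[2, 0] == 12 * 5

    def test_alternating_line_runs_of_one(self):
        q = make_quantized(np.array([[[1, 2, 1, 2]]]), ng=2)
        r = texture.build_glrlm(q)
        assert r.counts.shape[1] == 1  # no run longer than 1 anywhere
        assert r.counts.sum() == 13 * 4

    def test_voxel_mass_per_direction(self, rng):
        q = random_quantized(rng, ng=4)
        r = texture.build_glrlm(q)
        lengths = np.arange(1, r.counts.shape[1] + 1)
        assert np.sum(r.counts * lengths) == 13 * q.n_voxels


class TestNGTDM:
    def test_constant_roi_zero_differences(self):
        q = make_quantized(np.ones((3, 3, 3), int), ng=2)
        t = texture.build_ngtdm(q)
        assert np.all(t.s == 0)
        assert t.n.sum() == 27

    def test_isolated_voxel_no_valid_neighbors(self):
        levels = np.zeros((5, 5, 5), int)
        levels[2, 2, 2] = 1
        q = make_quantized(levels, ng=2)
        t = texture.build_ngtdm(q)
        assert t.n.sum() == 0
        feats = texture.ngtdm_features(t)
        assert all(np.isfinite(v) for v in feats.values())


class TestFeatureVector:
    def test_exactly_39_named_features(self, rng):
        q = random_quantized(rng, ng=8)
        vec = texture.extract_features(q)
        assert len(vec) == 39
        assert list(vec.index) == list(texture.FEATURE_NAMES)
        assert np.isfinite(vec).all()

    def test_constant_roi_composition(self):
        q = make_quantized(np.ones((4, 4, 2), int), ng=64)
        vec = texture.extract_features(q)
        assert vec["glcm_energy"] == 1.0
        assert vec["glszm_large_zone_emphasis"] == 32**2

    def test_deterministic(self, rng):
        q = random_quantized(rng, ng=8)
        v1 = texture.extract_features(q)
        v2 = texture.extract_features(q)
        pd.testing.assert_series_equal(v1, v2)

    def test_single_voxel_roi_defined(self):
        levels = np.zeros((3, 3, 3), int)
        levels[1, 1, 1] = 1
        vec = texture.extract_features(make_quantized(levels, ng=4))
        assert np.isfinite(vec).all()
        assert vec["glcm_energy"] == 1.0  # degenerate: maximally homogeneous


class TestFeatureInvariances:
    def test_label_permutation_leaves_energy_and_lze(self, rng):
        q = random_quantized(rng, ng=6)
        perm = rng.permutation(6) + 1
        permuted = np.where(q.mask, perm[q.levels - 1], 0)
        qp = make_quantized(permuted, ng=6)
        e1 = texture.glcm_energy(texture.build_glcm(q))
        e2 = texture.glcm_energy(texture.build_glcm(qp))
        assert e1 == pytest.approx(e2, rel=1e-12)
        l1 = texture.glszm_large_zone_emphasis(texture.build_glszm(q))
        l2 = texture.glszm_large_zone_emphasis(texture.build_glszm(qp))
        assert l1 == pytest.approx(l2, rel=1e-12)

    def test_translation_invariance(self, rng):
        q = random_quantized(rng, max_shape=(5, 5, 3), ng=4)
        shifted = np.zeros((q.levels.shape[0] + 2,
                            q.levels.shape[1] + 3,
                            q.levels.shape[2] + 1), int)
        shifted[2:, 3:, 1:] = q.levels
        qs = make_quantized(shifted, ng=4)
        pd.testing.assert_series_equal(
            texture.extract_features(q), texture.extract_features(qs)
        )

    def test_block_coarsening_increases_lze(self, rng):
        base = np.random.default_rng(5).integers(1, 5, (4, 4, 2))
        fine = make_quantized(base, ng=4)
        coarse = make_quantized(np.kron(base, np.ones((2, 2, 2), int)), ng=4)
        lze_fine = texture.glszm_large_zone_emphasis(texture.build_glszm(fine))
        lze_coarse = texture.glszm_large_zone_emphasis(texture.build_glszm(coarse))
        assert lze_coarse > lze_fine

    def test_quantized_pipeline_end_to_end_crop_equivalence(self, rng):
        data = rng.normal(100, 15, (14, 12, 8))
        mask = np.zeros(data.shape, bool)
        mask[3:10, 2:9, 2:6] = True
        vol = ImageVolume(data, (1.5, 1.5, 3.0))
        roi = ROIMask(mask, vol.spacing)
        v_crop = texture.extract_features(quantize_roi(vol, roi, ng=16, crop=True))
        v_full = texture.extract_features(quantize_roi(vol, roi, ng=16, crop=False))
        pd.testing.assert_series_equal(v_crop, v_full)
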