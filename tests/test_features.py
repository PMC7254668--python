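"""Radiomics feature extraction: counts, oracles, texture properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from deltarad.core import DCESeries
from deltarad.features import (
    PER_PHASE_FEATURES,
    TextureConfig,
    all_feature_names,
    assemble_lesion_vector,
    cluster_entropy,
    exam_features,
    feature_names,
    first_order,
    gabor_features,
    glcm,
    haralick5,
    intensity_feature_names,
)


def haralick_oracle(P):
    """Independent double-loop summation of the five Haralick features."""
    n = P.shape[0]
    pi = P.sum(axis=1)
    pj = P.sum(axis=0)
    mu_i = sum(i * pi[i] for i in range(n))
    mu_j = sum(j * pj[j] for j in range(n))
    var_i = sum((i - mu_i) ** 2 * pi[i] for i in range(n))
    var_j = sum((j - mu_j) ** 2 * pj[j] for j in range(n))
    energy = entropy = contrast = homogeneity = corr = 0.0
    for i in range(n):
        for j in range(n):
            p = P[i, j]
            energy += p * p
            if p > 0:
                entropy -= p * np.log2(p)
            contrast += (i - j) ** 2 * p
            homogeneity += p / (1 + abs(i - j))
            if var_i > 0 and var_j > 0:
                corr += (i - mu_i) * (j - mu_j) * p / np.sqrt(var_i * var_j)
    return {
        "energy": energy,
        "entropy": entropy,
        "correlation": corr,
        "contrast": contrast,
        "homogeneity": homogeneity,
    }


class TestFirstOrder:
    def test_known_values(self):
        vol = np.array([1.0, 2, 3, 4, 5]).reshape(5, 1, 1)
        mask = np.ones((5, 1, 1), bool)
        f = first_order(vol, mask)
        assert f["mean"] == pytest.approx(3.0)
        assert f["sd"] == pytest.approx(np.std([1, 2, 3, 4, 5], ddof=1))

    def test_constant_region_degenerates_to_zero(self):
        f = first_order(np.full((3, 3, 3), 7.0), np.ones((3, 3, 3), bool))
        assert (f["mean"], f["sd"], f["skewness"], f["kurtosis"]) == (7.0, 0.0, 0.0, 0.0)

    def test_symmetric_distribution_has_zero_skewness(self):
        rng = np.random.default_rng(0)
        vol = rng.normal(0, 1, (12, 12, 12))
        vol = np.concatenate([vol, -vol])  # exactly symmetric
        f = first_order(vol, np.ones(vol.shape, bool))
        assert f["skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_tiny_mask_raises(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[0, 0, :3] = True  # 3 voxels: too few for kurtosis/skewness
        with pytest.raises(ValueError):
            first_order(np.ones((3, 3, 3)), mask)


class TestGLCM:
    def test_constant_region_single_cell(self):
        P = glcm(np.full((4, 4, 4), 3.0), np.ones((4, 4, 4), bool))
        assert P[0, 0] == pytest.approx(1.0)
        assert P.sum() == pytest.approx(1.0)

    def test_stripe_pattern_matches_hand_enumeration(self):
        # 1-D two-level stripe, single voxel thick: only the x offset pairs
        vol = np.array([0.0, 1, 0, 1, 0, 1]).reshape(6, 1, 1)
        mask = np.ones((6, 1, 1), bool)
        cfg = TextureConfig(glcm_levels=2)
        P = glcm(vol, mask, cfg)
        # pairs (0,1)x5 symmetric -> 10 of 10 counts off-diagonal
        assert P[0, 1] == pytest.approx(0.5)
        assert P[1, 0] == pytest.approx(0.5)
        assert P[0, 0] == P[1, 1] == 0.0

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_normalization_for_random_volumes(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(2, 7, 3))
        vol = rng.normal(0, 1, shape)
        mask = rng.uniform(size=shape) < 0.7
        if not mask.any():
            mask[0, 0, 0] = True
        assert glcm(vol, mask).sum() == pytest.approx(1.0)


class TestHaralick:
    def test_single_cell_matrix(self):
        P = np.zeros((8, 8))
        P[2, 2] = 1.0
        h = haralick5(P)
        assert h == {
            "energy": 1.0, "entropy": 0.0, "correlation": 0.0,
            "contrast": 0.0, "homogeneity": 1.0,
        }

    @pytest.mark.parametrize("n", [2, 4, 8])
    def test_uniform_matrix_analytic(self, n):
        P = np.full((n, n), 1.0 / n**2)
        h = haralick5(P)
        assert h["entropy"] == pytest.approx(2 * np.log2(n))
        assert h["energy"] == pytest.approx(1.0 / n**2)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 16))
        P = rng.uniform(size=(n, n))
        P = P / P.sum()
        got = haralick5(P)
        want = haralick_oracle(P)
        for k in want:
            assert got[k] == pytest.approx(want[k], abs=1e-10)


class TestGabor:
    def test_constant_volume_gives_zero_edge_response(self):
        g = gabor_features(np.full((20, 20, 8), 50.0), np.ones((20, 20, 8), bool))
        assert abs(g["gab0"]) < 1e-9
        assert abs(g["gab90"]) < 1e-9

    def test_oriented_stripes_excite_one_angle(self):
        vol = np.zeros((24, 24, 6))
        vol[(np.arange(24) // 2) % 2 == 0, :, :] = 100.0
        g = gabor_features(vol, np.ones(vol.shape, bool))
        strong, weak = max(g["gab0"], g["gab90"]), min(g["gab0"], g["gab90"])
        assert strong > 10 * weak

    def test_axis_swap_exchanges_angles(self):
        rng = np.random.default_rng(1)
        vol = rng.normal(100, 20, (18, 22, 6))
        mask = np.ones(vol.shape, bool)
        g = gabor_features(vol, mask)
        gs = gabor_features(np.swapaxes(vol, 0, 1), np.swapaxes(mask, 0, 1))
        assert g["gab0"] == pytest.approx(gs["gab90"], rel=1e-6)
        assert g["gab90"] == pytest.approx(gs["gab0"], rel=1e-6)

    def test_feature_count_is_twelve(self, textured_lesion):
        g = gabor_features(
            textured_lesion.pre_exam.phases[1], textured_lesion.truth_mask_pre.mask
        )
        assert len(g) == 12


class TestClusterEntropy:
    def test_homogeneous_lesion_gives_zero(self):
        series = DCESeries(np.full((4, 12, 12, 8), 70.0))
        assert cluster_entropy(series, np.ones((12, 12, 8), bool),
                               TextureConfig(cluster_phase=0)) == 0.0

    def test_two_distinct_blobs_give_about_one_bit(self):
        # two spatially separated, texture-distinct blobs of equal size
        shape = (20, 8, 8)
        vol = np.full(shape, 50.0)
        idx = np.indices(shape).sum(axis=0)
        vol[12:] = 100.0 * (idx[12:] % 2)
        mask = np.zeros(shape, bool)
        mask[:8] = True
        mask[12:] = True
        series = DCESeries(np.stack([vol] * 4))
        ce = cluster_entropy(series, mask, TextureConfig(cluster_phase=0))
        assert ce == pytest.approx(1.0, abs=0.25)

    def test_entropy_bounded_by_log_cluster_count(self, textured_lesion):
        cfg = TextureConfig()
        ce = cluster_entropy(textured_lesion.pre_exam, textured_lesion.truth_mask_pre.mask, cfg)
        assert 0.0 <= ce <= np.log2(cfg.cluster_count_range[1])

    def test_small_mask_raises(self):
        series = DCESeries(np.zeros((4, 6, 6, 6)))
        mask = np.zeros((6, 6, 6), bool)
        mask[0, 0, :3] = True
        with pytest.raises(ValueError):
            cluster_entropy(series, mask)


class TestAssembly:
    def test_exam_feature_count_and_names(self, textured_lesion):
        feats = exam_features(textured_lesion.pre_exam, textured_lesion.truth_mask_pre)
        assert len(feats) == 85
        assert list(feats) == feature_names("bef")
        per_phase = [n for n in feats if n.startswith("bef_post1_")]
        assert len(per_phase) == len(PER_PHASE_FEATURES) == 21

    def test_exam_features_deterministic(self, textured_lesion):
        a = exam_features(textured_lesion.pre_exam, textured_lesion.truth_mask_pre)
        b = exam_features(textured_lesion.pre_exam, textured_lesion.truth_mask_pre)
        assert a == b

    def test_identical_exams_give_zero_deltas(self, textured_lesion):
        pre = exam_features(textured_lesion.pre_exam, textured_lesion.truth_mask_pre)
        post = {("af" + k[3:]): v for k, v in pre.items()}
        full = assemble_lesion_vector(pre, post)
        deltas = [v for k, v in full.items() if k.startswith("diff")]
        assert len(full) == 255
        assert len(deltas) == 85
        assert all(v == 0.0 for v in deltas)

    def test_delta_is_post_minus_pre(self):
        pre = {k: 0.0 for k in feature_names("bef")}
        post = {k: 0.0 for k in feature_names("af")}
        pre["bef_pre_mean"] = 4.0
        post["af_pre_mean"] = 10.0
        full = assemble_lesion_vector(pre, post)
        assert full["diff_pre_mean"] == 6.0

    def test_name_mismatch_raises(self):
        pre = {k: 0.0 for k in feature_names("bef")}
        with pytest.raises(ValueError):
            assemble_lesion_vector(pre, dict(pre))

    def test_canonical_vector_layout(self):
        names = all_feature_names()
        assert len(names) == 255
        assert len(set(names)) == 255
        for timing, count in (("bef", 85), ("af", 85), ("diff", 85)):
            assert sum(n.startswith(timing + "_") for n in names) == count
        assert len(intensity_feature_names()) == 12
        assert set(intensity_feature_names()) <= set(names)
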