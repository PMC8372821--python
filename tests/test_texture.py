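import numpy as np
import pytest

from lateromics.discretization import DiscretizedROI
from lateromics.texture import (
    DIRECTIONS_13,
    GLCM_FEATURE_NAMES,
    GLRLM_FEATURE_NAMES,
    TextureConfig,
    compute_glcm,
    compute_glrlm,
    glcm_features,
    glrlm_features,
    texture_features,
)

from oracles import (
    glcm_bruteforce,
    glcm_features_bruteforce,
    glrlm_bruteforce,
    glrlm_features_bruteforce,
)


def _droi(levels, n_levels=None):
    levels = np.asarray(levels, dtype=np.int16)
    if levels.ndim == 1:
        levels = levels.reshape(-1, 1, 1)
    mask = levels > 0
    ng = int(n_levels or levels.max())
    return DiscretizedROI(levels, mask, ng)


class TestGLCMMatrix:
    def test_constant_cube_single_entry(self):
        d = _droi(np.ones((2, 2, 2)))
        for dirn in DIRECTIONS_13:
            g = compute_glcm(d, 1, dirn)
            if g.empty:
                continue
            assert g.matrix[0, 0] == pytest.approx(1.0)
            assert g.matrix.sum() == pytest.approx(1.0)

    def test_alternating_strip_off_diagonal(self):
        d = _droi([1, 2, 1, 2])
        g = compute_glcm(d, 1, (1, 0, 0))
        assert g.matrix[0, 1] == pytest.approx(0.5)
        assert g.matrix[1, 0] == pytest.approx(0.5)
        assert g.matrix[0, 0] == 0 and g.matrix[1, 1] == 0

    def test_mask_thinner_than_offset_flagged_empty(self):
        d = _droi(np.ones((2, 2, 2)))
        g = compute_glcm(d, 3, (1, 0, 0))
        assert g.empty

    @pytest.mark.parametrize("distance", [1, 2, 3])
    def test_matches_bruteforce_on_random_roi(self, distance, rng, toy):
        levels = toy["random_levels"].copy()
        levels[rng.random(levels.shape) < 0.3] = 0  # carve mask holes
        d = _droi(levels, n_levels=4)
        for dirn in DIRECTIONS_13:
            got = compute_glcm(d, distance, dirn)
            want = glcm_bruteforce(levels, distance, dirn, 4)
            np.testing.assert_allclose(got.matrix, want, atol=1e-12)

    def test_symmetric_and_normalized(self, toy):
        d = _droi(toy["random_levels"], n_levels=4)
        g = compute_glcm(d, 1, (1, 1, 0))
        np.testing.assert_allclose(g.matrix, g.matrix.T)
        assert g.matrix.sum() == pytest.approx(1.0)


class TestGLCMFeatures:
    def test_constant_roi_point_mass(self):
        d = _droi(np.ones((3, 3, 3)))
        glcms = [compute_glcm(d, 1, dirn) for dirn in DIRECTIONS_13]
        feats = glcm_features(glcms)
        for agg in ("avg", "mrg"):
            assert feats[f"{agg}_joint_energy"] == pytest.approx(1.0)
            assert feats[f"{agg}_joint_entropy"] == pytest.approx(0.0)
            assert feats[f"{agg}_contrast"] == pytest.approx(0.0)
            assert feats[f"{agg}_maximum_probability"] == pytest.approx(1.0)

    def test_checkerboard_axis_contrast(self, toy):
        d = _droi(toy["checkerboard"], n_levels=2)
        for dirn in [(0, 0, 1), (0, 1, 0), (1, 0, 0)]:
            g = compute_glcm(d, 1, dirn)
            feats = glcm_features_bruteforce(g.matrix)
            # neighbours along an axis always differ by exactly one level
            assert feats["contrast"] == pytest.approx(1.0)

    def test_formulas_match_loop_oracle(self, toy, rng):
        levels = toy["random_levels"].copy()
        levels[rng.random(levels.shape) < 0.2] = 0
        d = _droi(levels, n_levels=4)
        for dirn in DIRECTIONS_13[::4]:
            g = compute_glcm(d, 1, dirn)
            from lateromics.texture import _glcm_single
            got = _glcm_single(g.matrix)
            want = glcm_features_bruteforce(g.matrix)
            for name in GLCM_FEATURE_NAMES:
                assert got[name] == pytest.approx(want[name], rel=1e-9), name

    def test_aggregations_agree_for_identical_matrices(self):
        d = _droi(np.ones((4, 4, 4)))
        glcms = [compute_glcm(d, 1, dirn) for dirn in [(0, 0, 1), (0, 1, 0)]]
        # same pair counts in both directions of a constant cube
        feats = glcm_features(glcms)
        for name in GLCM_FEATURE_NAMES:
            assert feats[f"avg_{name}"] == pytest.approx(feats[f"mrg_{name}"])

    def test_level_permutation_moves_contrast_not_entropy(self):
        base = _droi([1, 1, 2, 2, 3, 3], n_levels=3)
        permuted = _droi([2, 2, 1, 1, 3, 3], n_levels=3)  # swap levels 1<->2
        f1 = glcm_features([compute_glcm(base, 1, (1, 0, 0))])
        f2 = glcm_features([compute_glcm(permuted, 1, (1, 0, 0))])
        assert f1["avg_joint_entropy"] == pytest.approx(f2["avg_joint_entropy"])
        assert f1["avg_joint_energy"] == pytest.approx(f2["avg_joint_energy"])
        assert f1["avg_contrast"] != pytest.approx(f2["avg_contrast"])

    def test_direction_average_invariant_under_axis_flip(self, toy):
        levels = toy["random_levels"]
        d1 = _droi(levels, n_levels=4)
        d2 = _droi(np.flip(levels, axis=0), n_levels=4)
        f1 = glcm_features([compute_glcm(d1, 1, dirn) for dirn in DIRECTIONS_13])
        f2 = glcm_features([compute_glcm(d2, 1, dirn) for dirn in DIRECTIONS_13])
        for name in GLCM_FEATURE_NAMES:
            assert f1[f"avg_{name}"] == pytest.approx(f2[f"avg_{name}"]), name


class TestGLRLM:
    def test_strip_run_decomposition(self, toy):
        d = _droi(toy["strip"], n_levels=2)
        g = compute_glrlm(d, (1, 0, 0))
        assert g.matrix[0, 2] == 1  # level 1, length 3
        assert g.matrix[1, 1] == 1  # level 2, length 2
        assert g.n_runs == 2
        feats = glrlm_features([g])
        assert feats["avg_run_percentage"] == pytest.approx(2 / 5)

    def test_constant_line_single_run(self):
        d = _droi([1] * 7)
        g = compute_glrlm(d, (1, 0, 0))
        assert g.matrix.shape[1] == 7
        assert g.matrix[0, 6] == 1
        assert g.n_runs == 1

    def test_matches_bruteforce_on_random_roi(self, toy, rng):
        levels = toy["random_levels"].copy()
        levels[rng.random(levels.shape) < 0.3] = 0
        d = _droi(levels, n_levels=4)
        for dirn in DIRECTIONS_13:
            got = compute_glrlm(d, dirn)
            want = glrlm_bruteforce(levels, dirn, 4)
            np.testing.assert_array_equal(got.matrix, want)

    def test_run_length_times_count_covers_mask(self, toy):
        d = _droi(toy["random_levels"], n_levels=4)
        for dirn in DIRECTIONS_13:
            g = compute_glrlm(d, dirn)
            lengths = np.arange(1, g.matrix.shape[1] + 1)
            assert (g.matrix * lengths).sum() == d.mask.sum()

    def test_all_unit_runs_degenerate_emphases(self):
        d = _droi([1, 2, 1, 2, 1], n_levels=2)
        feats = glrlm_features([compute_glrlm(d, (1, 0, 0))])
        assert feats["avg_short_run_emphasis"] == pytest.approx(1.0)
        assert feats["avg_long_run_emphasis"] == pytest.approx(1.0)

    def test_single_run_percentage(self):
        d = _droi([1, 1, 1, 1])
        feats = glrlm_features([compute_glrlm(d, (1, 0, 0))])
        assert feats["avg_run_percentage"] == pytest.approx(1 / 4)

    def test_formulas_match_loop_oracle(self, toy):
        d = _droi(toy["random_levels"], n_levels=4)
        glrlms = [compute_glrlm(d, dirn) for dirn in DIRECTIONS_13]
        feats = glrlm_features(glrlms)
        per_dir = [
            glrlm_features_bruteforce(g.matrix, g.n_voxels) for g in glrlms
        ]
        for name in GLRLM_FEATURE_NAMES:
            want = np.mean([f[name] for f in per_dir])
            assert feats[f"avg_{name}"] == pytest.approx(want, rel=1e-9), name
        rmax = max(g.matrix.shape[1] for g in glrlms)
        merged = np.zeros((4, rmax), dtype=np.int64)
        for g in glrlms:
            merged[:, : g.matrix.shape[1]] += g.matrix
        want_mrg = glrlm_features_bruteforce(merged, glrlms[0].n_voxels, 13)
        for name in GLRLM_FEATURE_NAMES:
            assert feats[f"mrg_{name}"] == pytest.approx(want_mrg[name], rel=1e-9), name


def test_texture_family_totals_162(toy):
    d = _droi(toy["random_levels"], n_levels=4)
    feats = texture_features(d)
    assert len(feats) == 162
    glcm_keys = [k for k in feats if k.startswith("glcm")]
    glrlm_keys = [k for k in feats if k.startswith("glrlm")]
    assert len(glcm_keys) == 3 * 2 * 23
    assert len(glrlm_keys) == 2 * 12
    assert all(np.isfinite(v) for v in feats.values())
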