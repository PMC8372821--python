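import math

import numpy as np
import pytest

from lateromics.discretization import DiscretizationConfig, discretize
from lateromics.firstorder import (
    FIRSTORDER_NAMES,
    SHAPE_NAMES,
    firstorder_features,
    shape_features,
)


def _features(values, n_bins=32):
    arr = np.asarray(values, dtype=float).reshape(-1, 1, 1)
    mask = np.ones(arr.shape, dtype=bool)
    d = discretize(arr, mask, DiscretizationConfig(n_bins=n_bins))
    return firstorder_features(arr[mask], d)


def naive_firstorder(values, d):
    """Independent loop/stdlib computation of all 17 features."""
    xs = sorted(float(v) for v in values)
    n = len(xs)
    mean = sum(xs) / n
    var = sum((v - mean) ** 2 for v in xs) / n
    sd = math.sqrt(var)
    hist = d.histogram()
    probs = [h / n for h in hist if h > 0]

    def perc(q):
        # linear interpolation between order statistics (numpy default)
        pos = q / 100 * (n - 1)
        lo = math.floor(pos)
        hi = math.ceil(pos)
        return xs[lo] + (pos - lo) * (xs[hi] - xs[lo])

    return {
        "mean": mean,
        "median": perc(50),
        "minimum": xs[0],
        "maximum": xs[-1],
        "range": xs[-1] - xs[0],
        "variance": var,
        "standard_deviation": sd,
        "skewness": sum((v - mean) ** 3 for v in xs) / n / sd**3 if sd else 0.0,
        "kurtosis": sum((v - mean) ** 4 for v in xs) / n / sd**4 if sd else 0.0,
        "energy": sum(v**2 for v in xs),
        "root_mean_square": math.sqrt(sum(v**2 for v in xs) / n),
        "mean_absolute_deviation": sum(abs(v - mean) for v in xs) / n,
        "entropy": -sum(p * math.log2(p) for p in probs),
        "uniformity": sum(p**2 for p in probs),
        "percentile10": perc(10),
        "percentile90": perc(90),
        "interquartile_range": perc(75) - perc(25),
    }


class TestFirstOrder:
    def test_exactly_the_17_features(self):
        feats = _features([1, 2, 3])
        assert tuple(feats) == FIRSTORDER_NAMES

    def test_constant_roi_degenerate_values(self):
        feats = _features([4.0] * 20)
        assert feats["variance"] == 0
        assert feats["entropy"] == 0
        assert feats["uniformity"] == 1
        assert feats["range"] == 0
        assert feats["skewness"] == 0 and feats["kurtosis"] == 0
        assert feats["mean"] == feats["median"] == 4.0

    def test_hand_computed_small_multiset(self):
        feats = _features([1, 2, 3, 4])
        assert feats["mean"] == pytest.approx(2.5)
        assert feats["variance"] == pytest.approx(1.25)
        assert feats["range"] == 3
        assert feats["energy"] == pytest.approx(1 + 4 + 9 + 16)

    def test_two_equal_mass_levels_entropy_one_bit(self):
        feats = _features([0.0] * 8 + [1.0] * 8, n_bins=2)
        assert feats["entropy"] == pytest.approx(1.0)
        assert feats["uniformity"] == pytest.approx(0.5)

    def test_matches_naive_oracle_on_random_multisets(self, rng):
        for _ in range(5):
            values = rng.normal(size=50) * rng.uniform(0.5, 20)
            arr = values.reshape(-1, 1, 1)
            mask = np.ones(arr.shape, bool)
            d = discretize(arr, mask)
            got = firstorder_features(arr[mask], d)
            want = naive_firstorder(values, d)
            for name in FIRSTORDER_NAMES:
                assert got[name] == pytest.approx(want[name], rel=1e-10), name

    def test_shift_invariance(self, rng):
        values = rng.normal(size=80)
        base = _features(values)
        shifted = _features(values + 13.5)
        for name in ("variance", "entropy", "uniformity", "standard_deviation",
                     "mean_absolute_deviation", "range", "interquartile_range"):
            assert shifted[name] == pytest.approx(base[name], abs=1e-9)
        for name in ("mean", "median", "percentile10", "percentile90",
                     "minimum", "maximum"):
            assert shifted[name] == pytest.approx(base[name] + 13.5)

    def test_entropy_and_uniformity_bounds(self, rng):
        feats = _features(rng.normal(size=500), n_bins=32)
        assert 0 <= feats["entropy"] <= math.log2(32)
        assert 0 < feats["uniformity"] <= 1

    def test_empty_rejected(self):
        arr = np.ones((2, 1, 1))
        mask = np.ones_like(arr, bool)
        d = discretize(arr, mask)
        with pytest.raises(ValueError):
            firstorder_features(np.array([]), d)


class TestShape:
    def test_single_voxel_geometry(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        feats = shape_features(mask, (1, 1, 1))
        assert tuple(feats) == SHAPE_NAMES
        assert feats["volume"] == 1.0
        assert feats["surface_area"] == 6.0
        assert feats["maximum_diameter"] == 0.0

    def test_cube_face_counting(self):
        mask = np.zeros((4, 4, 4), bool)
        mask[1:3, 1:3, 1:3] = True
        feats = shape_features(mask, (1, 1, 1))
        assert feats["volume"] == 8.0
        assert feats["surface_area"] == 24.0
        assert feats["surface_to_volume_ratio"] == pytest.approx(3.0)
        assert feats["maximum_diameter"] == pytest.approx(np.sqrt(3))

    def test_digital_ball_sphericity_approaches_one(self):
        r = 20
        n = 2 * r + 3
        c = n // 2
        g = np.ogrid[0:n, 0:n, 0:n]
        mask = sum((gi - c) ** 2 for gi in g) <= r**2
        feats = shape_features(mask, (1, 1, 1))
        # face-count surface of a ball exceeds the smooth sphere area by
        # a known constant factor (~1.5), so sphericity sits below 1
        assert 0.5 < feats["sphericity"] < 1.0
        assert feats["spherical_disproportion"] == pytest.approx(
            1.0 / feats["sphericity"], rel=1e-6
        )
        assert feats["maximum_diameter"] == pytest.approx(2 * r, rel=0.05)

    def test_mask_touching_grid_edge_counts_boundary_faces(self):
        mask = np.ones((2, 2, 2), bool)
        feats = shape_features(mask, (1, 1, 1))
        assert feats["surface_area"] == 24.0

    def test_anisotropic_spacing(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        feats = shape_features(mask, (1.0, 2.0, 3.0))
        assert feats["volume"] == pytest.approx(6.0)
        assert feats["surface_area"] == pytest.approx(2 * (6 + 3 + 2))

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            shape_features(np.zeros((2, 2, 2), bool), (1, 1, 1))
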