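"""Brute-force reference implementations used only by the test suite.

These deliberately trade speed for transparency: explicit loops over
voxel pairs, runs, cut points and filter taps, so that the vectorized
package code can be checked against an independent computation.
"""

from __future__ import annotations

import numpy as np


def glcm_bruteforce(levels: np.ndarray, distance: int, direction, n_levels: int) -> np.ndarray:
    """Pair enumeration: count (x, x + distance*direction) level pairs, both
    orders, over in-mask voxels (level > 0); normalized, or zeros if empty."""
    off = tuple(distance * c for c in direction)
    counts = np.zeros((n_levels, n_levels))
    it = np.ndindex(*levels.shape)
    for idx in it:
        a = levels[idx]
        if a <= 0:
            continue
        jdx = tuple(i + o for i, o in zip(idx, off))
        if any(j < 0 or j >= n for j, n in zip(jdx, levels.shape)):
            continue
        b = levels[jdx]
        if b <= 0:
            continue
        counts[a - 1, b - 1] += 1
        counts[b - 1, a - 1] += 1
    total = counts.sum()
    return counts / total if total > 0 else counts


def glrlm_bruteforce(levels: np.ndarray, direction, n_levels: int) -> np.ndarray:
    """Run scan: walk every line along ``direction`` and count maximal
    same-level in-mask runs.  Returns an (n_levels, rmax) count matrix."""
    shape = levels.shape
    d = np.array(direction)
    runs: list[tuple[int, int]] = []
    visited = np.zeros(shape, dtype=bool)
    for idx in np.ndindex(*shape):
        # line starts: no predecessor inside the grid
        prev = tuple(np.array(idx) - d)
        if all(0 <= p < n for p, n in zip(prev, shape)):
            continue
        pos = np.array(idx)
        current_level, current_len = 0, 0
        while all(0 <= p < n for p, n in zip(pos, shape)):
            lv = levels[tuple(pos)]
            if lv == current_level and lv > 0:
                current_len += 1
            else:
                if current_level > 0:
                    runs.append((current_level, current_len))
                current_level, current_len = (lv, 1) if lv > 0 else (0, 0)
            visited[tuple(pos)] = True
            pos = pos + d
        if current_level > 0:
            runs.append((current_level, current_len))
    assert visited.all()
    rmax = max((r for _, r in runs), default=1)
    mat = np.zeros((n_levels, rmax), dtype=np.int64)
    for g, r in runs:
        mat[g - 1, r - 1] += 1
    return mat


def subband_oracle(arr: np.ndarray, filters: dict[str, np.ndarray], band: str) -> np.ndarray:
    """Sequential 1D circular filtering, one axis at a time, via np.roll.

    Matches a centred correlation: out[n] = sum_j w[j] x[n + j - len(w)//2].
    """
    out = arr.astype(np.float64)
    for axis, letter in enumerate(band):
        w = filters[letter]
        half = len(w) // 2
        acc = np.zeros_like(out)
        for j, wj in enumerate(w):
            acc += wj * np.roll(out, half - j, axis=axis)
        out = acc
    return out


def youden_bruteforce(scores: np.ndarray, labels: np.ndarray):
    """Exhaustive scan over midpoint cut points; positive iff score >= t."""
    distinct = np.unique(scores)
    cands = (distinct[:-1] + distinct[1:]) / 2 if distinct.size > 1 else distinct
    best = None
    for t in cands:
        call = scores >= t
        sens = call[labels == 1].mean()
        spec = (~call[labels == 0]).mean()
        j = sens + spec
        if best is None or j > best[0] + 1e-12:
            best = (j, t, sens, spec)
    return best[1], best[2], best[3]


def auc_pair_enumeration(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney by explicit pair counting (ties = 1/2)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            wins += 1.0 if p > n else (0.5 if p == n else 0.0)
    return wins / (len(pos) * len(neg))


def glcm_features_bruteforce(p: np.ndarray) -> dict:
    """Plain-loop evaluation of the 23 co-occurrence formulas."""
    ng = p.shape[0]
    mu = sum((i + 1) * p[i, j] for i in range(ng) for j in range(ng))
    px = [p[i, :].sum() for i in range(ng)]
    sigma2 = sum(((i + 1) - mu) ** 2 * px[i] for i in range(ng))
    pdiff = {}
    psum = {}
    for i in range(ng):
        for j in range(ng):
            pdiff[abs(i - j)] = pdiff.get(abs(i - j), 0.0) + p[i, j]
            psum[i + j + 2] = psum.get(i + j + 2, 0.0) + p[i, j]

    def ent(vals):
        return -sum(v * np.log2(v) for v in vals if v > 0)

    hxy = ent(p.ravel())
    hx = ent(px)
    hxy1 = -sum(
        p[i, j] * np.log2(px[i] * px[j])
        for i in range(ng) for j in range(ng)
        if p[i, j] > 0 and px[i] * px[j] > 0
    )
    hxy2 = ent([px[i] * px[j] for i in range(ng) for j in range(ng)])
    da = sum(k * v for k, v in pdiff.items())

    out = {
        "autocorrelation": sum((i + 1) * (j + 1) * p[i, j] for i in range(ng) for j in range(ng)),
        "cluster_prominence": sum(((i + 1) + (j + 1) - 2 * mu) ** 4 * p[i, j] for i in range(ng) for j in range(ng)),
        "cluster_shade": sum(((i + 1) + (j + 1) - 2 * mu) ** 3 * p[i, j] for i in range(ng) for j in range(ng)),
        "cluster_tendency": sum(((i + 1) + (j + 1) - 2 * mu) ** 2 * p[i, j] for i in range(ng) for j in range(ng)),
        "contrast": sum((i - j) ** 2 * p[i, j] for i in range(ng) for j in range(ng)),
        "correlation": (
            (sum((i + 1) * (j + 1) * p[i, j] for i in range(ng) for j in range(ng)) - mu * mu) / sigma2
            if sigma2 > 0 else 1.0
        ),
        "difference_average": da,
        "difference_entropy": ent(pdiff.values()),
        "difference_variance": sum((k - da) ** 2 * v for k, v in pdiff.items()),
        "joint_average": mu,
        "joint_energy": sum(p[i, j] ** 2 for i in range(ng) for j in range(ng)),
        "joint_entropy": hxy,
        "imc1": (hxy - hxy1) / hx if hx > 0 else 0.0,
        "imc2": float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))),
        "inverse_difference": sum(p[i, j] / (1 + abs(i - j)) for i in range(ng) for j in range(ng)),
        "inverse_difference_normalized": sum(p[i, j] / (1 + abs(i - j) / ng) for i in range(ng) for j in range(ng)),
        "inverse_difference_moment": sum(p[i, j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng)),
        "inverse_difference_moment_normalized": sum(p[i, j] / (1 + (i - j) ** 2 / ng**2) for i in range(ng) for j in range(ng)),
        "inverse_variance": sum(p[i, j] / (i - j) ** 2 for i in range(ng) for j in range(ng) if i != j),
        "maximum_probability": p.max(),
        "sum_average": sum(k * v for k, v in psum.items()),
        "sum_entropy": ent(psum.values()),
        "sum_of_squares": sigma2,
    }
    return {k: float(v) for k, v in out.items()}


def glrlm_features_bruteforce(mat: np.ndarray, n_voxels: int, n_directions: int = 1) -> dict:
    """Plain-loop evaluation of the 12 run-length formulas."""
    ng, rmax = mat.shape
    nr = mat.sum()
    mu_g = sum((g + 1) * mat[g, r] / nr for g in range(ng) for r in range(rmax))
    out = {
        "short_run_emphasis": sum(mat[g, r] / (r + 1) ** 2 for g in range(ng) for r in range(rmax)) / nr,
        "long_run_emphasis": sum(mat[g, r] * (r + 1) ** 2 for g in range(ng) for r in range(rmax)) / nr,
        "gray_level_nonuniformity": sum(mat[g, :].sum() ** 2 for g in range(ng)) / nr,
        "run_length_nonuniformity": sum(mat[:, r].sum() ** 2 for r in range(rmax)) / nr,
        "run_percentage": nr / (n_voxels * n_directions),
        "low_gray_level_run_emphasis": sum(mat[g, r] / (g + 1) ** 2 for g in range(ng) for r in range(rmax)) / nr,
        "high_gray_level_run_emphasis": sum(mat[g, r] * (g + 1) ** 2 for g in range(ng) for r in range(rmax)) / nr,
        "short_run_low_gray_level_emphasis": sum(mat[g, r] / ((g + 1) ** 2 * (r + 1) ** 2) for g in range(ng) for r in range(rmax)) / nr,
        "short_run_high_gray_level_emphasis": sum(mat[g, r] * (g + 1) ** 2 / (r + 1) ** 2 for g in range(ng) for r in range(rmax)) / nr,
        "long_run_low_gray_level_emphasis": sum(mat[g, r] * (r + 1) ** 2 / (g + 1) ** 2 for g in range(ng) for r in range(rmax)) / nr,
        "long_run_high_gray_level_emphasis": sum(mat[g, r] * (g + 1) ** 2 * (r + 1) ** 2 for g in range(ng) for r in range(rmax)) / nr,
        "gray_level_variance": sum(((g + 1) - mu_g) ** 2 * mat[g, r] / nr for g in range(ng) for r in range(rmax)),
    }
    return {k: float(v) for k, v in out.items()}
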