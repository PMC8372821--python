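"""3D gray-level co-occurrence (GLCM) and run-length (GLRLM) texture features.

Both matrix families are built inside a binary mask on the discretized
level grid, over the 13 unique 3D neighbour directions (the 26-neighbour
shell modulo negation).  GLCMs are computed at voxel distances 1, 2 and 3
with integer offset = distance x unit direction, counted symmetrically
(each pair in both orders) and normalized to sum 1.  GLRLM entries count
maximal same-level runs wholly inside the mask.

Each family is reported under two aggregations:

* ``avg``  - the feature is computed per direction and averaged over the
  13 directions (empty directional matrices are skipped);
* ``mrg``  - the directional matrices are merged (summed, renormalized
  for GLCM) and the feature computed once on the merged matrix.

The default family therefore totals 162 features:
23 GLCM features x 2 aggregations x 3 distances + 12 GLRLM features x 2.
Formulas follow the IBSI reference definitions; degenerate matrices take
defined fallbacks (0 for entropy-like, 1 for energy-like quantities)
rather than NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .discretization import DiscretizedROI

# 13 unique 3D directions: one representative per +-pair of the 26 neighbours.
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = (
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1), (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)

GLCM_FEATURE_NAMES = (
    "autocorrelation", "cluster_prominence", "cluster_shade",
    "cluster_tendency", "contrast", "correlation", "difference_average",
    "difference_entropy", "difference_variance", "joint_average",
    "joint_energy", "joint_entropy", "imc1", "imc2", "inverse_difference",
    "inverse_difference_normalized", "inverse_difference_moment",
    "inverse_difference_moment_normalized", "inverse_variance",
    "maximum_probability", "sum_average", "sum_entropy", "sum_of_squares",
)

GLRLM_FEATURE_NAMES = (
    "short_run_emphasis", "long_run_emphasis", "gray_level_nonuniformity",
    "run_length_nonuniformity", "run_percentage",
    "low_gray_level_run_emphasis", "high_gray_level_run_emphasis",
    "short_run_low_gray_level_emphasis", "short_run_high_gray_level_emphasis",
    "long_run_low_gray_level_emphasis", "long_run_high_gray_level_emphasis",
    "gray_level_variance",
)


@dataclass
class TextureConfig:
    distances: tuple[int, ...] = (1, 2, 3)
    directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_13
    aggregations: tuple[str, ...] = ("avg", "mrg")


@dataclass
class GLCM:
    """Symmetric, normalized co-occurrence matrix for one (distance, direction)."""

    matrix: np.ndarray          # (Ng, Ng) probabilities, or zeros if empty
    distance: int
    direction: tuple[int, int, int]
    empty: bool = False         # no valid voxel pair at this offset
    n_pairs: int = 0            # symmetric pair count before normalization


@dataclass
class GLRLM:
    """Run-count matrix: entry (g-1, r-1) = # maximal runs of level g, length r."""

    matrix: np.ndarray          # (Ng, Rmax) integer counts
    direction: tuple[int, int, int]
    n_voxels: int = 0           # mask voxel count (for run percentage)

    @property
    def n_runs(self) -> int:
        return int(self.matrix.sum())


def _pair_slices(offset: tuple[int, int, int], shape: tuple[int, ...]):
    """Slices (sa, sb) so that A[sa] and A[sb] are voxels x and x+offset."""
    sa, sb = [], []
    for o, n in zip(offset, shape):
        if o >= 0:
            sa.append(slice(0, n - o))
            sb.append(slice(o, n))
        else:
            sa.append(slice(-o, n))
            sb.append(slice(0, n + o))
    return tuple(sa), tuple(sb)


def compute_glcm(d: DiscretizedROI, distance: int, direction: tuple[int, int, int]) -> GLCM:
    """Co-occurrence matrix at integer offset ``distance * direction``."""
    ng = d.n_levels
    offset = tuple(int(distance) * c for c in direction)
    if any(abs(o) >= n for o, n in zip(offset, d.levels.shape)):
        return GLCM(np.zeros((ng, ng)), distance, direction, empty=True)
    sa, sb = _pair_slices(offset, d.levels.shape)
    a = d.levels[sa].ravel()
    b = d.levels[sb].ravel()
    valid = (a > 0) & (b > 0)
    a, b = a[valid], b[valid]
    if a.size == 0:
        return GLCM(np.zeros((ng, ng)), distance, direction, empty=True)
    counts = np.bincount((a - 1) * ng + (b - 1), minlength=ng * ng).reshape(ng, ng)
    counts = counts + counts.T            # symmetric: count both orders
    total = counts.sum()
    return GLCM(counts / total, distance, direction, empty=False, n_pairs=int(total))


_GLCM_GRIDS: dict[int, tuple] = {}


def _glcm_grids(ng: int):
    """Cached index grids for the diagonal-band marginals of an Ng x Ng GLCM."""
    if ng not in _GLCM_GRIDS:
        i = np.arange(1, ng + 1)
        ii, jj = np.meshgrid(i, i, indexing="ij")
        _GLCM_GRIDS[ng] = (ii, jj, np.abs(ii - jj).ravel(), (ii + jj - 2).ravel())
    return _GLCM_GRIDS[ng]


def _glcm_single(p: np.ndarray) -> dict[str, float]:
    """The 23 co-occurrence features of one normalized symmetric matrix."""
    ng = p.shape[0]
    ii, jj, diff_idx, sum_idx = _glcm_grids(ng)
    px = p.sum(axis=1)                     # marginal (symmetric: px == py)
    mu = float((ii * p).sum())             # joint average
    sigma2 = float((((ii - mu) ** 2) * p).sum())

    # diagonal-band distributions
    k_diff = np.arange(0, ng)              # |i-j|
    p_diff = np.bincount(diff_idx, weights=p.ravel(), minlength=ng)
    k_sum = np.arange(2, 2 * ng + 1)       # i+j
    p_sum = np.bincount(sum_idx, weights=p.ravel(), minlength=2 * ng - 1)

    def ent(q: np.ndarray) -> float:
        nz = q[q > 0]
        return float(-(nz * np.log2(nz)).sum()) if nz.size else 0.0

    hxy = ent(p)
    hx = ent(px)
    with np.errstate(divide="ignore", invalid="ignore"):
        pxy_outer = np.outer(px, px)
        log_outer = np.where(pxy_outer > 0, np.log2(np.where(pxy_outer > 0, pxy_outer, 1.0)), 0.0)
    hxy1 = float(-(p * log_outer).sum())
    hxy2 = ent(pxy_outer.ravel())

    da = float((p_diff * k_diff).sum())
    imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0   # HX == HY for symmetric p
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    corr = ((ii * jj * p).sum() - mu * mu) / sigma2 if sigma2 > 0 else 1.0

    off = np.abs(ii - jj) > 0
    inv_var = float((p[off] / (ii - jj)[off] ** 2).sum()) if off.any() else 0.0

    return {
        "autocorrelation": float((ii * jj * p).sum()),
        "cluster_prominence": float((((ii + jj - 2 * mu) ** 4) * p).sum()),
        "cluster_shade": float((((ii + jj - 2 * mu) ** 3) * p).sum()),
        "cluster_tendency": float((((ii + jj - 2 * mu) ** 2) * p).sum()),
        "contrast": float((((ii - jj) ** 2) * p).sum()),
        "correlation": float(corr),
        "difference_average": da,
        "difference_entropy": ent(p_diff),
        "difference_variance": float((p_diff * (k_diff - da) ** 2).sum()),
        "joint_average": mu,
        "joint_energy": float((p**2).sum()),
        "joint_entropy": hxy,
        "imc1": float(imc1),
        "imc2": imc2,
        "inverse_difference": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "inverse_difference_normalized": float((p / (1.0 + np.abs(ii - jj) / ng)).sum()),
        "inverse_difference_moment": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "inverse_difference_moment_normalized": float((p / (1.0 + (ii - jj) ** 2 / ng**2)).sum()),
        "inverse_variance": inv_var,
        "maximum_probability": float(p.max()),
        "sum_average": float((p_sum * k_sum).sum()),
        "sum_entropy": ent(p_sum),
        "sum_of_squares": sigma2,
    }


_GLCM_DEGENERATE = {
    name: (1.0 if name in ("joint_energy", "maximum_probability", "correlation",
                           "inverse_difference", "inverse_difference_normalized",
                           "inverse_difference_moment",
                           "inverse_difference_moment_normalized") else 0.0)
    for name in GLCM_FEATURE_NAMES
}


def glcm_features(glcms: list[GLCM]) -> dict[str, float]:
    """46 features for one distance: 23 formulas x {avg, mrg} aggregations."""
    live = [g for g in glcms if not g.empty]
    out: dict[str, float] = {}
    if not live:
        for agg in ("avg", "mrg"):
            for name in GLCM_FEATURE_NAMES:
                out[f"{agg}_{name}"] = _GLCM_DEGENERATE[name]
        return out
    per_dir = [_glcm_single(g.matrix) for g in live]
    for name in GLCM_FEATURE_NAMES:
        out[f"avg_{name}"] = float(np.mean([f[name] for f in per_dir]))
    merged_counts = sum(g.matrix * g.n_pairs for g in live)
    merged = merged_counts / merged_counts.sum()
    for name, value in _glcm_single(merged).items():
        out[f"mrg_{name}"] = value
    return out


def compute_glrlm(d: DiscretizedROI, direction: tuple[int, int, int]) -> GLRLM:
    """Maximal same-level runs along ``direction``, wholly inside the mask."""
    L = d.levels
    shape = np.array(L.shape)
    o = np.array(direction, dtype=np.intp)

    # run starts: in-mask voxels whose predecessor (x - o) is absent or differs
    starts = L > 0
    sa, sb = _pair_slices(tuple(direction), L.shape)
    same_as_prev = np.zeros(L.shape, dtype=bool)
    same_as_prev[sb] = (L[sb] == L[sa]) & (L[sa] > 0)
    starts = starts & ~same_as_prev

    coords = np.argwhere(starts)
    lv = L[starts]
    n_runs = len(coords)
    lengths = np.ones(n_runs, dtype=np.int64)
    act = np.arange(n_runs)
    tip = coords.copy()
    while act.size:
        tip_next = tip[act] + o
        inb = np.all((tip_next >= 0) & (tip_next < shape), axis=1)
        act = act[inb]
        tip_next = tip_next[inb]
        same = L[tip_next[:, 0], tip_next[:, 1], tip_next[:, 2]] == lv[act]
        act = act[same]
        tip[act] = tip_next[same]
        lengths[act] += 1

    n_vox = int(d.mask.sum())
    if n_runs == 0:
        return GLRLM(np.zeros((d.n_levels, 1), dtype=np.int64), direction, n_vox)
    rmax = int(lengths.max())
    mat = np.bincount(
        (lv.astype(np.int64) - 1) * rmax + (lengths - 1),
        minlength=d.n_levels * rmax,
    ).reshape(d.n_levels, rmax)
    return GLRLM(mat, direction, n_vox)


def _glrlm_single(mat: np.ndarray, n_voxels: int, n_directions: int = 1) -> dict[str, float]:
    nr = mat.sum()
    if nr == 0:
        return {name: 0.0 for name in GLRLM_FEATURE_NAMES}
    g = np.arange(1, mat.shape[0] + 1, dtype=np.float64)
    r = np.arange(1, mat.shape[1] + 1, dtype=np.float64)
    gg, rr = np.meshgrid(g, r, indexing="ij")
    m = mat.astype(np.float64)
    p = m / nr
    mu_g = float((gg * p).sum())
    return {
        "short_run_emphasis": float((m / rr**2).sum() / nr),
        "long_run_emphasis": float((m * rr**2).sum() / nr),
        "gray_level_nonuniformity": float((m.sum(axis=1) ** 2).sum() / nr),
        "run_length_nonuniformity": float((m.sum(axis=0) ** 2).sum() / nr),
        "run_percentage": float(nr / (n_voxels * n_directions)),
        "low_gray_level_run_emphasis": float((m / gg**2).sum() / nr),
        "high_gray_level_run_emphasis": float((m * gg**2).sum() / nr),
        "short_run_low_gray_level_emphasis": float((m / (gg**2 * rr**2)).sum() / nr),
        "short_run_high_gray_level_emphasis": float((m * gg**2 / rr**2).sum() / nr),
        "long_run_low_gray_level_emphasis": float((m * rr**2 / gg**2).sum() / nr),
        "long_run_high_gray_level_emphasis": float((m * gg**2 * rr**2).sum() / nr),
        "gray_level_variance": float((((gg - mu_g) ** 2) * p).sum()),
    }


def glrlm_features(glrlms: list[GLRLM]) -> dict[str, float]:
    """24 run-length features: 12 formulas x {avg, mrg} aggregations."""
    out: dict[str, float] = {}
    per_dir = [_glrlm_single(g.matrix, g.n_voxels) for g in glrlms if g.n_runs > 0]
    if not per_dir:
        for agg in ("avg", "mrg"):
            for name in GLRLM_FEATURE_NAMES:
                out[f"{agg}_{name}"] = 0.0
        return out
    for name in GLRLM_FEATURE_NAMES:
        out[f"avg_{name}"] = float(np.mean([f[name] for f in per_dir]))
    rmax = max(g.matrix.shape[1] for g in glrlms)
    ng = glrlms[0].matrix.shape[0]
    merged = np.zeros((ng, rmax), dtype=np.int64)
    for g in glrlms:
        merged[:, : g.matrix.shape[1]] += g.matrix
    for name, value in _glrlm_single(
        merged, glrlms[0].n_voxels, n_directions=len(glrlms)
    ).items():
        out[f"mrg_{name}"] = value
    return out


def texture_features(d: DiscretizedROI, cfg: TextureConfig | None = None) -> dict[str, float]:
    """The full 162-feature texture family of one discretized ROI.

    Keys: ``glcm_d<dist>_<agg>_<feature>`` and ``glrlm_<agg>_<feature>``.
    """
    cfg = cfg or TextureConfig()
    out: dict[str, float] = {}
    for dist in cfg.distances:
        glcms = [compute_glcm(d, dist, dirn) for dirn in cfg.directions]
        for key, value in glcm_features(glcms).items():
            out[f"glcm_d{dist}_{key}"] = value
    glrlms = [compute_glrlm(d, dirn) for dirn in cfg.directions]
    for key, value in glrlm_features(glrlms).items():
        out[f"glrlm_{key}"] = value
    return out
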