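"""White-stripe intensity normalization for FLAIR volumes.

The white stripe anchors normal-appearing white matter to a standard
scale: the mode of the smoothed in-brain intensity density is located,
the "stripe" is the set of voxels whose intensities fall between the
quantiles ``F(mode) - tau`` and ``F(mode) + tau`` of the in-brain
empirical distribution, and the volume is standardized as
``(I - mu_ws) / sigma_ws`` with the stripe mean and SD.

A two-contrast hybrid entry point intersects the stripes estimated on
two volumes (e.g. T1 and FLAIR); the single-contrast FLAIR stripe is
the default used by the pipeline, since only FLAIR feeds feature
extraction downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .image_io import Volume


class NormalizationError(ValueError):
    """Raised for degenerate inputs (constant image, empty brain mask)."""


@dataclass
class NormalizationConfig:
    """Stripe parameters.

    tau : half-width of the stripe as a quantile fraction (0 < tau < 0.5);
        the stripe spans the [F(mode)-tau, F(mode)+tau] quantile band.
    mode_rule : 'largest_mode' (global density maximum, FLAIR default) or
        'last_mode' (right-most local maximum, the T1 convention).
    max_kde_voxels : in-brain voxels are subsampled to this count before
        density estimation, for speed; the empirical CDF uses all voxels.
    """

    tau: float = 0.05
    mode_rule: str = "largest_mode"
    max_kde_voxels: int = 50_000
    kde_grid: int = 512

    def __post_init__(self) -> None:
        if not 0 < self.tau < 0.5:
            raise ValueError("tau must lie in (0, 0.5)")
        if self.mode_rule not in ("largest_mode", "last_mode"):
            raise ValueError("mode_rule must be 'largest_mode' or 'last_mode'")


@dataclass
class StripeStats:
    mu_ws: float
    sigma_ws: float
    stripe_mask: np.ndarray
    mode_intensity: float


def _density_mode(intensities: np.ndarray, cfg: NormalizationConfig) -> float:
    # Gaussian KDE with Scott's plug-in bandwidth on a (deterministic)
    # subsample; the mode is read off a fine grid.
    x = intensities
    if x.size > cfg.max_kde_voxels:
        idx = np.linspace(0, x.size - 1, cfg.max_kde_voxels).astype(np.intp)
        x = np.sort(x)[idx]
    kde = stats.gaussian_kde(x, bw_method="scott")
    lo, hi = float(intensities.min()), float(intensities.max())
    grid = np.linspace(lo, hi, cfg.kde_grid)
    dens = kde(grid)
    if cfg.mode_rule == "largest_mode":
        return float(grid[int(np.argmax(dens))])
    # last_mode: right-most interior local maximum (fall back to argmax)
    interior = (dens[1:-1] >= dens[:-2]) & (dens[1:-1] >= dens[2:])
    idx = np.flatnonzero(interior)
    if idx.size == 0:
        return float(grid[int(np.argmax(dens))])
    return float(grid[idx[-1] + 1])


def estimate_stripe(
    v: Volume, brain: np.ndarray, cfg: NormalizationConfig | None = None
) -> StripeStats:
    """Locate the white stripe inside ``brain`` and return its statistics."""
    cfg = cfg or NormalizationConfig()
    brain = np.asarray(brain, dtype=bool)
    if brain.shape != v.shape:
        raise ValueError("brain mask shape must match the volume")
    if not brain.any():
        raise NormalizationError("empty brain mask")
    inside = v.values[brain]
    if np.ptp(inside) == 0:
        raise NormalizationError("constant image: stripe SD undefined")

    mode = _density_mode(inside, cfg)
    # empirical CDF position of the mode, then the +-tau quantile band
    f_mode = np.searchsorted(np.sort(inside), mode, side="right") / inside.size
    q_lo, q_hi = max(f_mode - cfg.tau, 0.0), min(f_mode + cfg.tau, 1.0)
    lo, hi = np.quantile(inside, [q_lo, q_hi])
    stripe_mask = brain & (v.values >= lo) & (v.values <= hi)
    stripe = v.values[stripe_mask]
    sigma = float(stripe.std())
    if sigma == 0:
        raise NormalizationError("degenerate stripe: zero spread")
    return StripeStats(float(stripe.mean()), sigma, stripe_mask, mode)


def normalize(v: Volume, s: StripeStats) -> Volume:
    """Standardize voxelwise: ``(I - mu_ws) / sigma_ws``."""
    if s.sigma_ws <= 0:
        raise NormalizationError("sigma_ws must be positive")
    return Volume((v.values - s.mu_ws) / s.sigma_ws, v.spacing, v.affine.copy())


def whitestripe_normalize(
    v: Volume, brain: np.ndarray, cfg: NormalizationConfig | None = None
) -> tuple[Volume, StripeStats]:
    """Convenience: estimate the stripe on ``v`` and normalize it."""
    s = estimate_stripe(v, brain, cfg)
    return normalize(v, s), s


def hybrid_stripe(
    v_primary: Volume,
    v_secondary: Volume,
    brain: np.ndarray,
    cfg_primary: NormalizationConfig | None = None,
    cfg_secondary: NormalizationConfig | None = None,
) -> StripeStats:
    """Two-contrast stripe: intersect the per-contrast stripe masks and
    recompute the stripe statistics of the primary volume on the
    intersection.  Falls back to the primary stripe if the intersection
    is degenerate."""
    s1 = estimate_stripe(v_primary, brain, cfg_primary)
    s2 = estimate_stripe(v_secondary, brain, cfg_secondary)
    joint = s1.stripe_mask & s2.stripe_mask
    stripe = v_primary.values[joint]
    if stripe.size < 2 or stripe.std() == 0:
        return s1
    return StripeStats(float(stripe.mean()), float(stripe.std()), joint, s1.mode_intensity)
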