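"""Gray-level discretization of ROI intensities.

Histogram, GLCM and GLRLM features need integer gray levels.  Intensities
inside the mask are binned into ``n_bins`` equal-width levels over the
ROI's own [min, max] (fixed bin number), the common choice when inputs
are already on a standardized z-like scale after white-stripe
normalization:

    level(x) = min(N_g, floor(N_g * (I(x) - min) / (max - min)) + 1)

A constant ROI maps every voxel to level 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class DiscretizationConfig:
    n_bins: int = 32

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


@dataclass
class DiscretizedROI:
    """Integer levels 1..n_bins on a 3D grid; 0 marks voxels outside the mask."""

    levels: np.ndarray      # int grid, 0 outside mask
    mask: np.ndarray        # bool grid
    n_levels: int           # configured N_g

    @property
    def level_values(self) -> np.ndarray:
        """Levels of the masked voxels, as a flat array."""
        return self.levels[self.mask]

    def histogram(self) -> np.ndarray:
        """Counts per level 1..n_levels (sums to the mask voxel count)."""
        return np.bincount(self.level_values, minlength=self.n_levels + 1)[1:]


def discretize(
    values: np.ndarray, mask: np.ndarray, cfg: DiscretizationConfig | None = None
) -> DiscretizedROI:
    """Quantize masked intensities to integer levels 1..n_bins."""
    cfg = cfg or DiscretizationConfig()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    vals = np.asarray(values, dtype=np.float64)
    inside = vals[mask]
    lo, hi = float(inside.min()), float(inside.max())
    levels = np.zeros(mask.shape, dtype=np.int16)
    if hi == lo:
        levels[mask] = 1
    else:
        binned = np.floor(cfg.n_bins * (inside - lo) / (hi - lo)).astype(np.int16) + 1
        levels[mask] = np.minimum(binned, cfg.n_bins)
    return DiscretizedROI(levels, mask, cfg.n_bins)
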