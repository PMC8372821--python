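"""Single-level undecimated 3D wavelet decomposition and sub-band features.

The volume is separably filtered with the low-pass (L) and high-pass (H)
decomposition filters of a chosen wavelet family along each axis, with
periodic (circular) boundary handling and no decimation, yielding eight
sub-bands LLL..HHH on the original grid.  Letter k of a band name is the
filter applied along array axis k (axis 0 being the slowest axis).
Because the transform is undecimated, ROI masks carry over unchanged and
each sub-band re-enters the first-order and texture engines, giving
17 + 162 = 179 features per band and 8 x 179 = 1,432 wavelet features.

Filter taps come from PyWavelets; filtering uses a centred correlation
(``scipy.ndimage.correlate1d`` with its default origin).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy.ndimage import correlate1d

from .discretization import DiscretizationConfig, discretize
from .firstorder import firstorder_features
from .texture import TextureConfig, texture_features

BAND_NAMES = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")


@dataclass
class WaveletConfig:
    family: str = "coif1"

    def __post_init__(self) -> None:
        if self.family not in pywt.wavelist(kind="discrete"):
            raise ValueError(f"unknown wavelet family: {self.family}")


def _filters(cfg: WaveletConfig) -> tuple[np.ndarray, np.ndarray]:
    w = pywt.Wavelet(cfg.family)
    return np.asarray(w.dec_lo, dtype=np.float64), np.asarray(w.dec_hi, dtype=np.float64)


def dwt3(values: np.ndarray, cfg: WaveletConfig | None = None) -> dict[str, np.ndarray]:
    """Eight undecimated sub-bands of a 3D array, keyed LLL..HHH."""
    cfg = cfg or WaveletConfig()
    arr = np.asarray(values, dtype=np.float64)
    if arr.ndim != 3 or min(arr.shape) < 1:
        raise ValueError("dwt3 requires a non-empty 3D array")
    lo, hi = _filters(cfg)
    taps = {"L": lo, "H": hi}
    # separable cascade: 2 + 4 + 8 filtered arrays instead of 24
    stage0 = {c: correlate1d(arr, taps[c], axis=0, mode="wrap") for c in "LH"}
    stage1 = {
        c0 + c1: correlate1d(a0, taps[c1], axis=1, mode="wrap")
        for c0, a0 in stage0.items() for c1 in "LH"
    }
    return {
        name: correlate1d(stage1[name[:2]], taps[name[2]], axis=2, mode="wrap")
        for name in BAND_NAMES
    }


def wavelet_features(
    values: np.ndarray,
    mask: np.ndarray,
    wavelet_cfg: WaveletConfig | None = None,
    disc_cfg: DiscretizationConfig | None = None,
    texture_cfg: TextureConfig | None = None,
) -> dict[str, float]:
    """First-order + texture features of all 8 sub-bands within ``mask``.

    Each sub-band is discretized independently over its own ROI range.
    Keys are prefixed ``wavelet-<BAND>_<family>_...``.
    """
    out: dict[str, float] = {}
    for band, sub in dwt3(values, wavelet_cfg).items():
        d = discretize(sub, mask, disc_cfg)
        for name, value in firstorder_features(sub[mask], d).items():
            out[f"wavelet-{band}_firstorder_{name}"] = value
        for name, value in texture_features(d, texture_cfg).items():
            out[f"wavelet-{band}_{name}"] = value
    return out
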