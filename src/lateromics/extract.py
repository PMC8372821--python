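"""Full per-ROI feature extraction: the 1,618-dimensional radiomic vector.

The default vector decomposes as

* original image: 17 first-order + 7 shape + 162 texture = 186
* 8 undecimated wavelet sub-bands: (17 + 162) x 8        = 1,432

for a total of 1,618 named features.  Shape features are geometric and
only meaningful on the original grid, so they are never recomputed on
sub-bands.  Names follow ``<image>_<family>[_<dist>][_<agg>]_<feature>``
(e.g. ``original_glcm_d2_avg_contrast``, ``wavelet-HHL_firstorder_entropy``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .discretization import DiscretizationConfig, discretize
from .firstorder import (
    FIRSTORDER_NAMES,
    SHAPE_NAMES,
    firstorder_features,
    shape_features,
)
from .texture import (
    GLCM_FEATURE_NAMES,
    GLRLM_FEATURE_NAMES,
    TextureConfig,
    texture_features,
)
from .wavelet import BAND_NAMES, WaveletConfig, dwt3


@dataclass
class ExtractionConfig:
    discretization: DiscretizationConfig = field(default_factory=DiscretizationConfig)
    texture: TextureConfig = field(default_factory=TextureConfig)
    wavelet: WaveletConfig = field(default_factory=WaveletConfig)


def texture_feature_keys(cfg: TextureConfig | None = None) -> list[str]:
    cfg = cfg or TextureConfig()
    keys = [
        f"glcm_d{dist}_{agg}_{name}"
        for dist in cfg.distances
        for agg in cfg.aggregations
        for name in GLCM_FEATURE_NAMES
    ]
    keys += [f"glrlm_{agg}_{name}" for agg in cfg.aggregations for name in GLRLM_FEATURE_NAMES]
    return keys


def feature_names(cfg: ExtractionConfig | None = None) -> list[str]:
    """The canonical ordered feature-name list (length 1,618 by default)."""
    cfg = cfg or ExtractionConfig()
    tex = texture_feature_keys(cfg.texture)
    names = [f"original_firstorder_{n}" for n in FIRSTORDER_NAMES]
    names += [f"original_shape_{n}" for n in SHAPE_NAMES]
    names += [f"original_{k}" for k in tex]
    for band in BAND_NAMES:
        names += [f"wavelet-{band}_firstorder_{n}" for n in FIRSTORDER_NAMES]
        names += [f"wavelet-{band}_{k}" for k in tex]
    return names


def extract_roi_features(
    values: np.ndarray,
    mask: np.ndarray,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    cfg: ExtractionConfig | None = None,
    subbands: dict[str, np.ndarray] | None = None,
) -> dict[str, float]:
    """Extract the full feature vector for one ROI mask.

    ``subbands`` may carry a precomputed wavelet decomposition of
    ``values`` so that the (subject-level) transform is shared across
    the four ROIs of one volume.
    """
    cfg = cfg or ExtractionConfig()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    out: dict[str, float] = {}

    for name, value in shape_features(mask, spacing).items():
        out[f"original_shape_{name}"] = value

    # texture matrices only see in-mask pairs, so the grid can be cropped
    # to the mask bounding box without changing any feature value
    box = tuple(
        slice(int(idx.min()), int(idx.max()) + 1)
        for idx in np.nonzero(mask)
    )
    mask_c = mask[box]
    values_c = np.asarray(values, dtype=np.float64)[box]

    if subbands is None:
        subbands = dwt3(values, cfg.wavelet)

    d = discretize(values_c, mask_c, cfg.discretization)
    for name, value in firstorder_features(values_c[mask_c], d).items():
        out[f"original_firstorder_{name}"] = value
    for key, value in texture_features(d, cfg.texture).items():
        out[f"original_{key}"] = value

    for band in BAND_NAMES:
        sub = subbands[band][box]
        db = discretize(sub, mask_c, cfg.discretization)
        for name, value in firstorder_features(sub[mask_c], db).items():
            out[f"wavelet-{band}_firstorder_{name}"] = value
        for key, value in texture_features(db, cfg.texture).items():
            out[f"wavelet-{band}_{key}"] = value
    return out
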