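"""Volume / label-map I/O, isotropic resampling, and ROI assembly.

All downstream feature extraction happens on a single canonical grid:
volumes are resampled to isotropic voxels (1 mm by default), label maps
are resampled to the same grid with nearest-neighbour interpolation, and
the four study ROIs (left/right hippocampal, left/right extrahippocampal
temporal) are assembled from a parcellation by a label -> ROI grouping
table.

Voxel indices are 0-based; world coordinates are carried by the NIfTI
affine.  The resampled extent is ``ceil(physical extent / target)``
voxels with the origin preserved, so tissue is never cropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
from scipy import ndimage

ROI_NAMES = (
    "right_temporal",
    "right_hippocampal",
    "left_temporal",
    "left_hippocampal",
)

# Default label -> ROI grouping using FreeSurfer aseg/aparc label IDs:
# hippocampi from the subcortical segmentation, temporal neocortex from
# the Desikan/Killiany parcellation (ctx-lh-* = 1000 + index,
# ctx-rh-* = 2000 + index).
DK_TEMPORAL_GROUPING: dict[int, str] = {
    17: "left_hippocampal",   # Left-Hippocampus
    53: "right_hippocampal",  # Right-Hippocampus
    # Desikan/Killiany temporal-lobe cortical labels, left hemisphere
    1001: "left_temporal",    # bankssts
    1006: "left_temporal",    # entorhinal
    1007: "left_temporal",    # fusiform
    1009: "left_temporal",    # inferiortemporal
    1015: "left_temporal",    # middletemporal
    1016: "left_temporal",    # parahippocampal
    1030: "left_temporal",    # superiortemporal
    1033: "left_temporal",    # temporalpole
    1034: "left_temporal",    # transversetemporal
    # right hemisphere
    2001: "right_temporal",
    2006: "right_temporal",
    2007: "right_temporal",
    2009: "right_temporal",
    2015: "right_temporal",
    2016: "right_temporal",
    2030: "right_temporal",
    2033: "right_temporal",
    2034: "right_temporal",
}


class ImageIOError(Exception):
    """Base class for volume/label-map I/O failures."""


class MissingFileError(ImageIOError):
    """The requested image file does not exist."""


class NonThreeDimensionalError(ImageIOError):
    """The image on disk is not a 3D volume."""


class HeaderError(ImageIOError):
    """The image header could not be parsed."""


class GroupingError(ValueError):
    """An ROI grouping table is malformed or incomplete."""


@dataclass
class Volume:
    """A 3D intensity grid with voxel spacing and affine metadata."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError("Volume requires a non-empty 3D grid")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacings must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("Volume values must be finite")
        if self.affine is None:
            self.affine = np.diag([*self.spacing, 1.0])
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass
class LabelMap:
    """A 3D non-negative integer parcellation; 0 is background."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError("LabelMap requires a 3D grid")
        if np.any(labels < 0):
            raise ValueError("labels must be non-negative")
        self.labels = labels.astype(np.int32)
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacings must be positive")
        if self.affine is None:
            self.affine = np.diag([*self.spacing, 1.0])
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]


@dataclass
class ROIGrouping:
    """Mapping from parcellation label IDs to the four study ROI names."""

    mapping: Mapping[int, str]

    def __post_init__(self) -> None:
        mapping = {int(k): str(v) for k, v in dict(self.mapping).items()}
        bad = sorted(set(mapping.values()) - set(ROI_NAMES))
        if bad:
            raise GroupingError(f"unknown ROI names in grouping: {bad}")
        missing = sorted(set(ROI_NAMES) - set(mapping.values()))
        if missing:
            raise GroupingError(f"grouping is missing ROI names: {missing}")
        self.mapping = mapping

    @classmethod
    def default(cls) -> "ROIGrouping":
        return cls(dict(DK_TEMPORAL_GROUPING))

    @classmethod
    def from_table(cls, path: str | Path) -> "ROIGrouping":
        """Read a two-column (label_id, roi_name) whitespace/tab table."""
        mapping: dict[int, str] = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 2:
                raise GroupingError(f"malformed grouping line: {raw!r}")
            label = int(parts[0])
            if label in mapping:
                raise GroupingError(f"label {label} mapped twice")
            mapping[label] = parts[1]
        return cls(mapping)

    def to_table(self, path: str | Path) -> None:
        lines = [f"{label}\t{roi}" for label, roi in sorted(self.mapping.items())]
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class ROISet:
    """Four named binary masks aligned to one analysis grid."""

    masks: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if set(self.masks) != set(ROI_NAMES):
            raise ValueError(f"ROISet requires exactly the masks {ROI_NAMES}")
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) != 1:
            raise ValueError("ROI masks must share one grid shape")
        total = sum(int(m.sum()) for m in self.masks.values())
        union = int(np.logical_or.reduce(list(self.masks.values())).sum())
        if total != union:
            raise ValueError("ROI masks must be pairwise disjoint")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]


def read_volume(path: str | Path) -> Volume:
    """Read a 3D NIfTI volume; raises on missing files and non-3D data."""
    path = Path(path)
    if not path.exists():
        raise MissingFileError(f"no such volume: {path}")
    try:
        img = nib.load(str(path))
        zooms = img.header.get_zooms()
        data = np.asanyarray(img.dataobj)
    except MissingFileError:
        raise
    except Exception as exc:  # pragma: no cover - nibabel error variety
        raise HeaderError(f"unreadable image header in {path}: {exc}") from exc
    if data.ndim != 3:
        raise NonThreeDimensionalError(
            f"{path} holds {data.ndim}D data; a 3D volume is required"
        )
    return Volume(np.asarray(data, dtype=np.float64), tuple(zooms[:3]), np.asarray(img.affine))


def write_volume(v: Volume, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(v.values.astype(np.float32), v.affine), str(path))


def read_label_map(path: str | Path) -> LabelMap:
    path = Path(path)
    if not path.exists():
        raise MissingFileError(f"no such label map: {path}")
    try:
        img = nib.load(str(path))
        zooms = img.header.get_zooms()
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # pragma: no cover
        raise HeaderError(f"unreadable image header in {path}: {exc}") from exc
    if data.ndim != 3:
        raise NonThreeDimensionalError(
            f"{path} holds {data.ndim}D data; a 3D label map is required"
        )
    return LabelMap(np.rint(data).astype(np.int32), tuple(zooms[:3]), np.asarray(img.affine))


def write_label_map(lm: LabelMap, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(lm.labels.astype(np.int16), lm.affine), str(path))


def _resample_grid(values: np.ndarray, spacing: tuple[float, float, float],
                   target_mm: float, order: int) -> np.ndarray:
    if target_mm <= 0:
        raise ValueError("target spacing must be positive")
    in_shape = values.shape
    out_shape = tuple(
        max(1, int(np.ceil(n * s / target_mm))) for n, s in zip(in_shape, spacing)
    )
    if out_shape == in_shape and all(abs(s - target_mm) < 1e-12 for s in spacing):
        return values.copy()
    # Output voxel centre i maps to input index i * target / spacing.
    grids = np.meshgrid(
        *[np.arange(n) * target_mm / s for n, s in zip(out_shape, spacing)],
        indexing="ij",
    )
    coords = np.stack([g.reshape(-1) for g in grids])
    out = ndimage.map_coordinates(
        values.astype(np.float64), coords, order=order, mode="nearest"
    )
    return out.reshape(out_shape)


def resample_isotropic(v: Volume, target_mm: float = 1.0, mode: str = "linear") -> Volume:
    """Resample a volume to an isotropic grid (trilinear by default)."""
    if mode not in ("linear", "nearest"):
        raise ValueError("mode must be 'linear' or 'nearest'")
    order = 1 if mode == "linear" else 0
    out = _resample_grid(v.values, v.spacing, target_mm, order)
    affine = v.affine.copy()
    scale = np.array([target_mm / s for s in v.spacing])
    affine[:3, :3] = affine[:3, :3] @ np.diag(scale)
    return Volume(out, (target_mm,) * 3, affine)


def resample_label_map(lm: LabelMap, target_mm: float = 1.0) -> LabelMap:
    """Nearest-neighbour resampling; the output value set never grows."""
    out = _resample_grid(lm.labels.astype(np.float64), lm.spacing, target_mm, order=0)
    affine = lm.affine.copy()
    scale = np.array([target_mm / s for s in lm.spacing])
    affine[:3, :3] = affine[:3, :3] @ np.diag(scale)
    return LabelMap(np.rint(out).astype(np.int32), (target_mm,) * 3, affine)


def build_rois(lm: LabelMap, grouping: ROIGrouping) -> ROISet:
    """Assemble the four study masks: voxel in ROI r iff its label maps to r."""
    masks = {name: np.zeros(lm.shape, dtype=bool) for name in ROI_NAMES}
    present = np.unique(lm.labels)
    for label in present:
        if label == 0:
            continue
        roi = grouping.mapping.get(int(label))
        if roi is not None:
            masks[roi] |= lm.labels == label
    return ROISet(masks)


def brain_mask_from_labels(lm: LabelMap) -> np.ndarray:
    """Default brain mask: union of all non-background parcellation labels."""
    return lm.labels > 0
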