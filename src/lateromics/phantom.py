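"""Synthetic FLAIR-like phantom cohorts with a planted laterality effect.

No imaging data is distributed with the package, so every stage of the
pipeline is exercised on phantoms that carry the statistical structure
the analysis assumes: a brain-like ellipsoid of base tissue intensity,
mirrored ellipsoidal "hippocampi" and shell-like "temporal" regions,
spatially correlated texture (a Gaussian random field realized as
kernel-smoothed white noise, whose kernel width sets the correlation
length), plus white measurement noise.  In patients, the two ROIs of
the affected side additionally receive an intensity shift ``delta``
(in units of the background field SD) and a random field with a longer
correlation length ``ell_affected`` — altered voxel-level heterogeneity
that moves entropy- and co-occurrence-type features, emulating the
textural asymmetry the laterality models are built to detect.

Cohorts are deterministic given the spec seed and can be written to
disk as NIfTI volumes + label maps + a grouping table + a manifest CSV,
exactly the file set the CLI consumes for clinical inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .image_io import LabelMap, ROIGrouping, Volume, write_label_map, write_volume

# label IDs reuse the FreeSurfer conventions of the shipped default grouping
LEFT_HIPPO, RIGHT_HIPPO = 17, 53
LEFT_TEMP_A, LEFT_TEMP_B = 1015, 1030
RIGHT_TEMP_A, RIGHT_TEMP_B = 2015, 2030
BRAIN_FILL = 2  # white matter: in the brain mask, outside every ROI

PHANTOM_GROUPING = ROIGrouping({
    LEFT_HIPPO: "left_hippocampal",
    RIGHT_HIPPO: "right_hippocampal",
    LEFT_TEMP_A: "left_temporal",
    LEFT_TEMP_B: "left_temporal",
    RIGHT_TEMP_A: "right_temporal",
    RIGHT_TEMP_B: "right_temporal",
})


@dataclass
class PhantomSpec:
    """Parameters of the synthetic cohort.

    delta : affected-side intensity shift in units of ``noise_sd``.
    ell_null / ell_affected : correlation length (mm) of the smoothed
        random field in normal vs affected tissue.
    noise_sd : marginal SD of the correlated field (intensity units).
    white_sd : SD of the additional iid voxel noise.
    """

    n_patients: int = 20
    n_controls: int = 20
    shape: tuple[int, int, int] = (64, 64, 48)
    spacing: float = 1.0
    base_intensity: float = 100.0
    roi_boost: float = 5.0          # ROIs slightly brighter than white matter
    delta: float = 2.0
    ell_null: float = 1.0
    ell_affected: float = 3.0
    noise_sd: float = 5.0
    white_sd: float = 1.0
    p_left_affected: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_controls < 1:
            raise ValueError("cohort counts must be >= 1")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if min(self.shape) < 24:
            raise ValueError("phantom grid too small for the ROI geometry")


@dataclass
class PhantomSubject:
    subject_id: str
    volume: Volume
    label_map: LabelMap
    group: str                       # 'patient' | 'control'
    affected_side: str | None = None # patients only


@dataclass
class PhantomCohort:
    subjects: list[PhantomSubject]
    grouping: ROIGrouping
    spec: PhantomSpec


def _ellipsoid(shape, center, semi) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    acc = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, semi))
    return acc <= 1.0


def phantom_label_map(spec: PhantomSpec) -> LabelMap:
    """The mirrored parcellation shared by every phantom subject.

    Axis 0 is left-right; the right-hemisphere masks are the mirror
    image of the left across the axis-0 midplane.
    """
    nx, ny, nz = spec.shape
    cy, cz = ny / 2 - 0.5, nz / 2 - 0.5
    scale = min(nx, ny, nz) / 48.0  # geometry scales with the grid

    labels = np.zeros(spec.shape, dtype=np.int32)

    brain = _ellipsoid(spec.shape, (nx / 2 - 0.5, cy, cz),
                       (nx * 0.46, ny * 0.46, nz * 0.46))
    labels[brain] = BRAIN_FILL

    hip_center = (nx * 0.30, cy, cz)
    hip = _ellipsoid(spec.shape, hip_center, (4 * scale, 6 * scale, 4 * scale))
    outer = _ellipsoid(spec.shape, hip_center, (9 * scale, 12 * scale, 8.5 * scale))
    inner = _ellipsoid(spec.shape, hip_center, (6 * scale, 8.5 * scale, 6 * scale))
    shell = outer & ~inner & brain

    left_temp_a = shell & (np.arange(ny)[None, :, None] < cy)
    left_temp_b = shell & ~left_temp_a

    labels[shell] = 0
    labels[left_temp_a] = LEFT_TEMP_A
    labels[left_temp_b] = LEFT_TEMP_B
    labels[hip] = LEFT_HIPPO

    # mirror the left-hemisphere structures onto the right
    flipped = np.flip(labels, axis=0)
    right = {LEFT_HIPPO: RIGHT_HIPPO, LEFT_TEMP_A: RIGHT_TEMP_A,
             LEFT_TEMP_B: RIGHT_TEMP_B}
    for left_label, right_label in right.items():
        labels[flipped == left_label] = right_label
    return LabelMap(labels, (spec.spacing,) * 3)


def _smooth_field(white: np.ndarray, ell: float, sd: float) -> np.ndarray:
    field = gaussian_filter(white, sigma=ell, mode="wrap") if ell > 0 else white
    s = field.std()
    return field * (sd / s if s > 0 else 1.0)


def make_subject(
    spec: PhantomSpec,
    labels: LabelMap,
    rng: np.random.Generator,
    subject_id: str,
    group: str,
    affected_side: str | None,
) -> PhantomSubject:
    brain = labels.labels > 0
    roi = (labels.labels != BRAIN_FILL) & brain
    values = np.zeros(spec.shape)
    values[brain] = spec.base_intensity
    values[roi] += spec.roi_boost

    # one white-noise draw feeds both correlation lengths, so with
    # delta=0 and ell_affected == ell_null a "patient" is voxelwise
    # identical to a control: the null cohort is exact, with no seam
    # artifact at the affected-ROI boundary
    white = rng.standard_normal(spec.shape)
    field = _smooth_field(white, spec.ell_null, spec.noise_sd)
    if affected_side is not None:
        side_labels = (
            (LEFT_HIPPO, LEFT_TEMP_A, LEFT_TEMP_B)
            if affected_side == "left"
            else (RIGHT_HIPPO, RIGHT_TEMP_A, RIGHT_TEMP_B)
        )
        aff = np.isin(labels.labels, side_labels)
        aff_field = _smooth_field(white, spec.ell_affected, spec.noise_sd)
        field[aff] = aff_field[aff]
        values[aff] += spec.delta * spec.noise_sd
    values += field

    values += rng.standard_normal(spec.shape) * spec.white_sd
    vol = Volume(values, (spec.spacing,) * 3)
    return PhantomSubject(subject_id, vol, labels, group, affected_side)


def make_cohort(spec: PhantomSpec) -> PhantomCohort:
    """Generate the full phantom cohort, deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    labels = phantom_label_map(spec)
    subjects: list[PhantomSubject] = []
    for i in range(spec.n_patients):
        side = "left" if rng.random() < spec.p_left_affected else "right"
        subjects.append(
            make_subject(spec, labels, rng, f"patient{i:03d}", "patient", side)
        )
    for i in range(spec.n_controls):
        subjects.append(
            make_subject(spec, labels, rng, f"control{i:03d}", "control", None)
        )
    return PhantomCohort(subjects, PHANTOM_GROUPING, spec)


def write_cohort(cohort: PhantomCohort, out_dir: str | Path) -> pd.DataFrame:
    """Write NIfTI volumes/label maps, the grouping table and a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.grouping.to_table(out / "grouping.tsv")
    rows = []
    for s in cohort.subjects:
        vol_path = out / f"{s.subject_id}_flair.nii.gz"
        lab_path = out / f"{s.subject_id}_labels.nii.gz"
        write_volume(s.volume, vol_path)
        write_label_map(s.label_map, lab_path)
        rows.append({
            "subject_id": s.subject_id,
            "group": s.group,
            "affected_side": s.affected_side or "",
            "volume": vol_path.name,
            "labels": lab_path.name,
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def make_toy_fixtures() -> dict[str, np.ndarray]:
    """Small deterministic arrays shared by the texture/wavelet oracles."""
    checker = np.indices((4, 4, 4)).sum(axis=0) % 2 + 1
    rng = np.random.default_rng(7)
    return {
        "constant": np.full((3, 3, 3), 5.0),
        "checkerboard": checker.astype(np.int16),
        "strip": np.array([1, 1, 1, 2, 2], dtype=np.int16).reshape(5, 1, 1),
        "random_levels": rng.integers(1, 5, size=(5, 5, 5)).astype(np.int16),
        "random_volume": rng.standard_normal((4, 4, 4)),
    }
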