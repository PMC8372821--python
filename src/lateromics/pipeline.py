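"""Stage orchestration: simulate -> extract -> train -> evaluate.

These functions are the library behind the command-line interface; each
consumes only the declared artifacts of the previous stage (files or
in-memory tables), so a run is reproducible from its config and seeds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .enet import EnetConfig, EnetModel, cv_tune
from .evaluation import ROCResult, evaluate_scores, laterality_call
from .extract import ExtractionConfig, extract_roi_features, feature_names
from .image_io import (
    LabelMap,
    ROIGrouping,
    Volume,
    brain_mask_from_labels,
    build_rois,
    read_label_map,
    read_volume,
    resample_isotropic,
    resample_label_map,
)
from .phantom import PhantomCohort, PhantomSpec, make_cohort, write_cohort
from .selection import (
    DESIGNS,
    SelectionResult,
    Standardizer,
    build_design,
    feature_columns,
    select_features,
)
from .wavelet import dwt3
from .whitestripe import NormalizationConfig, whitestripe_normalize

ROI_TO_ROW = {
    "left_hippocampal": ("left", "hippocampal"),
    "right_hippocampal": ("right", "hippocampal"),
    "left_temporal": ("left", "temporal"),
    "right_temporal": ("right", "temporal"),
}


@dataclass
class PipelineConfig:
    """Validated bundle of every stage's parameters."""

    target_mm: float = 1.0
    normalization: NormalizationConfig = field(default_factory=NormalizationConfig)
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    enet: EnetConfig = field(default_factory=EnetConfig)
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    design: str = "H_minus"
    q_threshold: float = 0.05
    control_side_seed: int = 0
    n_boot: int = 2000
    eval_seed: int = 0

    def __post_init__(self) -> None:
        if self.target_mm <= 0:
            raise ValueError("target_mm must be positive")
        if self.design not in DESIGNS:
            raise ValueError(f"design must be one of {sorted(DESIGNS)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        def build(klass, data):
            if not isinstance(data, dict):
                raise ValueError(f"expected a mapping for {klass.__name__}")
            names = {f.name for f in dataclasses.fields(klass)}
            unknown = set(data) - names
            if unknown:
                raise ValueError(f"unknown {klass.__name__} keys: {sorted(unknown)}")
            kwargs = {}
            for f in dataclasses.fields(klass):
                if f.name not in data:
                    continue
                val = data[f.name]
                if isinstance(val, dict):
                    factory = f.default_factory
                    if factory is dataclasses.MISSING:
                        raise ValueError(f"{f.name} does not take a mapping")
                    val = build(type(factory()), val)
                elif isinstance(val, list):
                    val = tuple(tuple(v) if isinstance(v, list) else v for v in val)
                kwargs[f.name] = val
            return klass(**kwargs)

        return build(cls, raw)


def simulate(cfg: PipelineConfig, out_dir: str | Path) -> pd.DataFrame:
    """Write a phantom cohort to ``out_dir``; fails before writing on a
    bad spec (spec validation happens at construction)."""
    cohort = make_cohort(cfg.phantom)
    return write_cohort(cohort, out_dir)


def extract_subject(
    volume: Volume,
    labels: LabelMap,
    grouping: ROIGrouping,
    cfg: PipelineConfig,
) -> dict[str, dict[str, float]]:
    """Resample, normalize, assemble ROIs and extract all four vectors."""
    vol = resample_isotropic(volume, cfg.target_mm, mode="linear")
    lab = resample_label_map(labels, cfg.target_mm)
    if lab.shape != vol.shape:
        raise ValueError("volume and label map disagree after resampling")
    brain = brain_mask_from_labels(lab)
    norm, _ = whitestripe_normalize(vol, brain, cfg.normalization)
    rois = build_rois(lab, grouping)
    subbands = dwt3(norm.values, cfg.extraction.wavelet)
    out = {}
    for roi_name, mask in rois.masks.items():
        if not mask.any():
            continue
        out[roi_name] = extract_roi_features(
            norm.values, mask, norm.spacing, cfg.extraction, subbands=subbands
        )
    return out


def extract_cohort(cohort: PhantomCohort, cfg: PipelineConfig) -> pd.DataFrame:
    """Feature table of an in-memory cohort: one row per (subject, side, roi)."""
    rows = []
    for s in cohort.subjects:
        per_roi = extract_subject(s.volume, s.label_map, cohort.grouping, cfg)
        for roi_name, feats in per_roi.items():
            side, roi = ROI_TO_ROW[roi_name]
            rows.append({
                "subject_id": s.subject_id, "group": s.group, "side": side,
                "roi": roi, "affected_side": s.affected_side or "", **feats,
            })
    return pd.DataFrame(rows)


def extract_directory(
    cohort_dir: str | Path,
    cfg: PipelineConfig,
    on_error: str = "raise",
) -> tuple[pd.DataFrame, list[dict]]:
    """Feature table from an on-disk cohort (manifest + NIfTI + grouping).

    With ``on_error='skip'`` a failing subject is recorded in the
    returned failure list and the rest of the cohort still extracts.
    """
    if on_error not in ("raise", "skip"):
        raise ValueError("on_error must be 'raise' or 'skip'")
    cohort_dir = Path(cohort_dir)
    manifest = pd.read_csv(cohort_dir / "manifest.csv", keep_default_na=False)
    grouping = ROIGrouping.from_table(cohort_dir / "grouping.tsv")
    rows = []
    failures: list[dict] = []
    for _, rec in manifest.iterrows():
        try:
            vol = read_volume(cohort_dir / rec["volume"])
            lab = read_label_map(cohort_dir / rec["labels"])
            per_roi = extract_subject(vol, lab, grouping, cfg)
        except Exception as exc:
            if on_error == "raise":
                raise
            failures.append({"subject_id": rec["subject_id"], "error": str(exc)})
            continue
        for roi_name, feats in per_roi.items():
            side, roi = ROI_TO_ROW[roi_name]
            rows.append({
                "subject_id": rec["subject_id"], "group": rec["group"],
                "side": side, "roi": roi,
                "affected_side": rec.get("affected_side", "") or "", **feats,
            })
    return pd.DataFrame(rows), failures


@dataclass
class TrainedModel:
    model: EnetModel
    selection: SelectionResult
    design: str


def train(table: pd.DataFrame, cfg: PipelineConfig) -> TrainedModel:
    """Filter (t-test + BH) then tune/fit the elastic-net laterality model."""
    X, y = build_design(table, cfg.design, cfg.control_side_seed)
    selection = select_features(X, y, cfg.q_threshold)
    kept = selection.selected
    if not kept:
        # no feature survives filtering: fall back to all finite-variance
        # features so training still completes (model may be intercept-only)
        kept = feature_columns(X)
    std = Standardizer.fit(X, kept)
    Z = std.transform(X)
    model, curve = cv_tune(Z, y, cfg.enet)
    model.standardizer = std
    model.meta.update({
        "design": cfg.design,
        "n_filtered": len(selection.selected),
        "n_selected": len(model.selected_features),
    })
    return TrainedModel(model, selection, cfg.design)


def design_scores(
    model: EnetModel, table: pd.DataFrame, design: str, control_side_seed: int = 0
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Model scores and labels for a design's rows of a feature table."""
    X, y = build_design(table, design, control_side_seed)
    scores = np.asarray(model.predict_score(X))
    return scores, y, X


def evaluate(
    trained: TrainedModel, table: pd.DataFrame, cfg: PipelineConfig
) -> tuple[ROCResult, pd.DataFrame]:
    """ROC evaluation on side-level samples plus per-patient laterality calls."""
    scores, y, X = design_scores(
        trained.model, table, trained.design, cfg.control_side_seed
    )
    roc = evaluate_scores(scores, y, n_boot=cfg.n_boot, seed=cfg.eval_seed)

    roi = DESIGNS[trained.design]
    calls = []
    patients = table[(table["group"] == "patient") & (table["roi"] == roi)]
    for sid, grp in patients.groupby("subject_id", sort=True):
        sides = {row["side"]: row for _, row in grp.iterrows()}
        if not {"left", "right"} <= set(sides):
            continue
        call = laterality_call(trained.model, sides["left"], sides["right"])
        calls.append({
            "subject_id": sid,
            "called_side": call,
            "affected_side": grp["affected_side"].iloc[0],
            "correct": call == grp["affected_side"].iloc[0],
        })
    return roc, pd.DataFrame(calls)


def expected_feature_count(cfg: PipelineConfig | None = None) -> int:
    cfg = cfg or PipelineConfig()
    return len(feature_names(cfg.extraction))
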