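"""Contrast construction, univariate filtering with BH FDR, standardization.

A feature table holds one row per (subject, side, roi) with metadata
columns ``subject_id, group, side, roi`` followed by feature columns.
Two laterality contrasts are supported, mirroring a case-control design
with 36 patients and 50 controls (36 positives vs 86 negatives):

* ``H_plus``  - hippocampal ROI rows: affected-side rows of patients are
  positives; unaffected-side patient rows plus one randomly chosen side
  per control are negatives.
* ``H_minus`` - the same construction on the extrahippocampal temporal ROI.

Filtering uses an independent two-sample (pooled-variance) Student t
test per feature with Benjamini-Hochberg step-up adjustment; features
passing q < 0.05 proceed to the penalized model.  Standardization
statistics are estimated on the training rows only and stored so that
validation data is transformed with the training statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

METADATA_COLUMNS = ("subject_id", "group", "side", "roi")
DESIGNS = {"H_plus": "hippocampal", "H_minus": "temporal"}


class DesignError(ValueError):
    """Raised when a contrast cannot be built from the table."""


def feature_columns(table: pd.DataFrame) -> list[str]:
    extra = set(METADATA_COLUMNS) | {"affected_side", "label"}
    return [c for c in table.columns if c not in extra]


def build_design(
    table: pd.DataFrame, design: str, control_side_seed: int = 0
) -> tuple[pd.DataFrame, np.ndarray]:
    """Assemble the (X, y) contrast for one design.

    Patients must carry an ``affected_side`` annotation; each control
    contributes exactly one hemisphere, chosen uniformly at random with
    the given seed (the choice is deterministic per seed).
    Returns the feature matrix X (with metadata columns retained) and
    the binary label vector y (1 = affected side).
    """
    if design not in DESIGNS:
        raise DesignError(f"design must be one of {sorted(DESIGNS)}")
    roi = DESIGNS[design]
    sub = table[table["roi"] == roi]
    rng = np.random.default_rng(control_side_seed)

    rows: list[pd.DataFrame] = []
    labels: list[int] = []
    patients = sub[sub["group"] == "patient"]
    for sid, grp in patients.groupby("subject_id", sort=True):
        affected = grp["affected_side"].iloc[0]
        if affected not in ("left", "right") or pd.isna(affected):
            raise DesignError(f"patient {sid} lacks an affected-side annotation")
        for _, row in grp.iterrows():
            rows.append(row.to_frame().T)
            labels.append(1 if row["side"] == affected else 0)
    controls = sub[sub["group"] == "control"]
    for sid, grp in controls.groupby("subject_id", sort=True):
        side = rng.choice(sorted(grp["side"].unique()))
        row = grp[grp["side"] == side].iloc[0]
        rows.append(row.to_frame().T)
        labels.append(0)
    if not rows:
        raise DesignError(f"no rows for design {design}")
    X = pd.concat(rows, ignore_index=True)
    return X, np.asarray(labels, dtype=int)


def student_t(x1: np.ndarray, x0: np.ndarray) -> tuple[float, float]:
    """Two-sided pooled-variance two-sample t test."""
    x1 = np.asarray(x1, dtype=float)
    x0 = np.asarray(x0, dtype=float)
    if len(x1) < 2 or len(x0) < 2:
        raise ValueError("both groups need at least 2 values")
    n1, n0 = len(x1), len(x0)
    df = n1 + n0 - 2
    sp2 = ((n1 - 1) * x1.var(ddof=1) + (n0 - 1) * x0.var(ddof=1)) / df
    if sp2 == 0:
        return (0.0, 1.0) if x1.mean() == x0.mean() else (np.inf, 0.0)
    t = (x1.mean() - x0.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n0))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def bh_fdr(p: np.ndarray, q_threshold: float = 0.05) -> pd.DataFrame:
    """Benjamini-Hochberg step-up adjustment.

    Returns a frame with columns ``p, q, passed`` in input order;
    ``q_i = min_{j >= rank(i)} m * p_(j) / j`` capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return pd.DataFrame({"p": p, "q": q, "passed": q < q_threshold})


@dataclass
class SelectionResult:
    """Per-feature filtering outcome for one contrast."""

    table: pd.DataFrame  # index = feature name; columns t, p, q, passed

    @property
    def selected(self) -> list[str]:
        return list(self.table.index[self.table["passed"]])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="feature")


def select_features(
    X: pd.DataFrame, y: np.ndarray, q_threshold: float = 0.05
) -> SelectionResult:
    """t-test every feature column and apply BH FDR at ``q_threshold``."""
    feats = feature_columns(X)
    y = np.asarray(y)
    vals = X[feats].to_numpy(dtype=float)
    x1, x0 = vals[y == 1], vals[y == 0]
    results = np.array([student_t(x1[:, j], x0[:, j]) for j in range(len(feats))])
    bh = bh_fdr(results[:, 1], q_threshold)
    out = pd.DataFrame(
        {"t": results[:, 0], "p": bh["p"].to_numpy(), "q": bh["q"].to_numpy(),
         "passed": bh["passed"].to_numpy()},
        index=pd.Index(feats, name="feature"),
    )
    return SelectionResult(out)


@dataclass
class Standardizer:
    """Column-wise z-scoring with statistics frozen on the fit rows."""

    means: pd.Series
    sds: pd.Series
    dropped: list[str]

    @classmethod
    def fit(cls, X: pd.DataFrame, columns: list[str] | None = None) -> "Standardizer":
        cols = columns if columns is not None else feature_columns(X)
        vals = X[cols].astype(float)
        means = vals.mean()
        sds = vals.std(ddof=0)
        dropped = list(sds.index[sds == 0])
        keep = [c for c in cols if c not in dropped]
        return cls(means[keep], sds[keep], dropped)

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        cols = list(self.means.index)
        return (X[cols].astype(float) - self.means) / self.sds
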