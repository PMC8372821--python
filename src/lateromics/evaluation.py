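"""ROC/AUC evaluation, Youden threshold, bootstrap CIs, laterality calls.

AUC is the Mann-Whitney probability that a random positive scores above
a random negative (ties count 1/2).  The operating threshold maximizes
sensitivity + specificity (the Youden criterion) over midpoints between
adjacent distinct scores, calling a sample positive when score >=
threshold; ties prefer the lowest such threshold.  Confidence intervals
are stratified percentile bootstrap (resampling positives and negatives
separately), 2,000 replicates by default.  Per-patient laterality is the
hemisphere with the larger model score.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

from .enet import EnetModel


@dataclass
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    threshold: float
    sensitivity: float
    specificity: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("both classes must be present")
    return labels


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC: fraction of correctly ordered (pos, neg) pairs."""
    labels = _check_labels(labels)
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def youden_threshold(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[float, float, float]:
    """Threshold maximizing sensitivity + specificity; positive iff score >= t.

    Candidates are midpoints between adjacent distinct scores (lowest
    maximizer wins).  A single distinct score yields that score itself.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_labels(labels)
    distinct = np.unique(scores)
    if distinct.size == 1:
        candidates = distinct
    else:
        candidates = (distinct[:-1] + distinct[1:]) / 2.0
    pos = labels == 1
    best = (-np.inf, np.nan, np.nan, np.nan)
    for t in candidates:
        call = scores >= t
        sens = float(call[pos].mean())
        spec = float((~call[~pos]).mean())
        if sens + spec > best[0] + 1e-12:
            best = (sens + spec, t, sens, spec)
    return best[1], best[2], best[3]


def auc_ci(
    scores: np.ndarray,
    labels: np.ndarray,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Stratified percentile bootstrap 95% CI for the AUC."""
    if n_boot < 1000:
        raise ValueError("n_boot must be >= 1000")
    scores = np.asarray(scores, dtype=float)
    labels = _check_labels(labels)
    rng = np.random.default_rng(seed)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    n1, n0 = len(pos), len(neg)
    # all resamples at once; AUC per row via the rank-sum identity
    # (average ranks make ties count 1/2, matching the Mann-Whitney AUC)
    sp = rng.choice(pos, size=(n_boot, n1), replace=True)
    sn = rng.choice(neg, size=(n_boot, n0), replace=True)
    ranks = stats.rankdata(np.concatenate([sp, sn], axis=1), axis=1)
    aucs = (ranks[:, :n1].sum(axis=1) - n1 * (n1 + 1) / 2) / (n1 * n0)
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return float(lo), float(hi)


def evaluate_scores(
    scores: np.ndarray, labels: np.ndarray, n_boot: int = 2000, seed: int = 0
) -> ROCResult:
    """AUC with bootstrap CI plus the Youden operating point."""
    auc = roc_auc(scores, labels)
    lo, hi = auc_ci(scores, labels, n_boot=n_boot, seed=seed)
    t, sens, spec = youden_threshold(scores, labels)
    return ROCResult(auc, lo, hi, t, sens, spec)


def laterality_call(model: EnetModel, left_features, right_features) -> str:
    """Side with the larger laterality score; exact ties are indeterminate."""
    left = model.predict_score(left_features)
    right = model.predict_score(right_features)
    if left > right:
        return "left"
    if right > left:
        return "right"
    return "indeterminate"
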