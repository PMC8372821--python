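"""Repeatable simulation studies exercising the full pipeline.

These are the package's own benchmark experiments: end-to-end phantom
laterality recovery (train on one cohort, evaluate on an independently
generated one), the false-discovery behaviour of the BH filter under a
global null, and planted-feature recovery by the tuned elastic net.
Problem sizes default to values that keep a full study in the
several-minute range on one CPU; every function is deterministic given
its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enet import EnetConfig, cv_tune
from .evaluation import roc_auc
from .phantom import PhantomSpec, make_cohort
from .pipeline import PipelineConfig, design_scores, extract_cohort, train
from .selection import bh_fdr, student_t

# a CV budget sized for repeated small-cohort studies; the full default
# grid (21 alphas x 100 lambdas) is for one-shot analyses
FAST_ENET = dict(alpha_grid=(0.5,), n_lambda=10, lambda_decades=2.0,
                 k_folds=10, fold_seed=0, tol=1e-3, max_iter=500)

STUDY_SHAPE = (40, 40, 28)


@dataclass
class EndToEndResult:
    heldout_auc: float
    laterality_accuracy: float
    n_filtered: int
    n_selected: int


def _study_config(delta: float, ell_affected: float, seed: int,
                  n_patients: int, n_controls: int) -> PipelineConfig:
    cfg = PipelineConfig()
    cfg.phantom = PhantomSpec(
        n_patients=n_patients, n_controls=n_controls, shape=STUDY_SHAPE,
        delta=delta, ell_affected=ell_affected, seed=seed,
    )
    cfg.enet = EnetConfig(**FAST_ENET)
    cfg.n_boot = 1000
    return cfg


def end_to_end_study(
    delta: float,
    ell_affected: float,
    seed: int,
    n_patients: int = 8,
    n_controls: int = 8,
    design: str = "H_minus",
) -> EndToEndResult:
    """Train on one phantom cohort, evaluate on an independent one.

    The held-out cohort is generated from the same spec with a shifted
    seed, so no image or subject is shared between fitting and testing.
    """
    cfg = _study_config(delta, ell_affected, seed, n_patients, n_controls)
    cfg.design = design
    table = extract_cohort(make_cohort(cfg.phantom), cfg)
    trained = train(table, cfg)

    test_spec = PhantomSpec(
        n_patients=n_patients, n_controls=n_controls, shape=STUDY_SHAPE,
        delta=delta, ell_affected=ell_affected, seed=seed + 104729,
    )
    test_table = extract_cohort(make_cohort(test_spec), cfg)
    scores, y, _ = design_scores(trained.model, test_table, design,
                                 cfg.control_side_seed)
    auc = roc_auc(scores, y)

    from .pipeline import evaluate
    _, calls = evaluate(trained, test_table, cfg)
    acc = float(calls["correct"].mean()) if len(calls) else float("nan")
    return EndToEndResult(auc, acc,
                          trained.model.meta["n_filtered"],
                          trained.model.meta["n_selected"])


def bh_null_false_discovery(
    n_replicates: int = 200,
    n_features: int = 200,
    n_per_group: int = 20,
    q_threshold: float = 0.05,
    seed: int = 0,
) -> float:
    """Realized false-discovery fraction of the t-test + BH filter when
    every feature is exchangeable between groups (mean of FP/max(R,1))."""
    rng = np.random.default_rng(seed)
    fdp = np.empty(n_replicates)
    for r in range(n_replicates):
        x1 = rng.normal(size=(n_per_group, n_features))
        x0 = rng.normal(size=(n_per_group, n_features))
        pvals = np.array([
            student_t(x1[:, j], x0[:, j])[1] for j in range(n_features)
        ])
        res = bh_fdr(pvals, q_threshold)
        n_pass = int(res["passed"].sum())
        fdp[r] = n_pass / max(n_pass, 1)  # all discoveries are false here
    return float(fdp.mean())


def enet_planted_recovery(
    n_replicates: int = 25,
    n_samples: int = 200,
    n_features: int = 50,
    n_planted: int = 5,
    effect: float = 1.0,
    min_found: int = 4,
    seed: int = 0,
) -> float:
    """Fraction of replicates in which the CV-tuned elastic net keeps at
    least ``min_found`` of the planted signal features."""
    cfg = EnetConfig(alpha_grid=(0.5, 0.9), n_lambda=12, lambda_decades=3.0,
                     k_folds=10, fold_seed=0, tol=1e-3, max_iter=500)
    hits = 0
    for rep in range(n_replicates):
        rng = np.random.default_rng(seed + rep)
        X = rng.normal(size=(n_samples, n_features))
        beta = np.zeros(n_features)
        beta[:n_planted] = effect
        p = 1.0 / (1.0 + np.exp(-(X @ beta)))
        y = (rng.random(n_samples) < p).astype(int)
        if y.sum() < 2 or y.sum() > n_samples - 2:
            continue
        Z = (X - X.mean(axis=0)) / X.std(axis=0)
        names = [f"f{j}" for j in range(n_features)]
        model, _ = cv_tune(pd.DataFrame(Z, columns=names), y, cfg)
        found = sum(f"f{j}" in set(model.selected_features)
                    for j in range(n_planted))
        hits += found >= min_found
    return hits / n_replicates
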