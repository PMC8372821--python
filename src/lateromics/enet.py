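"""Elastic-net penalized logistic regression for the laterality score.

The model minimizes the glmnet-style objective

    -(1/n) sum_i [y_i log p_i + (1-y_i) log(1-p_i)]
        + lambda * [ (1-alpha)/2 ||beta||_2^2 + alpha ||beta||_1 ]

with p = logistic(beta0 + beta^T z) on standardized features and an
unpenalized intercept.  alpha in [0, 1] blends ridge (0) and lasso (1);
lambda sets the penalty strength.  Hyperparameters are tuned by
stratified k-fold cross-validation (k = 10 by default) minimizing the
mean squared error between predicted probability and the 0/1 label,
with ties broken toward the sparser model (larger lambda, then larger
alpha).  Optimization is delegated to scikit-learn's saga solver with
``C = 1 / (n * lambda)`` and ``l1_ratio = alpha``.

The fitted model — standardization statistics, coefficients and the
chosen (alpha, lambda) — is the laterality score and serializes to JSON.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .selection import Standardizer


@dataclass
class EnetConfig:
    """Hyperparameter search space and CV settings."""

    alpha_grid: tuple[float, ...] = tuple(np.round(np.arange(0.0, 1.0001, 0.05), 2))
    n_lambda: int = 100
    lambda_decades: float = 4.0
    k_folds: int = 10
    fold_seed: int = 0
    tol: float = 1e-4
    max_iter: int = 2000

    def __post_init__(self) -> None:
        if any(a < 0 or a > 1 for a in self.alpha_grid):
            raise ValueError("alpha grid must lie in [0, 1]")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")


@dataclass
class EnetModel:
    """A fitted laterality score: logistic(beta0 + beta^T z)."""

    intercept: float
    coef: pd.Series                 # indexed by standardized feature name
    alpha: float
    lam: float
    standardizer: Standardizer | None = None
    meta: dict = field(default_factory=dict)

    @property
    def selected_features(self) -> list[str]:
        return list(self.coef.index[self.coef != 0])

    def score_standardized(self, Z: np.ndarray | pd.DataFrame) -> np.ndarray:
        z = np.asarray(Z, dtype=float)
        lin = self.intercept + z @ self.coef.to_numpy()
        return 1.0 / (1.0 + np.exp(-lin))

    def predict_score(self, x_raw: pd.DataFrame | pd.Series | dict) -> np.ndarray | float:
        """Apply stored standardization, then the logistic score.

        Accepts a DataFrame (batch), or a Series/dict (single sample,
        returns a scalar).  Raises KeyError if a model feature is absent.
        """
        if self.standardizer is None:
            raise ValueError("model carries no standardization statistics")
        single = not isinstance(x_raw, pd.DataFrame)
        frame = pd.DataFrame([x_raw]) if single else x_raw
        missing = [c for c in self.standardizer.means.index if c not in frame.columns]
        if missing:
            raise KeyError(f"missing model features: {missing[:5]}")
        z = self.standardizer.transform(frame).to_numpy()
        p = self.score_standardized(z)
        return float(p[0]) if single else p

    def to_json(self, path: str | Path) -> None:
        payload = {
            "intercept": self.intercept,
            "alpha": self.alpha,
            "lambda": self.lam,
            "features": list(self.coef.index),
            "coef": [float(c) for c in self.coef],
            "meta": self.meta,
        }
        if self.standardizer is not None:
            payload["standardization"] = {
                "means": [float(v) for v in self.standardizer.means],
                "sds": [float(v) for v in self.standardizer.sds],
                "dropped": list(self.standardizer.dropped),
            }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "EnetModel":
        payload = json.loads(Path(path).read_text())
        feats = payload["features"]
        std = None
        if "standardization" in payload:
            s = payload["standardization"]
            std = Standardizer(
                pd.Series(s["means"], index=feats),
                pd.Series(s["sds"], index=feats),
                list(s["dropped"]),
            )
        return cls(
            float(payload["intercept"]),
            pd.Series(payload["coef"], index=feats, dtype=float),
            float(payload["alpha"]),
            float(payload["lambda"]),
            std,
            payload.get("meta", {}),
        )


def _check_xy(Z: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("y must contain both classes (0 and 1)")
    return Z, y


def _refine_intercept(b0: float, lin: np.ndarray, y: np.ndarray) -> float:
    """Newton steps on the unpenalized intercept with coefficients fixed.

    The saga solver's stopping rule can leave the intercept short of its
    optimum when the penalty dominates (tiny C); given fixed beta the
    intercept sub-problem is 1-D, smooth and convex, so polish it.
    """
    for _ in range(50):
        p = 1.0 / (1.0 + np.exp(-(b0 + lin)))
        grad = float(np.mean(p - y))
        hess = float(np.mean(p * (1 - p)))
        if hess <= 0 or abs(grad) < 1e-12:
            break
        b0 -= grad / hess
    return b0


def fit_enet(
    Z: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    alpha: float,
    lam: float,
    cfg: EnetConfig | None = None,
) -> EnetModel:
    """Fit the penalized logistic model at fixed (alpha, lambda)."""
    cfg = cfg or EnetConfig()
    names = list(Z.columns) if isinstance(Z, pd.DataFrame) else [
        f"z{j}" for j in range(np.asarray(Z).shape[1])
    ]
    Zv, yv = _check_xy(np.asarray(Z), y)
    n = len(yv)
    clf = LogisticRegression(
        solver="saga",
        l1_ratio=float(alpha),
        C=1.0 / (n * lam),
        tol=cfg.tol,
        max_iter=cfg.max_iter,
        random_state=cfg.fold_seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(Zv, yv)
    b0 = _refine_intercept(float(clf.intercept_[0]), Zv @ clf.coef_[0], yv)
    return EnetModel(
        b0,
        pd.Series(clf.coef_[0], index=names),
        float(alpha),
        float(lam),
    )


def lambda_path(
    Z: np.ndarray, y: np.ndarray, alpha: float, cfg: EnetConfig
) -> np.ndarray:
    """glmnet-style path: log-spaced from lambda_max down ``lambda_decades``.

    lambda_max is the smallest penalty that zeroes every coefficient at
    this alpha (gradient bound max_j |<z_j, y - ybar>| / (n alpha));
    ridge-leaning alphas use a floor of 0.001 in the denominator.
    """
    Zv, yv = _check_xy(np.asarray(Z), y)
    n = len(yv)
    grad = np.abs(Zv.T @ (yv - yv.mean())) / n
    lam_max = float(grad.max()) / max(alpha, 1e-3)
    return np.logspace(
        np.log10(lam_max), np.log10(lam_max) - cfg.lambda_decades, cfg.n_lambda
    )


def enet_objective(
    Z: np.ndarray, y: np.ndarray, model: EnetModel
) -> float:
    """The penalized mean negative log-likelihood at the model's parameters."""
    Zv, yv = _check_xy(np.asarray(Z), y)
    p = np.clip(model.score_standardized(Zv), 1e-12, 1 - 1e-12)
    nll = -np.mean(yv * np.log(p) + (1 - yv) * np.log(1 - p))
    b = model.coef.to_numpy()
    pen = model.lam * ((1 - model.alpha) * 0.5 * (b**2).sum()
                       + model.alpha * np.abs(b).sum())
    return float(nll + pen)


def cv_tune(
    Z: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    cfg: EnetConfig | None = None,
) -> tuple[EnetModel, pd.DataFrame]:
    """Grid/path search with stratified k-fold CV on probability MSE.

    Returns the model refit on all rows at the optimum, and the CV curve
    (one row per (alpha, lambda) with the mean held-out MSE).  Ties are
    broken toward larger lambda, then larger alpha.
    """
    cfg = cfg or EnetConfig()
    names = list(Z.columns) if isinstance(Z, pd.DataFrame) else None
    Zv, yv = _check_xy(np.asarray(Z), y)
    if len(yv) < cfg.k_folds:
        raise ValueError("need at least k_folds samples")
    skf = StratifiedKFold(cfg.k_folds, shuffle=True, random_state=cfg.fold_seed)
    with warnings.catch_warnings():
        # small cohorts: fewer positives than folds is expected and fine
        warnings.simplefilter("ignore", UserWarning)
        folds = list(skf.split(Zv, yv))
    for train_idx, _ in folds:
        if len(np.unique(yv[train_idx])) < 2:
            raise ValueError("a training fold lost one class; check stratification")

    records = []
    for alpha in cfg.alpha_grid:
        lams = lambda_path(Zv, yv, alpha, cfg)
        fold_mse = np.zeros((len(folds), len(lams)))
        for f, (tr, te) in enumerate(folds):
            n_tr = len(tr)
            coef_init: np.ndarray | None = None
            for j, lam in enumerate(lams):
                clf = LogisticRegression(
                    solver="saga", warm_start=False,
                    l1_ratio=float(alpha), C=1.0 / (n_tr * lam),
                    tol=cfg.tol, max_iter=cfg.max_iter,
                    random_state=cfg.fold_seed,
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")  # saga hitting max_iter is fine for CV scoring
                    if coef_init is not None:
                        # warm start down the path: reuse the previous optimum
                        clf.coef_ = coef_init.copy()
                        clf.intercept_ = intercept_init.copy()
                        clf.warm_start = True
                    clf.fit(Zv[tr], yv[tr])
                coef_init, intercept_init = clf.coef_, clf.intercept_
                p = clf.predict_proba(Zv[te])[:, 1]
                fold_mse[f, j] = np.mean((p - yv[te]) ** 2)
        mean_mse = fold_mse.mean(axis=0)
        for lam, mse in zip(lams, mean_mse):
            records.append({"alpha": float(alpha), "lambda": float(lam),
                            "cv_mse": float(mse)})
    curve = pd.DataFrame(records)
    # minimize; ties -> larger lambda, then larger alpha
    best = curve.sort_values(
        ["cv_mse", "lambda", "alpha"], ascending=[True, False, False]
    ).iloc[0]
    Zdf = pd.DataFrame(Zv, columns=names) if names is not None else Zv
    model = fit_enet(Zdf, yv, best["alpha"], best["lambda"], cfg)
    model.meta.update({"cv_mse": float(best["cv_mse"]), "fold_seed": cfg.fold_seed,
                       "k_folds": cfg.k_folds})
    return model, curve
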