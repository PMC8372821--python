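import numpy as np
import pandas as pd
import pytest

from lateromics.enet import (
    EnetConfig,
    EnetModel,
    cv_tune,
    enet_objective,
    fit_enet,
    lambda_path,
)
from lateromics.selection import Standardizer


def _standardize(X):
    return (X - X.mean(axis=0)) / X.std(axis=0)


def _separable(n=60, p=5, seed=0, signal=2.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = np.zeros(p)
    beta[0] = signal
    logits = X @ beta
    y = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(int)
    if y.sum() in (0, n):
        y[0] = 1 - y[0]
    return _standardize(X), y


SMALL_CFG = EnetConfig(alpha_grid=(0.1, 0.9), n_lambda=12, lambda_decades=3,
                       k_folds=5, fold_seed=1, tol=1e-6, max_iter=20_000)


class TestFitEnet:
    def test_heavy_penalty_gives_null_model(self):
        Z, y = _separable()
        m = fit_enet(Z, y, alpha=1.0, lam=100.0)
        assert np.allclose(m.coef, 0.0, atol=1e-6)
        assert m.intercept == pytest.approx(np.log(y.mean() / (1 - y.mean())), abs=0.05)

    def test_tiny_penalty_matches_unpenalized_newton_fit(self):
        import statsmodels.api as sm
        Z, y = _separable(n=200, p=3, seed=5, signal=0.8)
        m = fit_enet(Z, y, alpha=0.5, lam=1e-7,
                     cfg=EnetConfig(tol=1e-10, max_iter=200_000))
        ref = sm.Logit(y, sm.add_constant(Z)).fit(disp=0)
        assert m.intercept == pytest.approx(ref.params[0], abs=2e-3)
        np.testing.assert_allclose(m.coef, ref.params[1:], atol=5e-3)

    def test_lasso_zeroes_coefficients_ridge_does_not(self):
        Z, y = _separable(n=120, p=2, seed=2, signal=1.0)
        lam = 0.05
        lasso = fit_enet(Z, y, alpha=1.0, lam=lam)
        ridge = fit_enet(Z, y, alpha=0.0, lam=lam)
        # the weak feature dies under L1 before it dies under L2
        assert np.sum(np.abs(lasso.coef.to_numpy()) < 1e-8) >= 1
        assert np.all(np.abs(ridge.coef.to_numpy()) > 1e-8)

    def test_single_class_rejected(self):
        Z = np.random.default_rng(0).normal(size=(10, 2))
        with pytest.raises(ValueError):
            fit_enet(Z, np.zeros(10, int), 0.5, 0.1)

    def test_fitted_objective_beats_null_and_perturbations(self):
        Z, y = _separable(n=100, p=4, seed=3)
        Zdf = pd.DataFrame(Z, columns=list("abcd"))
        m = fit_enet(Zdf, y, alpha=0.5, lam=0.01,
                     cfg=EnetConfig(tol=1e-8, max_iter=100_000))
        obj = enet_objective(Z, y, m)
        null = EnetModel(float(np.log(y.mean() / (1 - y.mean()))),
                         pd.Series(0.0, index=list("abcd")), 0.5, 0.01)
        assert obj <= enet_objective(Z, y, null) + 1e-8
        rng = np.random.default_rng(0)
        for _ in range(5):
            bumped = EnetModel(m.intercept,
                               m.coef + rng.normal(0, 0.05, size=4),
                               m.alpha, m.lam)
            assert obj <= enet_objective(Z, y, bumped) + 1e-8

    def test_sparsity_non_increasing_in_lambda(self):
        Z, y = _separable(n=80, p=10, seed=4, signal=1.5)
        lams = np.logspace(-4, 0, 12)
        nnz = [
            len(fit_enet(Z, y, 1.0, lam,
                         cfg=EnetConfig(tol=1e-7, max_iter=50_000)).selected_features)
            for lam in lams
        ]
        assert all(a >= b for a, b in zip(nnz, nnz[1:]))


class TestLambdaPath:
    def test_path_spans_requested_decades(self):
        Z, y = _separable()
        cfg = EnetConfig(n_lambda=20, lambda_decades=4)
        path = lambda_path(Z, y, 1.0, cfg)
        assert len(path) == 20
        assert path[0] / path[-1] == pytest.approx(1e4)
        assert np.all(np.diff(path) < 0)

    def test_lambda_max_kills_all_coefficients(self):
        Z, y = _separable(n=100, p=6, seed=7)
        cfg = EnetConfig()
        lam_max = lambda_path(Z, y, 1.0, cfg)[0]
        m = fit_enet(Z, y, 1.0, lam_max * 1.01,
                     cfg=EnetConfig(tol=1e-8, max_iter=50_000))
        assert np.allclose(m.coef, 0.0, atol=1e-6)


class TestCVTune:
    def test_informative_data_beats_null_model(self):
        Z, y = _separable(n=80, p=5, seed=1, signal=3.0)
        model, curve = cv_tune(pd.DataFrame(Z), y, SMALL_CFG)
        null_mse = curve.loc[curve["lambda"].idxmax(), "cv_mse"]
        assert model.meta["cv_mse"] < null_mse

    def test_pure_noise_selects_nearly_nothing(self):
        rng = np.random.default_rng(11)
        Z = _standardize(rng.normal(size=(200, 50)))
        y = (rng.random(200) < 0.5).astype(int)
        model, _ = cv_tune(pd.DataFrame(Z), y, SMALL_CFG)
        assert len(model.selected_features) <= 10
        bern = y.mean() * (1 - y.mean())
        assert model.meta["cv_mse"] == pytest.approx(bern, abs=0.05)

    def test_deterministic_given_fold_seed(self):
        Z, y = _separable(n=60, p=8, seed=9)
        m1, c1 = cv_tune(pd.DataFrame(Z), y, SMALL_CFG)
        m2, c2 = cv_tune(pd.DataFrame(Z), y, SMALL_CFG)
        assert m1.alpha == m2.alpha and m1.lam == m2.lam
        pd.testing.assert_frame_equal(c1, c2)


class TestPredictScore:
    def _model(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(2, 3, size=(30, 3)), columns=["a", "b", "c"])
        std = Standardizer.fit(X)
        coef = pd.Series([1.0, -0.5, 0.0], index=["a", "b", "c"])
        return X, EnetModel(0.3, coef, 0.5, 0.1, standardizer=std)

    def test_score_at_training_means_is_logistic_intercept(self):
        X, model = self._model()
        at_mean = dict(X.mean())
        expected = 1 / (1 + np.exp(-0.3))
        assert model.predict_score(at_mean) == pytest.approx(expected)

    def test_monotone_in_positive_coefficient_feature(self):
        X, model = self._model()
        base = dict(X.mean())
        lo = model.predict_score({**base, "a": 0.0})
        hi = model.predict_score({**base, "a": 10.0})
        assert hi > lo

    def test_batch_equals_single_row(self):
        X, model = self._model()
        batch = model.predict_score(X)
        singles = [model.predict_score(row) for _, row in X.iterrows()]
        np.testing.assert_allclose(batch, singles)

    def test_missing_feature_rejected(self):
        X, model = self._model()
        with pytest.raises(KeyError):
            model.predict_score({"a": 1.0, "b": 2.0})

    def test_json_round_trip(self, tmp_path):
        X, model = self._model()
        path = tmp_path / "model.json"
        model.to_json(path)
        back = EnetModel.from_json(path)
        assert back.alpha == model.alpha and back.lam == model.lam
        np.testing.assert_allclose(back.predict_score(X), model.predict_score(X))
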