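"""Elastic-net D-score model: closed-form limits, CV selection, reporting.

The mixing convention under test: alpha is the L2 fraction of the penalty
(alpha=1 pure ridge, alpha=0 pure lasso), with lambda2 = alpha*lambda and
lambda1 = (1-alpha)*lambda in the objective
||y - Xb||^2 + lambda2 ||b||^2 + lambda1 ||b||_1.
"""

from __future__ import annotations

import numpy as np
import pytest

from geneqc.dscore import (
    coefficient_report,
    fit_elastic_net,
    lambda_max,
    predict_dscores,
    select_lambda,
)


def make_data(seed=0, n=80, p=3, noise=0.05):
    rng = np.random.default_rng(seed)
    X = rng.random((n, p))
    beta = np.array([0.3, 0.2, 0.1][:p])
    y = 0.05 + X @ beta + noise * rng.standard_normal(n)
    return X, y, beta


def elastic_objective(X, y, intercept, beta, lam, alpha):
    resid = y - intercept - X @ beta
    return (
        resid @ resid
        + alpha * lam * (beta @ beta)
        + (1 - alpha) * lam * np.abs(beta).sum()
    )


class TestFitElasticNet:
    def test_lambda_zero_matches_ols(self):
        X, y, _ = make_data()
        model = fit_elastic_net(X, y, alpha=0.5, lambda_total=0.0)
        design = np.column_stack([np.ones(len(y)), X])
        beta_ols = np.linalg.solve(design.T @ design, design.T @ y)
        assert model.intercept == pytest.approx(beta_ols[0], abs=1e-6)
        np.testing.assert_allclose(model.coefficients, beta_ols[1:], atol=1e-6)

    def test_pure_l1_orthonormal_soft_threshold(self):
        # orthonormal, zero-mean design: Q from QR of centered Gaussians
        rng = np.random.default_rng(1)
        raw = rng.standard_normal((60, 3))
        raw -= raw.mean(axis=0)
        Q, _ = np.linalg.qr(raw)
        y = Q @ np.array([2.0, 0.5, 0.05]) + 0.01 * rng.standard_normal(60)
        lam = 0.4  # lambda1 = 0.4 at alpha=0 -> threshold 0.2
        model = fit_elastic_net(Q, y, alpha=0.0, lambda_total=lam)
        b_ols = Q.T @ (y - y.mean())
        expected = np.sign(b_ols) * np.maximum(np.abs(b_ols) - lam / 2.0, 0.0)
        np.testing.assert_allclose(model.coefficients, expected, atol=1e-6)

    def test_pure_l2_matches_ridge_closed_form(self):
        X, y, _ = make_data(seed=2)
        lam = 3.0
        model = fit_elastic_net(X, y, alpha=1.0, lambda_total=lam)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        expected = np.linalg.solve(Xc.T @ Xc + lam * np.eye(3), Xc.T @ yc)
        np.testing.assert_allclose(model.coefficients, expected, atol=1e-6)
        assert not (model.coefficients == 0).any()  # L2 never zeroes

    def test_objective_is_locally_optimal(self):
        X, y, _ = make_data(seed=3)
        lam, alpha = 0.8, 0.5
        model = fit_elastic_net(X, y, alpha=alpha, lambda_total=lam)
        base = elastic_objective(X, y, model.intercept, model.coefficients, lam, alpha)
        for j in range(3):
            for delta in (1e-4, -1e-4):
                perturbed = model.coefficients.copy()
                perturbed[j] += delta
                assert (
                    elastic_objective(X, y, model.intercept, perturbed, lam, alpha)
                    >= base - 1e-12
                )

    def test_l1_norm_non_increasing_along_lambda_path(self):
        X, y, _ = make_data(seed=4)
        lmax = lambda_max(X, y, alpha=0.5)
        grid = np.logspace(np.log10(lmax), np.log10(lmax) - 4, 20)
        norms = [
            np.abs(fit_elastic_net(X, y, 0.5, lam).coefficients).sum() for lam in grid
        ]
        # grid is descending in lambda, so the norms must be non-decreasing
        assert all(a <= b + 1e-9 for a, b in zip(norms, norms[1:]))
        assert norms[0] == pytest.approx(0.0, abs=1e-9)  # all zero at lambda_max

    def test_grouping_effect_on_duplicated_features(self):
        rng = np.random.default_rng(5)
        x = rng.random(100)
        X = np.column_stack([x, x, rng.random(100)])
        y = 2 * x + 0.01 * rng.standard_normal(100)
        model = fit_elastic_net(X, y, alpha=0.5, lambda_total=0.5)
        assert model.coefficients[0] == pytest.approx(model.coefficients[1], abs=1e-6)

    def test_nonfinite_input_rejected(self):
        X, y, _ = make_data()
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            fit_elastic_net(X, y, 0.5, 1.0)


class TestSelectLambda:
    def test_noise_free_linear_response_prefers_small_lambda(self):
        rng = np.random.default_rng(6)
        X = rng.random((100, 3))
        y = 0.1 + X @ np.array([0.4, 0.3, 0.2])
        lam = select_lambda(X, y, alpha=0.5, seed=1)
        lmax = lambda_max(X, y, 0.5)
        assert lam <= lmax * 10**-3.5  # at/near the bottom of the 4-decade grid
        model = fit_elastic_net(X, y, 0.5, lam)
        resid = y - model.intercept - X @ model.coefficients
        assert np.mean(resid**2) < 1e-6

    def test_pure_noise_prefers_lambda_max(self):
        rng = np.random.default_rng(7)
        X = rng.random((120, 3))
        y = rng.standard_normal(120)
        lam = select_lambda(X, y, alpha=0.5, seed=1)
        lmax = lambda_max(X, y, 0.5)
        grid = np.logspace(np.log10(lmax), np.log10(lmax) - 4, 50)
        # chance fold-level overfitting can move the argmin a few grid steps
        # down from lambda_max, but the fit must stay heavily shrunk
        assert lam >= grid[5]
        shrunk = np.abs(fit_elastic_net(X, y, 0.5, lam).coefficients).sum()
        ols = np.abs(fit_elastic_net(X, y, 0.5, 0.0).coefficients).sum()
        assert shrunk < 0.5 * ols

    def test_deterministic_under_seed(self):
        X, y, _ = make_data(seed=8)
        assert select_lambda(X, y, seed=3) == select_lambda(X, y, seed=3)

    def test_too_few_samples_for_folds(self):
        X, y, _ = make_data(n=4)
        with pytest.raises(ValueError):
            select_lambda(X, y, n_folds=5)


class TestPredictAndReport:
    def test_zero_features_zero_intercept(self):
        model = fit_elastic_net(np.eye(3), np.zeros(3), 0.5, 0.0)
        assert predict_dscores(model, np.zeros((1, 3)))[0] == pytest.approx(0.0, abs=1e-12)

    def test_ols_residuals_mean_zero(self):
        X, y, _ = make_data(seed=9)
        model = fit_elastic_net(X, y, 0.5, 0.0)
        fitted = model.intercept + X @ model.coefficients
        assert np.mean(fitted - y) == pytest.approx(0.0, abs=1e-10)

    def test_predictions_floored_at_zero(self):
        X, y, _ = make_data(seed=10)
        model = fit_elastic_net(X, y - 10.0, 0.5, 0.0)  # strongly negative fit
        assert predict_dscores(model, X).min() == 0.0

    def test_monotone_prediction_with_positive_coefficients(self):
        X, y, _ = make_data(seed=11, noise=0.01)
        model = fit_elastic_net(X, y, 0.5, 0.01)
        assert (model.coefficients >= 0).all()
        top = predict_dscores(model, np.ones((1, 3)))[0]
        assert top >= predict_dscores(model, X).max() - 1e-9

    def test_column_mismatch_rejected(self):
        X, y, _ = make_data()
        model = fit_elastic_net(X, y, 0.5, 0.0)
        with pytest.raises(ValueError):
            predict_dscores(model, X[:, :2])

    def test_report_flags_zeroed_coefficients(self):
        rng = np.random.default_rng(12)
        X = np.column_stack([rng.random(100), rng.random(100), rng.random(100)])
        y = 3 * X[:, 0] + 0.01 * rng.standard_normal(100)
        model = fit_elastic_net(
            X, y, alpha=0.0, lambda_total=2.0, feature_names=("a", "b", "c")
        )
        report = coefficient_report(model)
        assert list(report["term"]) == ["intercept", "a", "b", "c"]
        assert not report.loc[report["term"] == "a", "zeroed"].item()
        assert report.loc[report["term"].isin(["b", "c"]), "zeroed"].all()
        ridge = coefficient_report(fit_elastic_net(X, y, 1.0, 2.0))
        assert not ridge["zeroed"].iloc[1:].any()
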