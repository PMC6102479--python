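"""Elastic-net regression of D4 on the normalized features; D-scores.

Objective (for a total penalty weight λ = lambda_total and mixing α):

    L(λ1, λ2, β) = ||y − Xβ||² + λ2 ||β||² + λ1 ||β||₁,
    λ2 = α·λ,  λ1 = (1 − α)·λ,  intercept unpenalized.

NOTE the α convention: **α is the L2 fraction** — α = 1 is ridge, α = 0 is
the lasso.  This is the REVERSE of glmnet's / scikit-learn's ``l1_ratio``;
the translation to scikit-learn's parameterization happens inside
:func:`fit_elastic_net` and nowhere else.  Default α = 0.5.

The fitted value of this regression, floored at 0, is the gene's D-score:
its predicted ambiguous-read proportion, i.e. its mapping-uncertainty level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet
from sklearn.model_selection import KFold

__all__ = [
    "ElasticNetModel",
    "fit_elastic_net",
    "select_lambda",
    "predict_dscores",
    "coefficient_report",
]


@dataclass
class ElasticNetModel:
    """A fitted elastic-net regression (α = L2 mixing fraction)."""

    intercept: float
    coefficients: np.ndarray
    alpha: float
    lambda_total: float
    n: int
    feature_names: tuple[str, ...] = ()
    cv_folds: int | None = None
    cv_seed: int | None = None

    @property
    def p(self) -> int:
        return self.coefficients.size


def _validate_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    if X.shape[0] != y.size:
        raise ValueError("X and y disagree on the number of samples")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("X and y must be finite")
    if X.shape[0] < X.shape[1]:
        raise ValueError("need at least as many samples as features")
    return X, y


def fit_elastic_net(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float = 0.5,
    lambda_total: float = 0.0,
    feature_names: tuple[str, ...] = (),
) -> ElasticNetModel:
    """Minimize ||y − Xβ||² + αλ||β||² + (1−α)λ||β||₁ (intercept free).

    λ = 0 reduces to ordinary least squares (solved directly); otherwise the
    problem is handed to scikit-learn's cyclic coordinate descent with the
    parameter translation  a·l1 = λ1/(2n),  a·(1−l1) = λ2/n.
    """
    X, y = _validate_xy(X, y)
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if lambda_total < 0:
        raise ValueError("lambda_total must be >= 0")
    n, p = X.shape

    if lambda_total == 0.0:
        design = np.column_stack([np.ones(n), X])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        return ElasticNetModel(
            intercept=float(beta[0]),
            coefficients=beta[1:].copy(),
            alpha=alpha,
            lambda_total=0.0,
            n=n,
            feature_names=tuple(feature_names),
        )

    lam1 = (1.0 - alpha) * lambda_total
    lam2 = alpha * lambda_total
    sk_alpha = lam1 / (2.0 * n) + lam2 / n
    l1_ratio = 0.0 if sk_alpha == 0 else (lam1 / (2.0 * n)) / sk_alpha
    est = ElasticNet(
        alpha=sk_alpha,
        l1_ratio=l1_ratio,
        fit_intercept=True,
        max_iter=100_000,
        tol=1e-10,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.filterwarnings("ignore", message=".*l1_ratio.*")
        est.fit(X, y)
    return ElasticNetModel(
        intercept=float(est.intercept_),
        coefficients=np.asarray(est.coef_, dtype=float).copy(),
        alpha=alpha,
        lambda_total=float(lambda_total),
        n=n,
        feature_names=tuple(feature_names),
    )


def lambda_max(X: np.ndarray, y: np.ndarray, alpha: float) -> float:
    """Smallest λ shrinking every coefficient to zero at mixing α.

    From the coordinate-descent stationarity condition this is
    2·max_j |X_cᵀ y_c|_j / (1 − α); for α near 1 (ridge keeps everything
    nonzero) the denominator is floored so the CV grid stays finite.
    """
    X, y = _validate_xy(X, y)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    grad = np.abs(Xc.T @ yc)
    top = 2.0 * float(grad.max()) if grad.size else 0.0
    return max(top, 1e-12) / max(1.0 - alpha, 1e-3)


def select_lambda(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float = 0.5,
    n_folds: int = 5,
    seed: int = 1,
    n_grid: int = 50,
    decades: float = 4.0,
) -> float:
    """Pick λ by seeded K-fold CV over a log grid from λ_max down ``decades``.

    Ties in mean CV error resolve toward the larger (more parsimonious) λ.
    """
    X, y = _validate_xy(X, y)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if X.shape[0] < n_folds:
        raise ValueError("fewer samples than CV folds")
    lmax = lambda_max(X, y, alpha)
    grid = np.logspace(np.log10(lmax), np.log10(lmax) - decades, n_grid)
    folds = list(KFold(n_splits=n_folds, shuffle=True, random_state=seed).split(X))
    mean_err = np.empty(n_grid)
    for gi, lam in enumerate(grid):
        errs = []
        for train, test in folds:
            model = fit_elastic_net(X[train], y[train], alpha, lam)
            resid = y[test] - (model.intercept + X[test] @ model.coefficients)
            errs.append(float(np.mean(resid**2)))
        mean_err[gi] = np.mean(errs)
    # grid is descending, so argmin's first hit is the largest tied lambda
    return float(grid[int(np.argmin(mean_err))])


def predict_dscores(model: ElasticNetModel, X: np.ndarray) -> np.ndarray:
    """D-scores: fitted values floored at 0 (scores are uncertainty magnitudes)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.p:
        raise ValueError(
            f"X has {X.shape[1] if X.ndim == 2 else '?'} columns, model expects {model.p}"
        )
    return np.maximum(model.intercept + X @ model.coefficients, 0.0)


def coefficient_report(model: ElasticNetModel) -> pd.DataFrame:
    """Per-feature coefficient table, flagging exact zeros (L1 selection)."""
    names = list(model.feature_names) or [f"x{j + 1}" for j in range(model.p)]
    rows = [
        {
            "term": "intercept",
            "coefficient": model.intercept,
            "sign": int(np.sign(model.intercept)),
            "zeroed": False,
        }
    ]
    for name, coef in zip(names, model.coefficients):
        rows.append(
            {
                "term": name,
                "coefficient": float(coef),
                "sign": int(np.sign(coef)),
                "zeroed": coef == 0.0,
            }
        )
    return pd.DataFrame(rows, columns=["term", "coefficient", "sign", "zeroed"])
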