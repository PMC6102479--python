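"""Mixture-model fitting for D-score samples: k-means init + EM + BIC.

The D-score distribution of a dataset is modelled as a k-component mixture
(default k = 3, one component per uncertainty level)

    P(x | θ) = Σ_k β_k Y_k(x | θ_k)

with Y_k either Gaussian or Gamma.  Fitting is classical EM seeded by
one-dimensional k-means with randomized initial grouping:

* E step: responsibilities r_jk = β_k Y_k(x_j) / Σ_m β_m Y_m(x_j).
* M step (Gaussian): μ_k, σ_k² are the responsibility-weighted mean and
  (biased, N_k-denominator) variance; β_k = Σ_j r_jk / N.
* M step (Gamma): responsibility-weighted method of moments,
  shape = m²/v and scale = v/m from the weighted mean m and variance v.
  This is an approximation to the MLE M step (no digamma iterations), so the
  log-likelihood is guaranteed non-decreasing only to a small tolerance.

Model choice between the Gaussian and Gamma candidates (and, optionally,
across k) is by BIC = p·ln(n) − 2·L̂ with p = 3k − 1 free parameters
(2 per component plus k − 1 free weights), minimized.  The literal variant
−2k·ln(n) − 2·L̂ is available as ``mode="paper_literal"`` for auditing but
decreases with both k and fit, so it cannot drive selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import logsumexp

__all__ = [
    "DegenerateSampleError",
    "MixtureFitError",
    "MixtureModel",
    "kmeans_1d",
    "em_gaussian",
    "em_gamma",
    "bic",
    "select_best",
    "fit_mixture",
]

_VAR_FLOOR = 1e-10


class DegenerateSampleError(ValueError):
    """Too few distinct values to support the requested number of clusters."""


class MixtureFitError(RuntimeError):
    """No mixture candidate could be fitted."""


@dataclass
class MixtureModel:
    """A fitted k-component mixture, components sorted by mean ascending.

    ``params`` holds (mean, variance) per component for the Gaussian family
    and (shape, scale) for the Gamma family.
    """

    family: str
    weights: np.ndarray
    params: list[tuple[float, float]]
    loglik: float
    bic: float
    n: int
    converged: bool
    iterations: int

    @property
    def k(self) -> int:
        return len(self.params)

    def component_mean(self, j: int) -> float:
        a, b = self.params[j]
        return a if self.family == "gaussian" else a * b

    def component_mode(self, j: int) -> float:
        a, b = self.params[j]
        if self.family == "gaussian":
            return a
        return (a - 1.0) * b if a > 1.0 else 0.0

    def component_logpdf(self, j: int, x: np.ndarray) -> np.ndarray:
        a, b = self.params[j]
        if self.family == "gaussian":
            return stats.norm.logpdf(x, loc=a, scale=np.sqrt(b))
        return stats.gamma.logpdf(x, a=a, scale=b)

    def component_pdf(self, j: int, x: np.ndarray) -> np.ndarray:
        return np.exp(self.component_logpdf(j, x))

    def component_cdf(self, j: int, x: np.ndarray | float) -> np.ndarray | float:
        a, b = self.params[j]
        if self.family == "gaussian":
            return stats.norm.cdf(x, loc=a, scale=np.sqrt(b))
        return stats.gamma.cdf(x, a=a, scale=b)

    def log_density(self, x: np.ndarray) -> np.ndarray:
        comp = np.stack(
            [np.log(self.weights[j]) + self.component_logpdf(j, x) for j in range(self.k)]
        )
        return logsumexp(comp, axis=0)


def kmeans_1d(
    values: np.ndarray,
    k: int,
    seed: int = 1,
    restarts: int = 10,
    max_iter: int = 300,
) -> tuple[np.ndarray, np.ndarray]:
    """One-dimensional k-means with randomized initial grouping.

    Each restart assigns points to k groups uniformly at random, then runs
    Lloyd iterations (reassign to nearest mean / recompute means) until no
    reassignment.  The restart with the lowest within-cluster sum of squares
    wins.  Labels are relabelled so cluster means are ascending.

    Returns (labels, means).
    """
    x = np.asarray(values, dtype=float).ravel()
    if np.unique(x).size < k:
        raise DegenerateSampleError(
            f"need >= {k} distinct values for k={k}, got {np.unique(x).size}"
        )
    rng = np.random.default_rng(seed)
    best_labels: np.ndarray | None = None
    best_means: np.ndarray | None = None
    best_wcss = np.inf
    n = x.size
    for _ in range(max(restarts, 1)):
        labels = rng.integers(0, k, size=n)
        # guarantee non-empty initial groups
        labels[rng.choice(n, size=k, replace=False)] = np.arange(k)
        means = np.array([x[labels == j].mean() for j in range(k)])
        for _it in range(max_iter):
            new_labels = np.argmin(np.abs(x[:, None] - means[None, :]), axis=1)
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
            for j in range(k):
                members = x[labels == j]
                if members.size:
                    means[j] = members.mean()
        if np.unique(labels).size < k:  # a cluster died during Lloyd iterations
            continue
        wcss = float(np.sum((x - means[labels]) ** 2))
        if wcss < best_wcss:
            best_wcss, best_labels, best_means = wcss, labels.copy(), means.copy()
    if best_labels is None:
        raise DegenerateSampleError(
            f"k-means could not sustain {k} non-empty clusters"
        )
    order = np.argsort(best_means)
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    return relabel[best_labels], best_means[order]


def _init_from_labels(
    x: np.ndarray, labels: np.ndarray, family: str
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    k = int(labels.max()) + 1
    weights = np.empty(k)
    params: list[tuple[float, float]] = []
    for j in range(k):
        members = x[labels == j]
        if members.size == 0:
            raise DegenerateSampleError(f"empty initial cluster {j}")
        weights[j] = members.size / x.size
        m = float(members.mean())
        v = max(float(members.var()), _VAR_FLOOR)  # biased (N_k) variance
        if family == "gaussian":
            params.append((m, v))
        else:
            params.append((m * m / v, v / m))
    return weights, params


def _em(
    x: np.ndarray,
    weights: np.ndarray,
    params: list[tuple[float, float]],
    family: str,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> MixtureModel:
    n = x.size
    weights = weights.copy()
    params = list(params)
    loglik = -np.inf
    converged = False
    iteration = 0
    for iteration in range(1, max_iter + 1):
        # E step
        k = len(params)
        log_comp = np.empty((k, n))
        for j, (a, b) in enumerate(params):
            if family == "gaussian":
                log_comp[j] = stats.norm.logpdf(x, loc=a, scale=np.sqrt(b))
            else:
                log_comp[j] = stats.gamma.logpdf(x, a=a, scale=b)
            log_comp[j] += np.log(weights[j])
        log_norm = logsumexp(log_comp, axis=0)
        new_loglik = float(log_norm.sum())
        resp = np.exp(log_comp - log_norm)  # rows: components

        # M step
        nk = resp.sum(axis=1)
        keep = nk / n >= 1.0 / (10.0 * n)
        if not keep.all():
            warnings.warn(
                f"pruning {int((~keep).sum())} collapsed mixture component(s)",
                stacklevel=2,
            )
            resp = resp[keep]
            nk = nk[keep]
            resp /= resp.sum(axis=0, keepdims=True)
            nk = resp.sum(axis=1)
        weights = nk / n
        new_params: list[tuple[float, float]] = []
        for j in range(len(nk)):
            r = resp[j]
            m = float(r @ x / nk[j])
            v = max(float(r @ (x - m) ** 2 / nk[j]), _VAR_FLOOR)
            if family == "gaussian":
                new_params.append((m, v))
            else:
                new_params.append((max(m * m / v, 1e-8), max(v / m, 1e-12)))
        params = new_params

        if np.isfinite(loglik):
            delta = new_loglik - loglik
            if family == "gamma" and delta < -tol * max(1.0, abs(loglik)):
                # moment-matching M step overshot; keep the previous state
                converged = True
                new_loglik = loglik
                break
            if abs(delta) < tol * max(1.0, abs(loglik)):
                loglik = new_loglik
                converged = True
                break
        loglik = new_loglik

    order = np.argsort([a if family == "gaussian" else a * b for a, b in params])
    weights = weights[order]
    params = [params[j] for j in order]
    model = MixtureModel(
        family=family,
        weights=weights,
        params=params,
        loglik=loglik,
        bic=0.0,
        n=n,
        converged=converged,
        iterations=iteration,
    )
    model.bic = bic(model)
    return model


def em_gaussian(
    values: np.ndarray,
    init_labels: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> MixtureModel:
    """Fit a Gaussian mixture by EM from a k-means labelling."""
    x = np.asarray(values, dtype=float).ravel()
    weights, params = _init_from_labels(x, np.asarray(init_labels), "gaussian")
    return _em(x, weights, params, "gaussian", tol=tol, max_iter=max_iter)


def em_gamma(
    values: np.ndarray,
    init_labels: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> MixtureModel:
    """Fit a Gamma mixture by EM (weighted method-of-moments M step)."""
    x = np.asarray(values, dtype=float).ravel()
    if np.any(x <= 0):
        raise ValueError("gamma mixture requires strictly positive values")
    weights, params = _init_from_labels(x, np.asarray(init_labels), "gamma")
    return _em(x, weights, params, "gamma", tol=tol, max_iter=max_iter)


def bic(model: MixtureModel, mode: str = "standard") -> float:
    """BIC of a fitted mixture; ``standard`` = p·ln(n) − 2L̂ with p = 3k − 1.

    ``paper_literal`` evaluates −2k·ln(n) − 2L̂ (kept for auditability only).
    """
    k, n, ll = model.k, model.n, model.loglik
    if mode == "standard":
        return float((3 * k - 1) * np.log(n) - 2.0 * ll)
    if mode == "paper_literal":
        return float(-2.0 * k * np.log(n) - 2.0 * ll)
    raise ValueError(f"unknown BIC mode {mode!r}")


def select_best(candidates: list[MixtureModel]) -> MixtureModel:
    """Minimal-BIC candidate; exact ties resolve toward the Gaussian family
    (its cutoffs have a closed form)."""
    usable = [c for c in candidates if c is not None and np.isfinite(c.bic)]
    if not usable:
        raise MixtureFitError("no usable mixture candidate")
    return min(usable, key=lambda m: (m.bic, 0 if m.family == "gaussian" else 1))


def fit_mixture(
    values: np.ndarray,
    k: int = 3,
    families: tuple[str, ...] = ("gaussian", "gamma"),
    seed: int = 1,
    restarts: int = 10,
    gamma_floor: float = 1e-6,
) -> tuple[MixtureModel, list[MixtureModel]]:
    """k-means-initialize and fit every candidate family; select by BIC.

    Returns (best, all_candidates).  For the Gamma candidate the sample is
    clipped at ``gamma_floor`` (D-scores of exactly 0 must be excluded by the
    caller before fitting).
    """
    x = np.asarray(values, dtype=float).ravel()
    labels, _means = kmeans_1d(x, k, seed=seed, restarts=restarts)
    candidates: list[MixtureModel] = []
    for family in families:
        try:
            if family == "gaussian":
                candidates.append(em_gaussian(x, labels))
            elif family == "gamma":
                candidates.append(em_gamma(np.maximum(x, gamma_floor), labels))
            else:
                raise ValueError(f"unknown mixture family {family!r}")
        except (ValueError, FloatingPointError) as exc:  # pragma: no cover
            warnings.warn(f"{family} mixture fit failed: {exc}", stacklevel=2)
    return select_best(candidates), candidates
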