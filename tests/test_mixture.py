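"""k-means initialization, Gaussian/Gamma EM, BIC and family selection."""

from __future__ import annotations

import numpy as np
import pytest

from geneqc.mixture import (
    DegenerateSampleError,
    MixtureModel,
    bic,
    em_gamma,
    em_gaussian,
    fit_mixture,
    kmeans_1d,
    select_best,
)
from geneqc.simulate import simulate_dscore_sample

BENCH_MEANS = (0.05, 0.25, 0.45)
BENCH_SD = 0.02
BENCH_WEIGHTS = (0.7, 0.2, 0.1)


def bench_sample(n=10_000, seed=1):
    return simulate_dscore_sample(
        "gaussian",
        BENCH_WEIGHTS,
        [(m, BENCH_SD) for m in BENCH_MEANS],
        n,
        seed=seed,
    )


class TestKmeans1d:
    def test_two_point_masses(self):
        values = np.array([0.0, 0.0, 0.0, 10.0, 10.0, 10.0])
        labels, means = kmeans_1d(values, k=2, seed=1)
        assert means.tolist() == [0.0, 10.0]
        assert labels.tolist() == [0, 0, 0, 1, 1, 1]
        assert np.sum((values - means[labels]) ** 2) == 0.0

    def test_recovers_separated_blob_centers(self):
        rng = np.random.default_rng(2)
        blobs = np.concatenate(
            [rng.normal(c, 0.01, size=300) for c in (0.1, 0.5, 0.9)]
        )
        _labels, means = kmeans_1d(blobs, k=3, seed=1)
        np.testing.assert_allclose(means, [0.1, 0.5, 0.9], atol=0.05)

    def test_deterministic_under_seed(self):
        x = bench_sample(500)
        l1, m1 = kmeans_1d(x, 3, seed=9)
        l2, m2 = kmeans_1d(x, 3, seed=9)
        assert np.array_equal(l1, l2) and np.array_equal(m1, m2)

    def test_too_few_distinct_values(self):
        with pytest.raises(DegenerateSampleError):
            kmeans_1d(np.array([1.0, 1.0, 1.0]), k=2)


class TestEmGaussian:
    def test_single_component_closed_form(self):
        x = bench_sample(2000)
        model = em_gaussian(x, np.zeros(x.size, dtype=int))
        mu, var = model.params[0]
        assert mu == pytest.approx(x.mean(), abs=1e-9)
        assert var == pytest.approx(x.var(), abs=1e-9)  # biased (N) variance
        assert model.weights.tolist() == [1.0]

    def test_benchmark_parameter_recovery(self):
        x = bench_sample()
        labels, _ = kmeans_1d(x, 3, seed=1)
        model = em_gaussian(x, labels)
        assert model.converged
        for (mu, _var), truth in zip(model.params, BENCH_MEANS):
            assert mu == pytest.approx(truth, abs=0.01)
        np.testing.assert_allclose(model.weights, BENCH_WEIGHTS, atol=0.02)

    def test_recovery_robust_across_restarts(self):
        """>= 95% of 20 random initializations recover the benchmark means."""
        x = bench_sample()
        successes = 0
        for seed in range(20):
            labels, _ = kmeans_1d(x, 3, seed=seed, restarts=1)
            model = em_gaussian(x, labels)
            ok = all(
                abs(mu - t) <= 0.01 for (mu, _), t in zip(model.params, BENCH_MEANS)
            )
            successes += ok
        assert successes >= 19

    def test_loglik_monotone_and_posteriors_normalized(self):
        """EM guarantee: log-likelihood never decreases across iterations."""
        x = bench_sample(3000, seed=5)
        labels, _ = kmeans_1d(x, 3, seed=1)
        weights, params = _init(x, labels)
        logliks = _em_loglik_trace(x, weights, params, family="gaussian", iters=60)
        assert all(b - a >= -1e-9 for a, b in zip(logliks, logliks[1:]))

    def test_components_sorted_by_mean(self):
        x = bench_sample(3000, seed=6)
        labels, _ = kmeans_1d(x, 3, seed=2)
        model = em_gaussian(x, labels)
        means = [p[0] for p in model.params]
        assert means == sorted(means)
        assert model.weights.sum() == pytest.approx(1.0, abs=1e-9)


def _init(x, labels, family="gaussian"):
    from geneqc.mixture import _init_from_labels

    return _init_from_labels(x, labels, family)


def _em_loglik_trace(x, weights, params, family, iters):
    """Re-run the E/M recursions independently, recording the log-likelihood."""
    from scipy.special import logsumexp
    from scipy import stats

    logliks = []
    weights = np.array(weights, dtype=float)
    params = list(params)
    for _ in range(iters):
        k = len(params)
        log_comp = np.empty((k, x.size))
        for j, (a, b) in enumerate(params):
            if family == "gaussian":
                log_comp[j] = stats.norm.logpdf(x, a, np.sqrt(b)) + np.log(weights[j])
            else:
                log_comp[j] = stats.gamma.logpdf(x, a=a, scale=b) + np.log(weights[j])
        norm = logsumexp(log_comp, axis=0)
        logliks.append(float(norm.sum()))
        resp = np.exp(log_comp - norm)
        assert np.allclose(resp.sum(axis=0), 1.0, atol=1e-9)
        nk = resp.sum(axis=1)
        weights = nk / x.size
        assert weights.sum() == pytest.approx(1.0, abs=1e-9)
        new_params = []
        for j in range(k):
            m = float(resp[j] @ x / nk[j])
            v = max(float(resp[j] @ (x - m) ** 2 / nk[j]), 1e-10)
            new_params.append((m, v) if family == "gaussian" else (m * m / v, v / m))
        params = new_params
    return logliks


class TestEmGamma:
    def test_single_component_shape_recovery(self):
        x = simulate_dscore_sample("gamma", [1.0], [(4.0, 0.05)], 10_000, seed=3)
        model = em_gamma(x, np.zeros(x.size, dtype=int))
        shape, scale = model.params[0]
        assert shape == pytest.approx(4.0, abs=0.3)
        assert shape * scale == pytest.approx(0.2, abs=0.01)

    def test_two_component_weight_recovery(self):
        x = simulate_dscore_sample(
            "gamma", [0.6, 0.4], [(20.0, 0.005), (30.0, 0.02)], 10_000, seed=4
        )
        labels, _ = kmeans_1d(x, 2, seed=1)
        model = em_gamma(x, labels)
        np.testing.assert_allclose(model.weights, [0.6, 0.4], atol=0.03)

    def test_loglik_nondecreasing_within_tolerance(self):
        x = simulate_dscore_sample(
            "gamma", [0.5, 0.5], [(8.0, 0.01), (40.0, 0.01)], 3000, seed=5
        )
        labels, _ = kmeans_1d(x, 2, seed=1)
        weights, params = _init(x, labels, "gamma")
        logliks = _em_loglik_trace(x, weights, params, family="gamma", iters=40)
        scale = max(1.0, abs(logliks[0]))
        assert all(b - a >= -1e-6 * scale for a, b in zip(logliks, logliks[1:]))

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError):
            em_gamma(np.array([0.0, 0.1, 0.2]), np.zeros(3, dtype=int))


class TestBicAndSelection:
    def test_formula(self):
        model = MixtureModel("gaussian", np.array([1.0]), [(0.0, 1.0)],
                             loglik=-10.0, bic=0.0, n=100, converged=True, iterations=5)
        # p = 3k - 1 = 2 free parameters at k = 1
        assert bic(model) == pytest.approx(2 * np.log(100) + 20.0)
        assert bic(model, "paper_literal") == pytest.approx(-2 * np.log(100) + 20.0)

    def test_penalty_monotone_in_k(self):
        kwargs = dict(loglik=-50.0, bic=0.0, n=500, converged=True, iterations=1)
        m1 = MixtureModel("gaussian", np.ones(1), [(0, 1)], **kwargs)
        m3 = MixtureModel("gaussian", np.ones(3) / 3, [(0, 1)] * 3, **kwargs)
        assert bic(m3) > bic(m1)

    def test_overfitted_k_loses(self):
        x = bench_sample(5000, seed=8)
        best3, _ = fit_mixture(x, k=3, families=("gaussian",), seed=1)
        best6, _ = fit_mixture(x, k=6, families=("gaussian",), seed=1)
        assert best3.bic < best6.bic

    def test_gaussian_data_selects_gaussian(self):
        x = bench_sample(6000, seed=9)
        best, candidates = fit_mixture(x, k=3, seed=1)
        assert len(candidates) == 2
        assert best.family == "gaussian"

    def test_skewed_gamma_data_selects_gamma(self):
        x = simulate_dscore_sample(
            "gamma",
            [0.6, 0.3, 0.1],
            [(1.5, 0.02), (2.0, 0.12), (3.0, 0.25)],
            6000,
            seed=10,
        )
        best, _ = fit_mixture(x, k=3, seed=1)
        assert best.family == "gamma"

    def test_single_candidate_returned(self):
        x = bench_sample(1000, seed=11)
        best, candidates = fit_mixture(x, k=2, families=("gaussian",), seed=1)
        assert select_best([best]) is best

    def test_agrees_with_reference_em_loglik(self):
        """Independent cross-check: sklearn's EM reaches a comparable optimum."""
        from sklearn.mixture import GaussianMixture

        x = bench_sample(4000, seed=12)
        ours, _ = fit_mixture(x, k=3, families=("gaussian",), seed=1)
        ref = GaussianMixture(3, covariance_type="spherical", n_init=5,
                              random_state=0).fit(x.reshape(-1, 1))
        ref_loglik = ref.score(x.reshape(-1, 1)) * x.size
        assert ours.loglik == pytest.approx(ref_loglik, rel=1e-3)
        np.testing.assert_allclose(
            sorted(ref.means_.ravel()), [p[0] for p in ours.params], atol=0.01
        )
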