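"""Variational DP-GMM: priors, inference correctness, sampling."""

import json

import numpy as np
import pytest
from scipy.special import digamma

import bgmm_oce as bo
from bgmm_oce import engine as E


class TestPriors:
    @pytest.mark.parametrize(
        "opt,mode,expected",
        [(10, "exp", np.exp(-10)), (10, "inverse", 0.1), (1, "exp", np.exp(-1))],
    )
    def test_gamma_closed_forms(self, opt, mode, expected):
        X = np.random.default_rng(0).standard_normal((50, 3))
        pri = bo.make_priors(X, opt, gamma_mode=mode)
        assert pri.T == opt
        assert pri.gamma == pytest.approx(expected)

    def test_invalid_opt_errors(self):
        X = np.random.default_rng(0).standard_normal((50, 3))
        with pytest.raises(ValueError):
            bo.make_priors(X, 0)


class TestFit:
    def test_single_component_conjugate_limit(self, single_component_posterior):
        X, post = single_component_posterior
        assert np.abs(post.m[0] - X.mean(axis=0)).max() < 1e-8
        prec = post.nu[0] * post.W[0]
        approx_eye = prec @ np.cov(X.T)
        assert np.abs(approx_eye - np.eye(3)).max() < 0.05

    def test_two_blob_parameter_recovery(self):
        mix = bo.GroundTruthMixture(
            [0.5, 0.5],
            np.array([[-5.0, 0.0], [5.0, 0.0]]),
            np.stack([np.eye(2)] * 2),
            n=1000,
            seed=1,
        )
        X, _ = bo.sample_mixture(mix)
        post = bo.fit_variational(X, bo.make_priors(X, 2), seed=0)
        means = post.m[np.argsort(post.m[:, 0])]
        assert np.abs(means - np.array([[-5.0, 0.0], [5.0, 0.0]])).max() < 0.15
        assert (post.responsibilities.max(axis=1) >= 0.999).mean() > 0.99

    def test_elbo_monotone_battery(self):
        for seed in range(10):
            rg = np.random.default_rng(seed)
            n, d, T = int(rg.integers(60, 150)), int(rg.integers(2, 5)), int(
                rg.integers(1, 6)
            )
            X = rg.standard_normal((n, d)) + rg.integers(0, 3, size=(n, 1)) * 2.0
            post = bo.fit_variational(X, bo.make_priors(X, T), seed=seed, max_iter=80)
            trace = np.array(post.elbo_trace)
            slack = 1e-8 * np.maximum(1.0, np.abs(trace[1:]))
            assert (np.diff(trace) >= -slack).all()

    def test_responsibilities_normalized(self, single_component_posterior):
        _, post = single_component_posterior
        assert np.abs(post.responsibilities.sum(axis=1) - 1.0).max() < 1e-9

    def test_responsibility_step_matches_brute_force(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((40, 3))
        post = bo.fit_variational(X, bo.make_priors(X, 4), seed=0, max_iter=15)
        a, b, m, beta, W, nu = post.a, post.b, post.m, post.beta, post.W, post.nu
        log_rho = E._log_rho(X, a, b, m, beta, W, nu)
        r_fast = np.exp(log_rho - log_rho.max(1, keepdims=True))
        r_fast /= r_fast.sum(1, keepdims=True)
        # independent elementwise computation from the update equations
        T, d = 4, 3
        e_v = digamma(a) - digamma(a + b)
        e_1mv = digamma(b) - digamma(a + b)
        e_v[-1] = 0.0
        slow = np.zeros_like(r_fast)
        for i in range(X.shape[0]):
            for t in range(T):
                e_w = e_v[t] + sum(e_1mv[s] for s in range(t))
                _, logdet = np.linalg.slogdet(W[t])
                e_det = (
                    sum(digamma((nu[t] + 1 - j) / 2.0) for j in range(1, d + 1))
                    + d * np.log(2.0)
                    + logdet
                )
                diff = X[i] - m[t]
                slow[i, t] = (
                    e_w
                    + 0.5 * e_det
                    - 0.5 * d * np.log(2 * np.pi)
                    - 0.5 * (d / beta[t] + nu[t] * diff @ W[t] @ diff)
                )
        slow = np.exp(slow - slow.max(1, keepdims=True))
        slow /= slow.sum(1, keepdims=True)
        assert np.abs(r_fast - slow).max() < 1e-10

    def test_weight_shrinkage_with_exponential_gamma(self):
        mix = bo.random_mixture(3, 2, 1200, seed=11, separation=12.0)
        X, _ = bo.sample_mixture(mix)
        post = bo.fit_variational(X, bo.make_priors(X, 8), seed=0)
        assert (post.expected_weights() > 0.01).sum() <= 4

    def test_missing_values_rejected(self):
        X = np.random.default_rng(0).standard_normal((50, 2))
        X[3, 1] = np.nan
        with pytest.raises(ValueError, match="missing"):
            bo.fit_variational(X, bo.make_priors(np.nan_to_num(X), 2))


class TestSample:
    def test_empty_draw(self, single_component_posterior):
        _, post = single_component_posterior
        out = bo.sample(post, 0, seed=0)
        assert out.matrix.shape == (0, 3)

    def test_deterministic_per_seed(self, single_component_posterior):
        _, post = single_component_posterior
        a = bo.sample(post, 200, seed=9).matrix
        b = bo.sample(post, 200, seed=9).matrix
        c = bo.sample(post, 200, seed=10).matrix
        assert np.array_equal(a, b) and not np.array_equal(a, c)

    def test_mean_within_clt_bound(self, single_component_posterior):
        _, post = single_component_posterior
        out = bo.sample(post, 50000, seed=4)
        se = np.sqrt(np.diag(post.component_covariances()[0]) / 50000)
        assert (np.abs(out.matrix.mean(axis=0) - post.m[0]) < 3 * se).all()

    def test_round_trip_units(self, single_component_posterior):
        X, post = single_component_posterior
        sm = bo.robust_scale_fit(X)
        post_scaled = E.BGMMPosterior(
            priors=post.priors, a=post.a, b=post.b, m=post.m, beta=post.beta,
            W=post.W, nu=post.nu, responsibilities=post.responsibilities,
            elbo_trace=post.elbo_trace, seed=post.seed, scaling=sm,
        )
        original_units = bo.sample(post_scaled, 100, seed=2).matrix
        internal = bo.sample(post, 100, seed=2).matrix
        assert np.abs(sm.transform(original_units) - internal).max() < 1e-10

    def test_negative_p_errors(self, single_component_posterior):
        _, post = single_component_posterior
        with pytest.raises(ValueError):
            bo.sample(post, -1)


class TestPersistence:
    def test_json_round_trip(self, single_component_posterior, tmp_path):
        _, post = single_component_posterior
        path = tmp_path / "model.json"
        post.save(path)
        back = E.BGMMPosterior.load(path)
        assert np.allclose(back.m, post.m)
        assert np.allclose(back.W, post.W)
        assert back.elbo_trace == post.elbo_trace
        a = bo.sample(post, 50, seed=1).matrix
        b = bo.sample(back, 50, seed=1).matrix
        assert np.allclose(a, b)

    def test_sampling_consistency_of_mixture_moments(self):
        # empirical moments of a large draw match the model's mixture moments
        mix = bo.random_mixture(2, 3, 2000, seed=5, separation=6.0)
        X, _ = bo.sample_mixture(mix)
        post = bo.fit_variational(X, bo.make_priors(X, 2), seed=0)
        out = bo.sample(post, 100000, seed=0, weight_mode="expected")
        w = post.expected_weights()
        w = w / w.sum()
        model_mean = (w[:, None] * post.m).sum(axis=0)
        scale = np.abs(model_mean) + 1.0
        assert (np.abs(out.matrix.mean(axis=0) - model_mean) / scale < 0.02).all()
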