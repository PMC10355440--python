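"""Tests for the coordinate-ascent fitting loop, imputation and prediction."""

import time

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from mrmash import (
    FitOptions,
    MixturePrior,
    ModelFit,
    RegressionDataset,
    ScenarioSpec,
    bmsr_mix_posterior,
    fit_mrmash,
    impute_missing,
    predict,
    simulate_dataset,
    univariate_stats,
)
from oracles import exact_log_marginal

FIXED = FitOptions(
    update_w0=False,
    update_V=False,
    standardize_X=False,
    fit_intercept=False,
    elbo_tol=1e-10,
    coef_tol=1e-12,
    max_iter=500,
)


def two_comp_prior(r, slab=0.5):
    S0 = np.stack([np.zeros((r, r)), slab * np.eye(r)])
    return MixturePrior(S0, np.array([0.5, 0.5]), ("null", "slab"))


class TestFitOptions:
    def test_validation(self):
        with pytest.raises(ValueError):
            FitOptions(max_iter=0)
        with pytest.raises(ValueError):
            FitOptions(elbo_tol=0.0)
        with pytest.raises(ValueError):
            FitOptions(w0_threshold=0.5)
        with pytest.raises(ValueError):
            FitOptions(V_structure="sparse")


class TestFit:
    def test_single_predictor_reduces_to_mixture_posterior(self, rng):
        """With p=1 one sweep must reproduce the single-variable posterior exactly."""
        n, r = 40, 3
        x = rng.standard_normal(n)
        Y = np.outer(x, [0.5, 0.5, 0.0]) + 0.3 * rng.standard_normal((n, r))
        V = 0.09 * np.eye(r)
        prior = two_comp_prior(r)
        opts = FitOptions(
            update_w0=False, update_V=False, standardize_X=False,
            fit_intercept=False, max_iter=1,
        )
        fit = fit_mrmash(RegressionDataset(x[:, None], Y), prior, opts, V_init=V)
        bhat, S = univariate_stats(x, Y, V)
        post = bmsr_mix_posterior(bhat, S, prior)
        np.testing.assert_allclose(fit.Bbar[0], post.mean, atol=1e-12)
        np.testing.assert_allclose(fit.posteriors[0].w1, post.w1, atol=1e-12)
        assert not fit.converged and len(fit.elbo_trace) == 1

    def test_ridge_limit_with_isotropic_prior(self, rng):
        """K=1 isotropic prior and fixed isotropic V recover the ridge estimator."""
        n, p, r = 40, 10, 3
        Q, _ = np.linalg.qr(rng.standard_normal((n, p)))
        Y = rng.standard_normal((n, r))
        sigma2, tau2 = 0.7, 1.3
        prior = MixturePrior(sigma2 * np.eye(r)[None], np.array([1.0]))
        fit = fit_mrmash(
            RegressionDataset(Q, Y), prior, FIXED, V_init=tau2 * np.eye(r)
        )
        ridge = np.linalg.solve(Q.T @ Q + (tau2 / sigma2) * np.eye(p), Q.T @ Y)
        np.testing.assert_allclose(fit.Bbar, ridge, atol=1e-8)

    def test_constant_predictor_rejected(self, rng):
        X = rng.standard_normal((30, 3))
        X[:, 1] = 2.0
        Y = rng.standard_normal((30, 2))
        from mrmash import ConstantPredictorError

        data = RegressionDataset(X, Y)
        assert data.constant_predictors.tolist() == [False, True, False]
        with pytest.raises(ConstantPredictorError):
            fit_mrmash(data, two_comp_prior(2))

    def test_elbo_monotone_across_configurations(self, rng):
        """ELBO trajectories are nondecreasing with/without missing data and updates."""
        spec = ScenarioSpec(scenario="B", n=250, p=30, r=4, n_causal=3, seed=5)
        sim = simulate_dataset(spec)
        configs = [
            (sim.train, FitOptions(max_iter=60)),
            (sim.train, FitOptions(max_iter=60, update_w0=False)),
            (sim.train, FitOptions(max_iter=60, update_V=False)),
            (sim.train, FitOptions(max_iter=60, V_structure="diagonal")),
        ]
        spec_m = ScenarioSpec(scenario="B", n=250, p=30, r=4, n_causal=3,
                              missing_rate=0.4, seed=5)
        sim_m = simulate_dataset(spec_m)
        configs.append((sim_m.train, FitOptions(max_iter=60)))
        prior = two_comp_prior(4, slab=0.2)
        for data, opts in configs:
            fit = fit_mrmash(data, prior, opts)
            deltas = np.diff(fit.elbo_trace)
            assert deltas.min() >= -1e-6

    def test_elbo_lower_bounds_exact_marginal_likelihood(self, rng):
        """On a tiny instance the converged ELBO sits at or below the exact evidence."""
        n, p = 20, 2
        X = rng.standard_normal((n, p))
        y = 0.5 * X.sum(axis=1) + rng.standard_normal(n)
        w0 = [0.5, 0.5]
        s0 = [0.0, 0.5]
        prior = MixturePrior(np.array([[[0.0]], [[0.5]]]), np.array(w0))
        fit = fit_mrmash(
            RegressionDataset(X, y[:, None]), prior, FIXED, V_init=np.array([[1.0]])
        )
        logml = exact_log_marginal(X, y, w0, s0, 1.0)
        assert fit.elbo_trace[-1] <= logml + 1e-8

    def test_elbo_exact_for_single_predictor(self, rng):
        """With p=1 the factorised family contains the truth: ELBO == evidence."""
        X = rng.standard_normal((15, 1))
        y = 0.4 * X[:, 0] + rng.standard_normal(15)
        w0 = [0.3, 0.7]
        s0 = [0.0, 0.8]
        prior = MixturePrior(np.array([[[0.0]], [[0.8]]]), np.array(w0))
        fit = fit_mrmash(
            RegressionDataset(X, y[:, None]), prior, FIXED, V_init=np.array([[1.0]])
        )
        logml = exact_log_marginal(X, y, w0, s0, 1.0)
        assert abs(fit.elbo_trace[-1] - logml) < 1e-8

    def test_pure_noise_concentrates_weight_on_null(self, rng):
        """With no true signal the estimated prior puts nearly all mass on the null."""
        n, p, r = 300, 20, 5
        X = rng.binomial(2, 0.3, size=(n, p)).astype(float)
        Y = rng.standard_normal((n, r))
        prior = two_comp_prior(r, slab=0.3)
        fit = fit_mrmash(RegressionDataset(X, Y), prior)
        assert fit.prior.w0[0] >= 0.95

    def test_deterministic_given_inputs(self):
        spec = ScenarioSpec(scenario="A", n=200, p=20, r=3, n_causal=2, seed=9)
        sim = simulate_dataset(spec)
        prior = two_comp_prior(3)
        f1 = fit_mrmash(sim.train, prior)
        f2 = fit_mrmash(sim.train, prior)
        np.testing.assert_array_equal(f1.Bbar, f2.Bbar)
        np.testing.assert_array_equal(f1.elbo_trace, f2.elbo_trace)

    def test_masked_entry_recovery_beats_column_means(self):
        """Integrated imputation recovers 30%-masked entries better than column means."""
        wins = 0
        for seed in range(1, 11):
            spec = ScenarioSpec(scenario="A", n=375, p=40, r=5, n_causal=5,
                                missing_rate=0.3, test_fraction=0.2, seed=seed)
            sim = simulate_dataset(spec)
            tr = sim.train
            hidden = ~tr.mask
            truth = simulate_dataset(
                ScenarioSpec(scenario="A", n=375, p=40, r=5, n_causal=5,
                             missing_rate=0.0, test_fraction=0.2, seed=seed)
            ).train.Y
            prior = two_comp_prior(5, slab=0.2)
            fit = fit_mrmash(tr, prior)
            col_means = np.array([tr.Y[tr.mask[:, s], s].mean() for s in range(5)])
            err_fit = np.sqrt(np.mean((fit.Y_imputed[hidden] - truth[hidden]) ** 2))
            err_col = np.sqrt(
                np.mean((np.broadcast_to(col_means, truth.shape)[hidden]
                         - truth[hidden]) ** 2)
            )
            wins += err_fit < err_col
        assert wins >= 8

    def test_per_iteration_cost_scales_linearly_in_p(self):
        """Doubling p at fixed n, r, K should roughly double per-iteration time."""
        prior = two_comp_prior(5, slab=0.2)
        opts = FitOptions(max_iter=3, elbo_tol=1e-12, coef_tol=1e-15)

        def time_fit(p):
            spec = ScenarioSpec(scenario="B", n=300, p=p, r=5, n_causal=5, seed=11)
            sim = simulate_dataset(spec)
            best = np.inf
            for _ in range(3):
                t0 = time.perf_counter()
                fit_mrmash(sim.train, prior, opts)
                best = min(best, time.perf_counter() - t0)
            return best

        assert time_fit(400) / time_fit(200) < 2.8


class TestImputeMissing:
    def test_all_observed_passthrough(self, rng):
        Y = rng.standard_normal((10, 3))
        mask = np.ones_like(Y, dtype=bool)
        X = rng.standard_normal((10, 2))
        Yf, cov = impute_missing(Y, mask, np.zeros(3), np.zeros((2, 3)), X, np.eye(3))
        np.testing.assert_array_equal(Yf, Y)
        np.testing.assert_array_equal(cov, 0.0)

    def test_diagonal_V_fills_marginal_means(self, rng):
        n, p, r = 12, 2, 3
        X = rng.standard_normal((n, p))
        B = rng.standard_normal((p, r))
        b0 = np.array([1.0, -1.0, 0.5])
        V = np.diag([0.5, 1.0, 2.0])
        Y = b0 + X @ B + rng.standard_normal((n, r))
        mask = rng.random((n, r)) > 0.3
        mask[:, 0] = True
        Yf, cov = impute_missing(Y, mask, b0, B, X, V)
        expected = b0 + X @ B
        np.testing.assert_allclose(Yf[~mask], expected[~mask], atol=1e-12)
        for i in range(n):
            for s in range(r):
                if not mask[i, s]:
                    assert cov[i][s, s] == pytest.approx(V[s, s])

    def test_bivariate_conditional_formula(self):
        V = np.array([[1.0, 0.8], [0.8, 1.0]])
        Y = np.array([[np.nan, 1.0]])
        mask = np.array([[False, True]])
        X = np.zeros((1, 1))
        Yf, cov = impute_missing(Y, mask, np.zeros(2), np.zeros((1, 2)), X, V)
        assert Yf[0, 0] == pytest.approx(0.8)
        assert cov[0][0, 0] == pytest.approx(0.36)
        # Monte-Carlo cross-check of the conditional
        rng = np.random.default_rng(0)
        draws = rng.multivariate_normal(np.zeros(2), V, size=400_000)
        sel = np.abs(draws[:, 1] - 1.0) < 0.01
        assert np.mean(draws[sel, 0]) == pytest.approx(0.8, abs=0.01)
        assert np.var(draws[sel, 0]) == pytest.approx(0.36, abs=0.01)

    def test_elbo_trivial_case_equals_gaussian_loglik(self, rng):
        """All-null prior, no missing data: ELBO is the exact Gaussian log-likelihood."""
        n, r = 25, 2
        X = rng.standard_normal((n, 3))
        Y = rng.standard_normal((n, r))
        V = np.array([[1.0, 0.3], [0.3, 0.8]])
        prior = MixturePrior(np.zeros((1, r, r)), np.array([1.0]))
        fit = fit_mrmash(RegressionDataset(X, Y), prior, FIXED, V_init=V)
        loglik = multivariate_normal.logpdf(Y, np.zeros(r), V).sum()
        assert fit.elbo_trace[-1] == pytest.approx(loglik, abs=1e-9)
        np.testing.assert_array_equal(fit.Bbar, 0.0)


class TestPredict:
    def make_fit(self, b0, Bbar, p, r):
        return ModelFit(
            b0=np.asarray(b0, float), Bbar=np.asarray(Bbar, float), V=np.eye(r),
            prior=MixturePrior(np.zeros((1, r, r)), np.array([1.0])),
            elbo_trace=np.zeros(1), n_iter=1, converged=True,
            Y_imputed=np.empty((0, r)), x_center=np.zeros(p), x_scale=np.ones(p),
        )

    def test_null_model_predicts_intercept(self, rng):
        fit = self.make_fit([1.5, -2.0], np.zeros((3, 2)), 3, 2)
        Yhat = predict(rng.standard_normal((5, 3)), fit)
        np.testing.assert_array_equal(Yhat, np.tile([1.5, -2.0], (5, 1)))

    def test_hand_arithmetic(self):
        fit = self.make_fit([1.0, -1.0], [[1.0, 0.0], [0.0, 2.0]], 2, 2)
        Yhat = predict(np.array([[3.0, 4.0]]), fit)
        np.testing.assert_array_equal(Yhat, [[4.0, 7.0]])

    def test_training_consistency(self, rng):
        spec = ScenarioSpec(scenario="A", n=150, p=10, r=3, n_causal=2, seed=2)
        sim = simulate_dataset(spec)
        prior = two_comp_prior(3)
        fit = fit_mrmash(sim.train, prior)
        fitted = predict(sim.train.X, fit)
        manual = fit.b0 + ((sim.train.X - fit.x_center) / fit.x_scale) @ fit.Bbar
        np.testing.assert_allclose(fitted, manual, atol=1e-12)

    def test_predictor_id_mismatch(self, rng):
        fit = self.make_fit([0.0], np.zeros((2, 1)), 2, 1)
        fit.predictor_ids = ["v1", "v2"]
        with pytest.raises(ValueError, match="mismatch"):
            predict(np.zeros((1, 2)), fit, predictor_ids=["v1", "v3"])
        Y = predict(np.arange(2.0)[None, ::-1], fit, predictor_ids=["v2", "v1"])
        assert Y.shape == (1, 1)
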