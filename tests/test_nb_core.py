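"""Negative binomial primitives and the classical maximum-likelihood GLM."""

import numpy as np
import pytest
from scipy import optimize, stats

from hnbglm import (
    IdentifiabilityError,
    SimConfig,
    fit_nb_mle,
    iwls_pseudodata,
    nb_logpmf,
    nb_mean_var,
    sim_dataset,
    update_theta,
)
from hnbglm.nb import THETA_MAX, _theta_loglik


class TestLogPmf:
    def test_zero_count_closed_form(self):
        # P(Y=0) = (theta/(mu+theta))**theta
        assert nb_logpmf(0, 2.0, 1.0)[0] == pytest.approx(np.log(1 / 3))

    def test_matches_scipy_nbinom(self, rng):
        # scipy parameterization: n=theta, p=theta/(theta+mu)
        y = np.arange(0, 40)
        for mu, theta in [(0.5, 0.1), (3.0, 1.0), (10.0, 5.0), (25.0, 0.3)]:
            expected = stats.nbinom.logpmf(y, theta, theta / (theta + mu))
            np.testing.assert_allclose(nb_logpmf(y, mu, theta), expected,
                                       rtol=1e-10)

    @pytest.mark.parametrize("mu", [0.5, 2.0, 10.0])
    @pytest.mark.parametrize("theta", [0.1, 1.0, 5.0])
    def test_normalization(self, mu, theta):
        upper = int(stats.nbinom.ppf(1 - 1e-13, theta, theta / (theta + mu))) + 50
        total = np.sum(np.exp(nb_logpmf(np.arange(upper), mu, theta)))
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_poisson_limit(self):
        y = np.arange(21)
        poisson = stats.poisson.logpmf(y, 4.0)
        np.testing.assert_allclose(nb_logpmf(y, 4.0, 1e8), poisson, atol=1e-4)

    @pytest.mark.parametrize("bad", [
        dict(y=[1], mu=-1.0, theta=1.0),
        dict(y=[1], mu=2.0, theta=0.0),
        dict(y=[-1], mu=2.0, theta=1.0),
        dict(y=[1.5], mu=2.0, theta=1.0),
    ])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            nb_logpmf(**bad)


class TestMeanVar:
    def test_closed_form(self):
        assert nb_mean_var(2.0, 1.0) == (2.0, 6.0)

    def test_poisson_limit_variance(self):
        mean, var = nb_mean_var(5.0, 1e12)
        assert var == pytest.approx(mean, rel=1e-10)

    def test_overdispersion_always(self, rng):
        mu = rng.uniform(0.01, 100, 200)
        theta = rng.uniform(0.01, 100, 200)
        mean, var = nb_mean_var(mu, theta)
        assert np.all(var >= mean)

    def test_sampling_oracle(self, rng):
        # empirical variance of gamma-Poisson draws matches mu + mu^2/theta
        mu, theta = 3.0, 0.5
        lam = rng.gamma(theta, mu / theta, size=10 ** 6)
        y = rng.poisson(lam)
        assert y.mean() == pytest.approx(3.0, rel=0.02)
        assert y.var() == pytest.approx(21.0, rel=0.05)


class TestIwlsPseudodata:
    def test_residual_vanishes_at_fit(self):
        eta = np.array([0.5, 1.0, 2.0])
        y = np.exp(eta)  # y == mu
        z, w = iwls_pseudodata(y.round(), np.log(y.round()), 2.0)
        np.testing.assert_allclose(z, np.log(y.round()))

    def test_poisson_limit_weights(self):
        eta = np.array([0.0, 1.0, 2.5])
        _, w = iwls_pseudodata(np.array([1.0, 2.0, 3.0]), eta, 1e10)
        np.testing.assert_allclose(w, np.exp(eta), rtol=1e-6)

    def test_wls_step_equals_fisher_scoring(self, rng):
        # one weighted LS solve on (z, w) must equal one Fisher-scoring
        # step computed from the analytic score and information
        n, theta = 20, 1.7
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        beta = np.array([1.0, 0.3])
        offset = rng.uniform(1, 2, n)
        eta = offset + X @ beta
        y = rng.poisson(np.exp(eta)).astype(float)
        z, w = iwls_pseudodata(y, eta, theta)
        wls = np.linalg.solve(X.T @ (X * w[:, None]), X.T @ (w * (z - offset)))
        mu = np.exp(eta)
        score = X.T @ ((y - mu) * theta / (mu + theta))
        fisher = X.T @ (X * w[:, None])
        newton = beta + np.linalg.solve(fisher, score)
        np.testing.assert_allclose(wls, newton, atol=1e-10)


class TestUpdateTheta:
    def test_consistency(self, rng):
        mu = np.full(5000, 8.0)
        y = rng.poisson(rng.gamma(2.0, mu / 2.0)).astype(float)
        theta = update_theta(y, mu, 1.0)
        assert 1.7 <= theta <= 2.3

    def test_beats_grid_search(self, rng):
        mu = np.exp(rng.uniform(0, 3, 300))
        y = rng.poisson(rng.gamma(0.8, mu / 0.8)).astype(float)
        theta = update_theta(y, mu, 1.0)
        grid = np.logspace(np.log10(0.01), np.log10(100), 1000)
        best_grid = max(_theta_loglik(y, mu, t) for t in grid)
        assert _theta_loglik(y, mu, theta) >= best_grid - 1e-6

    def test_monotone_improvement(self, rng):
        mu = np.exp(rng.uniform(0, 2, 100))
        y = rng.poisson(mu).astype(float)
        for theta0 in (0.01, 0.5, 10.0):
            res = update_theta(y, mu, theta0, full_output=True)
            assert res.loglik >= _theta_loglik(y, mu, theta0) - 1e-8

    def test_degenerate_no_dispersion(self):
        # y identical to mu: likelihood increases toward the Poisson
        # limit, so theta is driven to the upper bound and flagged
        y = np.full(50, 6.0)
        res = update_theta(y, y, 1.0, full_output=True)
        assert res.at_bound
        assert res.theta == pytest.approx(THETA_MAX, rel=1e-6)


class TestFitNbMle:
    def test_intercept_only_saturated_mean(self):
        fit = fit_nb_mle(np.array([4, 4, 4, 4]))
        assert fit.beta_hat[0] == pytest.approx(np.log(4.0), abs=1e-6)

    def test_offset_rescaling_contract(self, small_replicate):
        rep = small_replicate
        base = fit_nb_mle(rep.y, rep.X, offset=rep.log_T)
        shifted = fit_nb_mle(rep.y, rep.X, offset=rep.log_T + np.log(10.0))
        assert shifted.beta_hat[0] == pytest.approx(
            base.beta_hat[0] - np.log(10.0), abs=1e-6)
        np.testing.assert_allclose(shifted.beta_hat[1:], base.beta_hat[1:],
                                   atol=1e-8)

    def test_identifiability_error_wide_design(self, wide_replicate):
        rep = wide_replicate
        with pytest.raises(IdentifiabilityError):
            fit_nb_mle(rep.y, rep.X, offset=rep.log_T)

    def test_identifiability_error_rank_deficient(self, small_replicate):
        rep = small_replicate
        X = np.column_stack([rep.X, rep.X[:, 0]])
        with pytest.raises(IdentifiabilityError):
            fit_nb_mle(rep.y, X, offset=rep.log_T)

    def test_matches_direct_likelihood_maximization(self, rng):
        # small fixture: compare against a generic optimizer over
        # (beta, log theta)
        rep = sim_dataset(SimConfig(n=30, k=2, rho_class="weak",
                                    effects={1: "large"}, seed=11))
        fit = fit_nb_mle(rep.y, rep.X, offset=rep.log_T)
        Xd = np.column_stack([np.ones(30), rep.X])

        def negll(params):
            mu = np.exp(np.clip(rep.log_T + Xd @ params[:3], -30, 30))
            return -_theta_loglik(rep.y.astype(float), mu, np.exp(params[3]))

        start = np.concatenate([fit.beta_hat, [np.log(fit.theta_hat)]])
        direct = optimize.minimize(negll, start + 0.05, method="Nelder-Mead",
                                   options={"xatol": 1e-10, "fatol": 1e-12,
                                            "maxiter": 20000})
        assert -fit.deviance / 2 == pytest.approx(-direct.fun, abs=1e-5)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        rep = sim_dataset(SimConfig(n=150, k=3, rho_class="weak",
                                    effects={2: "large"}, seed=3))
        fit = fit_nb_mle(rep.y, rep.X, offset=rep.log_T)
        model = sm.NegativeBinomial(rep.y, sm.add_constant(rep.X),
                                    offset=rep.log_T, loglike_method="nb2")
        res = model.fit(disp=0, maxiter=500, method="bfgs")
        assert -fit.deviance / 2 == pytest.approx(res.llf, abs=1e-3)
        np.testing.assert_allclose(fit.beta_hat, res.params[:-1], atol=5e-3)
        assert fit.theta_hat == pytest.approx(1 / res.params[-1], rel=1e-2)

    def test_coverage_of_true_coefficients(self):
        # Wald intervals at +-3 SE should cover the truth in nearly all
        # well-conditioned replicates
        covered = total = 0
        for seed in range(100):
            rep = sim_dataset(SimConfig(n=500, k=3, rho_class="weak",
                                        effects={1: "moderate"}, seed=seed))
            fit = fit_nb_mle(rep.y, rep.X, offset=rep.log_T)
            err = np.abs(fit.beta_hat[1:] - rep.beta_true)
            covered += int(np.sum(err <= 3 * fit.se_beta[1:]))
            total += 3
        assert covered / total >= 0.95
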