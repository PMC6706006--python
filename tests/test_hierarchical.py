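"""Hierarchical NB model: E-step, penalized M-step, EM-IWLS fit and
prior-scale selection."""

import numpy as np
import pytest
from scipy import optimize, stats

from hnbglm import (
    DEFAULT_PRIOR_SCALES,
    PriorSpec,
    SimConfig,
    effective_params,
    estep_tau_inv,
    fit_hnb,
    fit_nb_mle,
    mstep_beta,
    scan_prior_scales,
    sim_dataset,
)
from hnbglm.nb import _theta_loglik


class TestEstep:
    def test_closed_form_at_zero(self):
        assert estep_tau_inv(0.0, 1.0, 1.0) == pytest.approx(2.0)

    def test_decreasing_in_effect_size(self):
        vals = [estep_tau_inv(b, 1.0, 0.5) for b in (0.0, 0.1, 0.5, 2.0, 50.0)]
        assert np.all(np.diff(vals) < 0)
        assert vals[-1] < 1e-3  # vanishing shrinkage on huge effects

    def test_matches_inverse_chisq_sampling(self, rng):
        # tau^2 | beta ~ scaled-Inv-chi2(1+nu, (nu s^2 + beta^2)/(1+nu));
        # the E-step must equal the Monte-Carlo mean of tau^-2
        for _ in range(20):
            nu = rng.uniform(0.5, 4.0)
            s = rng.uniform(0.05, 2.0)
            beta = rng.normal(scale=1.0)
            df = 1.0 + nu
            scale = (nu * s ** 2 + beta ** 2) / df
            # scaled-Inv-chi2(df, scale) == InvGamma(df/2, df*scale/2)
            tau2 = stats.invgamma.rvs(df / 2, scale=df * scale / 2,
                                      size=200_000, random_state=rng)
            draws = 1.0 / tau2
            mc_se = draws.std() / np.sqrt(draws.size)
            assert estep_tau_inv(beta, nu, s) == pytest.approx(
                draws.mean(), abs=4 * mc_se)


class TestMstep:
    @staticmethod
    def _fixture(rng, n, k):
        X = np.column_stack([np.ones(n), rng.normal(size=(n, k))])
        z = rng.normal(size=n)
        w = rng.uniform(0.2, 3.0, n)
        offset = rng.uniform(-1, 1, n)
        return X, z, w, offset

    def test_flat_prior_equals_wls(self, rng):
        X, z, w, offset = self._fixture(rng, 40, 3)
        beta = mstep_beta(z, w, offset, X, np.zeros(4), 1.0)
        wls = np.linalg.solve(X.T @ (X * w[:, None]),
                              X.T @ (w * (z - offset)))
        np.testing.assert_allclose(beta, wls, atol=1e-10)

    def test_infinite_shrinkage_zeroes_coefficient(self, rng):
        X, z, w, offset = self._fixture(rng, 40, 3)
        tau2_inv = np.array([0.0, 1e14, 0.0, 0.0])
        beta = mstep_beta(z, w, offset, X, tau2_inv, 1.0)
        assert abs(beta[1]) < 1e-8

    def test_wide_design_matches_direct_optimizer(self, rng):
        # k > n: the ridge system is still the unique maximizer of the
        # penalized weighted least-squares objective
        X, z, w, offset = self._fixture(rng, 25, 40)
        tau2_inv = np.concatenate([[0.0], rng.uniform(0.5, 5.0, 40)])
        sigma2 = 1.3
        beta = mstep_beta(z, w, offset, X, tau2_inv, sigma2)

        def negobj(b):
            resid = z - offset - X @ b
            return (np.sum(w * resid ** 2) / sigma2 + tau2_inv @ b ** 2)

        direct = optimize.minimize(negobj, beta + 0.01, method="L-BFGS-B",
                                   options={"ftol": 1e-15, "gtol": 1e-12,
                                            "maxiter": 10000})
        assert negobj(beta) <= direct.fun + 1e-8
        np.testing.assert_allclose(beta, direct.x, atol=1e-4)


class TestEffectiveParams:
    def test_flat_prior_counts_all_columns(self, rng):
        X = np.column_stack([np.ones(30), rng.normal(size=(30, 4))])
        w = rng.uniform(0.5, 2.0, 30)
        assert effective_params(X, w, 1.0, np.zeros(5)) == pytest.approx(5.0)

    def test_scalar_ridge_case(self):
        # single unit column, unit weight/precision: trace = 1/(1+1)
        X = np.ones((1, 1))
        assert effective_params(X, np.ones(1), 1.0, np.ones(1)) == \
            pytest.approx(0.5)

    def test_monotone_in_prior_scale(self, small_replicate):
        rep = small_replicate
        fits = [fit_hnb(rep.y, rep.X, offset=rep.log_T,
                        prior=PriorSpec(nu=1.0, scales=s))
                for s in (0.01, 2.0)]
        assert fits[0].effective_params <= fits[1].effective_params + 1e-8
        for f in fits:
            assert 0 < f.effective_params <= rep.X.shape[1] + 1


class TestFitHnb:
    def test_flat_prior_limit_matches_mle(self, small_replicate):
        rep = small_replicate
        mle = fit_nb_mle(rep.y, rep.X, offset=rep.log_T)
        flat = fit_hnb(rep.y, rep.X, offset=rep.log_T,
                       prior=PriorSpec(nu=1.0, scales=100.0))
        np.testing.assert_allclose(flat.beta_hat, mle.beta_hat, atol=0.01)

    def test_handles_k_equal_n(self, wide_replicate):
        rep = wide_replicate
        fit = fit_hnb(rep.y, rep.X, offset=rep.log_T,
                      prior=PriorSpec(nu=1.0, scales=0.01))
        assert fit.converged
        assert np.all(np.isfinite(fit.beta_hat))
        assert np.all(fit.se_beta > 0)

    def test_stronger_scale_shrinks_more(self, wide_replicate):
        rep = wide_replicate
        null_idx = [j for j in range(1, 51) if j not in (15, 30, 45)]
        mags = []
        for s in (0.01, 2.0):
            fit = fit_hnb(rep.y, rep.X, offset=rep.log_T,
                          prior=PriorSpec(nu=1.0, scales=s))
            mags.append(np.mean(np.abs(fit.beta_hat[null_idx])))
        assert mags[0] < mags[1]

    def test_shrinkage_monotone_across_default_scales(self, small_replicate):
        rep = small_replicate
        norms = [np.linalg.norm(
            fit_hnb(rep.y, rep.X, offset=rep.log_T,
                    prior=PriorSpec(nu=1.0, scales=s)).beta_hat[1:])
            for s in DEFAULT_PRIOR_SCALES]
        assert np.all(np.diff(norms) >= -1e-8)

    def test_deterministic(self, small_replicate):
        rep = small_replicate
        a = fit_hnb(rep.y, rep.X, offset=rep.log_T,
                    prior=PriorSpec(nu=1.0, scales=0.1))
        b = fit_hnb(rep.y, rep.X, offset=rep.log_T,
                    prior=PriorSpec(nu=1.0, scales=0.1))
        assert np.array_equal(a.beta_hat, b.beta_hat)
        assert np.array_equal(a.se_beta, b.se_beta)
        assert a.theta_hat == b.theta_hat

    def test_aic_identity_and_convergence_flag(self, small_replicate):
        rep = small_replicate
        fit = fit_hnb(rep.y, rep.X, offset=rep.log_T,
                      prior=PriorSpec(nu=1.0, scales=0.25))
        assert fit.adjusted_aic == pytest.approx(
            fit.deviance + 2 * fit.effective_params)
        d = fit.deviance_trace
        assert fit.converged == (
            abs(d[-1] - d[-2]) / (0.1 + abs(d[-1])) < 1e-5)

    def test_posterior_mode_stationarity(self):
        # at the EM fixed point the gradient of the exact log posterior
        # (t prior integrated over the mixing variances) must vanish
        rep = sim_dataset(SimConfig(n=80, k=3, rho_class="weak",
                                    effects={1: "large"}, seed=5))
        nu, s = 1.0, 0.5
        fit = fit_hnb(rep.y, rep.X, offset=rep.log_T,
                      prior=PriorSpec(nu=nu, scales=s), eps=1e-12,
                      max_iter=2000, standardize=False)
        Xd = np.column_stack([np.ones(80), rep.X])
        beta, theta = fit.beta_hat, fit.theta_hat
        mu = np.exp(rep.log_T + Xd @ beta)
        score = Xd.T @ ((rep.y - mu) * theta / (mu + theta))
        prior_grad = np.concatenate(
            [[0.0], -(1 + nu) * beta[1:] / (nu * s ** 2 + beta[1:] ** 2)])
        grad = score + prior_grad
        assert np.max(np.abs(grad)) < 1e-3


class TestScanPriorScales:
    def test_default_scan_runs_nine_fits(self, small_replicate):
        rep = small_replicate
        scan = scan_prior_scales(rep.y, rep.X, offset=rep.log_T)
        assert len(scan.fits) == 9
        np.testing.assert_allclose(scan.scales, DEFAULT_PRIOR_SCALES)

    def test_single_scale(self, small_replicate):
        rep = small_replicate
        scan = scan_prior_scales(rep.y, rep.X, offset=rep.log_T, scales=[0.1])
        assert scan.best_index == 0

    def test_best_minimizes_adjusted_aic(self, small_replicate):
        rep = small_replicate
        scan = scan_prior_scales(rep.y, rep.X, offset=rep.log_T)
        aics = [f.adjusted_aic for f in scan.fits if f.converged]
        assert scan.best.adjusted_aic == pytest.approx(min(aics))
        assert scan.best.converged

    def test_unsorted_scales_rejected(self, small_replicate):
        rep = small_replicate
        with pytest.raises(ValueError):
            scan_prior_scales(rep.y, rep.X, offset=rep.log_T,
                              scales=[0.5, 0.1])

    def test_frame_export(self, small_replicate):
        rep = small_replicate
        frame = scan_prior_scales(rep.y, rep.X, offset=rep.log_T).to_frame()
        assert list(frame.columns) == ["scale", "deviance",
                                       "effective_params", "adjusted_aic",
                                       "converged"]
        assert len(frame) == 9


class TestPriorSpec:
    def test_scalar_broadcasts(self):
        np.testing.assert_allclose(PriorSpec(scales=0.3).scales_for(4),
                                   [0.3] * 4)

    def test_invalid_scales(self):
        with pytest.raises(ValueError):
            PriorSpec(scales=-1.0).scales_for(2)
        with pytest.raises(ValueError):
            PriorSpec(nu=0.0)
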