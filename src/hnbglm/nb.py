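"""Negative binomial distribution primitives and the classical NB GLM.

The model for a single microbial feature is

    y_i ~ NB(mu_i, theta),    log mu_i = log T_i + x_i' beta,

where ``T_i`` is the library size (total reads) of sample *i*, entering
the linear predictor as an offset with coefficient fixed at one, and
``theta`` is the dispersion parameter of the mean/dispersion ("NB2")
parameterization:

    E(y_i) = mu_i,    Var(y_i) = mu_i + mu_i**2 / theta.

Small ``theta`` means strong over-dispersion; ``theta -> inf`` recovers
the Poisson model.  Maximum likelihood alternates iteratively
reweighted least squares (IWLS) updates of ``beta`` with Newton-Raphson
updates of ``theta`` on the log scale, the same alternation used by
``glm.nb``-style fitters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import special
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

logger = logging.getLogger(__name__)

#: Bound on |linear predictor| before exponentiation.  exp(30) ~ 1e13
#: comfortably exceeds any realistic library-size-scaled mean while
#: keeping mu, the IWLS weights and the log-pmf finite in double
#: precision.
ETA_MAX = 30.0

#: Box constraints for the dispersion.  The lower bound guards the
#: profile likelihood against degenerate all-equal data; the upper bound
#: is effectively the Poisson limit.
THETA_MIN = 1e-4
THETA_MAX = 1e4

DEFAULT_TOL = 1e-5
DEFAULT_MAX_ITER = 50


class IdentifiabilityError(ValueError):
    """Maximum-likelihood fit is not identifiable (``n <= k+1`` or a
    rank-deficient design)."""


def _as_counts(y) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise ValueError("y must be a 1-d count vector")
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite values")
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("y must contain non-negative integers")
    return y


def _as_positive(x, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(~np.isfinite(x)) or np.any(x <= 0):
        raise ValueError(f"{name} must be positive and finite")
    return x


def nb_logpmf(y, mu, theta) -> np.ndarray:
    """Elementwise log NB(y | mu, theta) in the mean/dispersion form.

    Computed through ``gammaln`` for numerical stability::

        log Gamma(y+theta) - log Gamma(theta) - log Gamma(y+1)
        + theta*log(theta/(mu+theta)) + y*log(mu/(mu+theta))
    """
    y = _as_counts(np.atleast_1d(y))
    mu = _as_positive(mu, "mu")
    theta = float(_as_positive(theta, "theta"))
    log_denom = np.log(mu + theta)
    return (
        special.gammaln(y + theta)
        - special.gammaln(theta)
        - special.gammaln(y + 1.0)
        + theta * (np.log(theta) - log_denom)
        + y * (np.log(mu) - log_denom)
    )


def nb_deviance(y, mu, theta) -> float:
    """-2 * sum log NB(y | mu, theta), the deviance used for the
    convergence rule and the adjusted AIC."""
    return float(-2.0 * np.sum(nb_logpmf(y, mu, theta)))


def nb_mean_var(mu, theta):
    """Mean and variance implied by the NB pmf: (mu, mu + mu**2/theta).

    The variance always dominates the mean, which is how the model
    accommodates over-dispersed counts.
    """
    mu = _as_positive(mu, "mu")
    theta = _as_positive(theta, "theta")
    mean = mu + 0.0
    var = mu + mu * mu / theta
    if mean.ndim == 0:
        return float(mean), float(var)
    return mean, var


def iwls_pseudodata(y, eta, theta):
    """Working response and weights for one IWLS step under the log link.

    With ``mu = exp(eta)`` (eta clipped to ``|eta| <= ETA_MAX``):

        z_i = eta_i + (y_i - mu_i) / mu_i
        w_i = mu_i * theta / (mu_i + theta)

    ``w_i`` is the inverse of ``Var(y_i) * (d eta / d mu)**2``, i.e. the
    Fisher weight of the NB GLM at fixed theta; as ``theta -> inf`` it
    tends to the Poisson weight ``mu_i``.
    """
    y = _as_counts(y)
    theta = float(_as_positive(theta, "theta"))
    eta = np.asarray(eta, dtype=float)
    if not np.all(np.isfinite(eta)):
        raise ValueError("eta must be finite")
    eta_c = np.clip(eta, -ETA_MAX, ETA_MAX)
    if np.any(eta_c != eta):
        logger.debug("linear predictor clipped to |eta| <= %g", ETA_MAX)
    mu = np.exp(eta_c)
    z = eta_c + (y - mu) / mu
    w = mu * theta / (mu + theta)
    return z, w


@dataclass
class ThetaUpdate:
    """Result of one profile-likelihood dispersion update."""

    theta: float
    converged: bool
    at_bound: bool
    loglik: float


def _theta_loglik(y, mu, theta) -> float:
    # Only the theta-dependent pieces are needed for maximization but
    # the full log likelihood is cheap and reusable.
    log_denom = np.log(mu + theta)
    return float(
        np.sum(
            special.gammaln(y + theta)
            - special.gammaln(theta)
            - special.gammaln(y + 1.0)
            + theta * (np.log(theta) - log_denom)
            + y * (np.log(mu) - log_denom)
        )
    )


def update_theta(y, mu, theta0, max_iter: int = 50, tol: float = 1e-8,
                 full_output: bool = False):
    """Maximize the profile log likelihood in theta at fixed means.

    Newton-Raphson on ``log(theta)`` with step halving, constrained to
    ``[THETA_MIN, THETA_MAX]``.  If Newton fails to converge the
    method-of-moments estimate is taken as a fallback (keeping whichever
    value has the higher likelihood) and the result is flagged.
    """
    y = _as_counts(y)
    mu = _as_positive(mu, "mu")
    theta0 = float(_as_positive(theta0, "theta0"))

    lo, hi = np.log(THETA_MIN), np.log(THETA_MAX)
    u = float(np.clip(np.log(theta0), lo, hi))
    ll = _theta_loglik(y, mu, np.exp(u))
    converged = False
    for _ in range(max_iter):
        theta = np.exp(u)
        r = y + theta
        denom = mu + theta
        grad = float(np.sum(
            special.digamma(r) - special.digamma(theta)
            + np.log(theta) + 1.0 - np.log(denom) - r / denom
        ))
        hess = float(np.sum(
            special.polygamma(1, r) - special.polygamma(1, theta)
            + 1.0 / theta - 2.0 / denom + r / denom ** 2
        ))
        g_u = theta * grad
        h_u = theta * grad + theta * theta * hess
        if h_u < 0:
            step = -g_u / h_u
        else:  # not locally concave: fall back to a gradient step
            step = np.sign(g_u)
        step = float(np.clip(step, -5.0, 5.0))
        u_new, ll_new = u, ll
        for _ in range(30):
            cand = float(np.clip(u + step, lo, hi))
            ll_cand = _theta_loglik(y, mu, np.exp(cand))
            if ll_cand >= ll - 1e-12:
                u_new, ll_new = cand, ll_cand
                break
            step *= 0.5
        if abs(u_new - u) < tol:
            u, ll = u_new, ll_new
            converged = True
            break
        u, ll = u_new, ll_new

    theta = float(np.exp(u))
    at_bound = theta <= THETA_MIN * (1 + 1e-8) or theta >= THETA_MAX * (1 - 1e-8)
    if not converged and not at_bound:
        # method-of-moments fallback: solve sum((y-mu)^2 - mu)/mu^2 = n/theta
        denom = float(np.sum(((y - mu) ** 2 - mu) / mu ** 2))
        if denom > 0:
            theta_mm = float(np.clip(len(y) / denom, THETA_MIN, THETA_MAX))
            ll_mm = _theta_loglik(y, mu, theta_mm)
            if ll_mm > ll:
                theta, ll = theta_mm, ll_mm
        logger.warning("dispersion update did not converge; "
                       "method-of-moments fallback used (theta=%g)", theta)
    if full_output:
        return ThetaUpdate(theta=theta, converged=converged or at_bound,
                           at_bound=at_bound, loglik=ll)
    return theta


@dataclass
class NBFit:
    """Classical NB GLM maximum-likelihood fit.

    ``beta_hat`` includes the intercept as its first entry; standard
    errors come from the inverse weighted Fisher information at the
    final iterate, and ``deviance`` is -2 times the NB log likelihood
    at the returned parameters.
    """

    beta_hat: np.ndarray
    se_beta: np.ndarray
    theta_hat: float
    deviance: float
    n_iter: int
    converged: bool
    vcov_diag: np.ndarray
    vcov: np.ndarray = field(repr=False, default=None)
    names: list = field(default_factory=list)


def _check_full_rank(Xd: np.ndarray) -> None:
    n, p = Xd.shape
    if n <= p:
        raise IdentifiabilityError(
            f"classical NB MLE is non-identifiable: n={n} samples <= {p} "
            "design columns (including intercept); use the hierarchical model"
        )
    if np.linalg.matrix_rank(Xd) < p:
        raise IdentifiabilityError("design matrix is rank deficient")


def _init_beta0(y: np.ndarray, offset: np.ndarray) -> float:
    total = float(np.sum(np.exp(np.clip(offset, -ETA_MAX, ETA_MAX))))
    s = float(np.sum(y))
    if s <= 0:
        raise ValueError("all counts are zero; nothing to fit")
    return float(np.log(s / total))


def _irls_nb(y, Xd, offset, tol=DEFAULT_TOL, max_iter=DEFAULT_MAX_ITER):
    """Core alternation: IWLS for beta, Newton-Raphson for theta.

    ``Xd`` is the full design including the intercept column.  Stops on
    the relative deviance rule |d(t)-d(t-1)| / (0.1+|d(t)|) < tol.
    """
    n, p = Xd.shape
    _check_full_rank(Xd)
    beta = np.zeros(p)
    beta[0] = _init_beta0(y, offset)
    theta = 1.0
    dev_prev = np.inf
    converged = False
    n_iter = 0
    dev = np.inf
    for t in range(max_iter):
        n_iter = t + 1
        eta = np.clip(offset + Xd @ beta, -ETA_MAX, ETA_MAX)
        ll_old = _theta_loglik(y, np.exp(eta), theta)
        z, w = iwls_pseudodata(y, eta, theta)
        A = Xd.T @ (Xd * w[:, None])
        b = Xd.T @ (w * (z - offset))
        try:
            beta_cand = np.linalg.solve(A, b)
        except np.linalg.LinAlgError as err:  # pragma: no cover - guarded above
            raise IdentifiabilityError(str(err)) from err
        # step halving: a full Fisher-scoring step can overshoot at
        # strong over-dispersion with many covariates
        direction = beta_cand - beta
        for _ in range(30):
            mu = np.exp(np.clip(offset + Xd @ (beta + direction),
                                -ETA_MAX, ETA_MAX))
            if _theta_loglik(y, mu, theta) >= ll_old - 1e-10:
                break
            direction *= 0.5
        beta = beta + direction
        mu = np.exp(np.clip(offset + Xd @ beta, -ETA_MAX, ETA_MAX))
        theta = update_theta(y, mu, theta)
        dev = -2.0 * _theta_loglik(y, mu, theta)
        if abs(dev - dev_prev) / (0.1 + abs(dev)) < tol:
            converged = True
            break
        dev_prev = dev

    eta = np.clip(offset + Xd @ beta, -ETA_MAX, ETA_MAX)
    _, w = iwls_pseudodata(y, eta, theta)
    fisher = Xd.T @ (Xd * w[:, None])
    vcov = np.linalg.inv(fisher)
    se = np.sqrt(np.diag(vcov))
    return {
        "beta": beta, "se": se, "theta": theta, "deviance": dev,
        "n_iter": n_iter, "converged": converged, "vcov": vcov,
    }


class NegativeBinomialRegressor(RegressorMixin, BaseEstimator):
    """Classical negative binomial GLM with log link and offset.

    Fit by maximum likelihood: IWLS updates of the coefficients
    alternated with Newton-Raphson updates of the dispersion on the log
    scale, until the relative change in deviance falls below ``tol``.

    Parameters
    ----------
    fit_intercept : bool, default True
        Prepend an (unpenalized) intercept column to the design.
    tol : float, default 1e-5
        Relative deviance convergence tolerance.
    max_iter : int, default 50
        Maximum number of outer IWLS/dispersion alternations.

    Attributes
    ----------
    coef_ : ndarray of shape (k,)
        Log-scale covariate coefficients.
    intercept_ : float
        Log-scale intercept (0.0 when ``fit_intercept=False``).
    theta_ : float
        Estimated dispersion.
    se_coef_, se_intercept_ : Wald standard errors.
    vcov_ : inverse weighted Fisher information of the full design.
    deviance_, n_iter_, converged_ : fit diagnostics.
    """

    def __init__(self, fit_intercept: bool = True, tol: float = DEFAULT_TOL,
                 max_iter: int = DEFAULT_MAX_ITER):
        self.fit_intercept = fit_intercept
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y, offset=None):
        X, y = check_X_y(X, y, ensure_min_samples=2)
        y = _as_counts(y)
        n = X.shape[0]
        offset = np.zeros(n) if offset is None else np.asarray(offset, float)
        if offset.shape != (n,) or not np.all(np.isfinite(offset)):
            raise ValueError("offset must be a finite vector of length n")
        Xd = np.column_stack([np.ones(n), X]) if self.fit_intercept else X
        if Xd.shape[1] == 0:
            raise ValueError("empty design: no covariates and no intercept")
        res = _irls_nb(y, Xd, offset, tol=self.tol, max_iter=self.max_iter)
        beta, se = res["beta"], res["se"]
        if self.fit_intercept:
            self.intercept_, self.coef_ = float(beta[0]), beta[1:]
            self.se_intercept_, self.se_coef_ = float(se[0]), se[1:]
        else:
            self.intercept_, self.coef_ = 0.0, beta
            self.se_intercept_, self.se_coef_ = 0.0, se
        self.theta_ = res["theta"]
        self.deviance_ = res["deviance"]
        self.n_iter_ = res["n_iter"]
        self.converged_ = res["converged"]
        self.vcov_ = res["vcov"]
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X, offset=None):
        """Expected counts exp(offset + intercept + X @ coef)."""
        check_is_fitted(self, "coef_")
        X = check_array(X)
        eta = self.intercept_ + X @ self.coef_
        if offset is not None:
            eta = eta + np.asarray(offset, float)
        return np.exp(np.clip(eta, -ETA_MAX, ETA_MAX))

    def to_result(self, names=None) -> NBFit:
        """Package the fitted state as an :class:`NBFit` record."""
        check_is_fitted(self, "coef_")
        if self.fit_intercept:
            beta = np.concatenate([[self.intercept_], self.coef_])
            se = np.concatenate([[self.se_intercept_], self.se_coef_])
            default = ["(Intercept)"] + [f"x{j+1}" for j in range(len(self.coef_))]
        else:
            beta, se = self.coef_, self.se_coef_
            default = [f"x{j+1}" for j in range(len(self.coef_))]
        return NBFit(
            beta_hat=beta, se_beta=se, theta_hat=self.theta_,
            deviance=self.deviance_, n_iter=self.n_iter_,
            converged=self.converged_, vcov_diag=np.diag(self.vcov_).copy(),
            vcov=self.vcov_, names=list(names) if names is not None else default,
        )


def fit_nb_mle(y, X=None, offset=None, tol=DEFAULT_TOL,
               max_iter=DEFAULT_MAX_ITER, names=None) -> NBFit:
    """Fit the classical NB GLM by maximum likelihood.

    Thin wrapper over :class:`NegativeBinomialRegressor`.  ``X`` holds
    the covariates only (no intercept column; pass ``None`` for an
    intercept-only model); an intercept is always included.
    """
    y = _as_counts(y)
    if X is None:
        X = np.empty((len(y), 0))
    est = NegativeBinomialRegressor(tol=tol, max_iter=max_iter)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] == 0:
        # bypass sklearn's min-feature validation for intercept-only fits
        n = len(y)
        offset_v = np.zeros(n) if offset is None else np.asarray(offset, float)
        res = _irls_nb(y, np.ones((n, 1)), offset_v, tol=tol, max_iter=max_iter)
        return NBFit(
            beta_hat=res["beta"], se_beta=res["se"], theta_hat=res["theta"],
            deviance=res["deviance"], n_iter=res["n_iter"],
            converged=res["converged"], vcov_diag=np.diag(res["vcov"]).copy(),
            vcov=res["vcov"],
            names=list(names) if names is not None else ["(Intercept)"],
        )
    est.fit(X, y, offset=offset)
    if names is not None:
        names = ["(Intercept)"] + list(names)
    return est.to_result(names=names)
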