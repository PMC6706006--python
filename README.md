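# hnbglm

Bayesian hierarchical negative binomial regression for multivariable
differential-abundance analysis of microbiome count data.

## Why

16S rRNA studies summarize each sample as a vector of OTU (taxon)
counts with a library size `T_i`, alongside tens or hundreds of host
characteristics (diet, medication, demographics, ...).  Testing
whether a taxon's abundance is associated with a condition while
*adjusting for all of those covariates at once* breaks the classical
negative binomial GLM as soon as the number of covariates `k`
approaches the number of samples `n` — the MLE is not identifiable —
and inflates its type I error well before that.

`hnbglm` implements a hierarchical NB model for exactly this regime.
Counts are modeled as

    y_i ~ NB(mu_i, theta),    log mu_i = log T_i + beta_0 + x_i' beta,

with `log T_i` an offset (so the model describes the taxon's rate per
read) and `Var(y_i) = mu_i + mu_i^2/theta` handling over-dispersion.
Each coefficient carries a Student-t shrinkage prior,

    beta_p ~ N(0, tau_p^2),   tau_p^2 ~ scaled-Inv-chi2(nu, s_p^2),

(`nu = 1`: Cauchy).  Posterior modes are found by an EM algorithm
nested in iteratively reweighted least squares: the E-step sets each
mixing precision to `E(tau_p^-2 | beta_p) = (1+nu)/(nu s_p^2 +
beta_p^2)`, the M-step solves a ridge-penalized weighted
least-squares system and updates `theta` by Newton-Raphson.  The
adaptive penalty shrinks null coefficients hard while leaving strong
effects nearly untouched, so the model stays identifiable and
calibrated at `k >= n`.  Prior scales are selected by an AIC adjusted
for the effective number of parameters (ridge hat-matrix trace).

The package also provides the classical NB MLE as a comparator, Wald
tests with Benjamini-Hochberg correction, rare-taxa filtering,
one-by-one feature screening, a synthetic-data generator for
NB-distributed microbiome counts, and a simulation grid runner that
measures type I error, power, FDR and estimation accuracy.

## Worked example

Simulate one feature for 200 samples and 50 covariates (the truth has
three non-zero effects, at coefficients 15, 30 and 45), then fit the
hierarchical model across the nine default prior scales and report
the AIC-selected fit:

```python
import numpy as np
from hnbglm import SimConfig, sim_dataset, scan_prior_scales, wald_test

rep = sim_dataset(SimConfig(n=200, k=50, rho_class="weak", seed=1))
scan = scan_prior_scales(rep.y, rep.X, offset=rep.log_T)
best = scan.best
print("selected scale:", scan.scales[scan.best_index],
      " adjusted AIC: %.2f" % best.adjusted_aic,
      " theta_hat: %.2f (true %.2f)" % (best.theta_hat, rep.theta_true))
for j in (15, 30, 45, 7):
    t = wald_test(best.beta_hat[j], best.se_beta[j])
    print("beta_%-3d  %8.3f  %6.3f  %7.1e  %6.3f"
          % (j, t.estimate, t.se, t.p_value, rep.beta_true[j - 1]))
```

prints

```
selected scale: 0.05  adjusted AIC: 1114.27  theta_hat: 5.64 (true 4.76)
beta_15      0.062   0.038  9.8e-02   0.097
beta_30      0.267   0.046  6.3e-09   0.320
beta_45      0.464   0.043  1.3e-26   0.498
beta_7      -0.006   0.026  8.3e-01   0.000
```

The moderate and large effects (true 0.32, 0.50) are recovered with
small p-values, the small effect (0.097) is borderline — detecting
effects that size at this sample size is genuinely hard — and a
representative null coefficient is shrunk to -0.006 with p = 0.83.
The columns are: posterior-mode estimate, standard error, two-sided
Wald p-value, simulated truth.

The same workflow is available from the shell: `hnbglm simulate`,
`hnbglm fit`, `hnbglm screen` (whole count table to a results TSV,
with rare-taxa filtering and BH correction) and `hnbglm evaluate`
(simulation grid to a summary TSV).  See `hnbglm --help`.

## Scikit-learn style estimators

`NegativeBinomialRegressor` and `HierarchicalNegativeBinomial` are
sklearn-compatible estimators (`fit(X, y, offset=...)` /
`predict(X, offset=...)`, `get_params`/`set_params`, fitted
attributes `coef_`, `intercept_`, `theta_`, `se_coef_`, ...), so they
compose with sklearn tooling; the functional API (`fit_nb_mle`,
`fit_hnb`, `scan_prior_scales`) wraps them and returns plain result
records.

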