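# Methods

## The model

For one microbial feature (OTU/taxon) observed in samples
`i = 1..n` with counts `y_i`, library sizes `T_i` and host
characteristics `x_i = (x_i1, ..., x_ik)`, the package fits

```
y_i ~ NB(mu_i, theta),      log mu_i = log T_i + beta_0 + x_i' beta,
```

the mean/dispersion ("NB2") negative binomial with
`Var(y_i) = mu_i + mu_i^2 / theta`.  The log library size enters as an
offset, so the regression describes the *rate* of the taxon per read
and differing sequencing depths are absorbed without normalization.
Smaller `theta` means stronger over-dispersion; `theta -> inf` is the
Poisson limit.

Two fitters share this likelihood:

* **Classical MLE** (`NegativeBinomialRegressor`, `fit_nb_mle`):
  iteratively reweighted least squares (IWLS) for `beta` alternated
  with Newton-Raphson profile updates of `theta` on the log scale.
  Identifiable only when `n > k + 1` with a full-rank design; outside
  that regime it raises `IdentifiabilityError` by design.
* **Hierarchical posterior mode** (`HierarchicalNegativeBinomial`,
  `fit_hnb`): each covariate coefficient carries a Student-t shrinkage
  prior written as a normal/inverse-chi-square mixture,

  ```
  beta_p ~ N(0, tau_p^2),   tau_p^2 ~ scaled-Inv-chi2(nu, s_p^2),
  ```

  with `nu = 1` (Cauchy) by default.  An EM algorithm nested in IWLS
  finds the posterior mode: the E-step replaces each mixing precision
  by its conditional expectation `E(tau_p^-2 | beta_p) =
  (1 + nu) / (nu s_p^2 + beta_p^2)`; the M-step solves a
  ridge-penalized weighted least-squares system on the IWLS
  pseudo-data and then updates `theta`.  Because the penalty is
  adaptive — large `|beta_p|` dissolves its own shrinkage — strong
  signals survive while null coefficients collapse toward zero, and
  the system remains solvable for `k >= n`.

Both fitters stop when the relative deviance change
`|d(t) - d(t-1)| / (0.1 + |d(t)|)` falls below `1e-5`
(`d = -2 log L`).  Wald inference applies to both:
`U_p = beta_hat_p / se(beta_hat_p)` referred to the standard normal,
with BH correction across features in screens.

## Numerical choices

* **Step halving.**  A single Fisher-scoring / ridge step can
  overshoot when the dispersion is strong and the design wide, which
  makes the plain alternation oscillate.  Every coefficient update is
  therefore step-halved against the (penalized) deviance, which
  restores monotone progress; on hard replicates this is the
  difference between converging to the optimum and cycling around it.
* **Dispersion updates** run on `log theta` with step halving and box
  constraints `[1e-4, 1e4]`.  If Newton fails, the method-of-moments
  value is used as a fallback (keeping whichever has the higher
  likelihood) and flagged.  Data with no dispersion signal (`y == mu`)
  drive `theta` to the upper bound, which is reported via `at_bound`.
* **Linear predictor clipping** at `|eta| <= 30` before
  exponentiation guards `exp`, the weights and the log-pmf; `exp(30)`
  far exceeds any realistic mean count.
* **Initialization** is deterministic: `beta_0 = log(sum y / sum T)`,
  other coefficients 0, `theta = 1`.  The mixing variances start at
  `tau_p^2 = 1`, i.e. the first coefficient update is only weakly
  penalized and the E-step then adapts the shrinkage to the estimates.
  Starting instead from `tau_p^2 = s_p^2` with a strong prior such as
  `s = 0.01` would begin the EM inside the fully-shrunk basin of the
  multimodal Cauchy-prior posterior and annihilate every effect, real
  or not; the weak first step lets each coefficient settle into the
  mode the data support.  This is the package's convention, chosen for
  the adaptive behavior it produces (near-nominal-or-better type I
  error together with retained power; see the acceptance suite).
* **Working-model dispersion** `sigma^2` is fixed at 1, the GLM
  dispersion of a count family whose over-dispersion is carried by the
  separately-estimated `theta`.  Re-estimating `sigma^2` from the
  weighted working residuals is unstable precisely where the
  hierarchical model matters most: for `k >= n` the ridge fit nearly
  interpolates the working response, `sigma^2` collapses toward 0 and
  the shrinkage is disabled.  `sigma^2` remains an argument of
  `mstep_beta`/`effective_params` so other conventions can be studied.
* **Standardization.**  Covariates are centered and scaled internally
  (binary indicators identically), so one common prior scale is
  comparable across covariates; estimates, standard errors and the
  full covariance are transformed back to the input scale for all
  reports.  The intercept is never penalized, which keeps offset
  rescaling exact: multiplying all `T_i` by `c` shifts only the
  intercept by `-log c`.
* **Model selection** across prior scales uses
  `adjusted AIC = deviance + 2 * effective_params`, where
  `effective_params` is the trace of the ridge hat matrix
  `X (X'WX/sigma^2 + diag(tau^-2))^-1 X'W/sigma^2` — the raw
  column count under flat priors, smaller under shrinkage.  The
  default scan covers nine scales from 0.01 to 2.00; ties prefer the
  smaller scale (the sparser model), and non-convergent scales are
  excluded from selection.

## The synthetic-data generator

`simulate` emulates one microbiome feature under controlled
conditions; its defaults *are* the study conditions used throughout
the tests and the acceptance script:

* covariates: rows i.i.d. multivariate normal, mean 0,
  compound-symmetry correlation with `rho` drawn per replicate from
  one of three classes — strong negative U(-0.8, -0.5), weak
  U(-0.1, 0.1), strong positive U(0.5, 0.8);
* log library sizes in (7.1, 10.5), built from a scaling factor
  `log T_i + mu ~ U(0.1, 3.5)` with overall mean `mu = -7`, so
  expected base counts per sample span roughly 1-33;
* dispersion `theta ~ U(0.1, 5.0)` per replicate (moderate to strong
  over-dispersion);
* effects zero except at configured positions; non-zero magnitudes
  from small U(0.01, 0.15), moderate U(0.20, 0.35) or large
  U(0.40, 0.55) ranges.  For `k >= 50` the default non-zero positions
  are coefficients 15, 30 and 45 (small/moderate/large);
* counts drawn as a gamma-mixture of Poissons, which is exact for the
  NB and stable at small `theta`.

Compound symmetry is positive definite only for `rho > -1/(k-1)`, so
for wide designs a drawn negative `rho` is clamped to just above that
bound before the design is built (both the drawn and the effective
value are recorded).  At `k = 50` the entire strong-negative class is
therefore effectively near-independent; this is a structural limit of
a common-correlation design, not a tunable choice, and it is why
strong-negative results track the weak class closely.

The generator emulates a *single* feature at a time: it has no
taxon-to-taxon correlation, no compositional (closed-sum) structure
and no zero inflation beyond what the NB itself produces.  Passing
tests therefore demonstrate calibration and power under NB sampling
with realistic depths, dispersions and collinearity — not robustness
to compositionality or to model misspecification in real microbiome
data.

## Evaluation framework and problem sizes

`evaluate.run_grid` simulates each configuration `n_iter` times,
fits every requested variant (the hierarchical model once per prior
scale; the classical MLE where identifiable, its failures recorded per
replicate), and aggregates per-coefficient rejection frequencies
(type I error / power), BH-threshold FDP curves, ROC points, and
coefficient / dispersion deviations (the latter on the `log(theta+1)`
scale).  All randomness derives from one master seed via
`SeedSequence(master, config_index, iteration)`, so results are a pure
function of the grid specification and the seed, independent of
scheduling.

`scripts/acceptance.py` runs the benchmark at 100 replicates per cell
(the package's standard replication): the single-covariate design over
`n in {50, 100, 200, 500}` for the zero/small/moderate/large effect
classes, and the 50-covariate design at `n in {50, 200, 500}` over the
three correlation classes.  The in-package acceptance tests rerun the
same checks at 12-30 replicates with correspondingly wider binomial
tolerance bands.  Per-coefficient frequencies are averaged with equal
weight per configuration; pooled numbers average the three correlation
classes equally.

## Known limitations

* Wald inference after shrinkage uses the curvature of the penalized
  objective; its intervals are approximate and, under strong
  shrinkage, conservative for null effects.
* Only posterior modes are computed — no MCMC, hence no finite-sample
  posterior uncertainty for `tau_p^2` or `theta`.
* The Cauchy-prior posterior is multimodal; the EM is deterministic
  given the initialization convention above, but a different
  initialization can reach a different mode.  The stationarity of the
  returned mode is verified in the test suite.
* Small-effect power under strong positive correlation is intrinsically
  limited: with common correlation `rho ~ 0.65` among 50 covariates the
  per-coefficient information is roughly a third of the independent
  case, and detection rates for effects in U(0.01, 0.15) drop
  accordingly.
* `theta` estimates from the classical MLE are strongly upward-biased
  when `k` approaches `n`; the hierarchical fit moderates but does not
  remove this bias.
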