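"""Performance metrics and the simulation grid runner.

Reproduces the standard benchmarking summaries for the differential-
abundance models: per-coefficient rejection frequency (type I error
for true zeros, power for true non-zeros), false-discovery-proportion
curves against nominal BH thresholds, ROC points, and estimation-
accuracy deviations for the coefficients and the dispersion (the
latter on the log(theta + 1) scale, which tames the long right tail of
dispersion over-estimates).

The grid runner simulates each configuration ``n_iter`` times, fits
every requested model variant (the hierarchical model counts once per
prior scale; the classical MLE is skipped with a recorded failure
where it is not identifiable), collects Wald p-values and estimates,
and emits long-format summaries.  All randomness derives from a single
master seed: the replicate seed is a deterministic function of
(master seed, configuration index, iteration).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hierarchical import DEFAULT_PRIOR_SCALES, PriorSpec, fit_hnb
from .inference import bh_adjust, wald_test
from .nb import fit_nb_mle
from .simulate import SimConfig, sim_dataset

EFFECT_CLASS_BY_POSITION = {15: "small", 30: "moderate", 45: "large"}


@dataclass
class EvalSummary:
    """Aggregated performance for one (configuration, model) cell."""

    per_coef_frequency: dict = field(default_factory=dict)
    type1_mean: float = float("nan")
    power_by_effect: dict = field(default_factory=dict)
    fdp_curve: list = field(default_factory=list)
    roc: list = field(default_factory=list)
    beta_deviation: tuple = (float("nan"), float("nan"))
    theta_deviation_log1p: tuple = (float("nan"), float("nan"))
    n_replicates: int = 0


def rejection_frequencies(pvals, beta_nonzero, alpha: float = 0.05,
                          effect_classes: dict | None = None) -> EvalSummary:
    """Per-coefficient rejection frequencies at level ``alpha``.

    ``pvals`` is a replicate x coefficient matrix (NaN marks a failed
    fit and is excluded for that coefficient); ``beta_nonzero`` is a
    boolean mask (or a true-coefficient vector whose non-zeros are
    taken) marking the truly non-zero positions.  ``effect_classes``
    maps 1-based positions to effect-class names for the power report;
    wide-design defaults (15/30/45 -> small/moderate/large) are used
    when omitted.
    """
    pvals = np.asarray(pvals, dtype=float)
    if pvals.ndim == 1:
        pvals = pvals[None, :]
    nonzero = np.asarray(beta_nonzero)
    if nonzero.dtype != bool:
        nonzero = nonzero != 0
    k = pvals.shape[1]
    if nonzero.shape != (k,):
        raise ValueError("beta_nonzero length must match the number of "
                         "coefficients")
    with np.errstate(invalid="ignore"):
        reject = pvals < alpha
    valid = ~np.isnan(pvals)
    counts = valid.sum(axis=0)
    freq = np.where(counts > 0,
                    np.where(valid, reject, False).sum(axis=0)
                    / np.maximum(counts, 1), np.nan)
    summary = EvalSummary(
        per_coef_frequency={j + 1: float(freq[j]) for j in range(k)},
        n_replicates=int(pvals.shape[0]))
    if np.any(~nonzero):
        summary.type1_mean = float(np.nanmean(freq[~nonzero]))
    classes = effect_classes or {
        p: c for p, c in EFFECT_CLASS_BY_POSITION.items() if p <= k}
    power = {}
    for pos in np.flatnonzero(nonzero):
        cls = classes.get(pos + 1, f"coef_{pos + 1}")
        power.setdefault(cls, []).append(freq[pos])
    summary.power_by_effect = {c: float(np.nanmean(v))
                               for c, v in power.items()}
    return summary


def fdp_at_threshold(pvals, is_null, threshold: float) -> float:
    """False discovery proportion of the BH rule at a nominal
    threshold: #(null rejected) / max(1, #rejected), rejecting where
    the BH-adjusted p-value is below the threshold."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    pvals = np.asarray(pvals, dtype=float)
    is_null = np.asarray(is_null, dtype=bool)
    adj = bh_adjust(pvals)
    rejected = adj < threshold
    if not rejected.any():
        return 0.0
    return float((rejected & is_null).sum() / rejected.sum())


def fdr_curve(pval_matrix, is_null, thresholds) -> list:
    """Mean FDP over replicates at each nominal threshold (estimates
    the FDR)."""
    rows = np.asarray(pval_matrix, dtype=float)
    out = []
    for t in thresholds:
        vals = [fdp_at_threshold(row[~np.isnan(row)],
                                 np.asarray(is_null)[~np.isnan(row)], t)
                for row in rows if np.any(~np.isnan(row))]
        out.append((float(t), float(np.mean(vals)) if vals else float("nan")))
    return out


def roc_points(pvals, is_null) -> list:
    """ROC sweep over the sorted unique p-values: at each threshold the
    FPR is the fraction of nulls rejected and the TPR the fraction of
    non-nulls rejected.  Endpoints (0,0) and (1,1) are always present."""
    pvals = np.asarray(pvals, dtype=float)
    is_null = np.asarray(is_null, dtype=bool)
    if not is_null.any() or is_null.all():
        raise ValueError("need at least one null and one non-null coefficient")
    pts = [(0.0, 0.0)]
    for t in np.unique(pvals):
        fpr = float(np.mean(pvals[is_null] <= t))
        tpr = float(np.mean(pvals[~is_null] <= t))
        pts.append((fpr, tpr))
    if pts[-1] != (1.0, 1.0):
        pts.append((1.0, 1.0))
    return pts


def _child_seed(master: int, config_index: int, iteration: int) -> int:
    ss = np.random.SeedSequence([int(master), int(config_index),
                                 int(iteration)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class GridCell:
    """Raw per-replicate outcomes for one (config, method, scale)."""

    pvals: np.ndarray       # n_iter x k (NaN where the fit failed)
    estimates: np.ndarray   # n_iter x k
    theta: np.ndarray       # n_iter
    failed: np.ndarray      # n_iter bool


@dataclass
class GridResult:
    """Everything the grid runner produced, plus the generating truth."""

    configs: list
    methods: list
    scales: np.ndarray
    n_iter: int
    seed: int
    alpha: float
    cells: dict = field(default_factory=dict)   # (ci, method, scale) -> GridCell
    beta_true: dict = field(default_factory=dict)   # ci -> n_iter x k
    theta_true: dict = field(default_factory=dict)  # ci -> n_iter
    rho: dict = field(default_factory=dict)         # ci -> n_iter

    def cell(self, config_index: int, method: str,
             scale: float | None = None) -> GridCell:
        key = (config_index, method,
               float(scale) if scale is not None else None)
        return self.cells[key]

    def summarize(self, alpha: float | None = None) -> pd.DataFrame:
        """Long-format metric table: one row per cell x metric."""
        alpha = self.alpha if alpha is None else alpha
        rows = []
        for (ci, method, scale), cell in self.cells.items():
            cfg = self.configs[ci]
            mask = cfg.nonzero_mask()
            rs = rejection_frequencies(cell.pvals, mask, alpha=alpha)
            base = {"config": ci, "n": cfg.n, "k": cfg.k,
                    "rho_class": cfg.rho_class, "method": method,
                    "scale": scale}
            rows.append({**base, "metric": "type1_mean",
                         "value": rs.type1_mean, "se": _freq_se(
                             cell.pvals[:, ~mask], alpha)})
            for cls, val in rs.power_by_effect.items():
                rows.append({**base, "metric": f"power_{cls}", "value": val,
                             "se": np.nan})
            ok = ~cell.failed
            if ok.any():
                dev = (cell.estimates[ok] - self.beta_true[ci][ok]).ravel()
                dev = dev[~np.isnan(dev)]
                rows.append({**base, "metric": "beta_deviation",
                             "value": float(np.mean(dev)),
                             "se": float(np.std(dev, ddof=1)
                                         / np.sqrt(len(dev)))
                             if len(dev) > 1 else np.nan})
                tdev = (np.log1p(cell.theta[ok])
                        - np.log1p(self.theta_true[ci][ok]))
                rows.append({**base, "metric": "theta_deviation_log1p",
                             "value": float(np.mean(tdev)),
                             "se": float(np.std(tdev, ddof=1)
                                         / np.sqrt(len(tdev)))
                             if len(tdev) > 1 else np.nan})
            rows.append({**base, "metric": "n_failed",
                         "value": float(cell.failed.sum()), "se": np.nan})
        return pd.DataFrame(rows)


def _freq_se(pvals, alpha) -> float:
    with np.errstate(invalid="ignore"):
        r = (pvals < alpha)[~np.isnan(pvals)]
    if r.size < 2:
        return float("nan")
    return float(np.std(r.astype(float), ddof=1) / np.sqrt(r.size))


def _fit_pvals(method, scale, rep, nu):
    """Fit one model variant to one replicate; return (pvals, estimates,
    theta) for the k covariate coefficients."""
    if method == "nb_mle":
        fit = fit_nb_mle(rep.y, rep.X, offset=rep.log_T)
    elif method == "hnb":
        fit = fit_hnb(rep.y, rep.X, offset=rep.log_T,
                      prior=PriorSpec(nu=nu, scales=float(scale)))
    else:
        raise ValueError(f"unknown method {method!r}")
    tests = [wald_test(b, s) for b, s in zip(fit.beta_hat[1:],
                                             fit.se_beta[1:])]
    return (np.array([t.p_value for t in tests]),
            np.array([t.estimate for t in tests]), fit.theta_hat)


def run_grid(grid, methods=("nb_mle", "hnb"), n_iter: int = 100,
             alpha: float = 0.05, scales=DEFAULT_PRIOR_SCALES,
             nu: float = 1.0, seed: int = 0) -> GridResult:
    """Simulate and fit every grid cell.

    ``grid`` is a list of :class:`SimConfig`; each is simulated
    ``n_iter`` times with deterministic child seeds.  ``"hnb"`` in
    ``methods`` expands to one variant per prior scale.  Individual fit
    failures (e.g. the classical MLE at k >= n) are recorded per
    replicate and never abort the run.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    grid = list(grid)
    scales = np.asarray(scales, dtype=float)
    result = GridResult(configs=grid, methods=list(methods), scales=scales,
                        n_iter=n_iter, seed=seed, alpha=alpha)
    variants = []
    for m in methods:
        if m == "hnb":
            variants.extend(("hnb", float(s)) for s in scales)
        else:
            variants.append((m, None))

    for ci, cfg in enumerate(grid):
        k = cfg.k
        result.beta_true[ci] = np.full((n_iter, k), np.nan)
        result.theta_true[ci] = np.full(n_iter, np.nan)
        result.rho[ci] = np.full(n_iter, np.nan)
        cells = {v: GridCell(pvals=np.full((n_iter, k), np.nan),
                             estimates=np.full((n_iter, k), np.nan),
                             theta=np.full(n_iter, np.nan),
                             failed=np.zeros(n_iter, dtype=bool))
                 for v in variants}
        for it in range(n_iter):
            rep = sim_dataset(cfg.with_seed(_child_seed(seed, ci, it)))
            result.beta_true[ci][it] = rep.beta_true
            result.theta_true[ci][it] = rep.theta_true
            result.rho[ci][it] = rep.rho
            for method, scale in variants:
                cell = cells[(method, scale)]
                try:
                    p, est, th = _fit_pvals(method, scale, rep, nu)
                except Exception:
                    cell.failed[it] = True
                    continue
                cell.pvals[it] = p
                cell.estimates[it] = est
                cell.theta[it] = th
        for (method, scale), cell in cells.items():
            result.cells[(ci, method, scale)] = cell
    return result
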