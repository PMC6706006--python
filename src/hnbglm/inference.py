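"""Wald inference, multiple-testing correction, taxa filtering and the
per-feature differential-abundance screen.

After a fit, each coefficient is tested with the Wald statistic
U_p = beta_hat_p / se(beta_hat_p), referred to the standard normal for a
two-sided test of H0: beta_p = 0.  Screening a whole count table fits
one model per feature (one-by-one), then adjusts p-values across
features with the Benjamini-Hochberg step-up procedure, separately for
each covariate by default (the typical family when one host
characteristic is screened across many taxa).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .hierarchical import DEFAULT_PRIOR_SCALES, PriorSpec, fit_hnb, scan_prior_scales
from .io import CountTable, DesignMatrix
from .nb import fit_nb_mle

logger = logging.getLogger(__name__)

SCREEN_METHODS = ("hnb_scan", "hnb_fixed_scale", "nb_mle")

#: Columns of the screen results table.
SCREEN_COLUMNS = ("feature_id", "coefficient", "estimate", "se", "statistic",
                  "p_value", "p_adjusted", "ci_low", "ci_high",
                  "selected_scale", "fit_status")


@dataclass
class CoefTest:
    """Wald test of a single coefficient."""

    name: str
    estimate: float
    se: float
    statistic: float
    p_value: float
    ci_low: float
    ci_high: float
    p_adjusted: float


@dataclass
class ScreenResult:
    """Per-feature outcome of the one-by-one screen."""

    feature_id: str
    fit_status: str  # converged | not_converged | skipped_filter | error
    tests: list = field(default_factory=list)
    selected_scale: float = float("nan")
    message: str = ""


def wald_test(estimate: float, se: float, level: float = 0.05,
              name: str = "") -> CoefTest:
    """Two-sided normal-reference Wald test with a symmetric
    (1-level) confidence interval."""
    if not np.isfinite(se) or se <= 0:
        raise ValueError("se must be positive and finite")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    stat = estimate / se
    p = float(2.0 * stats.norm.sf(abs(stat)))
    z = float(stats.norm.ppf(1.0 - level / 2.0))
    return CoefTest(name=name, estimate=float(estimate), se=float(se),
                    statistic=float(stat), p_value=p,
                    ci_low=float(estimate - z * se),
                    ci_high=float(estimate + z * se), p_adjusted=p)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def filter_taxa(table: CountTable,
                min_mean_rel_abund: float = 0.001) -> CountTable:
    """Keep features whose mean relative abundance (count over library
    size, averaged across samples) reaches the threshold.

    The default 0.1% mirrors common practice of excluding very rare
    taxa before differential-abundance screening.  Library sizes are
    carried over unchanged, so the offset still reflects the sequenced
    library rather than the filtered table.
    """
    if not 0 <= min_mean_rel_abund < 1:
        raise ValueError("min_mean_rel_abund must be in [0, 1)")
    totals = table.total_reads.to_numpy(dtype=float)
    rel = table.counts.to_numpy(dtype=float) / totals[None, :]
    keep = rel.mean(axis=1) >= min_mean_rel_abund
    return CountTable(counts=table.counts.loc[keep].copy(),
                      total_reads=table.total_reads.copy())


def _covariate_matrix(X):
    """Accept a DesignMatrix, DataFrame or ndarray of covariates
    (without intercept); return (matrix, names)."""
    if isinstance(X, DesignMatrix):
        return X.covariates, list(X.covariate_names)
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X, [f"x{j+1}" for j in range(X.shape[1])]


def screen_features(table: CountTable, X, offset=None,
                    method: str = "hnb_scan", scale: float | None = None,
                    scales=DEFAULT_PRIOR_SCALES, nu: float = 1.0,
                    alpha: float = 0.05, adjust: str = "bh",
                    adjust_family: str = "per_covariate") -> list:
    """Fit the chosen model to every feature and test each coefficient.

    Per-feature failures (non-identifiability, numerical errors) are
    recorded in the feature's ``fit_status`` and never abort the
    screen.  BH adjustment is applied across features separately per
    covariate (``adjust_family="per_covariate"``) or jointly over all
    feature x covariate tests (``"joint"``); the intercept is never
    part of the adjustment family.
    """
    if method not in SCREEN_METHODS:
        raise ValueError(f"method must be one of {SCREEN_METHODS}")
    if adjust not in ("bh", "none"):
        raise ValueError("adjust must be 'bh' or 'none'")
    if adjust_family not in ("per_covariate", "joint"):
        raise ValueError("adjust_family must be 'per_covariate' or 'joint'")
    if method == "hnb_fixed_scale" and scale is None:
        raise ValueError("method 'hnb_fixed_scale' requires a scale")
    if not table.feature_ids:
        raise ValueError("count table has no features")

    Xc, names = _covariate_matrix(X)
    offset = (table.log_total_reads() if offset is None
              else np.asarray(offset, dtype=float))

    results = []
    for fid in table.feature_ids:
        y = table.feature_counts(fid)
        sel_scale = float("nan")
        try:
            if method == "nb_mle":
                fit = fit_nb_mle(y, Xc, offset=offset, names=names)
            elif method == "hnb_fixed_scale":
                fit = fit_hnb(y, Xc, offset=offset,
                              prior=PriorSpec(nu=nu, scales=float(scale)),
                              names=names)
                sel_scale = float(scale)
            else:
                scan = scan_prior_scales(y, Xc, offset=offset, nu=nu,
                                         scales=scales, names=names)
                fit = scan.best
                sel_scale = float(scan.scales[scan.best_index])
        except Exception as err:  # isolate per-feature failures
            logger.warning("feature %s: fit failed (%s)", fid, err)
            results.append(ScreenResult(feature_id=str(fid),
                                        fit_status="error",
                                        message=str(err)))
            continue
        if not fit.converged:
            results.append(ScreenResult(feature_id=str(fid),
                                        fit_status="not_converged",
                                        selected_scale=sel_scale))
            continue
        tests = [wald_test(b, s, level=alpha, name=nm)
                 for nm, b, s in zip(fit.names, fit.beta_hat, fit.se_beta)]
        results.append(ScreenResult(feature_id=str(fid),
                                    fit_status="converged", tests=tests,
                                    selected_scale=sel_scale))

    if adjust == "bh":
        _apply_bh(results, family=adjust_family)
    return results


def _apply_bh(results, family: str) -> None:
    """Assign BH-adjusted p-values in place across converged features."""
    slots = []  # (result_index, test_index, coefficient_name)
    for i, r in enumerate(results):
        for j, t in enumerate(r.tests):
            if t.name != "(Intercept)":
                slots.append((i, j, t.name))
    if not slots:
        return
    if family == "joint":
        groups = {"all": slots}
    else:
        groups = {}
        for slot in slots:
            groups.setdefault(slot[2], []).append(slot)
    for members in groups.values():
        p = np.array([results[i].tests[j].p_value for i, j, _ in members])
        adj = bh_adjust(p)
        for (i, j, _), q in zip(members, adj):
            results[i].tests[j].p_adjusted = float(q)


def screen_to_frame(results) -> pd.DataFrame:
    """Long-format results table, one row per feature x coefficient
    (features without tests contribute a single status row)."""
    rows = []
    for r in results:
        if not r.tests:
            rows.append({"feature_id": r.feature_id, "coefficient": None,
                         "estimate": np.nan, "se": np.nan,
                         "statistic": np.nan, "p_value": np.nan,
                         "p_adjusted": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "selected_scale": r.selected_scale,
                         "fit_status": r.fit_status})
        for t in r.tests:
            rows.append({"feature_id": r.feature_id, "coefficient": t.name,
                         "estimate": t.estimate, "se": t.se,
                         "statistic": t.statistic, "p_value": t.p_value,
                         "p_adjusted": t.p_adjusted, "ci_low": t.ci_low,
                         "ci_high": t.ci_high,
                         "selected_scale": r.selected_scale,
                         "fit_status": r.fit_status})
    return pd.DataFrame(rows, columns=list(SCREEN_COLUMNS))


def write_screen_results(results, path, sep: str = "\t") -> None:
    screen_to_frame(results).to_csv(path, sep=sep, index=False)
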