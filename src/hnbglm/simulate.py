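"""Synthetic microbiome count data generator.

One replicate emulates a single microbial feature observed across *n*
samples together with *k* host-characteristic covariates:

* Covariates are multivariate normal with mean zero and
  compound-symmetry correlation (unit variances, common off-diagonal
  rho), with rho drawn per replicate from one of three classes: strong
  negative U(-0.8, -0.5), weak U(-0.1, 0.1), or strong positive
  U(0.5, 0.8).
* Log library sizes log(T_i) land in (7.1, 10.5) by drawing the
  scaling factor log(T_i) + mu ~ U(0.1, 3.5) with the overall mean mu
  fixed at -7, so per-sample expected base counts range from ~1 to ~33.
* True effects are zero except at configured positions; non-zero
  magnitudes come from three ranges — small U(0.01, 0.15), moderate
  U(0.20, 0.35), large U(0.40, 0.55).  For k >= 50 the default
  non-zero positions are coefficients 15, 30 and 45 (1-based) with the
  small/moderate/large ranges respectively.
* The dispersion theta is drawn per replicate from U(0.1, 5.0)
  (moderate to strong over-dispersion), and counts are drawn as
  y_i ~ NB(exp(eta_i), theta) with eta_i = log(T_i) + mu + x_i' beta,
  sampled as a Poisson-gamma mixture for robustness at small theta.

Compound symmetry is only positive definite for rho > -1/(k-1), so for
wide designs the drawn rho of a negative-correlation class is clamped
to just above that bound before the design is built; the replicate
records both the drawn and the effective value.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

RHO_RANGES = {
    "strong_negative": (-0.8, -0.5),
    "weak": (-0.1, 0.1),
    "strong_positive": (0.5, 0.8),
}

EFFECT_RANGES = {
    "zero": (0.0, 0.0),
    "small": (0.01, 0.15),
    "moderate": (0.20, 0.35),
    "large": (0.40, 0.55),
}

#: Default non-zero effect positions (1-based) for wide designs.
DEFAULT_EFFECT_POSITIONS = {15: "small", 30: "moderate", 45: "large"}

DEFAULT_THETA_RANGE = (0.1, 5.0)
DEFAULT_SCALING_RANGE = (0.1, 3.5)
DEFAULT_MU = -7.0


def default_effects(k: int) -> dict:
    """Default effect specification: positions 15/30/45 for k >= 50,
    otherwise no non-zero effects."""
    if k >= 50:
        return dict(DEFAULT_EFFECT_POSITIONS)
    return {}


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def cs_rho_bound(k: int) -> float:
    """Lower positive-definiteness bound for compound-symmetry rho."""
    return -1.0 / (k - 1) if k > 1 else -1.0


def sim_design(n: int, k: int, rho: float, seed=None) -> np.ndarray:
    """Draw an n x k design: rows i.i.d. N(0, V) with V compound
    symmetry (unit diagonal, rho off-diagonal)."""
    if n < 1 or k < 1:
        raise ValueError("n and k must be >= 1")
    if not -1 < rho < 1:
        raise ValueError("rho must lie in (-1, 1)")
    bound = cs_rho_bound(k)
    if k > 1 and rho <= bound:
        raise ValueError(
            f"compound symmetry is not positive definite for rho <= "
            f"-1/(k-1) = {bound:.4f} at k={k} (got rho={rho:.4f})")
    rng = _rng(seed)
    V = np.full((k, k), rho)
    np.fill_diagonal(V, 1.0)
    L = np.linalg.cholesky(V)
    return rng.standard_normal((n, k)) @ L.T


def sim_offsets(n: int, mu: float = DEFAULT_MU, seed=None,
                scaling_range=DEFAULT_SCALING_RANGE):
    """Draw scaling factors log(T_i) + mu ~ U(0.1, 3.5) and return
    (log_T, scaling); with mu = -7 every log_T falls in (7.1, 10.5)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    scaling = rng.uniform(*scaling_range, size=n)
    return scaling - mu, scaling


def sim_beta(k: int, effect_spec: dict | None = None, seed=None) -> np.ndarray:
    """Draw true coefficients: zeros except at the configured 1-based
    positions, whose magnitudes come from the named effect ranges."""
    rng = _rng(seed)
    beta = np.zeros(k)
    spec = effect_spec if effect_spec is not None else default_effects(k)
    seen = set()
    for pos, cls in spec.items():
        pos = int(pos)
        if not 1 <= pos <= k:
            raise ValueError(f"effect position {pos} outside 1..{k}")
        if pos in seen:
            raise ValueError(f"overlapping effect position {pos}")
        seen.add(pos)
        lo, hi = EFFECT_RANGES[cls] if isinstance(cls, str) else cls
        beta[pos - 1] = 0.0 if lo == hi == 0 else rng.uniform(lo, hi)
    return beta


def sim_counts(X, beta, log_T, mu: float, theta: float, seed=None) -> np.ndarray:
    """Draw y_i ~ NB(exp(log_T_i + mu + x_i' beta), theta) via the
    Poisson-gamma mixture."""
    rng = _rng(seed)
    X = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float)
    log_T = np.asarray(log_T, dtype=float)
    eta = np.clip(log_T + mu + X @ beta, -30.0, 30.0)
    mean = np.exp(eta)
    lam = rng.gamma(shape=theta, scale=mean / theta)
    return rng.poisson(lam)


@dataclass
class SimConfig:
    """One cell of the simulation grid."""

    n: int = 200
    k: int = 50
    rho_class: str = "weak"
    effects: dict | None = None  # None -> default_effects(k)
    theta_range: tuple = DEFAULT_THETA_RANGE
    scaling_range: tuple = DEFAULT_SCALING_RANGE
    mu: float = DEFAULT_MU
    seed: int = 0

    def __post_init__(self):
        if self.rho_class not in RHO_RANGES:
            raise ValueError(f"rho_class must be one of {sorted(RHO_RANGES)}")

    def resolved_effects(self) -> dict:
        return (self.effects if self.effects is not None
                else default_effects(self.k))

    def nonzero_mask(self) -> np.ndarray:
        mask = np.zeros(self.k, dtype=bool)
        for pos, cls in self.resolved_effects().items():
            if cls != "zero":
                mask[int(pos) - 1] = True
        return mask

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=int(seed))


@dataclass
class SimReplicate:
    """One simulated dataset plus its generating truth."""

    X: np.ndarray
    beta_true: np.ndarray
    theta_true: float
    rho: float
    rho_used: float
    log_T: np.ndarray
    y: np.ndarray
    seed: int
    scaling: np.ndarray = field(repr=False, default=None)
    config: SimConfig = None

    def save(self, directory) -> None:
        """Serialize to TSVs (counts, design, offsets, truth) for
        cross-language checking or CLI consumption."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        n, k = self.X.shape
        samples = [f"sample_{i+1}" for i in range(n)]
        pd.DataFrame([self.y], index=["feature_1"], columns=samples) \
            .to_csv(d / "counts.tsv", sep="\t", index_label="feature_id")
        pd.DataFrame(self.X, index=samples,
                     columns=[f"x{j+1}" for j in range(k)]) \
            .to_csv(d / "design.tsv", sep="\t", index_label="sample_id")
        pd.DataFrame({"log_total_reads": self.log_T}, index=samples) \
            .to_csv(d / "offsets.tsv", sep="\t", index_label="sample_id")
        truth = pd.DataFrame({
            "parameter": [f"beta_{j+1}" for j in range(k)]
                         + ["theta", "rho", "rho_used", "seed"],
            "value": list(self.beta_true)
                     + [self.theta_true, self.rho, self.rho_used, self.seed],
        })
        truth.to_csv(d / "truth.tsv", sep="\t", index=False)


def sim_dataset(config: SimConfig) -> SimReplicate:
    """Draw one replicate: rho and theta first, then design, offsets,
    coefficients and counts, all from a single per-replicate seed."""
    rng = np.random.default_rng(config.seed)
    rho = float(rng.uniform(*RHO_RANGES[config.rho_class]))
    bound = cs_rho_bound(config.k)
    rho_used = rho if config.k == 1 else max(rho, bound + 1e-3)
    theta = float(rng.uniform(*config.theta_range))
    X = sim_design(config.n, config.k, rho_used, seed=rng)
    log_T, scaling = sim_offsets(config.n, mu=config.mu, seed=rng,
                                 scaling_range=config.scaling_range)
    beta = sim_beta(config.k, config.resolved_effects(), seed=rng)
    y = sim_counts(X, beta, log_T, config.mu, theta, seed=rng)
    return SimReplicate(X=X, beta_true=beta, theta_true=theta, rho=rho,
                        rho_used=rho_used, log_T=log_T, y=y,
                        seed=config.seed, scaling=scaling, config=config)
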