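"""Synthetic censored-regression data emulating an HIV viral-load study.

The high-dimensional generator draws a binary mutation matrix (correlated
presence/absence markers), a Gaussian baseline viral load, and a latent
log10 outcome

    Y = beta0 + beta1_baseline * Y0 + X beta + eps,

then applies the Tobit observation rule at a fixed detection limit.  The
intercept beta0 is calibrated by root-finding on a large dedicated sample
so the censoring probability P(Y <= LOD) hits the requested target, and
the noise variance is set from the signal-to-noise ratio, defined as
Var(linear predictor) / sigma^2.

Binary predictors with a prescribed correlation-decay structure are not
realizable as a literal multivariate Bernoulli; a Gaussian-copula
construction is used instead (latent AR(1) with correlation rho^|i-j|,
thresholded at the (1 - prevalence) quantile).  The induced binary-scale
correlation is smaller than the latent one.

A separate low-dimensional (p = 1) generator supports the classical
single-predictor illustration with its own SNR convention.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .data import CensoredDataset, validate

__all__ = [
    "SimConfig",
    "SimDataset",
    "correlated_binary_matrix",
    "calibrate_sim",
    "generate_sim_dataset",
    "generate_paired_test",
    "generate_lowdim_dataset",
]

_CALIB_TAG = 0x5EED  # distinguishes the calibration stream from data streams


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the high-dimensional generator.

    Defaults are the study conditions: n = p = 100, mutation prevalence
    0.15 with latent AR(0.4) correlation, ten true effects of size 1,
    SNR 3:1, baseline viral load N(12, 1) on the log10 copies/mL scale
    with carry-over slope 0.5, detection limit at 1.0 on the simulated
    scale.
    """

    n: int = 100
    p: int = 100
    prevalence: float = 0.15
    rho: float = 0.4
    n_relevant: int = 10
    effect: float = 1.0
    snr: float = 3.0
    baseline_mean: float = 12.0
    baseline_var: float = 1.0
    beta1_baseline: float = 0.5
    target_censoring: float = 0.5
    lod: float = 1.0
    seed: int = 0
    calib_size: int = 100_000

    def __post_init__(self):
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must be in [0, 1)")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.n_relevant > self.p:
            raise ValueError("n_relevant exceeds p")
        if not 0 <= self.target_censoring < 1:
            raise ValueError("target_censoring must be in [0, 1)")

    @property
    def beta_x(self) -> np.ndarray:
        """Mutation effects: `effect` for the first n_relevant, else 0."""
        b = np.zeros(self.p)
        b[: self.n_relevant] = self.effect
        return b


@dataclass(frozen=True)
class SimDataset:
    """A realized dataset plus the simulation truth.

    ``ds.X`` carries the baseline covariate as its first column;
    ``beta_true`` is aligned with ``ds.X`` (baseline slope first).
    """

    ds: CensoredDataset
    y_latent: np.ndarray
    beta_true: np.ndarray
    beta0_true: float
    sigma2_true: float
    achieved_censoring: float
    config: SimConfig | None = None


def correlated_binary_matrix(n, p, prevalence, rho, seed) -> np.ndarray:
    """Correlated Bernoulli(prevalence) matrix via a Gaussian copula.

    Latent rows follow a stationary AR(1) with correlation rho^|i-j|;
    thresholding each latent column at the (1 - prevalence) Gaussian
    quantile gives marginal prevalence exactly, with positive dependence
    decaying in column distance.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g = rng.standard_normal((n, p))
    lat = np.empty((n, p))
    lat[:, 0] = g[:, 0]
    root = np.sqrt(1.0 - rho**2)
    for j in range(1, p):
        lat[:, j] = rho * lat[:, j - 1] + root * g[:, j]
    return (lat > norm.ppf(1.0 - prevalence)).astype(float)


def _linear_predictor(cfg: SimConfig, rng: np.random.Generator, n: int):
    """Draw (Y0, X, lp) for n rows: everything except intercept and noise."""
    y0 = cfg.baseline_mean + np.sqrt(cfg.baseline_var) * rng.standard_normal(n)
    X = correlated_binary_matrix(n, cfg.p, cfg.prevalence, cfg.rho, rng)
    lp = cfg.beta1_baseline * y0 + X @ cfg.beta_x
    return y0, X, lp


def calibrate_sim(cfg: SimConfig) -> tuple[float, float]:
    """Return (beta0, sigma2) hitting the censoring target and SNR.

    A large dedicated calibration sample (default 1e5 rows, its own seed
    stream) fixes sigma^2 = Var(lp)/snr, then beta0 solves
    mean_i Phi((lod - beta0 - lp_i)/sigma) = target by bracketed
    root-finding.  A target of zero is mapped to 1e-4 so the intercept
    sits far above the detection limit.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, _CALIB_TAG]))
    _, _, lp = _linear_predictor(cfg, rng, cfg.calib_size)
    sigma2 = float(np.var(lp) / cfg.snr)
    sigma = np.sqrt(sigma2)
    target = max(cfg.target_censoring, 1e-4)

    def prob(beta0):
        return float(np.mean(norm.cdf((cfg.lod - beta0 - lp) / sigma))) - target

    lo = cfg.lod - np.max(lp) - 10 * sigma  # prob ~ 1 here
    hi = cfg.lod - np.min(lp) + 10 * sigma  # prob ~ 0 here
    beta0 = brentq(prob, lo, hi, xtol=1e-10)
    return float(beta0), sigma2


def generate_sim_dataset(
    cfg: SimConfig, calibration: tuple[float, float] | None = None,
) -> SimDataset:
    """Draw one dataset under the Tobit observation rule.

    ``calibration`` lets a precomputed (beta0, sigma2) be reused across
    replicates of the same configuration.
    """
    beta0, sigma2 = calibration if calibration is not None else calibrate_sim(cfg)
    rng = np.random.default_rng(cfg.seed)
    y0, X, lp = _linear_predictor(cfg, rng, cfg.n)
    eps = np.sqrt(sigma2) * rng.standard_normal(cfg.n)
    y_latent = beta0 + lp + eps
    delta = (y_latent > cfg.lod).astype(int)
    z = np.maximum(y_latent, cfg.lod)
    names = ("baseline",) + tuple(f"m{j + 1:03d}" for j in range(cfg.p))
    ds = validate(
        CensoredDataset(z, delta, np.full(cfg.n, cfg.lod),
                        np.column_stack([y0, X]), names)
    )
    return SimDataset(
        ds=ds,
        y_latent=y_latent,
        beta_true=np.concatenate([[cfg.beta1_baseline], cfg.beta_x]),
        beta0_true=beta0,
        sigma2_true=sigma2,
        achieved_censoring=float(np.mean(delta == 0)),
        config=cfg,
    )


def generate_paired_test(
    sim: SimDataset, seed: int, n_test: int | None = None,
    rate_tol: float = 0.05, max_tries: int = 50,
) -> SimDataset:
    """Companion test set with roughly the training censoring proportion.

    Redraws (new seed stream) until the test censoring rate is within
    ``rate_tol`` of the training rate; the least-discrepant draw is kept
    if no draw qualifies within ``max_tries``.
    """
    cfg = sim.config
    calibration = (sim.beta0_true, sim.sigma2_true)
    best = None
    for t in range(max_tries):
        child = int(np.random.SeedSequence([seed, t]).generate_state(1)[0] % 2**31)
        sub = replace(cfg, seed=child, n=n_test or cfg.n)
        cand = generate_sim_dataset(sub, calibration)
        gap = abs(cand.achieved_censoring - sim.achieved_censoring)
        if best is None or gap < best[0]:
            best = (gap, cand)
        if gap <= rate_tol:
            return cand
    return best[1]


def generate_lowdim_dataset(
    n: int, target_censoring: float, beta: float = 10.0,
    snr: float = 4.0 / 3.0, seed: int = 0,
) -> SimDataset:
    """Single-predictor illustration: Y = X beta + eps, X ~ N(0, 1).

    The noise variance is beta^2/snr (default SNR 4:3 so sigma^2 = 75 at
    beta = 10) and the detection limit is set at the empirical quantile of
    the latent outcome matching the requested censoring rate.
    """
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    sigma2 = beta**2 / snr
    y = beta * x + np.sqrt(sigma2) * rng.standard_normal(n)
    if target_censoring <= 0:
        lod = float(np.min(y)) - 1.0
    else:
        lod = float(np.quantile(y, target_censoring))
    delta = (y > lod).astype(int)
    z = np.maximum(y, lod)
    ds = validate(CensoredDataset(z, delta, np.full(n, lod), x[:, None], ("x1",)))
    return SimDataset(
        ds=ds,
        y_latent=y,
        beta_true=np.array([beta]),
        beta0_true=0.0,
        sigma2_true=sigma2,
        achieved_censoring=float(np.mean(delta == 0)),
        config=None,
    )
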