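"""Censoring-aware cross-validation for the regularization parameter.

Folds are stratified on the censoring indicator so every fold carries
roughly the sample's censoring proportion.  Two hold-out losses are
offered: a squared loss after imputing censored test responses with the
learning-fold model ("imputed_sq"), and a Gaussian loss that scores
uncensored test rows by squared error and censored rows by their negative
log-probability of falling below the detection limit ("gaussian"); the
latter is proportional to the negative Tobit log-likelihood but comparable
in scale to the squared loss.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import log_ndtr

from .buckley_james import (
    BJOptions,
    gaussian_bj_fit,
    nonpar_bj_fit,
    simple_imputation_fit,
)
from .data import CensoredDataset, flip
from .imputation import km_conditional_mean, km_fit
from .solver import ModelFit, lambda_grid

__all__ = [
    "CVResult",
    "stratified_kfold",
    "loss_imputed_sq",
    "loss_gaussian",
    "cv_select_lambda",
    "METHODS",
]

logger = logging.getLogger(__name__)

METHODS = ("gaussbj", "gaussbj_1step", "nonparbj", "lod", "lod2")


@dataclass
class CVResult:
    """Cross-validation curve and the selected penalty."""

    lambdas: np.ndarray
    cv_mean: np.ndarray
    cv_se: np.ndarray
    lambda_opt: float
    fold_assignment: np.ndarray
    loss_type: str
    fold_losses: np.ndarray | None = None  # (K, len(lambdas))

    @property
    def opt_index(self) -> int:
        return int(np.argmin(self.cv_mean))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"lambda": self.lambdas, "cv_mean": self.cv_mean, "cv_se": self.cv_se}
        )


def stratified_kfold(delta, K: int, seed: int) -> np.ndarray:
    """Fold assignment balancing the censoring proportion across folds.

    Censored and uncensored indices are shuffled independently (seeded)
    and dealt round-robin, so per-fold censored counts differ by at most
    one and fold sizes by at most two.
    """
    delta = np.asarray(delta, dtype=int)
    n = delta.shape[0]
    if K < 2:
        raise ValueError("K must be at least 2")
    if K > n:
        raise ValueError("K exceeds the number of observations")
    rng = np.random.default_rng(seed)
    assign = np.empty(n, dtype=int)
    offset = 0  # continue dealing across groups so fold sizes stay even
    for group in (np.flatnonzero(delta == 0), np.flatnonzero(delta == 1)):
        order = rng.permutation(group)
        assign[order] = (offset + np.arange(order.size)) % K
        offset = (offset + order.size) % K
    return assign


def _impute_test(method: str, fit: ModelFit, learn: CensoredDataset,
                 test: CensoredDataset) -> np.ndarray:
    """Learning-model conditional imputation of censored test responses."""
    y = test.z.astype(float).copy()
    cens = test.censored
    if not np.any(cens):
        return y
    if method in ("gaussbj", "gaussbj_1step"):
        from .imputation import gaussian_conditional_mean

        mu = fit.predict(test.X[cens])
        y[cens] = gaussian_conditional_mean(mu, np.sqrt(fit.sigma2), test.lod[cens])
    elif method == "nonparbj":
        # KM on learning-fold flipped residuals, applied at the test rows'
        # flipped residual thresholds
        fd = flip(learn, float(max(learn.z.max(), test.z.max())))
        beta_f, int_f = -fit.beta, fd.M - fit.intercept
        resid = fd.y_flip - (int_f + fd.X @ beta_f)
        curve = km_fit(resid, fd.delta)
        mu_f = int_f + test.X[cens] @ beta_f
        thr = fd.M - test.lod[cens]
        out = np.empty(thr.shape[0])
        for k in range(thr.shape[0]):
            e = thr[k] - mu_f[k]
            try:
                out[k] = km_conditional_mean(curve, e)
            except ValueError:
                out[k] = curve.times[-1] if curve.times.size else e
        y[cens] = fd.M - (mu_f + out)
    elif method == "lod":
        pass  # observed z already equals LOD on censored rows
    elif method == "lod2":
        y[cens] = test.lod[cens] / 2.0
    else:
        raise ValueError(f"unknown method {method!r}")
    return y


def loss_imputed_sq(fit: ModelFit, test: CensoredDataset, y_tilde) -> float:
    """Mean squared hold-out error against (imputed) test responses."""
    mu = fit.predict(test.X)
    return float(np.mean((np.asarray(y_tilde, dtype=float) - mu) ** 2))


def loss_gaussian(fit: ModelFit, test: CensoredDataset,
                  sigma2: float | None = None) -> float:
    """Censoring-aware Gaussian hold-out loss.

    ``(1/n_unc) sum_unc (z_i - mu_i)^2
    + (2 sigma^2 / n_unc) sum_cens [-ln Phi((lod_i - mu_i)/sigma)]``
    with sigma^2 taken from the learning-fold fit.  Reduces to the mean
    squared error (with the uncensored-count denominator) on folds without
    censoring.
    """
    sigma2 = fit.sigma2 if sigma2 is None else sigma2
    if sigma2 is None or sigma2 <= 0:
        raise ValueError("loss_gaussian needs a positive learning-fold sigma2")
    unc = test.uncensored
    n_unc = int(unc.sum())
    if n_unc == 0:
        raise ValueError("no uncensored rows in fold")
    mu = fit.predict(test.X)
    sq = float(np.sum((test.z[unc] - mu[unc]) ** 2)) / n_unc
    cens = ~unc
    if np.any(cens):
        a = (test.lod[cens] - mu[cens]) / np.sqrt(sigma2)
        sq += (2.0 * sigma2 / n_unc) * float(np.sum(-log_ndtr(a)))
    return sq


def _fit_method(method: str, learn: CensoredDataset, lam: float,
                opts: BJOptions, init: ModelFit | None,
                solver=None) -> ModelFit:
    if method == "gaussbj":
        return gaussian_bj_fit(learn, lam, opts, init=init, solver=solver)
    if method == "gaussbj_1step":
        one = BJOptions(**{**opts.__dict__, "one_step": True})
        return gaussian_bj_fit(learn, lam, one, init=init, solver=solver)
    if method == "nonparbj":
        return nonpar_bj_fit(learn, lam, opts, init=init, solver=solver)
    if method == "lod":
        return simple_imputation_fit(learn, lam, divisor=1, solver=solver)
    if method == "lod2":
        return simple_imputation_fit(learn, lam, divisor=2, solver=solver)
    raise ValueError(f"unknown method {method!r}")


def _uncensored_resid_var(fit: ModelFit, ds: CensoredDataset) -> float:
    unc = ds.uncensored
    r = ds.z[unc] - fit.predict(ds.X[unc])
    return max(float(np.mean(r**2)), 1e-10)


def cv_select_lambda(
    ds: CensoredDataset,
    method: str = "gaussbj",
    loss_type: str = "imputed_sq",
    K: int = 5,
    seed: int = 0,
    n_lambda: int = 100,
    lambda_ratio: float = 0.001,
    opts: BJOptions | None = None,
) -> CVResult:
    """Stratified K-fold CV over a shared lambda grid; returns the minimizer.

    The grid is built once from the full data after LOD imputation.  Within
    each fold the method is refit at every grid value from largest to
    smallest penalty, warm-starting each fit from its neighbour; the
    iterative Buckley-James methods run their full loop at every value.
    Ties in the CV minimum resolve toward the larger (more parsimonious)
    penalty.  Folds that end up with no uncensored row (which would make
    the Gaussian loss undefined) trigger a reseeded re-draw of the folds,
    up to 10 attempts.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    if loss_type not in ("imputed_sq", "gaussian"):
        raise ValueError("loss_type must be 'imputed_sq' or 'gaussian'")
    opts = opts or BJOptions()

    z_imp = ds.z.astype(float).copy()
    z_imp[ds.censored] = ds.lod[ds.censored]
    grid = lambda_grid(ds.X, z_imp, n_points=n_lambda, ratio=lambda_ratio)

    assign = None
    for attempt in range(10):
        cand = stratified_kfold(ds.delta, K, seed + attempt)
        ok = all(ds.delta[cand == k].sum() > 0 for k in range(K))
        if ok:
            assign = cand
            break
        logger.warning("fold draw %d left a fold without uncensored rows; "
                       "reseeding", attempt)
    if assign is None:
        raise ValueError("could not build folds with uncensored rows in each")

    from .solver import CDSolver

    losses = np.empty((K, grid.size))
    for k in range(K):
        learn = ds.subset(assign != k)
        test = ds.subset(assign == k)
        # one warm-started solver per fold: the design never changes along
        # the grid (the flip leaves X untouched), only the working response
        solver = CDSolver(learn.X)
        init = None
        for j, lam in enumerate(grid):
            fit = _fit_method(method, learn, float(lam), opts, init, solver)
            if method in ("gaussbj", "nonparbj"):
                # warm-start only the fully-iterated loops; the one-step
                # variant must keep its defining initialization
                init = fit
            if loss_type == "imputed_sq":
                y_tilde = _impute_test(method, fit, learn, test)
                losses[k, j] = loss_imputed_sq(fit, test, y_tilde)
            else:
                s2 = fit.sigma2
                if s2 is None:
                    s2 = _uncensored_resid_var(fit, learn)
                    logger.debug("gaussian loss with %s: using uncensored "
                                 "residual variance (non-canonical)", method)
                losses[k, j] = loss_gaussian(fit, test, sigma2=s2)

    cv_mean = losses.mean(axis=0)
    cv_se = losses.std(axis=0, ddof=1) / np.sqrt(K)
    i_opt = int(np.argmin(cv_mean))  # first index = largest lambda on ties
    return CVResult(
        lambdas=grid,
        cv_mean=cv_mean,
        cv_se=cv_se,
        lambda_opt=float(grid[i_opt]),
        fold_assignment=assign,
        loss_type=loss_type,
        fold_losses=losses,
    )
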