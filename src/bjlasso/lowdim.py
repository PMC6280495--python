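"""Unpenalized baselines for small-p censored regression.

These are the classical estimators a practitioner would compare against in
a low-dimensional detection-limit problem: the Tobit maximum-likelihood
estimator for a censored Gaussian outcome, median (least absolute
deviations) regression on LOD-imputed data, and Powell's censored LAD
estimator fit by iterative trimming.  They are intentionally unpenalized
and meant for p small relative to n.
"""

from __future__ import annotations

import numpy as np
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import log_ndtr

from .data import CensoredDataset
from .imputation import _mills_lower
from .solver import ModelFit, ols_fit

__all__ = ["tobit_mle", "lad_fit", "clad_fit", "tobit_loglik"]


def tobit_loglik(ds: CensoredDataset, beta, intercept, sigma2) -> float:
    """Censored-Gaussian log-likelihood at the given parameters."""
    mu = intercept + ds.X @ np.asarray(beta, dtype=float)
    unc = ds.uncensored
    r = ds.z[unc] - mu[unc]
    ll = -0.5 * unc.sum() * np.log(2 * np.pi * sigma2) - r @ r / (2 * sigma2)
    cens = ~unc
    if np.any(cens):
        ll += log_ndtr((ds.lod[cens] - mu[cens]) / np.sqrt(sigma2)).sum()
    return float(ll)


def tobit_mle(ds: CensoredDataset, start=None) -> ModelFit:
    """Maximum-likelihood Tobit fit by smooth optimization on (beta, log sigma).

    Uncensored rows contribute Gaussian densities, censored rows the
    probability mass below their detection limit.  The analytic score is
    supplied to BFGS; the default start is OLS on LOD-imputed responses.
    Requires n > p + 2 and at least two uncensored rows.
    """
    n = ds.n
    p_eff = int(np.count_nonzero(ds.X.std(axis=0) > 0))  # constant cols are free
    if n <= p_eff + 2:
        raise ValueError("tobit_mle needs n > p + 2")
    if ds.uncensored.sum() < 2:
        raise ValueError("need at least 2 uncensored observations")
    X1 = np.column_stack([np.ones(n), ds.X])
    unc = ds.uncensored
    cens = ~unc

    if start is None:
        z_imp = ds.z.copy()
        z_imp[cens] = ds.lod[cens]
        f0 = ols_fit(ds.X, z_imp)
        start = np.concatenate([[f0.intercept], f0.beta,
                                [0.5 * np.log(max(f0.sigma2, 1e-6))]])
    start = np.asarray(start, dtype=float)

    def negloglik_and_grad(theta):
        coef, log_sigma = theta[:-1], theta[-1]
        sigma = np.exp(log_sigma)
        mu = X1 @ coef
        r = ds.z[unc] - mu[unc]
        nll = 0.5 * unc.sum() * np.log(2 * np.pi * sigma**2) + r @ r / (2 * sigma**2)
        dmu = np.zeros(n)
        dmu[unc] = r / sigma**2
        g_logsig = float(np.sum(r**2 / sigma**2 - 1.0))
        if np.any(cens):
            a = (ds.lod[cens] - mu[cens]) / sigma
            nll -= float(log_ndtr(a).sum())
            h = _mills_lower(a)
            dmu[cens] = -h / sigma
            g_logsig += float(np.sum(-a * h))
        grad = np.concatenate([-(X1.T @ dmu), [-g_logsig]])
        return float(nll), grad

    res = minimize(negloglik_and_grad, start, jac=True, method="BFGS",
                   options={"maxiter": 500, "gtol": 1e-8})
    if not np.all(np.isfinite(res.x)):
        raise RuntimeError("Tobit optimization diverged")
    sigma2 = float(np.exp(2 * res.x[-1]))
    if sigma2 < 1e-12:
        raise RuntimeError("sigma collapsed toward zero in Tobit fit")
    return ModelFit(beta=res.x[1:-1], intercept=float(res.x[0]), lam=0.0,
                    status="direct", sigma2=sigma2)


def lad_fit(X, y) -> ModelFit:
    """Median regression: minimize ``(1/n) sum |y_i - b0 - X_i beta|``."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need n > p for LAD")
    exog = sm.add_constant(X, has_constant="add")
    res = sm.QuantReg(y, exog).fit(q=0.5, max_iter=5000, p_tol=1e-10)
    params = np.asarray(res.params, dtype=float)
    return ModelFit(beta=params[1:], intercept=float(params[0]), lam=0.0,
                    status="direct")


def _clad_objective(ds: CensoredDataset, beta, intercept) -> float:
    mu = intercept + ds.X @ beta
    return float(np.mean(np.abs(ds.z - np.maximum(ds.lod, mu))))


def clad_fit(ds: CensoredDataset, max_iter: int = 50) -> ModelFit:
    """Powell's censored LAD via iterative trimming.

    Repeats: keep the rows whose fitted value exceeds their detection
    limit, refit LAD on them.  Stops when the kept set repeats; on a cycle
    the best-objective iterate is returned.  Minimizes
    ``(1/n) sum |z_i - max(lod_i, b0 + X_i beta)|``.
    """
    fit = lad_fit(ds.X, ds.z)
    seen = []
    best = (_clad_objective(ds, fit.beta, fit.intercept), fit)
    status = "max_iter"
    for _ in range(max_iter):
        keep = fit.predict(ds.X) > ds.lod
        if keep.sum() <= ds.p:
            raise ValueError("trimming set became too small")
        key = keep.tobytes()
        if seen and key == seen[-1]:
            status = "converged"
            best = (_clad_objective(ds, fit.beta, fit.intercept), fit)
            break
        if key in seen:  # cycle: fall back to best objective seen
            status = "converged"
            break
        seen.append(key)
        fit = lad_fit(ds.X[keep], ds.z[keep])
        obj = _clad_objective(ds, fit.beta, fit.intercept)
        if obj < best[0]:
            best = (obj, fit)
    out = best[1]
    out.status = status
    return out
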