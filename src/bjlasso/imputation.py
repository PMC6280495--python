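"""Conditional-expectation engines for censored-value imputation.

Two routes are provided for the conditional mean of a censored outcome
given that it lies below its detection limit:

* a closed-form truncated-Gaussian expression using the inverse Mills
  ratio, evaluated in log space so that observations censored far in the
  tail (many sigmas below the linear predictor) remain numerically stable;
* a non-parametric route that conditions on a Kaplan-Meier estimate of the
  residual distribution after flipping left-censored data to the
  right-censored scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import log_ndtr

__all__ = [
    "KMCurve",
    "gaussian_conditional_mean",
    "gaussian_conditional_var",
    "km_fit",
    "km_conditional_mean",
    "impute_responses_gaussian",
]


def _mills_lower(a):
    """phi(a)/Phi(a), stable for very negative a via log-space evaluation."""
    a = np.asarray(a, dtype=float)
    log_phi = -0.5 * a**2 - 0.5 * np.log(2.0 * np.pi)
    return np.exp(log_phi - log_ndtr(a))


def gaussian_conditional_mean(mu, sigma, c):
    """E(Y | Y <= c) for Y ~ Normal(mu, sigma^2).

    Closed form ``mu - sigma * phi(a)/Phi(a)`` with ``a = (c - mu)/sigma``;
    the Mills ratio is computed from log-densities so censoring points deep
    in the upper or lower tail do not underflow.  The result is strictly
    below ``c``.
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(c)) and np.all(np.isfinite(sigma))):
        raise ValueError("non-finite input")
    a = (np.asarray(c, dtype=float) - mu) / sigma
    out = mu - sigma * _mills_lower(a)
    return out if out.ndim else float(out)


def gaussian_conditional_var(mu, sigma, c):
    """Var(Y | Y <= c) for Y ~ Normal(mu, sigma^2).

    ``sigma^2 * (1 - a*h - h^2)`` with ``h = phi(a)/Phi(a)``; always in
    (0, sigma^2].
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(c)) and np.all(np.isfinite(sigma))):
        raise ValueError("non-finite input")
    a = (np.asarray(c, dtype=float) - mu) / sigma
    h = _mills_lower(a)
    out = sigma**2 * (1.0 - a * h - h**2)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class KMCurve:
    """Kaplan-Meier step function as (event time, survival, jump mass).

    ``surv[k]`` is the survival value just after ``times[k]``; ``jumps`` are
    the probability masses at the event times and sum to 1 whenever the
    largest observation is an event (or is treated as one by the tail
    correction).
    """

    times: np.ndarray
    surv: np.ndarray
    jumps: np.ndarray

    def survival_at(self, c: float) -> float:
        """S(c) = mass strictly above c."""
        return float(self.jumps[self.times > c].sum())


def km_fit(values, events, tail_correction: bool = True) -> KMCurve:
    """Product-limit estimator for a right-censored sample.

    Ties are handled conventionally (events precede censorings at equal
    values).  With ``tail_correction`` (default), censored observations at
    the largest value are treated as events so the jump masses sum to 1 and
    conditional means above any threshold with positive mass stay finite --
    the standard Buckley-James tail convention.
    """
    values = np.asarray(values, dtype=float)
    events = np.asarray(events, dtype=int)
    if values.size == 0:
        raise ValueError("empty sample")
    if events.sum() == 0 and not tail_correction:
        raise ValueError("all observations censored")
    if tail_correction:
        events = events.copy()
        events[values == values.max()] = 1
    # sequential product-limit; sorting events before censorings at tied
    # values reproduces the grouped estimator with the conventional tie rule
    order = np.lexsort((1 - events, values))
    v, e = values[order], events[order]
    n = v.size
    at_risk = n - np.arange(n)
    surv_path = np.cumprod(1.0 - e / at_risk)
    # survival just after each distinct value = path value at its last index
    last = np.flatnonzero(np.diff(v, append=np.inf) != 0)
    has_event = np.logical_or.reduceat(e.astype(bool), np.concatenate([[0], last[:-1] + 1]))
    t_ev = v[last][has_event]
    s_ev = surv_path[last][has_event]
    prev = np.concatenate([[1.0], s_ev[:-1]])
    return KMCurve(times=t_ev, surv=s_ev, jumps=prev - s_ev)


def km_conditional_mean(curve: KMCurve, c: float) -> float:
    """E(T | T > c) under the discrete KM distribution.

    Sums jump-weighted event times above ``c`` normalized by the mass
    above ``c``; errors when no mass lies strictly above the threshold
    (callers fall back to a tail value).
    """
    above = curve.times > c
    mass = curve.jumps[above].sum()
    if mass <= 0:
        raise ValueError("no support above threshold")
    return float(np.sum(curve.jumps[above] * curve.times[above]) / mass)


def impute_responses_gaussian(ds, beta, intercept, sigma2) -> np.ndarray:
    """Replace censored responses by their truncated-Gaussian conditional mean.

    Uncensored rows keep their observed values; each censored row gets
    ``E(Y | Y <= LOD_i, X_i)`` under the current fit, which is strictly
    below its detection limit.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    z_star = ds.z.astype(float).copy()
    cens = ds.censored
    if np.any(cens):
        mu = intercept + ds.X[cens] @ np.asarray(beta, dtype=float)
        z_star[cens] = gaussian_conditional_mean(mu, np.sqrt(sigma2), ds.lod[cens])
    return z_star
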