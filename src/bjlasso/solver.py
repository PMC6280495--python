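"""L1-penalized and ordinary least squares with a fixed objective scaling.

The penalized objective throughout the package is

    ||y - intercept - X beta||_2^2 + lambda * ||beta||_1

i.e. a plain sum of squares with no 1/(2n) factor, and an unpenalized
intercept.  The coordinate-descent solve is delegated to scikit-learn's
``Lasso``, which minimizes ``(1/2n)||.||^2 + alpha ||beta||_1``; the exact
mapping ``alpha = lambda / (2n)`` makes the two objectives share their
minimizer.  Predictors are standardized internally (the penalty acts on
the standardized scale) and coefficients are reported back on the original
predictor scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import Lasso, _cd_fast

from .data import Standardizer, standardize

__all__ = ["ModelFit", "CDSolver", "lasso_fit", "ols_fit", "lambda_max",
           "lambda_grid"]


@dataclass
class ModelFit:
    """A fitted linear model.

    ``beta``/``intercept`` are on the original predictor scale; ``beta_std``
    (and the attached standardizer) give the standardized-scale view used
    by iterative algorithms for their convergence checks.  ``sigma2`` is
    present when the fitting route estimates a noise variance.
    """

    beta: np.ndarray
    intercept: float
    lam: float
    status: str = "direct"
    sigma2: float | None = None
    n_iter: int = 1
    trace: list = field(default_factory=list)
    beta_std: np.ndarray | None = None
    standardizer: Standardizer | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + np.asarray(X, dtype=float) @ self.beta

    def nonzero(self) -> np.ndarray:
        return np.flatnonzero(self.beta != 0)

    def to_json(self) -> str:
        return json.dumps(
            {
                "beta": self.beta.tolist(),
                "intercept": self.intercept,
                "lambda": self.lam,
                "status": self.status,
                "sigma2": self.sigma2,
                "n_iter": self.n_iter,
            }
        )


def _prepare(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y have different numbers of rows")
    return X, y


def lasso_fit(X, y, lam: float, tol: float = 1e-9) -> ModelFit:
    """Minimize ``||y - b0 - X beta||^2 + lam * ||beta||_1``.

    Deterministic (cyclic coordinate descent); ``lam = 0`` falls back to a
    least-squares solve.  Zero-variance columns are excluded from the fit
    and receive zero coefficients.
    """
    X, y = _prepare(X, y)
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    n, p = X.shape
    Xs, sc = standardize(X)
    if lam == 0 and n > Xs.shape[1]:
        A = np.column_stack([np.ones(n), Xs])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        b0_std, beta_std = coef[0], coef[1:]
    else:
        model = Lasso(alpha=lam / (2.0 * n), fit_intercept=True, tol=tol,
                      max_iter=100000)
        model.fit(Xs, y)
        b0_std, beta_std = float(model.intercept_), model.coef_.astype(float)
    return ModelFit(
        beta=sc.beta_to_original(beta_std, p),
        intercept=sc.intercept_to_original(b0_std, beta_std),
        lam=float(lam),
        status="direct",
        beta_std=beta_std,
        standardizer=sc,
    )


class CDSolver:
    """Repeated penalized solves on one fixed design, with warm starts.

    Iterative imputation schemes refit the same X against a sequence of
    nearby working responses; standardizing once and warm-starting the
    coordinate descent from the previous coefficients makes those refits
    cheap.  The first solve starts from zero coefficients and reproduces
    :func:`lasso_fit` on the same inputs.
    """

    def __init__(self, X, tol: float = 1e-7):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        self.p = X.shape[1]
        self.n = X.shape[0]
        self.tol = tol
        self.Xs, self.sc = standardize(X)
        self._XsF = np.asfortranarray(self.Xs)
        self._w = np.zeros(self.Xs.shape[1])
        self._rng = np.random.RandomState(0)  # unused by cyclic updates

    def solve(self, y, lam: float) -> ModelFit:
        y = np.asarray(y, dtype=float)
        if lam < 0:
            raise ValueError("lambda must be non-negative")
        if lam == 0 and self.n > self.Xs.shape[1]:
            A = np.column_stack([np.ones(self.n), self.Xs])
            coef, *_ = np.linalg.lstsq(A, y, rcond=None)
            b0_std, beta_std = coef[0], coef[1:]
        else:
            # the standardized columns have exactly zero mean, so fitting
            # the centered response leaves the intercept at mean(y); the
            # Cython solver minimizes 1/2||.||^2 + a||w||_1, hence a=lam/2
            ybar = y.mean()
            yc = y - ybar
            self._w, *_ = _cd_fast.enet_coordinate_descent(
                self._w, lam / 2.0, 0.0, self._XsF, yc, 100000,
                self.tol * max(yc @ yc, 1e-12), self._rng, 0, 0,
            )
            b0_std, beta_std = float(ybar), self._w.copy()
        return ModelFit(
            beta=self.sc.beta_to_original(beta_std, self.p),
            intercept=self.sc.intercept_to_original(b0_std, beta_std),
            lam=float(lam),
            status="direct",
            beta_std=beta_std,
            standardizer=self.sc,
        )


def ols_fit(X, y) -> ModelFit:
    """Ordinary least squares with intercept; requires n > p and full rank.

    The residual variance is recorded as ``sigma2`` with divisor
    ``n - p - 1`` (intercept counted).
    """
    X, y = _prepare(X, y)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("need n > p + 1 for OLS with intercept")
    A = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(A) < p + 1:
        raise ValueError("design matrix is rank deficient")
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    sigma2 = float(resid @ resid / (n - p - 1))
    return ModelFit(
        beta=coef[1:], intercept=float(coef[0]), lam=0.0, status="direct",
        sigma2=sigma2,
    )


def lambda_max(X, y) -> float:
    """Smallest penalty at which every coefficient is exactly zero.

    Under the sum-of-squares objective the KKT condition at beta = 0 reads
    ``2 |x_j' (y - ybar)| <= lambda`` for every standardized column, so
    lambda_max = 2 max_j |x_j' (y - ybar)|.
    """
    X, y = _prepare(X, y)
    Xs, _ = standardize(X)
    r = y - y.mean()
    return float(2.0 * np.max(np.abs(Xs.T @ r)))


def lambda_grid(X, y, n_points: int = 100, ratio: float = 0.001) -> np.ndarray:
    """Decreasing log-spaced grid from lambda_max down to ratio*lambda_max."""
    if n_points < 2:
        raise ValueError("n_points must be at least 2")
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    lmax = lambda_max(X, y)
    if lmax == 0:
        return np.zeros(n_points)
    return np.geomspace(lmax, ratio * lmax, n_points)
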