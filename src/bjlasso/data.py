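"""Censored-data containers, the left/right censoring flip, and standardization.

The observed response ``z`` follows the Tobit observation rule: a latent
Gaussian outcome ``y`` (e.g. log10 HIV viral load) is seen exactly when it
exceeds the assay's limit of detection (LOD) and is otherwise recorded *at*
the LOD with a censoring flag.  Detection limits are per-row so multicentre
data with heterogeneous assays are first-class; a constant LOD is the
special case of a constant vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CensoredDataset",
    "FlippedDataset",
    "Standardizer",
    "validate",
    "flip",
    "unflip",
    "standardize",
    "censoring_rate",
    "read_csv",
    "write_csv",
]

_COERCE_TOL = 1e-12


@dataclass(frozen=True)
class CensoredDataset:
    """A left-censored regression dataset.

    Attributes
    ----------
    z : observed response; equals ``lod`` on censored rows.
    delta : 1 = uncensored (latent value above its LOD), 0 = left-censored.
    lod : per-row detection limit.
    X : (n, p) predictor matrix.
    names : predictor labels (length p).
    """

    z: np.ndarray
    delta: np.ndarray
    lod: np.ndarray
    X: np.ndarray
    names: tuple[str, ...] = field(default=())

    def __post_init__(self):
        object.__setattr__(self, "z", np.asarray(self.z, dtype=float))
        object.__setattr__(self, "delta", np.asarray(self.delta, dtype=int))
        object.__setattr__(self, "lod", np.asarray(self.lod, dtype=float))
        X = np.asarray(self.X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        object.__setattr__(self, "X", X)
        if not self.names:
            object.__setattr__(
                self, "names", tuple(f"x{j + 1}" for j in range(X.shape[1]))
            )

    @property
    def n(self) -> int:
        return self.z.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def censored(self) -> np.ndarray:
        """Boolean mask of left-censored rows."""
        return self.delta == 0

    @property
    def uncensored(self) -> np.ndarray:
        return self.delta == 1

    def subset(self, idx) -> "CensoredDataset":
        """Row subset (fold extraction); no re-validation needed."""
        return CensoredDataset(
            self.z[idx], self.delta[idx], self.lod[idx], self.X[idx], self.names
        )


@dataclass(frozen=True)
class FlippedDataset:
    """Right-censored view ``M - z`` of a left-censored dataset.

    ``delta`` keeps its values but is reinterpreted as an event indicator
    (1 = exact observation) for the right-censoring scale, so standard
    survival machinery (Kaplan-Meier on residuals) applies directly.
    """

    y_flip: np.ndarray
    delta: np.ndarray
    threshold_flip: np.ndarray
    M: float
    X: np.ndarray


def validate(ds: CensoredDataset) -> CensoredDataset:
    """Check all dataset invariants; returns a (possibly coerced) dataset.

    Censored rows whose recorded response differs from the row LOD by at
    most 1e-12 are coerced to the LOD exactly; larger discrepancies and any
    uncensored response at or below its LOD are errors.
    """
    z, delta, lod, X = ds.z, ds.delta, ds.lod, ds.X
    n = z.shape[0]
    if not (delta.shape[0] == n and lod.shape[0] == n and X.shape[0] == n):
        raise ValueError(
            f"dimension mismatch: z {z.shape[0]}, delta {delta.shape[0]}, "
            f"lod {lod.shape[0]}, X rows {X.shape[0]}"
        )
    if n < 2:
        raise ValueError("need at least 2 observations")
    if X.shape[1] < 1:
        raise ValueError("need at least 1 predictor")
    if len(ds.names) != X.shape[1]:
        raise ValueError("names length does not match number of predictors")
    for name, arr in (("z", z), ("lod", lod), ("X", X)):
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite values in {name}")
    if not np.isin(delta, (0, 1)).all():
        raise ValueError("delta must contain only 0 and 1")
    unc = delta == 1
    if np.any(z[unc] <= lod[unc]):
        raise ValueError("uncensored value below LOD (z <= lod with delta=1)")
    cens = ~unc
    dev = np.abs(z[cens] - lod[cens])
    if np.any(dev > _COERCE_TOL):
        raise ValueError("censored rows must have z equal to their LOD")
    if np.any(dev > 0):
        z = z.copy()
        z[cens] = lod[cens]
        return replace(ds, z=z)
    return ds


def censoring_rate(ds: CensoredDataset) -> float:
    """Fraction of left-censored rows, ``mean(1 - delta)``."""
    return float(np.mean(1 - ds.delta))


def flip(ds: CensoredDataset, M: float | str = "auto") -> FlippedDataset:
    """Turn left-censoring at LOD into right-censoring at ``M - LOD``.

    ``M`` must equal or exceed the largest observation; the default
    ``"auto"`` uses ``max(z)`` exactly, the smallest admissible constant,
    which keeps the flipped values in the smallest numeric range.
    """
    if isinstance(M, str):
        if M != "auto":
            raise ValueError(f"unknown M specification {M!r}")
        M = float(np.max(ds.z))
    M = float(M)
    if M < np.max(ds.z):
        raise ValueError(f"M={M} is below the largest observation {np.max(ds.z)}")
    return FlippedDataset(
        y_flip=M - ds.z,
        delta=ds.delta.copy(),
        threshold_flip=M - ds.lod,
        M=M,
        X=ds.X,
    )


def unflip(fd: FlippedDataset, names=()) -> CensoredDataset:
    """Inverse of :func:`flip`; exact for any admissible ``M``."""
    return CensoredDataset(
        z=fd.M - fd.y_flip,
        delta=fd.delta.copy(),
        lod=fd.M - fd.threshold_flip,
        X=fd.X,
        names=tuple(names),
    )


@dataclass(frozen=True)
class Standardizer:
    """Column centers/scales of a standardized design, with dropped columns.

    Scales use the n-denominator (population) standard deviation so the
    transform can be undone bit-exactly when reporting coefficients on the
    original predictor scale.
    """

    centers: np.ndarray
    scales: np.ndarray
    kept: np.ndarray  # indices of retained (non-constant) columns

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X[:, self.kept] - self.centers) / self.scales

    def beta_to_original(self, beta_std: np.ndarray, p: int) -> np.ndarray:
        """Map standardized-scale coefficients to the original scale."""
        beta = np.zeros(p)
        beta[self.kept] = beta_std / self.scales
        return beta

    def intercept_to_original(self, intercept_std: float, beta_std) -> float:
        return float(intercept_std - np.sum(beta_std * self.centers / self.scales))


def standardize(X: np.ndarray, names=None) -> tuple[np.ndarray, Standardizer]:
    """Center and scale each column to mean 0, sd 1 (population sd).

    Constant columns carry no information and cannot be scaled; they are
    dropped with a warning (their coefficients are reported as zero).
    """
    X = np.asarray(X, dtype=float)
    centers = X.mean(axis=0)
    scales = X.std(axis=0)
    kept = np.flatnonzero(scales > 0)
    if kept.size == 0:
        raise ValueError("all predictor columns are constant")
    if kept.size < X.shape[1]:
        dropped = sorted(set(range(X.shape[1])) - set(kept.tolist()))
        labels = [names[j] if names else str(j) for j in dropped]
        warnings.warn(f"dropping constant predictor column(s): {labels}")
    sc = Standardizer(centers=centers[kept], scales=scales[kept], kept=kept)
    return sc.transform(X), sc


def read_csv(
    path,
    lod: float | None = None,
    response_col: str = "response",
    censored_col: str = "censored",
    lod_col: str = "lod",
    sep: str | None = None,
) -> CensoredDataset:
    """Read a censored dataset from CSV/TSV.

    Requires a ``response`` column and either a 0/1 ``censored`` column
    (1 = censored) together with a scalar ``lod``, or a per-row ``lod``
    column.  All remaining numeric columns are treated as predictors.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    if response_col not in df.columns:
        raise ValueError(f"missing required column {response_col!r}")
    z = df[response_col].to_numpy(dtype=float)
    if lod_col in df.columns:
        lod_vec = df[lod_col].to_numpy(dtype=float)
    elif lod is not None:
        lod_vec = np.full(len(df), float(lod))
    else:
        raise ValueError(f"need a {lod_col!r} column or a scalar lod")
    if censored_col in df.columns:
        delta = 1 - df[censored_col].to_numpy(dtype=int)
    else:
        delta = (z > lod_vec).astype(int)
    drop = [c for c in (response_col, censored_col, lod_col) if c in df.columns]
    Xdf = df.drop(columns=drop).select_dtypes(include=[np.number])
    if Xdf.shape[1] == 0:
        raise ValueError("no predictor columns found")
    return validate(
        CensoredDataset(z, delta, lod_vec, Xdf.to_numpy(dtype=float),
                        tuple(Xdf.columns))
    )


def write_csv(ds: CensoredDataset, path, sep: str = ",") -> None:
    """Write a dataset with the same column layout :func:`read_csv` expects."""
    df = pd.DataFrame({"response": ds.z, "censored": 1 - ds.delta, "lod": ds.lod})
    for j, name in enumerate(ds.names):
        df[name] = ds.X[:, j]
    df.to_csv(path, sep=sep, index=False)
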