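"""Test-set error, selection summaries, and the simulation benchmark runners.

The benchmark regenerates the study design — paired train/test draws at a
range of censoring rates — and compares the censoring-aware estimators
against simple substitution and against two references that see the
uncensored latent outcome (the Lasso "gold standard" and ordinary least
squares on the true support).  Prediction error is measured against the
latent uncensored response, which is available in simulation only.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .buckley_james import BJOptions, gaussian_bj_fit, nonpar_bj_fit, simple_imputation_fit
from .data import CensoredDataset
from .model_selection import cv_select_lambda
from .solver import ModelFit, lasso_fit, ols_fit
from .simulate import SimConfig, SimDataset, generate_paired_test, calibrate_sim, generate_sim_dataset

__all__ = [
    "test_mse",
    "selection_summary",
    "run_mse_experiment",
    "run_oscillation_experiment",
    "aggregate_mse",
]

# method -> CV loss used by default; the fully-iterated Gaussian BJ pairs
# with the censoring-aware Gaussian loss, everything else with imputed
# squared error
DEFAULT_LOSS = {
    "gaussbj": "gaussian",
    "gaussbj_1step": "imputed_sq",
    "nonparbj": "imputed_sq",
    "lod": "imputed_sq",
    "lod2": "imputed_sq",
}


def test_mse(fit: ModelFit, test: SimDataset) -> float:
    """Mean squared prediction error against the latent uncensored response."""
    if test.y_latent is None:
        raise ValueError(
            "test set has no latent response; use the cross-validation "
            "losses for real (censored-only) data"
        )
    mu = fit.predict(test.ds.X)
    return float(np.mean((test.y_latent - mu) ** 2))


def selection_summary(fit: ModelFit, groups: dict[str, str],
                      names=None) -> pd.DataFrame:
    """Count nonzero coefficients per annotation group.

    ``groups`` maps predictor names to category labels (e.g. resistance
    classes); returns per-group selected counts, group sizes and
    fractions.  Unknown predictor names raise.
    """
    names = list(names) if names is not None else [f"x{j+1}" for j in range(fit.beta.size)]
    unknown = [nm for nm in names if nm not in groups]
    if unknown:
        raise ValueError(f"predictors missing from group map: {unknown[:5]}")
    rows = {}
    for nm, b in zip(names, fit.beta):
        g = groups[nm]
        size, sel = rows.get(g, (0, 0))
        rows[g] = (size + 1, sel + (1 if b != 0 else 0))
    out = pd.DataFrame(
        [(g, size, sel, sel / size) for g, (size, sel) in sorted(rows.items())],
        columns=["group", "size", "selected", "fraction"],
    )
    return out


def _uncensored_view(ds: CensoredDataset, y: np.ndarray) -> CensoredDataset:
    """Wrap a fully-observed response as a censoring-free dataset."""
    lod = np.full(y.shape[0], float(np.min(y)) - 1.0)
    return CensoredDataset(y, np.ones(y.shape[0], dtype=int), lod, ds.X, ds.names)


def _final_fit(method: str, ds: CensoredDataset, lam: float,
               opts: BJOptions) -> ModelFit:
    if method == "gaussbj":
        return gaussian_bj_fit(ds, lam, opts)
    if method == "gaussbj_1step":
        return gaussian_bj_fit(ds, lam, replace(opts, one_step=True))
    if method == "nonparbj":
        return nonpar_bj_fit(ds, lam, opts)
    if method == "lod":
        return simple_imputation_fit(ds, lam, divisor=1)
    if method == "lod2":
        return simple_imputation_fit(ds, lam, divisor=2)
    raise ValueError(f"unknown method {method!r}")


def _child_seed(*parts) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % 2**31)


def _run_one(method, loss, train: SimDataset, test: SimDataset, K, seed,
             n_lambda, opts):
    """CV-select lambda, refit on the full training data, score on test."""
    ds = train.ds
    if method == "oracle":
        support = np.flatnonzero(train.beta_true != 0)
        f = ols_fit(ds.X[:, support], train.y_latent)
        fit = ModelFit(beta=np.zeros(ds.p), intercept=f.intercept, lam=0.0)
        fit.beta[support] = f.beta
        return fit, np.nan
    if method == "golds":
        view = _uncensored_view(ds, train.y_latent)
        cv = cv_select_lambda(view, "lod", "imputed_sq", K=K, seed=seed,
                              n_lambda=n_lambda, opts=opts)
        return lasso_fit(ds.X, train.y_latent, cv.lambda_opt), cv.lambda_opt
    cv = cv_select_lambda(ds, method, loss, K=K, seed=seed,
                          n_lambda=n_lambda, opts=opts)
    return _final_fit(method, ds, cv.lambda_opt, opts), cv.lambda_opt


def run_mse_experiment(
    reps: int = 50,
    censoring_levels=(0.0, 0.2, 0.5, 0.7),
    methods=("oracle", "golds", "gaussbj", "gaussbj_1step", "nonparbj", "lod", "lod2"),
    n: int = 100,
    p: int = 100,
    n_test: int = 100,
    K: int = 5,
    seed: int = 0,
    n_lambda: int = 50,
    loss_overrides: dict | None = None,
    opts: BJOptions | None = None,
) -> pd.DataFrame:
    """Replicated train/test benchmark across censoring rates.

    For each replicate and censoring level a paired train/test draw is
    generated, each method is tuned by stratified K-fold CV on the training
    data and refit at its selected penalty, and the latent-response test
    MSE is recorded together with the fit's termination status.  Returns a
    tidy frame (one row per replicate x method x level); per-replicate
    failures are recorded as NaN rows rather than aborting the run.
    """
    if reps < 2:
        raise ValueError("reps must be at least 2")
    opts = opts or BJOptions()
    losses = dict(DEFAULT_LOSS)
    losses.update(loss_overrides or {})
    rows = []
    for li, level in enumerate(censoring_levels):
        cfg = SimConfig(n=n, p=p, target_censoring=level,
                        seed=_child_seed(seed, li))
        calibration = calibrate_sim(cfg)
        for r in range(reps):
            train = generate_sim_dataset(
                replace(cfg, seed=_child_seed(seed, li, r, 0)), calibration)
            test = generate_paired_test(train, _child_seed(seed, li, r, 1),
                                        n_test=n_test)
            for method in methods:
                loss = losses.get(method, "imputed_sq")
                try:
                    fit, lam = _run_one(method, loss, train, test, K,
                                        _child_seed(seed, li, r, 2),
                                        n_lambda, opts)
                    rows.append({
                        "level": level, "rep": r, "method": method,
                        "mse": test_mse(fit, test), "status": fit.status,
                        "lambda_opt": lam,
                        "nnz": int(np.count_nonzero(fit.beta)),
                    })
                except Exception as exc:  # record, do not abort the sweep
                    rows.append({"level": level, "rep": r, "method": method,
                                 "mse": np.nan, "status": f"error:{exc}",
                                 "lambda_opt": np.nan, "nnz": 0})
    return pd.DataFrame(rows)


def aggregate_mse(table: pd.DataFrame) -> pd.DataFrame:
    """Mean/SD/SE of test MSE per method and censoring level."""
    g = table.groupby(["level", "method"])["mse"]
    out = g.agg(["mean", "std", "count"]).reset_index()
    out["se"] = out["std"] / np.sqrt(out["count"])
    return out


def run_oscillation_experiment(
    reps: int = 50,
    censoring_levels=(0.2, 0.5, 0.7),
    n: int = 100,
    p: int = 100,
    K: int = 5,
    seed: int = 0,
    n_lambda: int = 50,
    loss: str = "gaussian",
    opts: BJOptions | None = None,
) -> pd.DataFrame:
    """Fraction of replicates where the fully-iterated Gaussian BJ oscillates.

    Per replicate: draw a training set, select lambda by stratified K-fold
    CV for the fully-iterated Gaussian Buckley-James (censoring-aware loss
    by default), refit at the selected penalty, and record whether the
    loop terminated through oscillation detection.  Returns one row per
    censoring level with the rate and its binomial standard error.
    """
    if reps < 2:
        raise ValueError("reps must be at least 2")
    opts = opts or BJOptions()
    rows = []
    for li, level in enumerate(censoring_levels):
        cfg = SimConfig(n=n, p=p, target_censoring=level,
                        seed=_child_seed(seed, li))
        calibration = calibrate_sim(cfg)
        statuses = []
        for r in range(reps):
            train = generate_sim_dataset(
                replace(cfg, seed=_child_seed(seed, li, r, 0)), calibration)
            cv = cv_select_lambda(train.ds, "gaussbj", loss, K=K,
                                  seed=_child_seed(seed, li, r, 2),
                                  n_lambda=n_lambda, opts=opts)
            fit = gaussian_bj_fit(train.ds, cv.lambda_opt, opts)
            statuses.append(fit.status)
        k_osc = sum(s == "oscillated" for s in statuses)
        rate = k_osc / reps
        rows.append({
            "level": level, "reps": reps, "n_oscillated": k_osc,
            "rate": rate, "se": float(np.sqrt(rate * (1 - rate) / reps)),
            "n_converged": sum(s == "converged" for s in statuses),
            "n_max_iter": sum(s == "max_iter" for s in statuses),
        })
    return pd.DataFrame(rows)
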