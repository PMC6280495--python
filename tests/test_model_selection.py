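"""Stratified CV machinery and the two hold-out losses."""

import numpy as np
import pytest

from bjlasso import (
    CensoredDataset,
    cv_select_lambda,
    lasso_fit,
    loss_gaussian,
    loss_imputed_sq,
    stratified_kfold,
    validate,
)
from bjlasso.model_selection import _impute_test
from bjlasso.solver import ModelFit

from conftest import make_censored


class TestStratifiedKFold:
    def test_dealing_rule_example(self):
        delta = np.array([0, 0, 0, 0, 1, 1, 1, 1, 1, 1])  # 4 censored, n=10
        assign = stratified_kfold(delta, K=5, seed=0)
        sizes = np.bincount(assign, minlength=5)
        cens_counts = np.bincount(assign[delta == 0], minlength=5)
        assert np.all(sizes == 2)
        assert sorted(cens_counts) == [0, 1, 1, 1, 1]

    def test_all_uncensored_is_balanced(self):
        assign = stratified_kfold(np.ones(10, int), K=5, seed=1)
        assert np.all(np.bincount(assign, minlength=5) == 2)

    def test_determinism(self):
        delta = np.random.default_rng(0).integers(0, 2, 40)
        a = stratified_kfold(delta, 4, seed=7)
        b = stratified_kfold(delta, 4, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_rejects_bad_K(self):
        with pytest.raises(ValueError):
            stratified_kfold(np.ones(3, int), K=4, seed=0)
        with pytest.raises(ValueError):
            stratified_kfold(np.ones(3, int), K=1, seed=0)

    def test_balance_exhaustive_small_n(self):
        """Per-fold censored counts within 1 and sizes within 2 of each
        other for every (n, #censored, K) with n <= 30."""
        for n in range(2, 31):
            for K in (2, 3, 5):
                if K > n:
                    continue
                for n_cens in range(0, n + 1, max(1, n // 4)):
                    delta = np.zeros(n, int)
                    delta[n_cens:] = 1
                    assign = stratified_kfold(delta, K, seed=n * 31 + n_cens)
                    sizes = np.bincount(assign, minlength=K)
                    cens = np.bincount(assign[delta == 0], minlength=K)
                    assert sizes.max() - sizes.min() <= 2
                    assert cens.max() - cens.min() <= 1


def _fit(beta, intercept, sigma2=None):
    f = ModelFit(beta=np.atleast_1d(np.asarray(beta, float)),
                 intercept=float(intercept), lam=0.0)
    f.sigma2 = sigma2
    return f


class TestLosses:
    def test_imputed_sq_on_uncensored_fold_is_plain_mse(self):
        test = validate(CensoredDataset([1.0, 3.0], [1, 1], [-5, -5],
                                        [[0.0], [1.0]]))
        fit = _fit([0.0], 2.0)
        y_tilde = _impute_test("lod", fit, test, test)
        assert loss_imputed_sq(fit, test, y_tilde) == pytest.approx(1.0)

    def test_imputed_sq_censored_rows_contribute_mills_squared(self):
        # linear predictor at the LOD with sigma^2=1: imputed value is
        # lod - phi(0)/Phi(0), so each censored residual is the Mills ratio
        test = validate(CensoredDataset([0.0, 0.0], [0, 0], [0.0, 0.0],
                                        [[0.0], [1.0]]))
        fit = _fit([0.0], 0.0, sigma2=1.0)
        y_tilde = _impute_test("gaussbj", fit, test, test)
        assert loss_imputed_sq(fit, test, y_tilde) == pytest.approx(
            0.7978845608**2, abs=1e-9
        )

    def test_gaussian_loss_worked_fixture(self):
        # one uncensored row with residual 1, one censored row with mu=lod:
        # 1 + 2*sigma^2*ln(2) with sigma^2 = 1
        test = validate(CensoredDataset([2.0, 0.0], [1, 0], [-1.0, 0.0],
                                        [[0.0], [1.0]]))
        # beta=-1, intercept=1: uncensored residual 2-1=1; censored mu=0=lod
        fit = _fit([-1.0], 1.0, sigma2=1.0)
        assert loss_gaussian(fit, test) == pytest.approx(1 + 2 * np.log(2),
                                                         abs=1e-9)

    def test_gaussian_loss_reduces_to_squared_on_uncensored(self):
        ds, _, _ = make_censored(censor_frac=0.0, lod=-100, seed=5)
        fit = _fit(np.zeros(ds.p), 0.5, sigma2=2.0)
        expected = float(np.mean((ds.z - fit.predict(ds.X)) ** 2))
        assert loss_gaussian(fit, ds) == pytest.approx(expected, rel=1e-12)

    def test_gaussian_loss_censored_term_vanishes_far_below_lod(self):
        test = validate(CensoredDataset([1.0, 0.0], [1, 0], [-9.0, 0.0],
                                        [[0.0], [1.0]]))
        fit_far = _fit([0.0], -30.0, sigma2=1.0)  # mu far below the LOD
        unc_term = (1.0 - (-30.0)) ** 2
        assert loss_gaussian(fit_far, test) == pytest.approx(unc_term, rel=1e-9)

    def test_gaussian_loss_requires_uncensored_rows(self):
        test = validate(CensoredDataset([0.0, 0.0], [0, 0], [0.0, 0.0],
                                        [[0.0], [1.0]]))
        with pytest.raises(ValueError, match="no uncensored"):
            loss_gaussian(_fit([0.0], 0.0, sigma2=1.0), test)

    def test_gaussian_loss_nonnegative(self, rng):
        for _ in range(20):
            ds, _, _ = make_censored(censor_frac=0.4,
                                     seed=int(rng.integers(1e6)))
            fit = _fit(rng.normal(size=ds.p), rng.normal(), sigma2=1.5)
            assert loss_gaussian(fit, ds) >= 0


class TestCVSelect:
    def test_determinism(self):
        ds, _, _ = make_censored(n=50, p=5, censor_frac=0.4, seed=0)
        a = cv_select_lambda(ds, "lod", "imputed_sq", K=5, seed=3, n_lambda=12)
        b = cv_select_lambda(ds, "lod", "imputed_sq", K=5, seed=3, n_lambda=12)
        assert a.lambda_opt == b.lambda_opt
        np.testing.assert_array_equal(a.cv_mean, b.cv_mean)
        np.testing.assert_array_equal(a.fold_assignment, b.fold_assignment)

    def test_lod_on_uncensored_equals_standard_lasso_cv(self):
        """With nothing censored the whole pipeline is ordinary Lasso CV."""
        ds, _, _ = make_censored(n=40, p=4, censor_frac=0.0, lod=-100, seed=1)
        cv = cv_select_lambda(ds, "lod", "imputed_sq", K=4, seed=2, n_lambda=8)
        # reconstruct by hand with the same folds and grid
        for k in range(4):
            learn = ds.subset(cv.fold_assignment != k)
            test = ds.subset(cv.fold_assignment == k)
            for j, lam in enumerate(cv.lambdas):
                fit = lasso_fit(learn.X, learn.z, lam)
                mse = float(np.mean((test.z - fit.predict(test.X)) ** 2))
                assert cv.fold_losses[k, j] == pytest.approx(mse, rel=1e-4,
                                                             abs=1e-6)

    def test_cv_at_lambda_max_is_intercept_only_loss(self):
        ds, _, _ = make_censored(n=60, p=6, censor_frac=0.0, lod=-100, seed=2)
        cv = cv_select_lambda(ds, "lod", "imputed_sq", K=5, seed=0, n_lambda=5)
        by_hand = []
        for k in range(5):
            learn = ds.subset(cv.fold_assignment != k)
            test = ds.subset(cv.fold_assignment == k)
            by_hand.append(np.mean((test.z - learn.z.mean()) ** 2))
        assert cv.cv_mean[0] == pytest.approx(np.mean(by_hand), rel=1e-9)

    def test_learning_fits_never_see_test_rows(self):
        """Canary: perturbing held-out responses leaves the learning-fold
        fit bit-identical, and fold membership depends only on delta."""
        from bjlasso.buckley_james import BJOptions
        from bjlasso.model_selection import _fit_method

        ds, _, _ = make_censored(n=50, p=4, censor_frac=0.3, seed=4)
        assign = stratified_kfold(ds.delta, 5, seed=9)
        z2 = ds.z.copy()
        held = (assign == 0) & (ds.delta == 1)
        z2[held] += 0.37  # move only held-out uncensored rows
        ds2 = validate(CensoredDataset(z2, ds.delta, ds.lod, ds.X, ds.names))
        np.testing.assert_array_equal(assign, stratified_kfold(ds2.delta, 5, 9))
        learn1 = ds.subset(assign != 0)
        learn2 = ds2.subset(assign != 0)
        f1 = _fit_method("gaussbj", learn1, 2.0, BJOptions(), None, None)
        f2 = _fit_method("gaussbj", learn2, 2.0, BJOptions(), None, None)
        np.testing.assert_array_equal(f1.beta, f2.beta)
        assert f1.intercept == f2.intercept and f1.sigma2 == f2.sigma2

    def test_selected_lambda_is_first_minimizer(self):
        ds, _, _ = make_censored(n=40, p=3, censor_frac=0.2, seed=6)
        cv = cv_select_lambda(ds, "lod2", "imputed_sq", K=4, seed=1, n_lambda=10)
        i = int(np.argmin(cv.cv_mean))
        assert cv.lambda_opt == cv.lambdas[i]
        assert cv.cv_mean[i] == cv.cv_mean.min()

    @pytest.mark.parametrize("method,loss", [
        ("gaussbj", "gaussian"), ("gaussbj_1step", "imputed_sq"),
        ("nonparbj", "imputed_sq"), ("lod", "gaussian"),
    ])
    def test_all_method_loss_combinations_run(self, method, loss):
        ds, _, _ = make_censored(n=40, p=4, censor_frac=0.4, seed=8)
        cv = cv_select_lambda(ds, method, loss, K=3, seed=5, n_lambda=5)
        assert cv.lambdas[0] >= cv.lambda_opt >= cv.lambdas[-1]
        assert np.all(np.isfinite(cv.cv_mean))
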