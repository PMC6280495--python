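"""Truncated-Gaussian moments and Kaplan-Meier conditional means.

The Gaussian oracle is high-precision numerical quadrature of the
truncated-mean integral (mpmath, 40 digits), entirely independent of the
closed-form inverse-Mills implementation.  The KM oracle is a hand-written
sequential product-limit computation, independent of the package's
vectorized estimator.
"""

import itertools

import mpmath
import numpy as np
import pytest

from bjlasso import (
    CensoredDataset,
    gaussian_conditional_mean,
    gaussian_conditional_var,
    impute_responses_gaussian,
    km_conditional_mean,
    km_fit,
    validate,
)

mpmath.mp.dps = 40


def truncated_moment_oracle(mu, sigma, c, order):
    """E(Y^order | Y <= c) by high-precision quadrature, standardized scale."""
    a = (c - mu) / sigma
    phi = lambda t: mpmath.exp(-t * t / 2) / mpmath.sqrt(2 * mpmath.pi)
    Phi_a = mpmath.ncdf(a)
    num = mpmath.quad(lambda t: (mu + sigma * t) ** order * phi(t),
                      [-mpmath.inf, min(a, 0), a] if a > 0 else [-mpmath.inf, a])
    return float(num / Phi_a)


GRID = [(0.0, 1.0, a) for a in np.linspace(-8, 8, 17)] + [
    (2.0, 1.0, 0.0),   # a = -2
    (0.0, 2.0, 0.0),
    (-3.0, 0.5, -4.0),
    (12.0, 0.9, 1.0),  # deep tail, viral-load-like scale
]


class TestGaussianConditionalMean:
    @pytest.mark.parametrize("mu,sigma,c", GRID)
    def test_matches_quadrature_oracle(self, mu, sigma, c):
        expected = truncated_moment_oracle(mu, sigma, c, 1)
        assert gaussian_conditional_mean(mu, sigma, c) == pytest.approx(
            expected, abs=1e-8
        )

    def test_known_values(self):
        # at c = mu the mean is mu - sigma*phi(0)/Phi(0) = mu - sigma*sqrt(2/pi)
        assert gaussian_conditional_mean(0, 1, 0) == pytest.approx(
            -0.7978845608, abs=1e-9
        )
        assert gaussian_conditional_mean(2, 1, 0) == pytest.approx(-0.373, abs=1e-3)

    def test_far_upper_tail_reduces_to_mu(self):
        assert abs(gaussian_conditional_mean(0, 1, 10)) < 1e-20

    def test_strictly_below_threshold_and_increasing_in_mu(self):
        mus = np.linspace(-5, 5, 41)
        vals = np.array([gaussian_conditional_mean(m, 1.3, 0.7) for m in mus])
        assert np.all(vals < 0.7)
        assert np.all(np.diff(vals) > 0)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            gaussian_conditional_mean(0, 0, 1)
        with pytest.raises(ValueError):
            gaussian_conditional_mean(np.nan, 1, 1)


class TestGaussianConditionalVar:
    @pytest.mark.parametrize("mu,sigma,c", GRID)
    def test_matches_quadrature_oracle(self, mu, sigma, c):
        m1 = truncated_moment_oracle(mu, sigma, c, 1)
        m2 = truncated_moment_oracle(mu, sigma, c, 2)
        assert gaussian_conditional_var(mu, sigma, c) == pytest.approx(
            m2 - m1**2, abs=1e-8
        )

    def test_at_threshold_equals_one_minus_two_over_pi(self):
        assert gaussian_conditional_var(0, 1, 0) == pytest.approx(
            1 - 2 / np.pi, abs=1e-9
        )

    def test_scale_equivariance(self):
        assert gaussian_conditional_var(0, 2, 0) == pytest.approx(
            4 * gaussian_conditional_var(0, 1, 0), rel=1e-12
        )

    def test_no_truncation_limit_and_bounds(self):
        assert gaussian_conditional_var(0, 1, 50) == pytest.approx(1.0, abs=1e-12)
        for c in np.linspace(-8, 8, 33):
            v = gaussian_conditional_var(0.3, 1.7, c)
            assert 0 < v <= 1.7**2 + 1e-12


def km_oracle(values, events):
    """Sequential hand product-limit: returns {event time: jump mass}."""
    pairs = sorted(zip(values, events), key=lambda ve: (ve[0], -ve[1]))
    n = len(pairs)
    s_prev = 1.0
    jumps = {}
    for i, (v, e) in enumerate(pairs):
        at_risk = n - i
        if e:
            s_now = s_prev * (1 - 1 / at_risk)
            jumps[v] = jumps.get(v, 0.0) + (s_prev - s_now)
            s_prev = s_now
    return jumps


class TestKMFit:
    def test_hand_example_with_censoring(self):
        curve = km_fit([1, 2, 3], [1, 0, 1])
        np.testing.assert_allclose(curve.times, [1, 3])
        np.testing.assert_allclose(curve.surv, [2 / 3, 0.0])
        np.testing.assert_allclose(curve.jumps, [1 / 3, 2 / 3])

    def test_all_events_gives_empirical_distribution(self):
        curve = km_fit([4.0, 1.0, 3.0, 2.0], [1, 1, 1, 1])
        np.testing.assert_allclose(curve.jumps, [0.25] * 4)
        assert np.sum(curve.jumps * curve.times) == pytest.approx(2.5)

    def test_tail_correction_on_censored_maximum(self):
        curve = km_fit([1, 2], [1, 0])
        np.testing.assert_allclose(curve.jumps, [0.5, 0.5])
        assert curve.jumps.sum() == pytest.approx(1.0)

    def test_matches_hand_oracle_on_random_samples(self, rng):
        for _ in range(300):
            n = int(rng.integers(1, 10))
            v = rng.integers(-3, 4, n).astype(float) / 2
            e = rng.integers(0, 2, n)
            if e.sum() == 0:
                continue
            curve = km_fit(v, e, tail_correction=False)
            oracle = km_oracle(v, e)
            assert len(curve.times) == len(oracle)
            for t, j in zip(curve.times, curve.jumps):
                assert j == pytest.approx(oracle[t], abs=1e-12)

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        v = rng.standard_normal(60)
        e = rng.integers(0, 2, 60)
        curve = km_fit(v, e, tail_correction=False)
        sf = KaplanMeierFitter().fit(v, event_observed=e).survival_function_
        for t, s in zip(curve.times, curve.surv):
            assert sf.iloc[:, 0].loc[t] == pytest.approx(s, abs=1e-12)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match="empty"):
            km_fit([], [])
        with pytest.raises(ValueError, match="censored"):
            km_fit([1.0, 2.0], [0, 0], tail_correction=False)


class TestKMConditionalMean:
    def test_hand_example(self):
        curve = km_fit([1, 2, 3], [1, 0, 1])
        assert km_conditional_mean(curve, 2) == pytest.approx(3.0)

    def test_no_conditioning_recovers_sample_mean(self):
        curve = km_fit([1.0, 2.0, 5.0], [1, 1, 1])
        assert km_conditional_mean(curve, 0.0) == pytest.approx(8 / 3)

    def test_errors_above_support(self):
        curve = km_fit([1.0, 2.0], [1, 1])
        with pytest.raises(ValueError, match="no support"):
            km_conditional_mean(curve, 2.0)

    def test_exhaustive_small_samples(self):
        """Brute-force check over all event patterns for n <= 6."""
        values = [0.5, 1.0, 1.5, 2.0, 2.5, 3.0]
        for n in range(2, 7):
            v = np.array(values[:n])
            for pattern in itertools.product([0, 1], repeat=n):
                if sum(pattern) == 0:
                    continue
                e = np.array(pattern)
                curve = km_fit(v, e)  # tail-corrected: jumps sum to 1
                oracle = km_oracle(v, np.where(v == v.max(), 1, e))
                for c in np.arange(0.0, 3.5, 0.25):
                    mass = sum(j for t, j in oracle.items() if t > c)
                    if mass <= 0:
                        with pytest.raises(ValueError):
                            km_conditional_mean(curve, c)
                        continue
                    expected = (
                        sum(t * j for t, j in oracle.items() if t > c) / mass
                    )
                    got = km_conditional_mean(curve, c)
                    assert got == pytest.approx(expected, abs=1e-10)
                    assert got > c


class TestImputeResponses:
    def _ds(self):
        z = np.array([2.0, 1.0, 3.0, 1.0])
        delta = np.array([1, 0, 1, 0])
        lod = np.ones(4)
        X = np.arange(8.0).reshape(4, 2)
        return validate(CensoredDataset(z, delta, lod, X))

    def test_identity_on_uncensored(self, small_censored):
        ds = small_censored
        full = validate(
            CensoredDataset(ds.z + 10, np.ones(ds.n, int), ds.lod, ds.X)
        )
        out = impute_responses_gaussian(full, np.zeros(ds.p), 0.0, 1.0)
        np.testing.assert_array_equal(out, full.z)

    def test_censored_at_linear_predictor_equal_lod(self):
        ds = self._ds()
        # choose beta=0 and intercept = lod so mu = lod on censored rows
        out = impute_responses_gaussian(ds, np.zeros(2), 1.0, 1.0)
        assert out[1] == pytest.approx(1.0 - 0.7978845608, abs=1e-9)

    def test_imputations_lie_below_observed_placeholder(self, rng):
        ds = self._ds()
        out = impute_responses_gaussian(ds, rng.normal(size=2), 0.3, 2.0)
        assert np.all(out <= ds.z)
        assert np.all(out[ds.censored] < ds.lod[ds.censored])
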