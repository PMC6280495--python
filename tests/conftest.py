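import numpy as np
import pytest

from bjlasso import CensoredDataset, validate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_censored(n=40, p=5, censor_frac=0.4, lod=0.0, seed=0):
    """Small left-censored Gaussian dataset with censoring at a fixed LOD."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    beta = np.zeros(p)
    beta[: min(2, p)] = 1.0
    y = X @ beta + rng.standard_normal(n)
    lod_val = float(np.quantile(y, censor_frac)) if censor_frac > 0 else lod
    delta = (y > lod_val).astype(int)
    z = np.maximum(y, lod_val)
    return validate(
        CensoredDataset(z, delta, np.full(n, lod_val), X)
    ), y, beta


@pytest.fixture
def small_censored():
    ds, y, beta = make_censored()
    return ds
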