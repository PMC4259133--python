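import numpy as np
import pytest

from harmcox import SurvivalDataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture
def small_data(rng):
    """Random n=10, p=3 dataset with a mix of events and censorings."""
    n, p = 10, 3
    X = rng.standard_normal((n, p))
    time = rng.exponential(size=n) + 0.05
    event = rng.integers(0, 2, size=n)
    event[0] = 1
    return SurvivalDataset(X, time, event)


@pytest.fixture
def medium_data(rng):
    """n=50, p=2 dataset with real signal, for reference-fit comparisons."""
    n, p = 50, 2
    X = rng.standard_normal((n, p))
    lp = X @ np.array([1.0, -0.5])
    time = rng.exponential(scale=np.exp(-lp)) + 1e-3
    cens = rng.exponential(scale=2.0, size=n)
    event = (time <= cens).astype(int)
    obs = np.minimum(time, cens)
    return SurvivalDataset(X, obs, event)


def brute_partial_loglik(data, beta):
    """Straight-line evaluation of the partial likelihood (independent oracle)."""
    beta = np.asarray(beta, float)
    eta = data.X @ beta
    total = 0.0
    for i in range(data.n):
        if data.event[i] == 1:
            risk = [j for j in range(data.n) if data.time[j] >= data.time[i]]
            total += eta[i] - np.log(np.sum(np.exp(eta[risk])))
    return total
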