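import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20160701)


@pytest.fixture
def logistic_data(rng):
    """Medium logistic dataset with a genotype-like exposure and 8 clusters."""
    n = 600
    X = np.column_stack([rng.binomial(2, 0.4, n).astype(float),
                         rng.standard_normal(n)])
    eta = -0.3 + 0.4 * X[:, 0] - 0.2 * X[:, 1]
    y = rng.binomial(1, 1.0 / (1.0 + np.exp(-eta))).astype(float)
    clusters = rng.integers(0, 8, n)
    return X, y, clusters


@pytest.fixture
def survival_data(rng):
    """Left-truncated Weibull survival data on the age timescale."""
    n = 3000
    entry = np.clip(rng.normal(65.0, 8.0, n), 40.0, 90.0)
    X = np.column_stack([rng.binomial(2, 0.4, n).astype(float),
                         rng.standard_normal(n)])
    beta = np.array([0.3, -0.2])
    lam, k = 30.0, 1.2
    w = np.exp(X @ beta)
    e = rng.exponential(size=n)
    death = lam * ((entry / lam) ** k + e / w) ** (1.0 / k)
    censor = entry + 8.0
    exit = np.minimum(death, censor)
    event = (death <= censor).astype(int)
    return X, entry, exit, event, beta
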