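import numpy as np
import pytest

from esmdr.survival import SurvivalData


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


def random_survival(rng, n=60, p_cov=0, censor=0.4):
    """Small random right-censored dataset (exponential events, uniform
    censoring), optionally with covariates."""
    X = rng.normal(size=(n, p_cov)) if p_cov else None
    eta = X @ rng.normal(0.4, 0.2, p_cov) if p_cov else np.zeros(n)
    T = rng.exponential(1.0) * rng.exponential(1.0, n) / np.exp(eta)
    C = rng.uniform(0, np.quantile(T, 1 - censor) * 2, n)
    time = np.minimum(T, C)
    status = (T <= C).astype(int)
    if status.sum() == 0:
        status[np.argmin(time)] = 1
    return SurvivalData(time, status, X)


@pytest.fixture
def cox_dataset(rng):
    """500 subjects, one binary and one continuous covariate, ~40% censored;
    shared by the cross-library agreement tests."""
    n = 500
    X = np.column_stack([rng.integers(0, 2, n), rng.normal(0, 1, n)])
    T = rng.exponential(2 * np.exp(-0.5 * X[:, 0] + 0.3 * X[:, 1]))
    C = rng.uniform(0, 4, n)
    return SurvivalData(np.minimum(T, C), (T <= C).astype(int), X)
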