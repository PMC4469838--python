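import numpy as np
import pytest

from coxtp.data import SurvivalDataset


@pytest.fixture(scope="session")
def tiny_dataset() -> SurvivalDataset:
    """Fixed 6-patient, 2-gene dataset with one censored patient.

    Used as the hand-enumeration regression fixture throughout the suite.
    """
    return SurvivalDataset(
        times=np.array([2.0, 5.0, 1.0, 4.0, 3.0, 6.0]),
        events=np.array([1, 1, 1, 0, 1, 1]),
        expression=np.array([
            [0.5, -1.2],
            [1.0, 0.3],
            [-0.7, 0.8],
            [0.2, -0.5],
            [-1.5, 0.9],
            [0.4, 0.1],
        ]),
    )


def random_dataset(seed: int, n: int = 30, p: int = 4,
                   censor_frac: float = 0.2,
                   signal: float = 0.0) -> SurvivalDataset:
    """Small random survival dataset with optional planted signal."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    eta = signal * X[:, 0] if signal else np.zeros(n)
    t = -np.log(rng.uniform(size=n)) / np.exp(eta)
    events = (rng.uniform(size=n) > censor_frac).astype(int)
    if events.sum() == 0:
        events[rng.integers(n)] = 1
    return SurvivalDataset(times=t, events=events, expression=X)


@pytest.fixture
def make_dataset():
    return random_dataset


def enum_partial_loglik(beta, data: SurvivalDataset) -> float:
    """Independent Breslow partial log-likelihood by direct risk-set sums."""
    beta = np.asarray(beta, dtype=float)
    ll = 0.0
    for i in range(data.n):
        if data.events[i] == 1:
            risk = [r for r in range(data.n) if data.times[r] >= data.times[i]]
            ll += float(data.expression[i] @ beta) - np.log(
                sum(np.exp(float(data.expression[r] @ beta)) for r in risk))
    return ll
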