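import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import impcox as ic

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def _make_survival(n, p, beta=None, seed=0, censor_scale=2.0, ties=False):
    """Small ad-hoc survival dataset, independent of the synthetic module."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    eta = X @ (np.asarray(beta, dtype=float) if beta is not None else np.zeros(p))
    T = rng.exponential(1.0, n) / np.exp(eta)
    if censor_scale:
        C = rng.exponential(censor_scale, n)
        time, event = np.minimum(T, C), (T <= C).astype(int)
    else:
        time, event = T, np.ones(n, dtype=int)
    if ties:
        time = np.maximum(np.round(time, 1), 0.1)
    if event.sum() == 0:
        event[np.argmin(time)] = 1
    return ic.SurvivalDataset(X, time, event, [f"G{i}" for i in range(p)])


def _naive_nlpl(beta, X, time, event):
    """Term-by-term negative Breslow log partial likelihood (oracle)."""
    eta = np.asarray(X) @ np.asarray(beta, dtype=float)
    total = 0.0
    for k in np.flatnonzero(np.asarray(event) == 1):
        risk = np.asarray(time) >= time[k]
        total -= eta[k] - np.log(np.exp(eta[risk]).sum())
    return total


@pytest.fixture
def make_survival():
    return _make_survival


@pytest.fixture
def naive_nlpl():
    return _naive_nlpl
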