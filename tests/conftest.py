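"""Shared fixtures and small synthetic survival instances."""

from __future__ import annotations

import numpy as np
import pytest

from coopernet.cox_core import CauseView


def random_survival(rng: np.random.Generator, n: int, p: int,
                    beta: np.ndarray | None = None,
                    baseline: float = 0.2,
                    censor_rate: float = 0.15) -> tuple[CauseView, np.ndarray]:
    """Single-cause right-censored instance with exponential latent times."""
    X = rng.standard_normal((n, p))
    if beta is None:
        beta = np.zeros(p)
        beta[: min(3, p)] = [1.0, -0.8, 0.5][: min(3, p)]
    t_lat = -np.log(rng.uniform(size=n)) / (baseline * np.exp(X @ beta))
    c = -np.log(rng.uniform(size=n)) / censor_rate
    time = np.minimum(t_lat, c)
    delta = (t_lat <= c).astype(float)
    return CauseView(time=time, delta=delta), X


def brute_force_nll(beta: np.ndarray, view: CauseView, X: np.ndarray) -> float:
    """Direct product-form evaluation of the Breslow partial likelihood."""
    eta = X @ beta
    total = 0.0
    for i in range(len(view.time)):
        if view.delta[i] == 1.0:
            risk = view.time >= view.time[i]
            m = eta[risk].max()
            total -= eta[i] - (m + np.log(np.sum(np.exp(eta[risk] - m))))
    return total


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_view(rng):
    return random_survival(rng, 60, 5)
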