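"""Shared fixtures: small random survival datasets and simulated cohorts."""

import numpy as np
import pytest

from sigcombine import SurvivalData


def make_survival(rng, n, X=None, beta=None, h0=0.05, c_max=40.0):
    """Random right-censored cohort from an exponential-baseline PH model."""
    if X is None:
        X = np.zeros((n, 1))
    lp = X @ beta if beta is not None else np.zeros(n)
    event_time = rng.exponential(1.0 / (h0 * np.exp(lp)))
    censor_time = rng.uniform(0.0, c_max, size=n)
    time = np.maximum(np.minimum(event_time, censor_time), 1e-6)
    event = (event_time <= censor_time).astype(int)
    return SurvivalData([f"s{i}" for i in range(n)], time, event)


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)


@pytest.fixture
def small_cohort(rng):
    """30 subjects, 2 covariates, moderate signal, untied times."""
    X = rng.standard_normal((30, 2))
    surv = make_survival(rng, 30, X, np.array([0.6, -0.4]))
    return X, surv
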