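"""Shared fixtures and analytic helpers for the test suite."""

import numpy as np
import pytest

from prospectfit.model import (
    Gamble,
    PTParams,
    gamble_menu,
    predicted_ce,
    w_lattimore,
)


def analytic_ce(gamble: Gamble, params: PTParams) -> float:
    """Closed-form CE magnitude of a deterministic prospect-theory agent."""
    w = params.weight(gamble.p_float)
    return predicted_ce(gamble, params.alpha, w)


def lattimore_ce_table(alpha: float, delta: float, gamma: float, domain="gain"):
    """Noiseless 10-gamble CE table (magnitudes) of a Lattimore agent."""
    out = {}
    for g in gamble_menu(domain):
        w = w_lattimore(g.p_float, delta, gamma)
        out[g.index] = predicted_ce(g, alpha, w)
    return out


# parameter grid used for staircase accuracy and identifiability checks
PARAM_GRID = [
    PTParams(alpha=a, delta=d, gamma=c)
    for a in (0.5, 0.8, 1.0, 1.3)
    for d in (0.5, 1.0, 1.5)
    for c in (0.4, 0.7, 1.0)
]


@pytest.fixture
def gain_menu():
    return gamble_menu("gain")


@pytest.fixture
def loss_menu():
    return gamble_menu("loss")


@pytest.fixture
def ev_agent():
    """Deterministic risk-neutral agent (alpha = delta = gamma = 1)."""
    from prospectfit.cohort import make_choice_model

    return make_choice_model(PTParams(), temperature=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
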