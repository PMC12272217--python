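"""Shared fixtures: small synthetic sessions generated at test time."""

import numpy as np
import pytest

import periflick as pf
from periflick.synth import Condition


@pytest.fixture(scope="session")
def small_config() -> pf.SimConfig:
    """A reduced session (one strong condition, 20 trials) for fast tests."""
    return pf.SimConfig(
        n_trials_per_condition=20,
        conditions=(Condition("control", 0.70, response_gain=1.0),),
        inter_trial_gap=0.5,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_session(small_config):
    return pf.simulate_session(small_config)


@pytest.fixture(scope="session")
def small_epochs(small_session):
    rec, _ = small_session
    epochs, report = pf.preprocess(rec)
    return epochs


@pytest.fixture(scope="session")
def small_filters(small_config, small_epochs):
    return pf.fit_session_filters(small_epochs, small_config.tag_freqs)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
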