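"""Shared fixtures: small synthetic sessions and kinematic bundles.

Everything is generated programmatically with fixed seeds; module-scoped
fixtures keep the more expensive simulations shared across tests.
"""

import numpy as np
import pytest

import whisktask.synthetic as syn


@pytest.fixture(scope="session")
def base_session():
    """A 30-trial initial-rule session from a mid-learning learner."""
    return syn.generate_session_events("initial", syn.LearnerParams(), 30, seed=5)


@pytest.fixture(scope="session")
def bundle(base_session):
    """Whisker + position kinematics for the base session."""
    w = syn.generate_whisker_trace(base_session, 14.5, 15.0, seed=5)
    p = syn.generate_position_trace(base_session, 200.0, seed=5)
    return syn.KinematicBundle(whisker=w, position=p)


@pytest.fixture(scope="session")
def long_session():
    """~600 s session used for phase/place recovery runs."""
    return syn.generate_session_events("initial", syn.LearnerParams(), 58, seed=21)


@pytest.fixture(scope="session")
def long_bundle(long_session):
    w = syn.generate_whisker_trace(long_session, 14.5, 15.0, seed=21)
    p = syn.generate_position_trace(long_session, 200.0, seed=21)
    return syn.KinematicBundle(whisker=w, position=p)


def make_unit(session, bundle, spec, seed, **kw):
    return syn.generate_spike_trains(session, bundle, [spec], seed=seed, **kw)[0]


@pytest.fixture(scope="session")
def untuned_unit(base_session, bundle):
    return make_unit(base_session, bundle, syn.TuningSpec(baseline_rate=10.0), seed=42)
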