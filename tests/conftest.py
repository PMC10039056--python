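"""Shared fixtures: synthetic sessions generated once per test run."""

import numpy as np
import pytest

import sleepscape as ss
from sleepscape.simulate import SimConfig, simulate_state_sequence, simulate_ephys


@pytest.fixture(scope="session")
def default_session():
    """Full default-configuration session (ephys + BOLD + truth), seed 1."""
    cfg = SimConfig(seed=1)
    bundle, truth = ss.simulate_session(cfg)
    return cfg, bundle, truth


@pytest.fixture(scope="session")
def event_session():
    """Ephys-only session rich in events, used by the detector tests."""
    cfg = SimConfig(seed=7, total_duration=1200, n_ecog=2)
    rng = np.random.default_rng(7)
    hyp = simulate_state_sequence(cfg, rng)
    rec, events = simulate_ephys(hyp, cfg, rng)
    return cfg, hyp, rec, events


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_hypnogram(pattern):
    """Hypnogram from a compact [(state, dur_s), ...] spec."""
    epochs, t = [], 0.0
    for state, dur in pattern:
        epochs.append((state, t, t + dur))
        t += dur
    return ss.Hypnogram(epochs)
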