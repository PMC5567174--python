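import numpy as np
import pytest

from flexitorque import (
    ProtocolConfig,
    calibrate_connatural,
    make_subject,
    simulate_isokinetic_trial,
    simulate_passive_trial,
)

QUIET = dict(noise_torque_sd=0.0, noise_circ_sd=0.0, drift_amp=0.0)


@pytest.fixture
def subject():
    return make_subject(11)


@pytest.fixture
def quiet_subject():
    """A subject with no measurement noise and no sensor drift."""
    return make_subject(11, overrides=QUIET)


@pytest.fixture
def isokinetic_protocol():
    return ProtocolConfig("isokinetic", velocity=90.0, seed=21)


@pytest.fixture
def passive_protocol():
    return ProtocolConfig("passive", velocity=90.0, n_cycles=2, seed=22)


@pytest.fixture
def quiet_profile(quiet_subject, passive_protocol):
    trial = simulate_passive_trial(quiet_subject, passive_protocol)
    return calibrate_connatural([trial])


@pytest.fixture
def quiet_trial(quiet_subject, isokinetic_protocol):
    return simulate_isokinetic_trial(quiet_subject, isokinetic_protocol)


def make_quiet(seed=11, **extra):
    overrides = dict(QUIET)
    overrides.update(extra)
    return make_subject(seed, overrides=overrides)
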