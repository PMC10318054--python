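import numpy as np
import pytest

from pwavekit.synth import SimConfig, simulate_session


@pytest.fixture(scope="session")
def default_session():
    """One full-length (2 h) synthetic session with brief laser pulses.

    Shared across the round-trip tests; nothing mutates it.
    """
    cfg = SimConfig(duration_s=7200.0, seed=7, laser_mode="brief_pulse")
    rec, gt = simulate_session(cfg)
    return cfg, rec, gt


@pytest.fixture(scope="session")
def short_session():
    """A 30 min session without laser, for cheaper checks."""
    cfg = SimConfig(duration_s=1800.0, seed=1)
    rec, gt = simulate_session(cfg)
    return cfg, rec, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
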