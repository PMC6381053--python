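import numpy as np
import pytest

from ecogmap import PipelineConfig, SimConfig, generate_session
from ecogmap.pipeline import run_offline


@pytest.fixture(scope="session")
def default_session():
    """The standard desk-scale fixture: 16 ch, 1 kHz, 30 trials, 3 modulated
    channels, 3x high-gamma burst 0.2-0.8 s post onset."""
    return generate_session(SimConfig(seed=11))


@pytest.fixture(scope="session")
def default_run(default_session):
    """Offline pipeline output on the default fixture (truth-scored config:
    no re-referencing, so channel-level ground truth applies directly)."""
    return run_offline(default_session, PipelineConfig(car="off"))


@pytest.fixture(scope="session")
def small_session():
    """A shorter, narrower session for streaming/replay tests."""
    cfg = SimConfig(n_channels=8, n_trials=6, modulated_channels=(0, 2), seed=7)
    return generate_session(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
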