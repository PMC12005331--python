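import numpy as np
import pandas as pd
import pytest

from riftpipe.config import SimulationConfig
from riftpipe.containers import EpochSet
from riftpipe.layout import ChannelLayout
from riftpipe import synthgen


@pytest.fixture(scope="session")
def layout():
    return ChannelLayout()


@pytest.fixture(scope="session")
def posterior_channels(layout):
    return layout.posterior_channels()


@pytest.fixture(scope="session")
def small_config():
    """Light pre-cue configuration used by most integration-style tests."""
    return SimulationConfig.for_experiment(
        "pre-cue",
        n_participants=2,
        n_trials=32,
        block_size=8,
        tag_amplitude=0.8,
        noise_scale=10.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def noiseless_config():
    """Deterministic signal-only generator: no noise, no artifacts, no jitter."""
    return SimulationConfig.for_experiment(
        "pre-cue",
        n_participants=1,
        n_trials=8,
        block_size=8,
        tag_amplitude=1.0,
        tag_high_rel_amplitude=1.0,
        attention_gain=1.0,
        noise_scale=0.0,
        line_noise_amplitude=0.0,
        alpha_amplitude=0.0,
        artifact_prob=0.0,
        blink_rate=0.0,
        fixation_break_prob=0.0,
        gaze_noise_dva=0.0,
        gaze_drift_dva=0.0,
        offtime_prob=0.0,
        seed=3,
    )


@pytest.fixture(scope="session")
def small_participant(small_config, posterior_channels):
    """One simulated participant restricted to posterior channels."""
    return synthgen.simulate_participant(small_config, 0, channels=posterior_channels)


def make_epochs(data: np.ndarray, fs: float, channels, t0: float = 0.0, experiment: str = "pre-cue"):
    """Wrap a raw (trials, channels, time) array into an EpochSet."""
    n_tr, n_ch, n_t = data.shape
    times = np.arange(n_t) / fs + t0
    meta = pd.DataFrame({"trial_id": np.arange(n_tr), "participant_id": 0})
    return EpochSet(
        data=np.asarray(data, dtype=np.float32),
        times=times,
        fs=fs,
        channels=list(channels),
        meta=meta,
        experiment=experiment,
    )
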