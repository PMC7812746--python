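import numpy as np
import pytest

from cerecoh.containers import TrialTensor
from cerecoh.preprocess import segment_trials
from cerecoh.synthetic import SurrogateSpec, gen_coupled_lfp


@pytest.fixture(scope="session")
def coupled_spec():
    """Small two-area surrogate: 0.5 coupling in the 30-50 Hz band."""
    return SurrogateSpec(
        n_channels_per_area=2,
        sampling_rate=500.0,
        n_trials=80,
        trial_length=2.0,
        shared_band=(30.0, 50.0),
        shared_fraction=0.5,
        onset_offset=0.5,
        background_noise_amp=0.2,
        seed=1234,
    )


@pytest.fixture(scope="session")
def coupled_trials(coupled_spec):
    rec, events = gen_coupled_lfp(coupled_spec)
    return segment_trials(rec, events, (0.5, 1.5))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def sine_tensor():
    """Three trials of a pure 40 Hz unit sinusoid on one channel."""
    fs = 500.0
    t = np.arange(int(2.0 * fs)) / fs
    x = np.sin(2 * np.pi * 40.0 * t)
    data = np.tile(x, (3, 1, 1))
    return TrialTensor(data, fs, (0.5, 1.5))
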