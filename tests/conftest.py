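import numpy as np
import pytest

from entrainlock.montage import make_montage
from entrainlock.protocol import (StimProtocol, epoch_n_samples,
                                  pulse_sample_indices)
from entrainlock.synth import TrialSet


@pytest.fixture(scope="session")
def montage63():
    return make_montage()


def build_trialset(montage, data, fs_hz, protocol, channels=None,
                   pulse_samples=None):
    """Assemble a TrialSet around explicit data (unit-test plumbing)."""
    n_trials = data.shape[0]
    if pulse_samples is None:
        pulse_samples = np.tile(pulse_sample_indices(protocol, fs_hz),
                                (n_trials, 1))
    if channels is None:
        channels = list(montage.labels)[: data.shape[1]]
    return TrialSet(data=data, fs_hz=fs_hz, montage=montage,
                    channels=channels, pulse_samples=pulse_samples,
                    protocol=protocol)


@pytest.fixture
def small_protocol():
    return StimProtocol(site="visual", n_pulses=5, train_freq_hz=11.0,
                        n_trials=4, epoch_pre_s=2.0, epoch_post_s=3.0)


@pytest.fixture
def tiny_trialset(montage63, small_protocol):
    """4 trials x 8 channels of seeded noise at 500 Hz (plus earlobes)."""
    fs = 500.0
    rng = np.random.default_rng(42)
    n = epoch_n_samples(small_protocol, fs)
    chans = ["C3", "Cz", "Oz", "O2", "POz", "Fz", "A1", "A2"]
    data = rng.normal(0, 5.0, size=(small_protocol.n_trials, len(chans), n))
    return build_trialset(montage63, data, fs, small_protocol,
                          channels=chans)
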