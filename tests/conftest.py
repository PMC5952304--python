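import numpy as np
import pytest
from hypothesis import settings

from ictal import (DetectionProfile, SeizureSpec, SimConfig, compute_baseline,
                   generate_eeg)

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def quiet_record():
    """10 min of event-free synthetic background EEG."""
    record, truth = generate_eeg(SimConfig(duration=600.0, seed=101))
    return record, truth


@pytest.fixture(scope="session")
def srs_record():
    """A short chronic-style recording with one compliant seizure."""
    spec = SeizureSpec(onset=320.0, plateau_duration=33.0)
    config = SimConfig(duration=500.0, seed=202, seizure_specs=(spec,))
    record, truth = generate_eeg(config)
    return record, truth, config


@pytest.fixture(scope="session")
def chronic_profile():
    return DetectionProfile.chronic()


@pytest.fixture(scope="session")
def srs_baseline(srs_record):
    record, _, _ = srs_record
    return compute_baseline(record, (0.0, 300.0))


def make_sine_record(freq, amplitude, duration=10.0, fs=500.0):
    t = np.arange(int(duration * fs)) / fs
    from ictal import EEGRecord
    return EEGRecord(amplitude * np.sin(2 * np.pi * freq * t), fs)
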