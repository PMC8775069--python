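import numpy as np
import pytest

from eegsep.preprocessing import EEGRecording, MONTAGE_19
from eegsep.synthetic import CohortSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_spec():
    """Small cohort spec used by fast unit tests."""
    return CohortSpec(n_subjects_per_class=2, epochs_per_subject=6,
                      effect_size=2.0, seed=7)


@pytest.fixture
def sine_recording():
    """10 Hz sinusoid on 19 channels at 256 Hz, 8 s."""
    fs = 256.0
    t = np.arange(int(8 * fs)) / fs
    data = np.tile(np.sin(2 * np.pi * 10.0 * t), (19, 1))
    return EEGRecording(data, fs, MONTAGE_19)


@pytest.fixture
def random_epochs(rng):
    """(20, 19, 512) random epoch block."""
    return rng.standard_normal((20, 19, 512))
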