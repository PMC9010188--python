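import numpy as np
import pytest

from eegaffect import synthio
from eegaffect.core import RawRecording
from eegaffect.features import DETensor


@pytest.fixture(scope="session")
def channel_names():
    from eegaffect.io import canonical_channel_names

    return canonical_channel_names()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(n_channels=4, duration=10.0, sample_rate=200.0, seed=0, label=None):
    """Small generic recording for unit tests (white noise)."""
    r = np.random.default_rng(seed)
    n = int(duration * sample_rate)
    return RawRecording(
        data=r.standard_normal((n_channels, n)),
        sample_rate=sample_rate,
        channel_names=[f"ch{i}" for i in range(n_channels)],
        label=label,
    )


@pytest.fixture
def white_recording():
    return make_recording()


@pytest.fixture(scope="session")
def short_positive_recording():
    """A 30 s pipeline-conformant recording from the positive profile."""
    return synthio.generate_recording(synthio.default_profile(1), 30.0, 200.0, seed=99)


@pytest.fixture
def conformant_tensor(rng):
    """Random 62 x 180 x 5 DE tensor (no EEG synthesis needed)."""
    return DETensor(values=rng.normal(size=(62, 180, 5)), window_length=1.0)
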