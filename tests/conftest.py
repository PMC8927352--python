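import numpy as np
import pytest

from pulseid.signal_io import AudioSegment, RunConfig

FS = 100_000.0


@pytest.fixture
def fs():
    return FS


@pytest.fixture
def cfg():
    return RunConfig()


def tone(freq_hz, n=3000, fs=FS, amp=1.0, phase=0.0):
    t = np.arange(n) / fs
    return AudioSegment(amp * np.cos(2 * np.pi * freq_hz * t + phase), fs)


@pytest.fixture
def tone_factory():
    return tone
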