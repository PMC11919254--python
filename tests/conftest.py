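import numpy as np
import pytest

from speechtrack.envelope import EnvelopeSeries
from speechtrack.preprocess import EEGRecording, MASTOID_LABELS, SCALP_LABELS
from speechtrack.waveform import Waveform

AUDIO_RATE = 8000.0


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def speech_wave(rng):
    """A short speech-like test signal: amplitude-modulated tone complex."""
    t = np.arange(0, 1.0, 1 / AUDIO_RATE)
    carrier = np.sin(2 * np.pi * 440 * t) + 0.5 * np.sin(2 * np.pi * 1200 * t)
    am = 0.5 * (1 + np.sin(2 * np.pi * 4 * t))
    return Waveform(carrier * am + 0.01 * rng.standard_normal(t.size), AUDIO_RATE)


@pytest.fixture
def noise_wave(rng):
    return Waveform(rng.standard_normal(8000), AUDIO_RATE)


@pytest.fixture
def raw_recording(rng):
    """Raw 18-channel (16 scalp + mastoids) recording at 1024 Hz."""
    n = 4096
    data = 5.0 * rng.standard_normal((18, n))
    return EEGRecording(data, 1024.0, SCALP_LABELS + MASTOID_LABELS)


def small_envelope(n=2000, rate=512.0, seed=0):
    rng = np.random.default_rng(seed)
    return EnvelopeSeries(rng.random(n), rate, kind="onset")
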