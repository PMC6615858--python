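import numpy as np
import pandas as pd
import pytest

from mvinfo.containers import ContinuousRecording, make_channel_table
from mvinfo.synthdata import CONFIG_B, PopulationConfig, simulate_session


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def color_session():
    """A decodable 8-class color session at default SNR (shared, read-only)."""
    return simulate_session(
        CONFIG_B,
        [PopulationConfig(tuned_feature="color")],
        n_events=800,
        seed=42,
    )


def make_recording(data, fs, names=None):
    names = names or [f"ch{i}" for i in range(np.atleast_2d(data).shape[0])]
    return ContinuousRecording(np.atleast_2d(data), fs, make_channel_table(names))


def sine(freq, fs, duration_s, amplitude=1.0):
    t = np.arange(int(round(fs * duration_s))) / fs
    return amplitude * np.sin(2 * np.pi * freq * t)


def spectral_amplitude(x, fs, freq):
    """Amplitude of the component nearest ``freq`` from an rFFT."""
    spec = np.abs(np.fft.rfft(x)) * 2 / x.size
    freqs = np.fft.rfftfreq(x.size, 1 / fs)
    return spec[np.argmin(np.abs(freqs - freq))]
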