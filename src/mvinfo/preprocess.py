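"""Signal-conditioning chains mapping raw channel data to the analysis band.

Four chains are provided, matching the treatment of each signal class:

* multi-unit activity (MUA): band-pass 500-6000 Hz, rectification, low-pass
  250 Hz, resampling to 1 kHz,
* local field potential (LFP): low-pass 500 Hz plus a local bipolar
  reference,
* scalp signals: down-sampling with an anti-alias filter and an average
  reference,
* the common analysis band: 0.1-10 Hz Butterworth, applied forward and
  backward ("2-pass") so filtering is zero-phase.

All filters are Butterworth of the stated order applied forward-reverse
(`sosfiltfilt`), which doubles the effective order and cancels phase
delays; edges are reflect-padded to suppress transients on short synthetic
recordings.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal

from .containers import ContinuousRecording, EpochedData

__all__ = [
    "extract_mua",
    "extract_lfp",
    "analysis_bandpass",
    "resample_rereference",
    "epoch",
]


def _sosfiltfilt(sos: np.ndarray, data: np.ndarray) -> np.ndarray:
    # reflect padding, capped so short inputs remain filterable
    padlen = min(3 * 2 * sos.shape[0] * 3, data.shape[-1] - 1)
    return signal.sosfiltfilt(sos, data, axis=-1, padlen=padlen)


def _resample(data: np.ndarray, fs: float, target: float) -> np.ndarray:
    from fractions import Fraction

    frac = Fraction(target / fs).limit_denominator(1000)
    return signal.resample_poly(data, frac.numerator, frac.denominator, axis=-1)


def extract_mua(broadband: ContinuousRecording) -> ContinuousRecording:
    """Analog multi-unit activity from broadband data.

    Band-pass 500-6000 Hz (2nd-order zero-phase forward-reverse
    Butterworth), full-wave rectification, low-pass 250 Hz (same filter
    family), resampling to 1 kHz.  The rectified signal is nonnegative
    before the final low-pass, so the output tracks the envelope of
    high-frequency (spiking) activity.
    """
    fs = broadband.sampling_rate
    if fs <= 12000:
        raise ValueError(
            f"sampling rate {fs} Hz too low for the 500-6000 Hz band "
            "(need > 12 kHz)"
        )
    sos_band = signal.butter(2, [500.0, 6000.0], btype="bandpass", fs=fs, output="sos")
    sos_low = signal.butter(2, 250.0, btype="lowpass", fs=fs, output="sos")
    x = _sosfiltfilt(sos_band, broadband.data)
    x = np.abs(x)
    x = _sosfiltfilt(sos_low, x)
    x = _resample(x, fs, 1000.0)
    chan = broadband.channels.copy()
    chan["signal_class"] = "MUA"
    return ContinuousRecording(x, 1000.0, chan)


def extract_lfp(
    broadband: ContinuousRecording,
    pairing: list[tuple[int, int]] | None = None,
) -> ContinuousRecording:
    """Local field potential: low-pass at 500 Hz, then a local bipolar reference.

    ``pairing`` lists (anode, cathode) channel-index pairs; each output
    channel is the difference of its low-passed pair.  By default adjacent
    channels are paired (0-1, 1-2, ...), the usual laminar bipolar scheme.
    """
    fs = broadband.sampling_rate
    if fs <= 1000:
        raise ValueError("sampling rate too low for a 500 Hz low-pass")
    if pairing is None:
        pairing = [(i, i + 1) for i in range(broadband.n_channels - 1)]
    n = broadband.n_channels
    for a, b in pairing:
        if a == b or not (0 <= a < n and 0 <= b < n):
            raise ValueError(f"invalid bipolar pair ({a}, {b})")
    sos = signal.butter(2, 500.0, btype="lowpass", fs=fs, output="sos")
    low = _sosfiltfilt(sos, broadband.data)
    out = np.stack([low[a] - low[b] for a, b in pairing])
    names = broadband.channels["name"].to_list()
    chan = pd.DataFrame(
        {
            "name": [f"{names[a]}-{names[b]}" for a, b in pairing],
            "area": [broadband.channels["area"].iloc[a] for a, _ in pairing],
            "signal_class": "LFP",
        }
    )
    return ContinuousRecording(out, fs, chan)


def analysis_bandpass(
    x: ContinuousRecording | EpochedData,
    band: tuple[float, float] = (0.1, 10.0),
    order: int = 4,
):
    """Band-pass into the common analysis band (default 0.1-10 Hz).

    Butterworth of the given order applied forward-reverse ("2-pass"), so
    the result is zero-phase and the effective attenuation order doubles.
    Works on continuous recordings and on epoched data (filtering each
    epoch along time).
    """
    fs = x.sampling_rate
    if fs < 30:
        raise ValueError(f"sampling rate {fs} Hz below the 30 Hz minimum")
    sos = signal.butter(order, list(band), btype="bandpass", fs=fs, output="sos")
    filt = _sosfiltfilt(sos, x.data)
    if isinstance(x, EpochedData):
        return EpochedData(filt, x.time, x.trials.copy(), x.channels.copy())
    return ContinuousRecording(filt, fs, x.channels.copy())


def resample_rereference(
    x: ContinuousRecording,
    target_rate: float,
    reference: str = "average",
) -> ContinuousRecording:
    """Down-sample (with anti-alias low-pass) and optionally average-reference.

    After average referencing, the instantaneous mean over channels is zero.
    ``reference`` is ``"average"`` or ``"none"``.
    """
    fs = x.sampling_rate
    if target_rate > fs:
        raise ValueError("target_rate must not exceed the sampling rate")
    data = x.data if target_rate == fs else _resample(x.data, fs, target_rate)
    if reference == "average":
        data = data - data.mean(axis=0, keepdims=True)
    elif reference != "none":
        raise ValueError(f"unknown reference {reference!r}")
    return ContinuousRecording(data, target_rate, x.channels.copy())


def epoch(
    x: ContinuousRecording,
    events: pd.DataFrame,
    window: tuple[float, float] = (-250.0, 500.0),
    step: float = 10.0,
) -> EpochedData:
    """Cut epochs around stimulus onsets on a fixed time grid.

    The grid runs from ``window[0]`` to ``window[1]`` ms relative to onset
    in ``step`` ms steps, with t = 0 included; the default gives 76 samples.
    Overlapping windows from rapid stimulus streams are permitted and share
    samples.  Raises if any event's window falls outside the recording,
    listing the offending events.
    """
    rel = np.arange(
        window[0], window[1] + step / 2.0, step
    )  # ms relative to onset, t=0 on grid
    onsets = events["onset_time"].to_numpy(dtype=float)
    fs = x.sampling_rate
    idx = np.round((onsets[:, None] + rel[None, :]) * fs / 1000.0).astype(int)
    bad = np.flatnonzero((idx.min(axis=1) < 0) | (idx.max(axis=1) >= x.n_samples))
    if bad.size:
        raise ValueError(
            "epoch window exceeds the recording for events "
            f"{events['event_index'].to_numpy()[bad].tolist()}"
        )
    if len(events) == 0:
        data = np.empty((0, x.n_channels, rel.size))
    else:
        data = x.data[:, idx].transpose(1, 0, 2)
    return EpochedData(data, rel, events.copy(), x.channels.copy())
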