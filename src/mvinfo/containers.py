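"""In-memory containers shared by all analysis stages.

The pipeline's central objects are

``ContinuousRecording``
    channels x samples array with a sampling rate and per-channel metadata,
``EpochedData``
    epochs x channels x time array cut around stimulus onsets, carrying the
    trial table (circular class labels, sequence position, luminance level)
    and channel metadata,
``ConfusionTensor``
    time x K x K row-stochastic matrices of mean predicted class
    probabilities for each true class -- the decoder's output,
``InformationTimecourse``
    per-session accuracy (mean confusion diagonal) over time.

Channel metadata lives in a :class:`pandas.DataFrame` with at least the
columns ``name``, ``area`` and ``signal_class``; trial metadata mirrors the
trial-table CSV columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

#: Signal classes a channel may carry.
SIGNAL_CLASSES = ("SUA", "MUA", "LFP", "SENSOR", "SOURCE", "EEG", "MEG")

#: Columns of the trial table (one row per stimulus event).
TRIAL_COLUMNS = (
    "session_id",
    "event_index",
    "onset_time",
    "sequence_position",
    "color_angle",
    "motion_angle",
    "luminance_level",
    "config_tag",
)


def analysis_time_grid(
    tmin: float = -250.0, tmax: float = 500.0, step: float = 10.0
) -> np.ndarray:
    """Return the decoding time grid in ms (onset at 0, endpoints included).

    The default grid runs from 250 ms before to 500 ms after stimulus onset
    in 10 ms steps, i.e. 76 time points.
    """
    n = int(round((tmax - tmin) / step)) + 1
    return tmin + step * np.arange(n)


def circular_difference(a, b=0.0) -> np.ndarray | float:
    """Signed circular difference ``a - b`` in degrees, mapped to (-180, 180]."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    d = np.mod(d, 360.0)
    d = np.where(d > 180.0, d - 360.0, d)
    if d.ndim == 0:
        return float(d)
    return d


@dataclass
class ContinuousRecording:
    """A multichannel continuous recording (channels x samples)."""

    data: np.ndarray
    sampling_rate: float
    channels: pd.DataFrame

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError(
                f"channel metadata has {len(self.channels)} rows but data has "
                f"{self.data.shape[0]} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.n_samples / self.sampling_rate


def make_channel_table(
    names: Sequence[str],
    area: str | Sequence[str] = "NA",
    signal_class: str | Sequence[str] = "SENSOR",
    **extra,
) -> pd.DataFrame:
    """Build a channel metadata table from names plus area / signal class."""
    n = len(names)
    tab = pd.DataFrame(
        {
            "name": list(names),
            "area": [area] * n if isinstance(area, str) else list(area),
            "signal_class": (
                [signal_class] * n
                if isinstance(signal_class, str)
                else list(signal_class)
            ),
        }
    )
    for key, val in extra.items():
        tab[key] = val
    return tab


@dataclass
class EpochedData:
    """Epoched multichannel data: ``data`` is epochs x channels x time.

    ``time`` is in ms relative to stimulus onset, strictly increasing.
    ``trials`` holds one row per epoch with (at least) the stimulus labels;
    ``channels`` holds one row per channel.
    """

    data: np.ndarray
    time: np.ndarray
    trials: pd.DataFrame
    channels: pd.DataFrame

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (epochs x channels x time)")
        if self.data.shape[2] != self.time.size:
            raise ValueError("time axis length does not match data")
        if self.time.size > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        if len(self.trials) != self.data.shape[0]:
            raise ValueError(
                f"trial table has {len(self.trials)} rows but data has "
                f"{self.data.shape[0]} epochs"
            )
        if len(self.channels) != self.data.shape[1]:
            raise ValueError("channel metadata does not match channel count")
        self.trials = self.trials.reset_index(drop=True)
        self.channels = self.channels.reset_index(drop=True)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def sampling_rate(self) -> float:
        """Sampling rate in Hz implied by the (uniform) time grid."""
        if self.time.size < 2:
            raise ValueError("need at least two time points")
        return 1000.0 / float(np.median(np.diff(self.time)))

    def labels(self, feature: str) -> np.ndarray:
        """Class-angle labels for ``feature`` ('color' or 'motion')."""
        col = f"{feature}_angle"
        if col not in self.trials.columns:
            raise KeyError(f"trial table has no column {col!r}")
        return self.trials[col].to_numpy(dtype=float)

    def select_epochs(self, index) -> "EpochedData":
        index = np.asarray(index)
        return EpochedData(
            self.data[index],
            self.time,
            self.trials.iloc[index],
            self.channels,
        )

    def select_channels(self, index) -> "EpochedData":
        index = np.asarray(index)
        return EpochedData(
            self.data[:, index],
            self.time,
            self.trials,
            self.channels.iloc[index],
        )

    def select_times(self, window: tuple[float, float]) -> "EpochedData":
        lo, hi = window
        mask = (self.time >= lo) & (self.time <= hi)
        if not mask.any():
            raise ValueError(f"no samples in window {window}")
        return EpochedData(
            self.data[:, :, mask], self.time[mask], self.trials, self.channels
        )


@dataclass
class ConfusionTensor:
    """Time-resolved confusion-probability matrices.

    ``probs[t, i, j]`` is the mean predicted probability of class ``j`` for
    held-out trials of true class ``i`` at time point ``t``.  Every row of
    every matrix sums to one.
    """

    probs: np.ndarray
    time: np.ndarray
    class_angles: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        self.class_angles = np.asarray(self.class_angles, dtype=float)
        if self.probs.ndim != 3 or self.probs.shape[1] != self.probs.shape[2]:
            raise ValueError("probs must be (time, K, K)")
        if self.probs.shape[0] != self.time.size:
            raise ValueError("time axis does not match probs")
        if self.probs.shape[1] != self.class_angles.size:
            raise ValueError("class_angles does not match probs")

    @property
    def n_classes(self) -> int:
        return self.probs.shape[1]

    def validate(self, atol: float = 1e-9) -> None:
        """Raise if entries leave [0, 1] or any row does not sum to one."""
        if self.probs.min() < -atol or self.probs.max() > 1 + atol:
            raise ValueError("confusion probabilities outside [0, 1]")
        rows = self.probs.sum(axis=2)
        if not np.allclose(rows, 1.0, atol=atol):
            raise ValueError("confusion rows do not sum to 1")

    def time_mask(self, window: tuple[float, float]) -> np.ndarray:
        lo, hi = window
        return (self.time >= lo) & (self.time <= hi)


@dataclass
class InformationTimecourse:
    """Classifier accuracy (mean confusion diagonal) over time for one session."""

    values: np.ndarray
    time: np.ndarray
    chance: float
    session_id: str | int | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        if self.values.shape != self.time.shape:
            raise ValueError("values and time must have equal length")

    def shifted(self, delta_ms: float) -> "InformationTimecourse":
        return replace(self, time=self.time + delta_ms)
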