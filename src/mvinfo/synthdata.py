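"""Seeded synthetic data emulating tuned neural populations and sensor mixtures.

Everything downstream of this module (decoding, cluster statistics, latency
estimation, RSA, tuning analysis, controls) is exercised on data produced
here, so the generator mirrors the statistical structure the analyses
assume:

* rapid streams of stimuli drawn from 8 or 12 uniformly spaced circular
  classes for color and motion direction,
* per-channel circular tuning that is unimodal (direction-like, a von-Mises
  shaped bump), bimodal (axis-like, the same bump on the doubled angle) or
  absent,
* an evoked transient -- a half-cosine bump of configurable width starting
  at a population-specific onset latency -- scaled by the tuning gain, on
  top of additive Gaussian noise,
* a linear source-to-sensor forward mixing for EEG/MEG-like arrays,
* minimum-motion eye traces whose curvature is proportional to the
  luminance offset from the true equiluminant point.

All randomness flows through :func:`numpy.random.default_rng` seeds, so
identical seeds give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import (
    EpochedData,
    analysis_time_grid,
    circular_difference,
    make_channel_table,
)

__all__ = [
    "ConfigurationError",
    "StimulusConfig",
    "CONFIG_A",
    "CONFIG_B",
    "PopulationConfig",
    "MixingModel",
    "EyeTraceSet",
    "generate_stimulus_stream",
    "tuning_function",
    "temporal_kernel",
    "simulate_tuned_responses",
    "simulate_session",
    "mix_to_sensors",
    "random_mixing",
    "generate_eye_traces",
]


class ConfigurationError(ValueError):
    """Raised for invalid stimulus or population configurations."""


@dataclass(frozen=True)
class StimulusConfig:
    """Parameters of a rapid-stream stimulus protocol.

    ``n_classes`` circular classes at ``360 / n_classes`` degree spacing are
    used for both color hue and motion direction.  Stimuli last
    ``stim_duration`` ms and are separated by ``isi`` ms; every
    ``sequence_length`` stimuli form one fixation sequence (or a single
    continuous stream).
    """

    n_classes: int
    stim_duration: float
    isi: float
    sequence_length: int | str
    tag: str = "custom"
    features: tuple[str, ...] = ("color", "motion")

    def __post_init__(self):
        if self.n_classes not in (8, 12):
            raise ConfigurationError(
                f"n_classes must be 8 or 12, got {self.n_classes}"
            )
        if self.stim_duration <= 0:
            raise ConfigurationError("stim_duration must be > 0")
        if self.isi < 0:
            raise ConfigurationError("isi must be >= 0")
        if self.sequence_length != "continuous" and (
            not isinstance(self.sequence_length, int) or self.sequence_length < 1
        ):
            raise ConfigurationError(
                "sequence_length must be a positive integer or 'continuous'"
            )

    @property
    def class_angles(self) -> np.ndarray:
        """Class centers in degrees: k * (360 / n_classes), k = 0..K-1."""
        return 360.0 / self.n_classes * np.arange(self.n_classes)

    @property
    def soa(self) -> float:
        """Stimulus-onset asynchrony (stimulus duration + ISI) in ms."""
        return self.stim_duration + self.isi


#: 12 classes at 30 degrees, 150 ms stimuli with 50 ms ISI, sequences of 6.
CONFIG_A = StimulusConfig(12, 150.0, 50.0, 6, tag="A")
#: 8 classes at 45 degrees, 100 ms stimuli with 20 ms ISI, sequences of 8.
CONFIG_B = StimulusConfig(8, 100.0, 20.0, 8, tag="B")


def generate_stimulus_stream(
    config: StimulusConfig,
    n_events: int,
    seed: int = 0,
    session_id: str | int = 0,
    luminance_levels: Sequence[int] = (1,),
) -> pd.DataFrame:
    """Generate a trial table of ``n_events`` stimulus events.

    Color and motion labels are drawn independently and uniformly from the
    configuration's class angles; onsets follow the stimulus-duration + ISI
    spacing.  ``luminance_levels`` lists the levels to sample uniformly
    (level 2 denotes the 20 %-reduced-contrast variant used by the
    luminance control).
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    rng = np.random.default_rng(seed)
    angles = config.class_angles
    color = angles[rng.integers(0, config.n_classes, n_events)]
    motion = angles[rng.integers(0, config.n_classes, n_events)]
    lum = np.asarray(luminance_levels)[rng.integers(0, len(luminance_levels), n_events)]
    if config.sequence_length == "continuous":
        position = np.ones(n_events, dtype=int)
    else:
        position = np.arange(n_events) % int(config.sequence_length) + 1
    return pd.DataFrame(
        {
            "session_id": session_id,
            "event_index": np.arange(n_events),
            "onset_time": config.soa * np.arange(n_events),
            "sequence_position": position,
            "color_angle": color,
            "motion_angle": motion,
            "luminance_level": lum,
            "config_tag": config.tag,
        }
    )


def tuning_function(
    angle,
    pref: float,
    shape: str = "unimodal",
    amplitude: float = 1.0,
    kappa: float = 2.0,
    baseline: float = 0.0,
):
    """Circular tuning: response to a stimulus ``angle`` given a preference.

    * ``unimodal`` -- a von-Mises shaped bump ``exp(kappa * (cos(d) - 1))``
      peaking at the preferred angle (direction tuning),
    * ``bimodal`` -- the same bump evaluated on the doubled angle ``2 d``,
      hence 180-degree periodic (axis / orientation tuning),
    * ``untuned`` -- the baseline alone.

    The bump is normalized so the response at the preferred angle equals
    ``baseline + amplitude``.
    """
    delta = np.deg2rad(np.asarray(circular_difference(angle, pref)))
    if shape == "unimodal":
        bump = np.exp(kappa * (np.cos(delta) - 1.0))
    elif shape == "bimodal":
        bump = np.exp(kappa * (np.cos(2.0 * delta) - 1.0))
    elif shape == "untuned":
        bump = np.zeros_like(delta)
    else:
        raise ConfigurationError(f"unknown tuning shape {shape!r}")
    return baseline + amplitude * bump


def temporal_kernel(
    time_ms: np.ndarray, onset_latency: float, width: float
) -> np.ndarray:
    """Half-cosine evoked transient: ``sin(pi * u)`` for ``u`` in [0, 1].

    The bump starts at ``onset_latency`` (ms after stimulus onset), peaks at
    ``onset_latency + width / 2`` and returns to zero at
    ``onset_latency + width``; it is zero elsewhere.
    """
    u = (np.asarray(time_ms, dtype=float) - onset_latency) / width
    k = np.sin(np.pi * np.clip(u, 0.0, 1.0))
    k[(u < 0.0) | (u > 1.0)] = 0.0
    return k


@dataclass(frozen=True)
class PopulationConfig:
    """One simulated population: an area's worth of similarly tuned channels.

    ``amplitude`` is the evoked response at the preferred stimulus (rate
    units), ``kappa`` the tuning concentration, ``onset_latency`` the start
    of the evoked transient in ms, ``kernel_width`` its duration in ms,
    ``noise_sd`` the additive Gaussian noise per sample and ``baseline`` the
    spontaneous level.  ``luminance_gain`` adds an untuned evoked component
    scaled by the stimulus contrast (1.0 at luminance level 1, 0.8 at the
    reduced-contrast level 2), used to emulate luminance confounds.
    """

    area: str = "V1like"
    n_units: int = 12
    signal_class: str = "MUA"
    tuned_feature: str = "color"
    tuning_shape: str = "unimodal"
    amplitude: float = 1.0
    kappa: float = 2.0
    onset_latency: float = 80.0
    kernel_width: float = 40.0
    noise_sd: float = 0.35
    baseline: float = 0.0
    luminance_gain: float = 0.0

    def __post_init__(self):
        if self.amplitude < 0:
            raise ConfigurationError("amplitude must be >= 0")
        if self.kappa <= 0:
            raise ConfigurationError("kappa must be > 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.onset_latency < 0:
            raise ConfigurationError("onset_latency must be >= 0")
        if self.kernel_width <= 0:
            raise ConfigurationError("kernel_width must be > 0")
        if self.tuning_shape not in ("unimodal", "bimodal", "untuned"):
            raise ConfigurationError(f"unknown tuning_shape {self.tuning_shape!r}")
        if self.tuned_feature not in ("color", "motion"):
            raise ConfigurationError(f"unknown tuned_feature {self.tuned_feature!r}")


#: Contrast scaling per luminance level (level 2 = 20 % reduced contrast).
_LUMINANCE_CONTRAST = {1: 1.0, 2: 0.8}


def simulate_tuned_responses(
    trials: pd.DataFrame,
    populations: PopulationConfig | Sequence[PopulationConfig],
    time_axis: np.ndarray | None = None,
    seed: int = 0,
) -> EpochedData:
    """Simulate epoched responses of tuned populations to a trial stream.

    Each channel's trace is ``baseline + gain(label) * kernel(t) + noise``
    where ``gain`` is the channel's tuning evaluated at the trial's label
    for the population's tuned feature, and ``kernel`` is the half-cosine
    transient shifted by the population's onset latency.  Preferred angles
    are drawn uniformly on the circle per channel (seeded).
    """
    if len(trials) == 0:
        raise ValueError("trial table is empty")
    if isinstance(populations, PopulationConfig):
        populations = [populations]
    if time_axis is None:
        time_axis = analysis_time_grid()
    time_axis = np.asarray(time_axis, dtype=float)
    rng = np.random.default_rng(seed)
    n_trials = len(trials)

    blocks, chan_rows = [], []
    contrast = trials["luminance_level"].map(_LUMINANCE_CONTRAST).to_numpy(float) \
        if "luminance_level" in trials.columns else np.ones(n_trials)
    for pop in populations:
        labels = trials[f"{pop.tuned_feature}_angle"].to_numpy(dtype=float)
        kern = temporal_kernel(time_axis, pop.onset_latency, pop.kernel_width)
        prefs = rng.uniform(0.0, 360.0, pop.n_units)
        # tuned evoked gain per (trial, unit)
        gain = (
            tuning_function(
                labels[:, None],
                prefs[None, :],
                shape=pop.tuning_shape,
                amplitude=pop.amplitude,
                kappa=pop.kappa,
                baseline=0.0,
            )
            if pop.tuning_shape != "untuned"
            else np.zeros((n_trials, pop.n_units))
        )
        gain = gain + pop.luminance_gain * contrast[:, None]
        traces = pop.baseline + gain[:, :, None] * kern[None, None, :]
        if pop.noise_sd > 0:
            traces = traces + rng.normal(
                0.0, pop.noise_sd, size=(n_trials, pop.n_units, time_axis.size)
            )
        blocks.append(traces)
        for i, pref in enumerate(prefs):
            chan_rows.append(
                {
                    "name": f"{pop.area}_{pop.signal_class}_{i:02d}",
                    "area": pop.area,
                    "signal_class": pop.signal_class,
                    "tuned_feature": pop.tuned_feature,
                    "tuning_shape": pop.tuning_shape,
                    "pref_angle": pref,
                    "onset_latency": pop.onset_latency,
                }
            )
    data = np.concatenate(blocks, axis=1)
    return EpochedData(data, time_axis, trials.copy(), pd.DataFrame(chan_rows))


def simulate_session(
    config: StimulusConfig = CONFIG_B,
    populations: PopulationConfig | Sequence[PopulationConfig] | None = None,
    n_events: int = 2000,
    seed: int = 0,
    session_id: str | int = 0,
    luminance_levels: Sequence[int] = (1,),
    time_axis: np.ndarray | None = None,
) -> EpochedData:
    """Convenience wrapper: stimulus stream plus tuned responses, one seed."""
    if populations is None:
        populations = [PopulationConfig()]
    trials = generate_stimulus_stream(
        config, n_events, seed=seed, session_id=session_id,
        luminance_levels=luminance_levels,
    )
    return simulate_tuned_responses(trials, populations, time_axis, seed=seed + 1)


@dataclass
class MixingModel:
    """Linear source-to-sensor forward model.

    ``gain`` has shape (sources x channels); ``source_positions`` is a 1-D
    coordinate per source along an occipito-frontal axis (arbitrary units,
    low = occipital).
    """

    gain: np.ndarray
    source_positions: np.ndarray
    channel_labels: Sequence[str] | None = None

    def __post_init__(self):
        self.gain = np.asarray(self.gain, dtype=float)
        self.source_positions = np.asarray(self.source_positions, dtype=float)
        if self.gain.ndim != 2:
            raise ValueError("gain must be 2-D (sources x channels)")
        if self.source_positions.size != self.gain.shape[0]:
            raise ValueError("source_positions must have one entry per source")
        if np.any(np.all(self.gain == 0.0, axis=1)):
            raise ValueError("gain has an all-zero source row")
        if self.channel_labels is None:
            self.channel_labels = [f"sensor_{i:02d}" for i in range(self.gain.shape[1])]

    @property
    def n_sources(self) -> int:
        return self.gain.shape[0]

    @property
    def n_channels(self) -> int:
        return self.gain.shape[1]


def random_mixing(
    n_sources: int, n_channels: int, seed: int = 0, spread: float = 1.0
) -> MixingModel:
    """Random smooth forward model with sources on a unit occipito-frontal axis.

    Each source projects to all sensors with Gaussian-decaying weights
    centered at a sensor position matched to the source coordinate, the
    usual smooth leadfield structure of volume conduction.
    """
    rng = np.random.default_rng(seed)
    pos = np.linspace(0.0, 1.0, n_sources)
    sensor_pos = np.linspace(0.0, 1.0, n_channels)
    width = spread * max(1.0 / n_sources, 0.05)
    gain = np.exp(-((pos[:, None] - sensor_pos[None, :]) ** 2) / (2 * width**2))
    gain *= rng.uniform(0.8, 1.2, size=gain.shape)
    return MixingModel(gain, pos)


def mix_to_sensors(
    sources: EpochedData,
    model: MixingModel,
    sensor_noise_sd: float = 0.0,
    seed: int = 0,
) -> EpochedData:
    """Project source epochs through the forward model onto sensors.

    ``sensors[e, c, t] = sum_s gain[s, c] * sources[e, s, t]`` plus optional
    Gaussian sensor noise.  Channel metadata is marked ``SENSOR``.
    """
    if sources.n_channels != model.n_sources:
        raise ValueError(
            f"forward model expects {model.n_sources} sources, data has "
            f"{sources.n_channels} channels"
        )
    rng = np.random.default_rng(seed)
    data = np.einsum("est,sc->ect", sources.data, model.gain)
    if sensor_noise_sd > 0:
        data = data + rng.normal(0.0, sensor_noise_sd, size=data.shape)
    channels = make_channel_table(
        list(model.channel_labels), area="scalp", signal_class="SENSOR"
    )
    return EpochedData(data, sources.time, sources.trials.copy(), channels)


@dataclass
class EyeTraceSet:
    """Vertical eye-position traces from the minimum-motion procedure.

    One trace per trial; ``condition`` is 1 or 2 (the two grating-phase
    conditions with opposite luminance-to-motion mapping), ``probe_L`` the
    luminance of the probe color on that trial.  ``time`` is in ms.
    """

    positions: np.ndarray
    time: np.ndarray
    condition: np.ndarray
    probe_L: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        self.condition = np.asarray(self.condition, dtype=int)
        self.probe_L = np.asarray(self.probe_L, dtype=float)
        if self.positions.shape != (self.condition.size, self.time.size):
            raise ValueError("positions must be (trials x time)")
        for L in np.unique(self.probe_L):
            conds = set(self.condition[self.probe_L == L])
            if conds != {1, 2}:
                raise ValueError(f"probe L={L} lacks one of the two conditions")


def generate_eye_traces(
    L_values: Sequence[float] | None = None,
    L_eq: float = 55.0,
    n_trials_per_level: int = 20,
    gain: float = 1.0,
    noise_sd: float = 0.01,
    seed: int = 0,
    duration_ms: float = 500.0,
    sampling_rate: float = 100.0,
) -> EyeTraceSet:
    """Simulate minimum-motion eye traces across probe luminance levels.

    The expected curvature (second time derivative of vertical position, in
    units per s^2) of each trace is ``gain * (L - L_eq)`` in condition 1 and
    the negative of that in condition 2, so the condition difference crosses
    zero exactly at the true equiluminant level ``L_eq``.  White positional
    noise of ``noise_sd`` units is added.  Defaults follow the procedure of
    probing each color at 19 L values centered on the reference gray.
    """
    if L_values is None:
        L_values = L_eq + np.arange(-9.0, 10.0)  # 19 levels around the reference
    L_values = np.asarray(L_values, dtype=float)
    if np.unique(L_values).size < 2:
        raise ValueError("need at least two distinct L values")
    rng = np.random.default_rng(seed)
    n_samp = int(round(duration_ms / 1000.0 * sampling_rate)) + 1
    t_s = np.arange(n_samp) / sampling_rate
    traces, conds, probes = [], [], []
    for L in L_values:
        for cond in (1, 2):
            curv = gain * (L - L_eq) * (1.0 if cond == 1 else -1.0)
            base = 0.5 * curv * t_s**2
            block = base[None, :] + rng.normal(
                0.0, noise_sd, size=(n_trials_per_level, n_samp)
            )
            traces.append(block)
            conds.append(np.full(n_trials_per_level, cond))
            probes.append(np.full(n_trials_per_level, L))
    return EyeTraceSet(
        np.concatenate(traces, axis=0),
        1000.0 * t_s,
        np.concatenate(conds),
        np.concatenate(probes),
    )
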