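"""Control analyses: luminance cross-classification and equiluminance readout.

**Luminance control.**  Every color is shown at two contrast levels (level
2 = 20 % reduced).  Decoders are trained and tested within a level, across
levels, or -- the critical test -- on a *half-space split*: for each
diameter of the color circle, training pools high-contrast stimuli from one
half with low-contrast stimuli from the other, and testing uses the
complementary assignment.  A decoder driven purely by the contrast
manipulation is then systematically wrong on the test set and scores below
chance, so above-chance half-space accuracy indicates genuine color
information.  Confusion matrices are averaged over all axes before
accuracies are extracted; significance uses 100 label-shuffle repetitions.

**Equiluminance control.**  In the minimum-motion procedure, a probe color
brighter than the reference gray drives a vertical motion percept whose
direction reverses between the two grating-phase conditions.  The readout
is eye-trace curvature -- the second time derivative of vertical eye
position -- and the condition difference in mean curvature is, to first
order, proportional to the luminance offset of the probe.  A linear
regression of this measure against probe L locates its zero crossing, the
point of perceptual equiluminance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .containers import ConfusionTensor, EpochedData
from .decode import CVScheme, ShrinkageLDA, accuracy_timecourse, crossvalidated_confusion
from .synthdata import EyeTraceSet

__all__ = [
    "LUMINANCE_MODES",
    "LuminanceModeResult",
    "luminance_crossclassification",
    "EquiluminanceEstimate",
    "equiluminance_from_eyetraces",
    "second_derivative",
]

LUMINANCE_MODES = (
    "within_L1",
    "within_L2",
    "cross_L1L2",
    "cross_L2L1",
    "half_space_G1G2",
)


@dataclass
class LuminanceModeResult:
    mode: str
    confusion: ConfusionTensor
    accuracy: float
    window: tuple[float, float]
    shuffle_p: float = field(default=np.nan)
    shuffle_accuracies: np.ndarray | None = field(default=None, repr=False)


def _train_test_confusion(epoched, y, train, test, classes, shrinkage):
    """Single-split confusion tensor: fit on ``train``, evaluate on ``test``."""
    k = classes.size
    n_t = epoched.n_times
    probs = np.zeros((n_t, k, k))
    data = epoched.data
    for t in range(n_t):
        model = ShrinkageLDA(shrinkage=shrinkage).fit(data[train, :, t], y[train])
        pred = model.predict_proba(data[test, :, t])
        for i, c in enumerate(classes):
            sel = y[test] == c
            if sel.any():
                probs[t, i] = pred[sel].mean(axis=0)
            else:
                probs[t, i] = 1.0 / k
    return probs


def _half_space_mask(angles, classes, axis_index):
    """Boolean mask of trials whose class falls in half A for a split axis.

    Axis ``m`` assigns classes with ((angle - m * step) mod 360) < 180 to
    half A; classes exactly on the axis land in half A via the lower-angle
    rule.
    """
    step = 360.0 / classes.size
    shifted = np.mod(angles - axis_index * step, 360.0)
    return shifted < 180.0


def _mode_confusion(epoched, y, lum, classes, mode, scheme, shrinkage):
    if mode in ("within_L1", "within_L2"):
        level = 1 if mode == "within_L1" else 2
        sub = np.flatnonzero(lum == level)
        conf = crossvalidated_confusion(
            epoched.select_epochs(sub), _FEATURE, scheme, shrinkage
        )
        return conf.probs
    if mode in ("cross_L1L2", "cross_L2L1"):
        tr_level = 1 if mode == "cross_L1L2" else 2
        train = np.flatnonzero(lum == tr_level)
        test = np.flatnonzero(lum == (3 - tr_level))
        return _train_test_confusion(epoched, y, train, test, classes, shrinkage)
    if mode == "half_space_G1G2":
        acc = None
        n_axes = classes.size // 2
        for m in range(n_axes):
            in_a = _half_space_mask(y, classes, m)
            train = np.flatnonzero((in_a & (lum == 1)) | (~in_a & (lum == 2)))
            test = np.flatnonzero((in_a & (lum == 2)) | (~in_a & (lum == 1)))
            probs = _train_test_confusion(epoched, y, train, test, classes, shrinkage)
            acc = probs if acc is None else acc + probs
        return acc / n_axes
    raise ValueError(f"unknown mode {mode!r}")


_FEATURE = "color"


def luminance_crossclassification(
    epoched: EpochedData,
    modes=LUMINANCE_MODES,
    scheme: CVScheme | None = None,
    shrinkage: float = 0.1,
    n_shuffle: int = 100,
    seed: int = 0,
    accuracy_window: tuple[float, float] = (50.0, 250.0),
) -> dict[str, LuminanceModeResult]:
    """Color decoding within / across luminance levels and half-space splits.

    Returns one result per mode with the confusion tensor, the scalar
    accuracy (mean confusion diagonal averaged over ``accuracy_window``),
    and -- when ``n_shuffle`` > 0 -- the label-shuffle p-value, the
    fraction of shuffled accuracies reaching the observed one (with the +1
    correction).
    """
    if scheme is None:
        scheme = CVScheme(n_folds=2, seed=seed)
    y = epoched.labels(_FEATURE)
    lum = epoched.trials["luminance_level"].to_numpy(dtype=int)
    classes = np.unique(y)
    for c in classes:
        for level in (1, 2):
            if not np.any((y == c) & (lum == level)):
                raise ValueError(
                    f"missing luminance level {level} for color class {c}"
                )
    rng = np.random.default_rng(seed)
    results = {}
    for mode in modes:
        probs = _mode_confusion(epoched, y, lum, classes, mode, scheme, shrinkage)
        conf = ConfusionTensor(probs, epoched.time, classes, meta={"mode": mode})
        tc = accuracy_timecourse(conf)
        win = (tc.time >= accuracy_window[0]) & (tc.time <= accuracy_window[1])
        acc = float(tc.values[win].mean())
        res = LuminanceModeResult(mode, conf, acc, accuracy_window)
        if n_shuffle > 0:
            shuffled = np.empty(n_shuffle)
            for s in range(n_shuffle):
                y_s = y[rng.permutation(y.size)]
                ep_s = EpochedData(
                    epoched.data,
                    epoched.time,
                    epoched.trials.assign(color_angle=y_s),
                    epoched.channels,
                )
                probs_s = _mode_confusion(
                    ep_s, y_s, lum, classes, mode, scheme, shrinkage
                )
                diag = np.einsum("tkk->tk", probs_s).mean(axis=1)
                shuffled[s] = diag[win].mean()
            res.shuffle_accuracies = shuffled
            res.shuffle_p = float(
                (np.count_nonzero(shuffled >= acc) + 1) / (n_shuffle + 1)
            )
        results[mode] = res
    return results


def second_derivative(traces: np.ndarray, dt_s: float) -> np.ndarray:
    """Discrete second time derivative (central second difference / dt^2).

    Exact on polynomials of degree <= 2: applied to ``a * t**2`` it returns
    ``2 a`` everywhere.  Output has two fewer samples than the input.
    """
    traces = np.asarray(traces, dtype=float)
    return (traces[..., 2:] - 2.0 * traces[..., 1:-1] + traces[..., :-2]) / dt_s**2


@dataclass
class EquiluminanceEstimate:
    L_estimate: float
    slope: float
    intercept: float
    r_squared: float
    L_values: np.ndarray
    measure: np.ndarray


def equiluminance_from_eyetraces(
    traces: EyeTraceSet,
    stim_window_ms: tuple[float, float] | None = None,
    min_slope: float = 1e-9,
) -> EquiluminanceEstimate:
    """Estimate the equiluminant L value from minimum-motion eye traces.

    Per trial, curvature is the mean second derivative of vertical eye
    position over the stimulus period; per probe L, the measure is the mean
    curvature difference between the two conditions.  A linear fit
    ``measure ~ a + b L`` gives the zero crossing ``-a / b``.
    """
    L_values = np.unique(traces.probe_L)
    if L_values.size < 3:
        raise ValueError("need at least 3 distinct probe L values")
    dt_s = float(np.median(np.diff(traces.time))) / 1000.0
    curv = second_derivative(traces.positions, dt_s)
    t_mid = traces.time[1:-1]
    if stim_window_ms is not None:
        keep = (t_mid >= stim_window_ms[0]) & (t_mid <= stim_window_ms[1])
        curv = curv[:, keep]
    trial_curv = curv.mean(axis=1)
    measure = np.array(
        [
            trial_curv[(traces.probe_L == L) & (traces.condition == 1)].mean()
            - trial_curv[(traces.probe_L == L) & (traces.condition == 2)].mean()
            for L in L_values
        ]
    )
    fit = sps.linregress(L_values, measure)
    if abs(fit.slope) < min_slope:
        raise ValueError("no zero crossing: regression slope is ~0")
    return EquiluminanceEstimate(
        float(-fit.intercept / fit.slope),
        float(fit.slope),
        float(fit.intercept),
        float(fit.rvalue**2),
        L_values,
        measure,
    )
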