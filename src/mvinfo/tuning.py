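"""Population and single-channel tuning derived from confusion structure.

Collapsing a K x K confusion matrix across stimuli gives a *tuning curve*:
the mean prediction probability as a function of the circular distance
between true and predicted class.  A peak at 0 is correct classification;
a second peak at 180 degrees marks axis-like (orientation) tuning, where
opposite directions are confused.  The *bimodality index* quantifies this:

    BI = (P(180) - mean(P(135), P(225))) / (P_max - P_min)

positive for a secondary 180-degree peak, zero or negative for unimodal
tuning, and invariant to affine rescaling of the curve by construction.
Group-level bimodality is tested with a one-sided one-sample t-test over
sessions or subjects, and pairwise representational similarities are
regressed on absolute bimodality differences to ask how much of the
similarity structure bimodality explains.

Single-channel tuning works on the raw responses instead: channels with
significant one-way ANOVA class effects are aligned to their preferred
stimulus and averaged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

from .containers import EpochedData, circular_difference
from .rsa import RepresentationMatrix

__all__ = [
    "TuningCurve",
    "BimodalityIndex",
    "collapse_to_tuning",
    "bimodality_index",
    "bimodality_group_test",
    "similarity_vs_bimodality_regression",
    "single_channel_tuning",
    "SingleChannelTuningResult",
]


@dataclass
class TuningCurve:
    """Prediction probability (or response) per circular offset in degrees.

    ``offsets_deg`` covers each of the K circular offsets exactly once,
    mapped to (-180, 180] and sorted ascending.
    """

    offsets_deg: np.ndarray
    probs: np.ndarray

    def __post_init__(self):
        self.offsets_deg = np.asarray(self.offsets_deg, dtype=float)
        self.probs = np.asarray(self.probs, dtype=float)
        if self.offsets_deg.shape != self.probs.shape:
            raise ValueError("offsets and probs must have equal length")

    def value_at(self, offset: float) -> float:
        hit = np.isclose(self.offsets_deg, offset)
        if not hit.any():
            raise ValueError(f"offset {offset} not on the curve")
        return float(self.probs[hit][0])


@dataclass
class BimodalityIndex:
    value: float
    p_opposite: float
    p_next_to_opposite_mean: float
    p_max: float
    p_min: float


def collapse_to_tuning(m: RepresentationMatrix | np.ndarray) -> TuningCurve:
    """Collapse a confusion matrix across stimuli into a distance tuning curve.

    ``probs[d]`` is the mean of all entries (i, j) whose circular class
    difference (predicted minus true) equals offset ``d``.  For classes on
    a uniform circular grid each offset pools exactly K cells (the K
    wrapped diagonals of the matrix).
    """
    mat = m.matrix if isinstance(m, RepresentationMatrix) else np.asarray(m, float)
    k = mat.shape[0]
    step = 360.0 / k
    offsets, probs = [], []
    for shift in range(k):
        idx_i = np.arange(k)
        idx_j = (idx_i + shift) % k
        offsets.append(circular_difference(shift * step, 0.0))
        probs.append(mat[idx_i, idx_j].mean())
    order = np.argsort(offsets)
    return TuningCurve(np.asarray(offsets)[order], np.asarray(probs)[order])


def bimodality_index(tc: TuningCurve) -> BimodalityIndex:
    """Bimodality of a tuning curve on the 45-degree (K = 8) offset grid.

    The difference between the opposite (180 degree) and the mean of the
    next-to-opposite (135 / 225, i.e. +-135) probabilities, normalized by
    the curve's range.  A flat curve has index 0 by convention.
    """
    try:
        p_opp = tc.value_at(180.0)
        p_next = 0.5 * (tc.value_at(135.0) + tc.value_at(-135.0))
    except ValueError as err:
        raise ValueError(
            "tuning curve lacks the 135/180/225 degree offsets needed for "
            "the bimodality index"
        ) from err
    p_max = float(tc.probs.max())
    p_min = float(tc.probs.min())
    if p_max > p_min:
        value = (p_opp - p_next) / (p_max - p_min)
    else:
        value = 0.0
    return BimodalityIndex(float(value), p_opp, p_next, p_max, p_min)


def bimodality_group_test(indices) -> float:
    """One-sided one-sample t-test of bimodality indices against zero.

    Tests whether the group mean index is positive.  A zero-variance
    sample is degenerate: returns 1.0 (no positive evidence) when the
    common value is <= 0, else 0.0, with a warning.
    """
    x = np.asarray(indices, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values")
    if np.ptp(x) == 0:
        warnings.warn("zero-variance bimodality sample", RuntimeWarning)
        return 1.0 if x[0] <= 0 else 0.0
    res = sps.ttest_1samp(x, 0.0, alternative="greater")
    return float(res.pvalue)


def similarity_vs_bimodality_regression(
    similarities: dict[tuple[str, str], float],
    bimodality: dict[str, float],
) -> tuple[float, float, float]:
    """Regress pairwise similarity on absolute bimodality differences.

    ``similarities`` maps unordered entity pairs (area x signal-class
    combinations) to their representational similarity r; ``bimodality``
    maps each entity to its index.  Returns (R^2, regression p of the
    slope, slope).  A constant predictor is degenerate: R^2 = 0, p = NaN.
    """
    pairs = list(similarities)
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs")
    y = np.array([similarities[p] for p in pairs], dtype=float)
    x = np.array(
        [abs(bimodality[a] - bimodality[b]) for a, b in pairs], dtype=float
    )
    if np.ptp(x) == 0:
        warnings.warn("constant bimodality differences", RuntimeWarning)
        return 0.0, float("nan"), 0.0
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return float(model.rsquared), float(model.pvalues[1]), float(model.params[1])


@dataclass
class SingleChannelTuningResult:
    mean_curve: TuningCurve | None
    per_channel_bimodality: np.ndarray
    group_p: float
    selected: np.ndarray
    class_angles: np.ndarray


def single_channel_tuning(
    epoched: EpochedData,
    feature: str = "motion",
    response_window: tuple[float, float] = (50.0, 250.0),
    alpha: float = 0.05,
    response: str = "mean",
) -> SingleChannelTuningResult:
    """Aligned average tuning of individual channels.

    Per channel, the response to each class is the mean amplitude (or mean
    squared amplitude, ``response="power"``, for LFP-like signals) in the
    response window.  Channels with a one-way ANOVA class effect at
    p < ``alpha`` are kept, their tuning curves aligned so the preferred
    stimulus (highest response; ties broken toward the lowest class angle)
    sits at offset 0, and averaged.  Channel-wise bimodality indices are
    tested against zero (one-sided).
    """
    mask = (epoched.time >= response_window[0]) & (epoched.time <= response_window[1])
    if not mask.any():
        raise ValueError("response window outside the epoch")
    y = epoched.labels(feature)
    classes = np.unique(y)
    k = classes.size
    step = 360.0 / k
    seg = epoched.data[:, :, mask]
    resp = seg.mean(axis=2) if response == "mean" else (seg**2).mean(axis=2)

    selected = np.zeros(epoched.n_channels, dtype=bool)
    aligned_curves, bis = [], []
    for c in range(epoched.n_channels):
        groups = [resp[y == cls, c] for cls in classes]
        stat = sps.f_oneway(*groups)
        if not np.isfinite(stat.pvalue) or stat.pvalue >= alpha:
            continue
        selected[c] = True
        curve = np.array([g.mean() for g in groups])
        pref = int(np.argmax(curve))  # first max = lowest class angle
        shifted = np.roll(curve, -pref)
        offsets = np.array(
            [circular_difference(i * step, 0.0) for i in range(k)]
        )
        order = np.argsort(offsets)
        tc = TuningCurve(offsets[order], shifted[order])
        aligned_curves.append(tc.probs)
        bis.append(bimodality_index(tc).value)

    if not aligned_curves:
        return SingleChannelTuningResult(
            None, np.array([]), float("nan"), selected, classes
        )
    offsets_sorted = np.sort(
        np.array([circular_difference(i * step, 0.0) for i in range(k)])
    )
    mean_curve = TuningCurve(offsets_sorted, np.mean(aligned_curves, axis=0))
    bis = np.asarray(bis)
    group_p = bimodality_group_test(bis) if bis.size >= 3 else float("nan")
    return SingleChannelTuningResult(mean_curve, bis, group_p, selected, classes)
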