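"""Inference on information timecourses.

Three families of procedures:

* **Cluster sign permutation.**  After subtracting chance, temporally
  contiguous clusters are formed where a one-tailed t-test over sessions
  beats the cluster-forming alpha (default 0.01).  The null multiplies each
  session's timecourse with a random sign; the maximum cluster mass (summed
  t-values) per permutation calibrates the observed clusters' p-values with
  the (b + 1) / (m + 1) convention.  Sign flipping is exact under the null
  of symmetrically distributed chance-level information.

* **Latency estimation.**  Sessions are normalized to peak 1 above chance
  and kept only when the post-stimulus peak exceeds 1.5x the largest
  absolute baseline deviation.  The peak is the first post-stimulus local
  maximum reaching 75 % of the global maximum; the latency is the half-peak
  crossing, linearly interpolated between the bracketing samples.  Group
  CIs come from bootstrapping sessions; group contrasts from label
  permutations.

* **Latency-position correlation** between source coordinates and their
  estimated latencies, over sources with significant information.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .containers import InformationTimecourse

__all__ = [
    "Cluster",
    "ClusterTestResult",
    "LatencyEstimate",
    "cluster_sign_permutation",
    "bonferroni_correct",
    "normalize_and_select",
    "estimate_latency",
    "group_latency",
    "bootstrap_latency_ci",
    "latency_difference_permutation",
    "latency_position_correlation",
]


@dataclass
class Cluster:
    start_ms: float
    end_ms: float
    mass: float
    p_value: float


@dataclass
class ClusterTestResult:
    clusters: list[Cluster]
    n_permutations: int
    cluster_alpha: float

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value < 0.05]

    def min_p(self) -> float:
        return min((c.p_value for c in self.clusters), default=1.0)


def _session_matrix(sessions) -> tuple[np.ndarray, np.ndarray, float]:
    time = sessions[0].time
    chance = sessions[0].chance
    for s in sessions[1:]:
        if not np.array_equal(s.time, time):
            raise ValueError("sessions must share a time axis")
    x = np.stack([s.values - s.chance for s in sessions])
    return x, time, chance


def _t_rows(x_rows: np.ndarray, n: int, sumsq: np.ndarray) -> np.ndarray:
    """One-sample t statistics for many sign-flip replicates at once.

    Sign flips leave per-session squares unchanged, so the second moment
    ``sumsq`` is shared across replicates and only the means vary.
    """
    mean = x_rows
    var = (sumsq / n - mean**2) * n / (n - 1)
    var = np.maximum(var, 1e-300)
    return mean / np.sqrt(var / n)


def _max_cluster_masses(trows: np.ndarray, t_crit: np.ndarray | float) -> np.ndarray:
    """Max summed-t cluster mass per row of a (replicates x time) t array."""
    trows = np.atleast_2d(trows)
    r, t = trows.shape
    mask = np.zeros((r, t + 1), dtype=bool)
    mask[:, :t] = trows > t_crit
    flat = mask.ravel()
    d = np.diff(flat.astype(np.int8), prepend=0)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    tflat = np.concatenate([trows, np.zeros((r, 1))], axis=1).ravel()
    csum = np.concatenate([[0.0], np.cumsum(tflat)])
    masses = csum[ends] - csum[starts]
    out = np.zeros(r)
    np.maximum.at(out, starts // (t + 1), masses)
    return out


def cluster_sign_permutation(
    sessions: list[InformationTimecourse],
    cluster_alpha: float = 0.01,
    n_perm: int = 10000,
    seed: int = 0,
) -> ClusterTestResult:
    """Cluster-based sign-permutation test of above-chance information.

    Chance is subtracted per session first; clusters are contiguous runs
    where the one-tailed one-sample t-test over sessions has
    p < ``cluster_alpha``.  Each observed cluster's p-value is the fraction
    of sign-flip permutations whose *maximum* cluster mass reaches its
    mass, with the +1 correction.
    """
    if len(sessions) < 3:
        raise ValueError("need at least 3 sessions for the t-test")
    x, time, _ = _session_matrix(sessions)
    n, n_t = x.shape
    t_crit = sps.t.ppf(1.0 - cluster_alpha, df=n - 1)
    sumsq = (x**2).sum(axis=0)
    t_obs = _t_rows(x.mean(axis=0), n, sumsq)

    # observed clusters
    mask = np.concatenate([t_obs > t_crit, [False]])
    d = np.diff(mask.astype(np.int8), prepend=0)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    masses = [t_obs[a:b].sum() for a, b in zip(starts, ends)]

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    mean_perm = signs @ x / n
    t_perm = _t_rows(mean_perm, n, sumsq)
    null_max = _max_cluster_masses(t_perm, t_crit)

    clusters = []
    for a, b, m in zip(starts, ends, masses):
        p = (np.count_nonzero(null_max >= m) + 1) / (n_perm + 1)
        clusters.append(Cluster(float(time[a]), float(time[b - 1]), float(m), float(p)))
    return ClusterTestResult(clusters, n_perm, cluster_alpha)


def bonferroni_correct(results: dict[str, ClusterTestResult]) -> dict[str, ClusterTestResult]:
    """Bonferroni-correct cluster p-values across regions (in place copy)."""
    k = len(results)
    out = {}
    for name, res in results.items():
        clusters = [
            Cluster(c.start_ms, c.end_ms, c.mass, min(1.0, c.p_value * k))
            for c in res.clusters
        ]
        out[name] = ClusterTestResult(clusters, res.n_permutations, res.cluster_alpha)
    return out


def normalize_and_select(
    sessions: list[InformationTimecourse],
    inclusion_ratio: float = 1.5,
) -> tuple[list[InformationTimecourse], np.ndarray]:
    """Normalize sessions to peak 1 and flag which enter the latency analysis.

    Normalization maps chance to 0 and the post-stimulus peak to 1.  A
    session is included when its post-stimulus peak above chance is at
    least ``inclusion_ratio`` times the largest absolute deviation from
    chance during the pre-stimulus baseline (t < 0).  Degenerate sessions
    (no positive post-stimulus peak) are excluded.
    """
    normalized, included = [], []
    for s in sessions:
        pre = s.time < 0
        post = s.time >= 0
        if not pre.any():
            raise ValueError("time axis has no pre-stimulus baseline samples")
        dev = s.values - s.chance
        peak = dev[post].max() if post.any() else -np.inf
        base = np.abs(dev[pre]).max()
        ok = peak > 0 and peak >= inclusion_ratio * base
        vals = dev / peak if peak > 0 else np.zeros_like(dev)
        normalized.append(
            InformationTimecourse(vals, s.time, chance=0.0, session_id=s.session_id)
        )
        included.append(ok)
    return normalized, np.asarray(included, dtype=bool)


@dataclass
class LatencyEstimate:
    latency_ms: float
    peak_time_ms: float
    peak_value: float
    defined: bool = True
    ci_low_ms: float = field(default=np.nan)
    ci_high_ms: float = field(default=np.nan)


def estimate_latency(
    tc: InformationTimecourse, peak_fraction: float = 0.75
) -> LatencyEstimate:
    """Half-peak latency of a normalized information timecourse.

    The peak is the first post-stimulus local maximum reaching at least
    ``peak_fraction`` of the global post-stimulus maximum (so an early
    shoulder below 75 % of the main peak is skipped, while an early peak
    above it wins even when a later peak is higher).  The latency is the
    first time the curve reaches half the chosen peak's value, linearly
    interpolated between the bracketing samples.
    """
    post = tc.time >= 0
    if not post.any():
        raise ValueError("no post-stimulus samples")
    v = tc.values[post]
    t = tc.time[post]
    gmax = v.max()
    if gmax <= 0:
        return LatencyEstimate(np.nan, np.nan, np.nan, defined=False)
    peak_idx = None
    for i in range(v.size):
        left_ok = i == 0 or v[i] >= v[i - 1]
        right_ok = i == v.size - 1 or v[i] >= v[i + 1]
        if left_ok and right_ok and v[i] >= peak_fraction * gmax:
            peak_idx = i
            break
    if peak_idx is None:
        return LatencyEstimate(np.nan, np.nan, np.nan, defined=False)
    half = 0.5 * v[peak_idx]
    # half-peak crossing on the rising flank of the chosen peak: walk back
    # to the last sample below half, then interpolate the crossing.  (A
    # forward scan could latch onto an earlier sub-threshold bump that the
    # 75 % rule deliberately skipped.)
    below = None
    for i in range(peak_idx, -1, -1):
        if v[i] < half:
            below = i
            break
    if below is None:
        lat = float(t[0])  # at or above half throughout the post window
    else:
        t0, t1 = t[below], t[below + 1]
        v0, v1 = v[below], v[below + 1]
        lat = float(t0 + (half - v0) / (v1 - v0) * (t1 - t0))
    return LatencyEstimate(lat, float(t[peak_idx]), float(v[peak_idx]), True)


def group_latency(
    normalized_sessions: list[InformationTimecourse],
) -> LatencyEstimate:
    """Latency of the session-mean normalized timecourse."""
    x, time, _ = _session_matrix(normalized_sessions)
    mean_tc = InformationTimecourse(x.mean(axis=0), time, chance=0.0)
    return estimate_latency(mean_tc)


def bootstrap_latency_ci(
    normalized_sessions: list[InformationTimecourse],
    n_boot: int = 10000,
    seed: int = 0,
) -> tuple[float, float]:
    """95 % bootstrap CI of the group latency (resampling sessions)."""
    if len(normalized_sessions) < 2:
        raise ValueError("need at least 2 sessions to bootstrap")
    rng = np.random.default_rng(seed)
    n = len(normalized_sessions)
    lats = np.full(n_boot, np.nan)
    for b in range(n_boot):
        draw = rng.integers(0, n, size=n)
        est = group_latency([normalized_sessions[i] for i in draw])
        if est.defined:
            lats[b] = est.latency_ms
    lats = lats[np.isfinite(lats)]
    if lats.size == 0:
        return (np.nan, np.nan)
    lo, hi = np.percentile(lats, [2.5, 97.5])
    return float(lo), float(hi)


def latency_difference_permutation(
    group_a: list[InformationTimecourse],
    group_b: list[InformationTimecourse],
    n_perm: int = 10000,
    seed: int = 0,
) -> tuple[float, float]:
    """Two-sided permutation p for the group-latency difference A - B.

    Group latencies are recomputed after each reshuffle of the group
    labels; permutations where either group latency is undefined are
    counted as extreme (conservative).  Returns (observed difference, p).
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    la = group_latency(group_a)
    lb = group_latency(group_b)
    if not (la.defined and lb.defined):
        raise ValueError("group latency undefined for the observed grouping")
    obs = la.latency_ms - lb.latency_ms
    pool = list(group_a) + list(group_b)
    na = len(group_a)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        order = rng.permutation(len(pool))
        pa = [pool[i] for i in order[:na]]
        pb = [pool[i] for i in order[na:]]
        ea, eb = group_latency(pa), group_latency(pb)
        if not (ea.defined and eb.defined):
            count += 1
            continue
        if abs(ea.latency_ms - eb.latency_ms) >= abs(obs) - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return obs, float(p)


def latency_position_correlation(
    latencies: np.ndarray,
    positions: np.ndarray,
    mask: np.ndarray | None = None,
) -> tuple[float, float]:
    """Pearson correlation between source position and latency.

    ``mask`` restricts to sources with significant information (e.g.
    cluster permutation p < 0.05).  Undefined (NaN) latencies are dropped.
    Returns (r, p) from the standard correlation test.
    """
    latencies = np.asarray(latencies, dtype=float)
    positions = np.asarray(positions, dtype=float)
    keep = np.isfinite(latencies)
    if mask is not None:
        keep &= np.asarray(mask, dtype=bool)
    if keep.sum() < 3:
        raise ValueError("need at least 3 masked sources")
    r, p = sps.pearsonr(positions[keep], latencies[keep])
    return float(r), float(p)
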