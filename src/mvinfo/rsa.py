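"""Representational similarity between time-averaged confusion matrices.

A signal's representational structure is summarized by its confusion
matrix averaged over the window in which stimulus information is available
(default 50-250 ms).  Two structures are compared by the Pearson
correlation of their off-diagonal entries (the diagonal -- raw accuracy --
is removed, both off-diagonal triangles are kept since confusions need not
be symmetric).  Significance comes from a permutation null in which one
matrix's stimulus labels are randomly reassigned to its rows and columns
simultaneously; the two-sided p-value is the fraction of permutations
whose |r| reaches the observed |r|, with the +1 correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .containers import ConfusionTensor

__all__ = [
    "RepresentationMatrix",
    "SimilarityResult",
    "time_average_confusion",
    "representational_similarity",
    "rsa_permutation_test",
]


@dataclass
class RepresentationMatrix:
    """K x K time-averaged confusion matrix with a source descriptor."""

    matrix: np.ndarray
    descriptor: str = ""
    window: tuple[float, float] = (50.0, 250.0)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("matrix must be square")

    @property
    def n_classes(self) -> int:
        return self.matrix.shape[0]


@dataclass
class SimilarityResult:
    r: float
    p: float
    n_permutations: int
    null_r: np.ndarray | None = field(default=None, repr=False)


def time_average_confusion(
    conf: ConfusionTensor,
    window: tuple[float, float] = (50.0, 250.0),
    descriptor: str = "",
) -> RepresentationMatrix:
    """Arithmetic mean of the confusion matrices over the given time window."""
    mask = conf.time_mask(window)
    if not mask.any():
        raise ValueError(f"no time points inside window {window}")
    return RepresentationMatrix(
        conf.probs[mask].mean(axis=0), descriptor=descriptor, window=window
    )


def _as_matrix(x) -> np.ndarray:
    return x.matrix if isinstance(x, RepresentationMatrix) else np.asarray(x, float)


def _offdiag(m: np.ndarray) -> np.ndarray:
    k = m.shape[0]
    return m[~np.eye(k, dtype=bool)]


def representational_similarity(a, b) -> float:
    """Pearson correlation over the K(K-1) off-diagonal cells of two matrices.

    Returns NaN (with a warning) when either off-diagonal is constant, in
    which case the correlation is undefined.
    """
    ma, mb = _as_matrix(a), _as_matrix(b)
    if ma.shape != mb.shape:
        raise ValueError("matrices must have the same shape")
    va, vb = _offdiag(ma), _offdiag(mb)
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        warnings.warn("constant off-diagonal: similarity undefined", RuntimeWarning)
        return float("nan")
    r, _ = sps.pearsonr(va, vb)
    return float(r)


def rsa_permutation_test(
    a, b, n_perm: int = 10000, seed: int = 0
) -> SimilarityResult:
    """Permutation test of representational similarity.

    Each permutation draws one label permutation and applies it to the rows
    and columns of ``b`` simultaneously before recomputing the off-diagonal
    correlation with ``a``.  Permutations are sampled with replacement, so
    ``n_perm`` may exceed K!.
    """
    ma, mb = _as_matrix(a), _as_matrix(b)
    r_obs = representational_similarity(ma, mb)
    if not np.isfinite(r_obs):
        raise ValueError("similarity undefined (constant off-diagonal)")
    rng = np.random.default_rng(seed)
    k = ma.shape[0]
    va = _offdiag(ma)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(k)
        mp = mb[np.ix_(perm, perm)]
        vp = _offdiag(mp)
        if np.ptp(vp) == 0:
            null[i] = 0.0
        else:
            null[i] = sps.pearsonr(va, vp)[0]
    count = np.count_nonzero(np.abs(null) >= abs(r_obs) - 1e-12)
    p = (count + 1) / (n_perm + 1)
    return SimilarityResult(float(r_obs), float(p), n_perm, null_r=null)
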