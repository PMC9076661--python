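"""Zero-gap global alignment of two fragment-ion lists.

Given the interspectral similarity quadrant S^XY, the alignment score is
the terminal value of the Needleman–Wunsch recurrence with a fixed gap
penalty of zero:

    A(i, j) = max( A(i-1, j-1) + S_ij,  A(i-1, j),  A(i, j-1) )

with A(i, 0) = A(0, j) = 0.  Because gaps are free, the score equals the
best total similarity over all monotone matchings of fragments (pairs
with both indices strictly increasing), floored at zero.

Three entry points share this definition: :func:`align_dp` computes the
full DP table and traceback, :func:`align_score_fast` computes the score
only via at most min(m, n) rounds of vectorized element-wise and rolling
(prefix) maxima, and :func:`align_score_batch` applies the same scheme
to a stack of matrices at once — the workhorse of the permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

__all__ = ["AlignmentResult", "align_dp", "align_score_fast", "align_score_batch"]


@dataclass(frozen=True)
class AlignmentResult:
    """An optimal zero-gap alignment.

    ``pairs`` lists matched fragment indices (i, j), both strictly
    increasing, 0-based; ``contributing`` holds the corresponding
    S^XY[i, j] entries, whose sum is ``score``.  Only diagonal moves
    that strictly increase the DP value are recorded, so every recorded
    pair has a positive contribution and ``n_matched`` (the matching-ion
    count used by downstream cutoffs) equals ``len(pairs)``.
    """

    score: float
    pairs: tuple[tuple[int, int], ...]
    contributing: tuple[float, ...] = field(default=())

    @property
    def n_matched(self) -> int:
        return len(self.pairs)


def _check_finite(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ParameterError("similarity matrix contains non-finite entries")
    return arr


def align_dp(s_xy: np.ndarray) -> AlignmentResult:
    """Full dynamic program with traceback.

    Traceback tie-breaking is diagonal over up over left, which yields
    the co-optimal path with the most aligned pairs; deterministic.
    """
    S = _check_finite(s_xy)
    if S.ndim != 2 or S.shape[0] < 1 or S.shape[1] < 1:
        raise ParameterError("expected a 2-D matrix with at least one row and column")
    m, n = S.shape
    A = np.zeros((m + 1, n + 1))
    for i in range(1, m + 1):
        diag = A[i - 1, :-1] + S[i - 1]
        up = A[i - 1, 1:]
        row = A[i]
        for j in range(1, n + 1):
            row[j] = max(diag[j - 1], up[j - 1], row[j - 1])
    pairs: list[tuple[int, int]] = []
    contributing: list[float] = []
    i, j = m, n
    while i > 0 and j > 0:
        here = A[i, j]
        if here == A[i - 1, j - 1] + S[i - 1, j - 1]:
            if here > A[i - 1, j - 1]:  # strict increase: a real match
                pairs.append((i - 1, j - 1))
                contributing.append(float(S[i - 1, j - 1]))
            i, j = i - 1, j - 1
        elif here == A[i - 1, j]:
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    contributing.reverse()
    return AlignmentResult(
        score=float(A[m, n]), pairs=tuple(pairs), contributing=tuple(contributing)
    )


def _chain_score(stack: np.ndarray) -> np.ndarray:
    """Score-only alignment over the last two axes of ``stack``.

    Iteratively grows E_t(i, j), the best sum over monotone chains of at
    most t pairs ending exactly at (i, j):

        E_1 = S
        E_t = S + max(0, rolling-max of E_{t-1} over the strict
                          upper-left rectangle)

    E_t is element-wise non-decreasing in t and chains have at most
    min(m, n) pairs, so min(m, n) rounds suffice; the loop exits early
    once E stops changing.  The score is max(0, max E).
    """
    m, n = stack.shape[-2], stack.shape[-1]
    E = stack.copy()
    for _ in range(min(m, n) - 1):
        prefix = np.maximum.accumulate(np.maximum.accumulate(E, axis=-2), axis=-1)
        shifted = np.zeros_like(E)
        shifted[..., 1:, 1:] = np.maximum(prefix[..., :-1, :-1], 0.0)
        E_next = stack + shifted
        if np.array_equal(E_next, E):
            break
        E = E_next
    return np.maximum(E.max(axis=(-2, -1)), 0.0)


def align_score_fast(s_xy: np.ndarray) -> float:
    """Alignment score without traceback; equals ``align_dp(s_xy).score``."""
    S = _check_finite(s_xy)
    if S.ndim != 2 or S.shape[0] < 1 or S.shape[1] < 1:
        raise ParameterError("expected a 2-D matrix with at least one row and column")
    return float(_chain_score(S))


def align_score_batch(stack: np.ndarray) -> np.ndarray:
    """Alignment scores for a k x m x n stack of similarity quadrants."""
    arr = np.asarray(stack, dtype=float)
    if arr.ndim != 3:
        raise ParameterError("expected a 3-D stack of matrices")
    if arr.shape[0] == 0:
        return np.empty(0)
    if not np.all(np.isfinite(arr)):
        raise ParameterError("similarity stack contains non-finite entries")
    return _chain_score(arr)
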