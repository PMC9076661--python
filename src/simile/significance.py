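"""Monte Carlo permutation significance of an alignment score.

The null hypothesis is that m/z values are exchangeable between the two
spectra as long as both hypothetical spectra X' and Y' remain m/z
ordered.  A null draw therefore picks a size-m subset of the m+n
concatenated m/z values for X' (sorted), leaves the rest to Y' (sorted),
permutes the rows and columns of the full similarity matrix S
symmetrically according to the induced index permutation, and re-scores
the new interspectral quadrant with the zero-gap alignment.

The p-value is max(#(null >= observed) / k, 1/k) after k draws, with
ties counted conservatively.  Evaluation proceeds in stages (10, 100,
1000 draws by default) and stops early once the p-value fails to
improve twofold between stages — unless the current estimate sits at
its resolution floor 1/k, in which case the next stage is still run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .alignment import align_score_batch
from .errors import ParameterError

__all__ = [
    "PermutationPlan",
    "PValueResult",
    "DEFAULT_SCHEDULE",
    "sample_order_preserving_permutation",
    "permuted_score",
    "monte_carlo_pvalue",
]

DEFAULT_SCHEDULE: tuple[int, ...] = (10, 100, 1000)


@dataclass(frozen=True)
class PermutationPlan:
    """An order-preserving reassignment of concatenated m/z indices.

    ``perm`` is a bijection of 0..m+n-1; its first m entries index m/z
    values in ascending order (the hypothetical X') and its last n
    entries likewise (Y').
    """

    perm: np.ndarray
    m: int
    n: int


def _as_rng(rng) -> np.random.Generator:
    if rng is None:
        raise ParameterError(
            "an explicit seed or numpy Generator is required for reproducibility"
        )
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def sample_order_preserving_permutation(
    concat_mz: np.ndarray, m: int, n: int, rng
) -> PermutationPlan:
    """Uniformly sample one of the C(m+n, m) order-preserving plans."""
    rng = _as_rng(rng)
    concat_mz = np.asarray(concat_mz, dtype=float)
    if concat_mz.size != m + n:
        raise ParameterError("concat_mz length must equal m + n")
    chosen = rng.choice(m + n, size=m, replace=False)
    mask = np.zeros(m + n, dtype=bool)
    mask[chosen] = True
    x_idx = np.flatnonzero(mask)
    y_idx = np.flatnonzero(~mask)
    # order each block by m/z value (the concatenated list is only
    # sorted within its original blocks, not globally)
    x_idx = x_idx[np.argsort(concat_mz[x_idx], kind="stable")]
    y_idx = y_idx[np.argsort(concat_mz[y_idx], kind="stable")]
    return PermutationPlan(perm=np.concatenate([x_idx, y_idx]), m=m, n=n)


def _permutation_batch(
    concat_mz: np.ndarray, m: int, n: int, rng: np.random.Generator, k: int
) -> np.ndarray:
    """k order-preserving permutations as a k x (m+n) index array."""
    total = m + n
    perms = np.empty((k, total), dtype=np.intp)
    for s in range(k):
        plan = sample_order_preserving_permutation(concat_mz, m, n, rng)
        perms[s] = plan.perm
    return perms


def permuted_score(S: np.ndarray, plan: PermutationPlan) -> float:
    """Alignment score of the symmetrically permuted interspectral quadrant."""
    S = np.asarray(S, dtype=float)
    total = plan.m + plan.n
    if S.shape != (total, total):
        raise ParameterError(
            f"similarity matrix shape {S.shape} does not match plan size {total}"
        )
    quadrant = S[np.ix_(plan.perm[: plan.m], plan.perm[plan.m :])]
    return float(align_score_batch(quadrant[None])[0])


@dataclass(frozen=True)
class PValueResult:
    """Monte Carlo p-value with its evaluation trace."""

    pvalue: float
    iterations: int
    null_scores: np.ndarray
    stopped_early: bool


def monte_carlo_pvalue(
    S: np.ndarray,
    concat_mz: np.ndarray,
    m: int,
    n: int,
    observed: float,
    schedule: Sequence[int] = DEFAULT_SCHEDULE,
    rng=None,
) -> PValueResult:
    """Staged Monte Carlo estimate of P(null score >= observed).

    ``schedule`` lists cumulative draw counts (strictly increasing).
    After each stage, p = max(c/k, 1/k) where c counts null scores >=
    the observed score over all k draws so far.  The next stage runs
    only if p at least halved relative to the previous stage or p sits
    at its floor 1/k; otherwise evaluation stops early.
    """
    if not np.isfinite(observed):
        raise ParameterError("observed score must be finite")
    schedule = [int(s) for s in schedule]
    if not schedule or any(s <= 0 for s in schedule) or any(
        b <= a for a, b in zip(schedule, schedule[1:])
    ):
        raise ParameterError("schedule must be strictly increasing positive integers")
    rng = _as_rng(rng)
    S = np.asarray(S, dtype=float)

    null_scores: list[np.ndarray] = []
    done = 0
    count_ge = 0
    prev_p = None
    pvalue = 1.0
    stopped_early = False
    for stage_idx, target in enumerate(schedule):
        batch = target - done
        perms = _permutation_batch(concat_mz, m, n, rng, batch)
        quadrants = S[perms[:, :m, None], perms[:, None, m:]]
        scores = align_score_batch(quadrants)
        null_scores.append(scores)
        count_ge += int(np.count_nonzero(scores >= observed))
        done = target
        pvalue = max(count_ge / done, 1.0 / done)
        at_floor = count_ge <= 1
        if stage_idx < len(schedule) - 1:
            if prev_p is not None and not (pvalue <= prev_p / 2 or at_floor):
                stopped_early = True
                break
        prev_p = pvalue
    return PValueResult(
        pvalue=pvalue,
        iterations=done,
        null_scores=np.concatenate(null_scores),
        stopped_early=stopped_early,
    )
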