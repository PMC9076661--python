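"""Pair-specific fragment-ion similarity matrices.

For two spectra X (m fragments) and Y (n fragments) the chain is

    D -> C -> T -> p -> L -> S

* ``D`` — all pairwise signed m/z differences of the concatenated m/z
  list (row minus column), an (m+n) x (m+n) antisymmetric matrix.
* ``C`` — per-entry frequency of each difference within its own spectral
  block: an entry in the top m rows counts how often its difference
  recurs anywhere in the top m x (m+n) block (within a tolerance
  window), and likewise for the bottom n rows.  Every entry matches
  itself, so C >= 1 everywhere.
* ``T`` — row-normalized C, a Markov transition matrix over fragment
  ions; ``p`` its stationary distribution (pT = p).
* ``L`` — the directed graph Laplacian P^{1/2} (I - T) P^{-1/2}.
* ``S`` — the Moore–Penrose pseudoinverse of the symmetrized Laplacian
  (L + L^T)/2.  S acts as a covariance matrix with respect to Euclidean
  commute-time distance: two fragment ions score as similar when they
  are linked by many paths of frequently recurring m/z differences.

The interspectral quadrant ``S^XY`` feeds the zero-gap alignment in
:mod:`simile.alignment`; the full matrix is what the permutation test in
:mod:`simile.significance` shuffles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .errors import DegeneracyError, NumericalError, ParameterError
from .spectra_io import FragmentationSpectrum

__all__ = [
    "SpectrumPair",
    "DifferenceMatrix",
    "CountMatrix",
    "MarkovModel",
    "SimilarityDecomposition",
    "pairwise_difference_matrix",
    "mz_difference_counts",
    "transition_matrix",
    "stationary_distribution",
    "directed_graph_laplacian",
    "similarity_matrix",
    "decompose_pair",
    "dump_matrix",
]

DEFAULT_TOLERANCE = 0.01  # Th; suitable for high-resolution spectra
_STATIONARY_TOL = 1e-8
_TELEPORT_ALPHA = 1e-8
_PINV_RCOND_SCALE = 1e-12


@dataclass(frozen=True)
class SpectrumPair:
    """Two spectra and their concatenated m/z list (X first, then Y)."""

    x: FragmentationSpectrum
    y: FragmentationSpectrum

    def __post_init__(self):
        for spec in (self.x, self.y):
            if not spec.is_canonical:
                raise ParameterError(
                    f"spectrum {spec.spectrum_id!r} is not canonical "
                    "(m/z must be strictly ascending and positive)"
                )

    @property
    def m(self) -> int:
        return len(self.x)

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def concat_mz(self) -> np.ndarray:
        return np.concatenate([self.x.mz, self.y.mz])


@dataclass(frozen=True)
class DifferenceMatrix:
    """Signed pairwise m/z differences, row minus column."""

    D: np.ndarray
    m: int
    n: int


@dataclass(frozen=True)
class CountMatrix:
    """Block-wise m/z difference frequencies; every entry >= 1."""

    C: np.ndarray
    m: int
    n: int
    tolerance: float


@dataclass(frozen=True)
class MarkovModel:
    """Row-stochastic transition matrix and its stationary distribution."""

    T: np.ndarray
    p: np.ndarray


@dataclass(frozen=True)
class SimilarityDecomposition:
    """Directed graph Laplacian L and similarity matrix S with quadrants."""

    L: np.ndarray
    S: np.ndarray
    m: int
    n: int

    @property
    def s_xx(self) -> np.ndarray:
        return self.S[: self.m, : self.m]

    @property
    def s_xy(self) -> np.ndarray:
        return self.S[: self.m, self.m :]

    @property
    def s_yx(self) -> np.ndarray:
        return self.S[self.m :, : self.m]

    @property
    def s_yy(self) -> np.ndarray:
        return self.S[self.m :, self.m :]


def pairwise_difference_matrix(pair: SpectrumPair) -> DifferenceMatrix:
    """Outer difference of the concatenated m/z list.

    ``D[i, j] = concat_mz[i] - concat_mz[j]`` so the top-right m x n
    quadrant holds X minus Y.  D is antisymmetric with a zero diagonal.
    """
    mz = pair.concat_mz
    D = np.subtract.outer(mz, mz)
    return DifferenceMatrix(D=D, m=pair.m, n=pair.n)


def mz_difference_counts(diff: DifferenceMatrix, tolerance: float = DEFAULT_TOLERANCE) -> CountMatrix:
    """Count how often each signed difference recurs within its block.

    For an entry in the top m rows, the count is taken over the entire
    top m x (m+n) block of D; for the bottom n rows, over the bottom
    block.  A difference within ``tolerance`` (inclusive) of the entry's
    own value is counted, so each entry counts at least itself.
    """
    if tolerance < 0:
        raise ParameterError("tolerance must be >= 0")
    D, m, n = diff.D, diff.m, diff.n
    C = np.empty_like(D)
    for block in (slice(0, m), slice(m, m + n)):
        values = np.sort(D[block].ravel())
        queries = D[block].ravel()
        counts = np.searchsorted(values, queries + tolerance, side="right") - np.searchsorted(
            values, queries - tolerance, side="left"
        )
        C[block] = counts.reshape(D[block].shape)
    return CountMatrix(C=C.astype(float), m=m, n=n, tolerance=tolerance)


def transition_matrix(counts: CountMatrix) -> np.ndarray:
    """Normalize each row of C to sum to one."""
    C = counts.C
    row_sums = C.sum(axis=1)
    if np.any(row_sums <= 0):
        raise NumericalError("count matrix has a nonpositive row sum")
    return C / row_sums[:, None]


def _principal_left_eigenvector(T: np.ndarray) -> np.ndarray | None:
    eigvals, eigvecs = scipy.linalg.eig(T.T)
    idx = int(np.argmin(np.abs(eigvals - 1.0)))
    vec = np.real(eigvecs[:, idx])
    total = vec.sum()
    if total == 0:
        return None
    vec = vec / total
    vec = np.clip(vec, 0.0, None)
    s = vec.sum()
    if s == 0:
        return None
    return vec / s


def _power_iteration(T: np.ndarray, max_iter: int = 10_000) -> np.ndarray | None:
    k = T.shape[0]
    p = np.full(k, 1.0 / k)
    for _ in range(max_iter):
        p_next = p @ T
        p_next /= p_next.sum()
        if np.max(np.abs(p_next - p)) < 1e-14:
            return p_next
        p = p_next
    return p if np.max(np.abs(p @ T - p)) <= _STATIONARY_TOL else None


def stationary_distribution(T: np.ndarray) -> np.ndarray:
    """Stationary distribution p with pT = p.

    Computed as the principal left eigenvector of T, renormalized to sum
    to one with round-off negatives clipped to zero.  Falls back to
    power iteration, and as a last resort to a uniformly teleported
    chain ``(1-a) T + a/k`` with a = 1e-8, when the plain solve fails
    (possible only for pathological inputs; counts >= 1 make the chain
    irreducible and aperiodic in normal operation).
    """
    k = T.shape[0]
    if not np.allclose(T.sum(axis=1), 1.0, atol=1e-9):
        raise ParameterError("T is not row-stochastic")
    for candidate_T in (T, (1.0 - _TELEPORT_ALPHA) * T + _TELEPORT_ALPHA / k):
        p = _principal_left_eigenvector(candidate_T)
        if p is not None and np.max(np.abs(p @ T - p)) <= _STATIONARY_TOL:
            return p
        p = _power_iteration(candidate_T)
        if p is not None and np.max(np.abs(p @ T - p)) <= _STATIONARY_TOL:
            return p
    residual = np.max(np.abs(p @ T - p)) if p is not None else np.inf
    raise NumericalError(
        f"stationary distribution did not converge (residual {residual:.3e})"
    )


def directed_graph_laplacian(T: np.ndarray, p: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """Directed graph Laplacian L = P^{1/2} (I - T) P^{-1/2}."""
    small = np.flatnonzero(p <= eps)
    if small.size:
        raise DegeneracyError(
            f"stationary probability vanishes at fragment index {int(small[0])}"
        )
    sqrt_p = np.sqrt(p)
    identity = np.eye(T.shape[0])
    return sqrt_p[:, None] * (identity - T) / sqrt_p[None, :]


def similarity_matrix(L: np.ndarray, m: int, n: int) -> SimilarityDecomposition:
    """Pseudoinverse of the symmetrized Laplacian, with quadrant views.

    Singular values below (m+n) * sigma_max * 1e-12 are treated as zero.
    The result is symmetrized to remove round-off asymmetry.
    """
    sym = 0.5 * (L + L.T)
    S = np.linalg.pinv(sym, rcond=(m + n) * _PINV_RCOND_SCALE, hermitian=True)
    if not np.all(np.isfinite(S)):
        raise NumericalError("pseudoinverse produced non-finite entries")
    S = 0.5 * (S + S.T)
    return SimilarityDecomposition(L=L, S=S, m=m, n=n)


def decompose_pair(
    x: FragmentationSpectrum,
    y: FragmentationSpectrum,
    tolerance: float = DEFAULT_TOLERANCE,
) -> SimilarityDecomposition:
    """Run the full D -> C -> T -> p -> L -> S chain for one spectrum pair."""
    pair = SpectrumPair(x=x, y=y)
    diff = pairwise_difference_matrix(pair)
    counts = mz_difference_counts(diff, tolerance)
    T = transition_matrix(counts)
    p = stationary_distribution(T)
    L = directed_graph_laplacian(T, p)
    return similarity_matrix(L, pair.m, pair.n)


def dump_matrix(matrix: np.ndarray, concat_mz: np.ndarray, sink, delimiter: str = "\t") -> None:
    """Write a pipeline matrix as delimited text with an m/z header row."""
    header = delimiter.join(f"{v:.6f}" for v in concat_mz)
    np.savetxt(sink, matrix, delimiter=delimiter, header=header, fmt="%.10g")
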