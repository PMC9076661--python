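"""Independent brute-force reference implementations used only by tests.

Everything here is deliberately written with nested loops, enumeration
or a different numerical route (eigendecomposition instead of SVD,
linear solve instead of eigenvector extraction) so that agreement with
the package is a genuine cross-check rather than a tautology.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_difference_matrix(x_mz, y_mz):
    concat = list(x_mz) + list(y_mz)
    k = len(concat)
    return np.array([[concat[i] - concat[j] for j in range(k)] for i in range(k)])


def brute_count_matrix(D, m, n, tol):
    k = m + n
    C = np.zeros((k, k))
    for i in range(k):
        rows = range(0, m) if i < m else range(m, k)
        for j in range(k):
            c = 0
            for r in rows:
                for l in range(k):
                    if abs(D[r][l] - D[i][j]) <= tol:
                        c += 1
            C[i, j] = c
    return C


def brute_transition_matrix(C):
    C = np.asarray(C, dtype=float)
    k = C.shape[0]
    T = np.zeros_like(C)
    for i in range(k):
        s = C[i].sum()
        for j in range(k):
            T[i, j] = C[i, j] / s
    return T


def brute_stationary(T):
    """Solve pT = p, sum(p) = 1 as a linear system (not an eigensolver)."""
    k = T.shape[0]
    A = T.T - np.eye(k)
    A[-1, :] = 1.0
    b = np.zeros(k)
    b[-1] = 1.0
    return np.linalg.solve(A, b)


def brute_laplacian(T, p):
    k = T.shape[0]
    L = np.zeros_like(T)
    identity = np.eye(k)
    for i in range(k):
        for j in range(k):
            L[i, j] = np.sqrt(p[i]) * (identity[i, j] - T[i, j]) / np.sqrt(p[j])
    return L


def brute_pseudoinverse(M, rcond=1e-11):
    """Moore–Penrose pseudoinverse via eigendecomposition of a symmetric M."""
    vals, vecs = np.linalg.eigh(M)
    cutoff = rcond * np.max(np.abs(vals))
    inv = np.where(np.abs(vals) > cutoff, 1.0 / np.where(vals == 0, 1.0, vals), 0.0)
    return (vecs * inv) @ vecs.T


def enumerate_monotone_matchings(S):
    """Max sum over all monotone matchings (both indices strictly
    increasing), floored at 0 — exhaustive recursion."""
    m, n = S.shape

    def best_from(i, j):
        if i >= m or j >= n:
            return 0.0
        candidates = [0.0]
        for a in range(i, m):
            for b in range(j, n):
                candidates.append(S[a, b] + best_from(a + 1, b + 1))
        return max(candidates)

    return best_from(0, 0)


def enumerate_order_preserving_plans(concat_mz, m, n):
    """All C(m+n, m) order-preserving index permutations."""
    concat_mz = np.asarray(concat_mz, dtype=float)
    total = m + n
    plans = []
    for subset in itertools.combinations(range(total), m):
        x_idx = sorted(subset, key=lambda i: concat_mz[i])
        y_idx = sorted(set(range(total)) - set(subset), key=lambda i: concat_mz[i])
        plans.append(np.array(x_idx + y_idx))
    return plans


def rebuild_permuted_quadrant(S, perm, m, n):
    """Permuted interspectral quadrant built entry-by-entry by lookup."""
    Q = np.zeros((m, n))
    for i in range(m):
        for j in range(n):
            Q[i, j] = S[perm[i], perm[m + j]]
    return Q
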