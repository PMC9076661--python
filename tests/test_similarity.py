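"""Similarity-matrix chain: D, C, T, p, L, S and their invariants."""

import numpy as np
import pytest

import oracles as orc
from conftest import random_pair
from simile.errors import ParameterError
from simile.similarity import (
    SpectrumPair,
    decompose_pair,
    directed_graph_laplacian,
    mz_difference_counts,
    pairwise_difference_matrix,
    similarity_matrix,
    stationary_distribution,
    transition_matrix,
)
from simile.spectra_io import FragmentationSpectrum


def _pair(x_mz, y_mz):
    x = FragmentationSpectrum("x", max(x_mz) + 1, np.array(x_mz, dtype=float))
    y = FragmentationSpectrum("y", max(y_mz) + 1, np.array(y_mz, dtype=float))
    return SpectrumPair(x=x, y=y)


class TestDifferenceMatrix:
    def test_identical_single_masses(self):
        diff = pairwise_difference_matrix(_pair([100.0], [100.0]))
        np.testing.assert_array_equal(diff.D, np.zeros((2, 2)))

    def test_row_minus_column_orientation(self):
        diff = pairwise_difference_matrix(_pair([100.0, 150.0], [120.0, 170.0]))
        np.testing.assert_allclose(diff.D[0], [0.0, -50.0, -20.0, -70.0])

    def test_antisymmetry(self, rng):
        for _ in range(20):
            x, y = random_pair(rng)
            diff = pairwise_difference_matrix(SpectrumPair(x=x, y=y))
            np.testing.assert_allclose(diff.D + diff.D.T, 0.0, atol=1e-12)


class TestCountMatrix:
    def test_repeated_difference_counted_in_top_block(self):
        # -20 occurs twice in the top block (100-120 and 150-170), and the
        # two diagonal zeros of the top block count each other
        diff = pairwise_difference_matrix(_pair([100.0, 150.0], [120.0, 170.0]))
        counts = mz_difference_counts(diff, 0.01).C
        assert counts[0, 2] == 2 and counts[1, 3] == 2
        assert counts[0, 0] == 2 and counts[1, 1] == 2

    def test_self_match_floor(self, rng):
        x, y = random_pair(rng)
        diff = pairwise_difference_matrix(SpectrumPair(x=x, y=y))
        counts = mz_difference_counts(diff, 0.0).C
        assert np.all(counts >= 1)

    def test_saturation_at_huge_tolerance(self):
        diff = pairwise_difference_matrix(_pair([100.0, 150.0], [120.0, 170.0]))
        counts = mz_difference_counts(diff, 1e6).C
        m, n = 2, 2
        assert np.all(counts[:m] == m * (m + n))
        assert np.all(counts[m:] == n * (m + n))

    def test_negative_tolerance_rejected(self):
        diff = pairwise_difference_matrix(_pair([100.0], [120.0]))
        with pytest.raises(ParameterError):
            mz_difference_counts(diff, -0.1)

    def test_block_independence(self, rng):
        # moving the Y-block m/z values must not change the top-block counts
        x = FragmentationSpectrum("x", 500.0, np.array([100.0, 137.0, 245.0]))
        y1 = FragmentationSpectrum("y", 500.0, np.array([111.0, 202.0]))
        y2 = FragmentationSpectrum("y", 500.0, np.array([111.0 + 37.0, 202.0 + 37.0]))
        c1 = mz_difference_counts(pairwise_difference_matrix(SpectrumPair(x=x, y=y1)), 0.01).C
        c2 = mz_difference_counts(pairwise_difference_matrix(SpectrumPair(x=x, y=y2)), 0.01).C
        # XX differences are untouched; their counts within the top block
        # can change only via XY coincidences, which the shift avoids here
        np.testing.assert_array_equal(c1[:3, :3], c2[:3, :3])


class TestMarkov:
    def test_hand_normalization(self):
        from simile.similarity import CountMatrix

        C = CountMatrix(C=np.array([[2.0, 1.0, 2.0, 1.0]] * 4), m=2, n=2, tolerance=0.01)
        T = transition_matrix(C)
        np.testing.assert_allclose(T[0], [1 / 3, 1 / 6, 1 / 3, 1 / 6])

    def test_uniform_chain_has_uniform_stationary(self):
        T = np.full((4, 4), 0.25)
        np.testing.assert_allclose(stationary_distribution(T), np.full(4, 0.25), atol=1e-10)

    def test_two_state_swap_chain(self):
        T = np.array([[0.0, 1.0], [1.0, 0.0]])
        np.testing.assert_allclose(stationary_distribution(T), [0.5, 0.5], atol=1e-10)

    def test_defining_property_on_random_pairs(self, rng):
        for _ in range(20):
            x, y = random_pair(rng)
            diff = pairwise_difference_matrix(SpectrumPair(x=x, y=y))
            T = transition_matrix(mz_difference_counts(diff, 0.01))
            p = stationary_distribution(T)
            assert p.min() >= 0
            assert p.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.max(np.abs(p @ T - p)) <= 1e-8


class TestLaplacianAndSimilarity:
    def test_uniform_p_reduces_to_i_minus_t(self):
        T = np.array([[0.5, 0.5], [0.5, 0.5]])
        p = np.array([0.5, 0.5])
        np.testing.assert_allclose(directed_graph_laplacian(T, p), np.eye(2) - T)

    def test_two_state_hand_computation(self):
        T = np.array([[0.0, 1.0], [1.0, 0.0]])
        L = directed_graph_laplacian(T, np.array([0.5, 0.5]))
        np.testing.assert_allclose(L, [[1.0, -1.0], [-1.0, 1.0]])
        S = similarity_matrix(L, 1, 1).S
        np.testing.assert_allclose(S, [[0.25, -0.25], [-0.25, 0.25]], atol=1e-12)

    def test_moore_penrose_identities(self, rng):
        for _ in range(10):
            x, y = random_pair(rng)
            dec = decompose_pair(x, y)
            M = 0.5 * (dec.L + dec.L.T)
            np.testing.assert_allclose(dec.S @ M @ dec.S, dec.S, atol=1e-6)
            np.testing.assert_allclose(M @ dec.S @ M, M, atol=1e-6)
            np.testing.assert_allclose(dec.S, dec.S.T, atol=1e-8)

    def test_commute_distances_nonnegative(self, rng):
        for _ in range(10):
            x, y = random_pair(rng)
            S = decompose_pair(x, y).S
            d = np.diag(S)
            assert np.min(d[:, None] + d[None, :] - 2 * S) >= -1e-8

    def test_quadrant_symmetry_under_spectrum_swap(self, rng):
        x, y = random_pair(rng, max_size=5)
        fwd = decompose_pair(x, y)
        rev = decompose_pair(y, x)
        np.testing.assert_allclose(fwd.s_xy, rev.s_xy.T, atol=1e-8)
        np.testing.assert_allclose(fwd.s_xy, rev.s_yx, atol=1e-8)


class TestBruteForceEquivalence:
    def test_all_stages_match_nested_loop_oracle(self, rng):
        for _ in range(25):
            x, y = random_pair(rng)
            m, n = len(x), len(y)
            dec = decompose_pair(x, y, tolerance=0.01)
            bD = orc.brute_difference_matrix(x.mz, y.mz)
            bC = orc.brute_count_matrix(bD, m, n, 0.01)
            bT = orc.brute_transition_matrix(bC)
            bp = orc.brute_stationary(bT)
            bL = orc.brute_laplacian(bT, bp)
            bS = orc.brute_pseudoinverse(0.5 * (bL + bL.T), rcond=(m + n) * 1e-12)
            np.testing.assert_allclose(dec.L, bL, atol=1e-8)
            np.testing.assert_allclose(dec.S, bS, atol=1e-8)
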