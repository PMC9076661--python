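"""Order-preserving permutation sampling and the Monte Carlo p-value."""

import numpy as np
import pytest
from scipy import stats

import oracles as orc
from simile.alignment import align_dp
from simile.errors import ParameterError
from simile.significance import (
    monte_carlo_pvalue,
    permuted_score,
    sample_order_preserving_permutation,
)
from simile.similarity import decompose_pair
from simile.spectra_io import FragmentationSpectrum
from simile.synthetic import random_spectrum


def _spec(mz, sid="s"):
    return FragmentationSpectrum(sid, max(mz) + 1, np.array(mz, dtype=float))


class TestPermutationSampling:
    def test_requires_rng(self):
        with pytest.raises(ParameterError):
            sample_order_preserving_permutation(np.array([100.0, 200.0]), 1, 1, None)

    def test_both_plans_occur_for_one_plus_one(self):
        rng = np.random.default_rng(0)
        concat = np.array([100.0, 200.0])
        seen = {
            tuple(sample_order_preserving_permutation(concat, 1, 1, rng).perm)
            for _ in range(1000)
        }
        assert seen == {(0, 1), (1, 0)}

    def test_block_order_and_multiset_preserved(self):
        rng = np.random.default_rng(1)
        concat = np.concatenate([np.array([1.0, 3.0, 7.0]), np.array([2.0, 5.0])])
        for _ in range(200):
            plan = sample_order_preserving_permutation(concat, 3, 2, rng)
            assert sorted(plan.perm) == list(range(5))
            x_vals = concat[plan.perm[:3]]
            y_vals = concat[plan.perm[3:]]
            assert np.all(np.diff(x_vals) > 0) and np.all(np.diff(y_vals) > 0)

    def test_uniform_over_enumerable_plans(self):
        # x=[1,3], y=[2]: C(3,2)=3 plans, chi-square for uniformity
        rng = np.random.default_rng(2)
        concat = np.array([1.0, 3.0, 2.0])
        plans = orc.enumerate_order_preserving_plans(concat, 2, 1)
        assert len(plans) == 3
        keys = [tuple(p) for p in plans]
        counts = dict.fromkeys(keys, 0)
        for _ in range(3000):
            plan = sample_order_preserving_permutation(concat, 2, 1, rng)
            counts[tuple(plan.perm)] += 1
        chi = stats.chisquare(list(counts.values()))
        assert chi.pvalue > 0.001

    def test_identity_assignment_is_a_valid_plan(self):
        concat = np.array([1.0, 3.0, 2.0, 5.0])
        plans = {tuple(p) for p in orc.enumerate_order_preserving_plans(concat, 2, 2)}
        assert (0, 1, 2, 3) in plans


class TestPermutedScore:
    def test_identity_plan_reproduces_observed(self, rng):
        x = random_spectrum(3, (50, 500), rng, spectrum_id="x")
        y = random_spectrum(4, (50, 500), rng, spectrum_id="y")
        dec = decompose_pair(x, y)
        from simile.significance import PermutationPlan

        plan = PermutationPlan(perm=np.arange(7), m=3, n=4)
        assert permuted_score(dec.S, plan) == pytest.approx(
            align_dp(dec.s_xy).score, abs=1e-9
        )

    def test_all_plans_match_value_lookup_oracle(self, toy_pair):
        x, y = toy_pair
        dec = decompose_pair(x, y)
        concat = np.concatenate([x.mz, y.mz])
        from simile.significance import PermutationPlan

        plans = orc.enumerate_order_preserving_plans(concat, 2, 2)
        assert len(plans) == 6
        for perm in plans:
            plan = PermutationPlan(perm=perm, m=2, n=2)
            expected = align_dp(orc.rebuild_permuted_quadrant(dec.S, perm, 2, 2)).score
            assert permuted_score(dec.S, plan) == pytest.approx(expected, abs=1e-9)

    def test_conjugation_preserves_symmetry(self, toy_pair):
        x, y = toy_pair
        dec = decompose_pair(x, y)
        perm = np.array([2, 0, 1, 3])
        permuted = dec.S[np.ix_(perm, perm)]
        np.testing.assert_allclose(permuted, permuted.T, atol=1e-10)


class TestMonteCarloPvalue:
    def _setup(self, rng, m=6, n=6):
        x = random_spectrum(m, (50, 500), rng, spectrum_id="x")
        y = random_spectrum(n, (50, 500), rng, spectrum_id="y")
        dec = decompose_pair(x, y)
        return dec, np.concatenate([x.mz, y.mz])

    def test_pvalue_formula_matches_hand_count(self, rng):
        dec, concat = self._setup(rng)
        obs = align_dp(dec.s_xy).score
        res = monte_carlo_pvalue(
            dec.S, concat, 6, 6, obs, schedule=[10, 100], rng=np.random.default_rng(5)
        )
        c = int(np.sum(res.null_scores >= obs))
        assert res.pvalue == pytest.approx(max(c / res.iterations, 1 / res.iterations))
        assert res.pvalue >= 1 / res.iterations

    def test_unbeatable_observed_reaches_floor(self, rng):
        # an observed score above every permuted score improves twofold at
        # each stage and ends at the 1/1000 floor
        dec, concat = self._setup(rng)
        res = monte_carlo_pvalue(
            dec.S, concat, 6, 6, 1e9, rng=np.random.default_rng(6)
        )
        assert res.iterations == 1000
        assert res.pvalue == pytest.approx(0.001)
        assert not res.stopped_early

    def test_hopeless_observed_stops_after_second_stage(self, rng):
        # observed below every null score: p stays 1.0 and fails to halve
        dec, concat = self._setup(rng)
        res = monte_carlo_pvalue(
            dec.S, concat, 6, 6, -1.0, rng=np.random.default_rng(7)
        )
        assert res.iterations == 100
        assert res.pvalue == 1.0
        assert res.stopped_early

    def test_monotone_in_observed_score(self, rng):
        dec, concat = self._setup(rng)
        obs = align_dp(dec.s_xy).score
        p_low = monte_carlo_pvalue(
            dec.S, concat, 6, 6, obs, rng=np.random.default_rng(8)
        ).pvalue
        p_high = monte_carlo_pvalue(
            dec.S, concat, 6, 6, obs + 0.5, rng=np.random.default_rng(8)
        ).pvalue
        assert p_high <= p_low

    def test_rejects_bad_schedule_and_observed(self, rng):
        dec, concat = self._setup(rng)
        with pytest.raises(ParameterError):
            monte_carlo_pvalue(dec.S, concat, 6, 6, np.nan, rng=np.random.default_rng(0))
        with pytest.raises(ParameterError):
            monte_carlo_pvalue(
                dec.S, concat, 6, 6, 1.0, schedule=[100, 10], rng=np.random.default_rng(0)
            )
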