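"""Tests for site-selection policies, the reward rule, and closed-loop runs."""

import math

import numpy as np
import pytest

from dbsbandit import (ALGORITHMS, BanditState, BlockOutcome, GeneratorParams,
                       RunResult, forced_exploration, majority_vote,
                       run_closed_loop, select_site, update_state)
from dbsbandit.pool import SURFACES, StimProblem


def make_state(counts, sums, T=None, seed=0, **kw):
    counts = np.asarray(counts)
    st = BanditState(n_sites=counts.size, rng=np.random.default_rng(seed), **kw)
    st.counts = counts.astype(int)
    st.sums = np.asarray(sums, dtype=float)
    st.T = int(counts.sum()) if T is None else T
    return st


class TestSelectSite:
    def test_ucb1_equal_counts_picks_lower_mean(self):
        st = make_state([10, 10], [5.0, 6.0], T=20)
        assert select_site(st, "ucb1") == 0

    def test_ucb1_exploration_dominates(self):
        """Means (0.5, 0.6), counts (50, 2), T = 52: the bonus for the
        under-sampled site, sqrt(2 ln 52 / 2) = 1.987, wins."""
        st = make_state([50, 2], [25.0, 1.2], T=52)
        bonus1 = math.sqrt(2 * math.log(52) / 2)
        assert bonus1 == pytest.approx(1.987, abs=1e-3)
        assert select_site(st, "ucb1") == 1

    def test_greedy_tie_breaks_to_lowest_index(self):
        st = make_state([5, 5, 5], [2.5, 2.5, 3.0])
        assert select_site(st, "greedy") == 0

    def test_eps_zero_is_pure_greedy(self):
        st = make_state([5, 5], [3.0, 2.0], eps=0.0)
        assert all(select_site(st, "eps_greedy") == 1 for _ in range(20))

    def test_forced_phase_precedes_policy(self):
        st = BanditState(n_sites=4, rng=np.random.default_rng(3))
        order = forced_exploration(st)
        assert sorted(order) == [0, 1, 2, 3]
        # until every site is pulled once, selection follows the forced order
        for k in range(4):
            site = select_site(st, "greedy")
            assert site == order[k]
            update_state(st, site, BlockOutcome(k, site, 0.5 + 0.01 * k, 5), "greedy")
        assert st.exploration_done

    @pytest.mark.parametrize("alg", ["ts_bernoulli", "ts_poisson", "ts_normal", "c_ts"])
    def test_thompson_symmetry(self, alg):
        """Identical hyperparameters on all sites: selection frequencies are
        uniform over many seeded draws (3-sigma binomial band)."""
        st = make_state([5, 5, 5], [3.0, 3.0, 3.0], seed=12)
        st.mu_z[:] = 0.6
        st.k_z[:] = 2.0
        n = 6000
        picks = np.array([select_site(st, alg) for _ in range(n)])
        for s in range(3):
            p = np.mean(picks == s)
            assert abs(p - 1 / 3) < 3 * math.sqrt((1 / 3) * (2 / 3) / n)

    def test_unknown_algorithm(self):
        st = make_state([1], [0.5])
        with pytest.raises(ValueError):
            select_site(st, "bogus")


class TestUpdateState:
    def test_bernoulli_reward_branches(self):
        """Success (outcome below threshold) increments alpha; failure beta."""
        st = make_state([1, 1], [0.6, 0.7], seed=0)
        st.last_site, st.last_outcome = 1, 0.7
        a0, b0 = st.beta_a.copy(), st.beta_b.copy()
        update_state(st, 0, BlockOutcome(2, 0, 0.5, 5), "ts_bernoulli")  # 0.5 < 0.7
        assert st.beta_a[0] == a0[0] + 1 and st.beta_b[0] == b0[0]
        st.last_site, st.last_outcome = 0, 0.5
        update_state(st, 1, BlockOutcome(3, 1, 0.9, 5), "ts_bernoulli")  # 0.9 >= 0.5
        assert st.beta_b[1] == b0[1] + 1 and st.beta_a[1] == a0[1]

    def test_c_ts_posterior_arithmetic(self):
        st = make_state([1], [1.0], seed=0)
        st.mu_z[0], st.k_z[0] = 1.0, 1.0
        st.last_site, st.last_outcome = 0, 1.0
        update_state(st, 0, BlockOutcome(1, 0, 0.5, 5), "c_ts")
        assert st.mu_z[0] == pytest.approx(0.75)
        assert st.k_z[0] == 2.0

    def test_rt_val_new_site_uses_previous_outcome(self):
        """On a site switch the success threshold is the previous block's
        outcome, not the other sites' means."""
        st = make_state([3, 3], [3.0, 1.5], seed=0)  # means 1.0, 0.5
        st.last_site, st.last_outcome = 1, 0.8
        a0 = st.beta_a.copy()
        update_state(st, 0, BlockOutcome(6, 0, 0.7, 5), "ts_bernoulli")
        # 0.7 < 0.8 (previous outcome) => success, even though min other mean is 0.5
        assert st.beta_a[0] == a0[0] + 1

    def test_rt_val_same_site_uses_other_means(self):
        st = make_state([3, 3], [3.0, 1.5], seed=0)  # means 1.0, 0.5
        st.last_site, st.last_outcome = 0, 1.2
        b0 = st.beta_b.copy()
        update_state(st, 0, BlockOutcome(6, 0, 0.7, 5), "ts_bernoulli")
        # same site: threshold = min other mean = 0.5; 0.7 >= 0.5 => failure
        assert st.beta_b[0] == b0[0] + 1

    def test_counts_and_means_maintained(self):
        st = make_state([0, 0], [0.0, 0.0], T=0)
        update_state(st, 1, BlockOutcome(0, 1, 0.6, 5), "greedy")
        update_state(st, 1, BlockOutcome(1, 1, 0.8, 5), "greedy")
        assert st.T == 2 and st.counts[1] == 2
        assert st.means[1] == pytest.approx(0.7)

    def test_positive_outcome_required(self):
        with pytest.raises(ValueError):
            BlockOutcome(0, 0, -0.1, 5)


class TestForcedExploration:
    def test_seeded_permutations(self):
        a = BanditState(n_sites=8, rng=np.random.default_rng(1)).forced_order
        b = BanditState(n_sites=8, rng=np.random.default_rng(1)).forced_order
        c = BanditState(n_sites=8, rng=np.random.default_rng(2)).forced_order
        np.testing.assert_array_equal(a, b)
        assert sorted(a) == list(range(8))
        assert not np.array_equal(a, c)


class TestClosedLoop:
    @pytest.mark.parametrize("alg", ["ucb1", "greedy", "ts_bernoulli", "brute_force"])
    def test_noise_free_two_site_problem(self, alg):
        """With no state noise and tiny RT dispersion, the b2 surface
        (0 vs -0.10) is separable: every algorithm finds site 1 always."""
        correct = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            gen = GeneratorParams(alpha_offset=0.2, v=500, b0=math.log(0.6),
                                  sigma1=0.0, sigma2=0.0, x0_conflict=0.3)
            res = run_closed_loop(gen, SURFACES["b2"], alg, 300, 15, rng)
            correct += res.correct
        assert correct == 10

    def test_brute_force_equal_allocation(self):
        rng = np.random.default_rng(0)
        gen = GeneratorParams(alpha_offset=0.2, v=30, b0=math.log(0.6),
                              sigma1=0.005, sigma2=0.001, x0_conflict=0.3)
        res = run_closed_loop(gen, SURFACES["8-site"], "brute_force", 600, 15, rng)
        counts = np.bincount([o.site for o in res.outcomes], minlength=8)
        assert list(counts) == [5] * 8   # 600 / 15 / 8 blocks per site

    def test_count_conservation(self):
        rng = np.random.default_rng(1)
        gen = GeneratorParams(alpha_offset=0.2, v=30, b0=math.log(0.6),
                              sigma1=0.005, sigma2=0.001, x0_conflict=0.3)
        res = run_closed_loop(gen, SURFACES["4-site"], "ucb1", 320, 16, rng)
        assert res.bandit.T == len(res.outcomes) == 320 // 16
        assert res.bandit.counts.sum() == res.bandit.T

    def test_blocksize_one_is_trialwise(self):
        rng = np.random.default_rng(2)
        gen = GeneratorParams(alpha_offset=0.2, v=30, b0=math.log(0.6),
                              sigma1=0.005, sigma2=0.001, x0_conflict=0.3)
        res = run_closed_loop(gen, SURFACES["2-site"], "greedy", 60, 1, rng)
        assert len(res.outcomes) == 60
        assert all(o.n_trials == 1 for o in res.outcomes)

    def test_budget_too_small(self):
        rng = np.random.default_rng(0)
        gen = GeneratorParams(alpha_offset=0.2, v=30, b0=math.log(0.6),
                              sigma1=0.005, sigma2=0.001, x0_conflict=0.3)
        with pytest.raises(ValueError):
            run_closed_loop(gen, SURFACES["8-site"], "ucb1", 60, 15, rng)

    def test_ucb1_asymptotic_consistency(self):
        """On a fixed 2-site problem with well-separated means, the optimum's
        selection frequency approaches 1 (noise-free sensor bypass)."""
        rng = np.random.default_rng(0)
        st = BanditState(n_sites=2, rng=rng)
        picks = []
        for t in range(10_000):
            site = select_site(st, "ucb1")
            val = (0.5 if site == 0 else 1.5) + rng.normal(0, 0.05)
            update_state(st, site, BlockOutcome(t, site, max(val, 0.01), 1), "ucb1")
            picks.append(site)
        assert np.mean(np.array(picks[-5000:]) == 0) > 0.95


class TestMajorityVote:
    def _result(self, chosen, n_sites=4, outcome_by_site=None):
        outcomes = []
        if outcome_by_site:
            outcomes = [BlockOutcome(i, s, v, 5)
                        for i, (s, v) in enumerate(outcome_by_site)]
        return RunResult(chosen_site=chosen, correct=False, outcomes=outcomes,
                         site_means=np.zeros(n_sites), algorithm="ucb1",
                         optimal_site=0)

    def test_simple_majority(self):
        rs = [self._result(2), self._result(2), self._result(3)]
        assert majority_vote(rs) == 2

    def test_singleton(self):
        assert majority_vote([self._result(1)]) == 1

    def test_tie_breaks_by_pooled_mean(self):
        rs = [
            self._result(1, outcome_by_site=[(1, 0.9), (2, 0.5)]),
            self._result(1, outcome_by_site=[(1, 0.8), (2, 0.6)]),
            self._result(2, outcome_by_site=[(2, 0.4), (1, 0.7)]),
            self._result(2, outcome_by_site=[(2, 0.5), (1, 0.9)]),
        ]
        assert majority_vote(rs) == 2  # pooled mean: site 2 = 0.5 < site 1 = 0.825

    def test_empty(self):
        with pytest.raises(ValueError):
            majority_vote([])


def test_algorithm_registry_complete():
    assert set(ALGORITHMS) == {
        "brute_force", "greedy", "eps_greedy", "ucb1", "bayes_ucb",
        "ts_bernoulli", "ts_poisson", "ts_normal", "c_ts",
    }
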