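"""Proposal distributions, sampling, restriction, and subset frontiers."""

import numpy as np
import pytest
from scipy.stats import chisquare

import polcomp as pc


class TestProposalDistributions:
    def test_flat_proposal(self, exp_task):
        p = pc.proposal_distribution(exp_task, "flat")
        assert p.probs == pytest.approx(np.full(7, 1 / 7))

    def test_general_value_proposal_matches_hand_arithmetic(self, exp_task):
        p = pc.proposal_distribution(exp_task, "general_value")
        # V(safety)=0.2, V(unsafe)=0.1/6 each, sum 0.3
        assert p.probs[6] == pytest.approx(2 / 3)
        assert p.probs[:6] == pytest.approx(np.full(6, (0.1 / 6) / 0.3))

    def test_oracle_proposal_at_small_beta_concentrates_on_safety(self, exp_task):
        p = pc.proposal_distribution(exp_task, "oracle", beta=0.3)
        assert p.kind == "oracle" and p.beta == 0.3
        assert p.probs[6] > 0.95

    def test_oracle_requires_beta(self, exp_task):
        with pytest.raises(ValueError):
            pc.proposal_distribution(exp_task, "oracle")

    def test_negative_general_values_shifted_not_reranked(self):
        t = pc.Task(np.array([0.5, 0.5]), np.array([[-1.0, 2.0], [-3.0, 0.0]]))
        p = pc.proposal_distribution(t, "general_value")
        assert p.probs.min() >= 0 and p.probs.sum() == pytest.approx(1.0)
        # V = (-2, 1): ranking must survive the shift
        assert p.probs[1] > p.probs[0]


class TestSampling:
    def test_without_replacement_exhausts_action_set(self, exp_task):
        p = pc.proposal_distribution(exp_task, "flat")
        s = pc.sample_actions(p, 7, with_replacement=False, rng_seed=0)
        assert s.unique_actions == frozenset(range(7))

    def test_point_mass_proposal_repeats(self):
        p = pc.ProposalDistribution("oracle", np.array([0.0, 1.0, 0.0]), beta=1.0)
        s = pc.sample_actions(p, 20, with_replacement=True, rng_seed=1)
        assert set(s.draws) == {1}

    def test_oversized_without_replacement_rejected(self, exp_task):
        p = pc.proposal_distribution(exp_task, "flat")
        with pytest.raises(ValueError):
            pc.sample_actions(p, 8, with_replacement=False, rng_seed=0)

    def test_determinism(self, exp_task):
        p = pc.proposal_distribution(exp_task, "general_value")
        a = pc.sample_actions(p, 5, True, rng_seed=42)
        b = pc.sample_actions(p, 5, True, rng_seed=42)
        assert a.draws == b.draws

    @pytest.mark.parametrize("kind", ["flat", "general_value"])
    def test_draw_frequencies_match_proposal(self, exp_task, kind):
        """Chi-square goodness of fit at n=1e5 must not reject at alpha=0.001."""
        p = pc.proposal_distribution(exp_task, kind)
        s = pc.sample_actions(p, 100_000, with_replacement=True, rng_seed=7)
        counts = s.counts(7)
        assert chisquare(counts, 100_000 * p.probs).pvalue > 0.001

    def test_singleton_general_value_draws_safety_at_proposal_rate(self, exp_task):
        p = pc.proposal_distribution(exp_task, "general_value")
        hits = sum(
            pc.sample_actions(p, 1, True, rng_seed=seed).draws[0] == 6
            for seed in range(3000)
        )
        se = np.sqrt((2 / 3) * (1 / 3) / 3000)
        assert abs(hits / 3000 - 2 / 3) < 3 * se


class TestRestriction:
    def test_full_index_set_is_identity(self, exp_task):
        r = pc.restrict_task(exp_task, range(7))
        assert np.array_equal(r.rewards, exp_task.rewards)
        assert r.safety_index == 6
        assert r.parent_indices == tuple(range(7))

    def test_safety_index_remapped_or_cleared(self, exp_task):
        r = pc.restrict_task(exp_task, {2, 6})
        assert r.safety_index == 1 and r.action_labels == ("key3", "safety")
        r2 = pc.restrict_task(exp_task, {0, 1})
        assert r2.safety_index is None

    def test_safety_only_restriction_collapses_frontier(self, exp_task):
        r = pc.restrict_task(exp_task, {6})
        fr = pc.trace_frontier(r, [1.0, 10.0])
        assert np.allclose(fr.complexities, 0.0, atol=1e-12)
        assert np.allclose(fr.rewards, 0.2)

    def test_restriction_consistent_with_manual_slice(self, exp_task):
        subset = (1, 3, 6)
        sub = pc.restrict_task(exp_task, subset)
        manual = pc.Task(exp_task.state_probs, exp_task.rewards[:, list(subset)])
        a = pc.blahut_arimoto(sub, 2.5)
        b = pc.blahut_arimoto(manual, 2.5)
        assert np.array_equal(a.probs, b.probs)

    def test_symmetric_restriction_ba_oracle(self):
        t = pc.make_symmetric_task(6, 1, 0)
        sub = pc.restrict_task(t, {0, 1, 2})
        pol = pc.blahut_arimoto(sub, 60.0)
        # three states keep their optimal action (+1), three earn 0
        assert pc.trial_averaged_reward(sub, pol) == pytest.approx(0.5, abs=1e-6)
        # reward-blind states collapse onto the marginal, so only the three
        # rewarded states carry information: I = (1/2) log2(3)
        assert pc.policy_complexity(sub.state_probs, pol) == pytest.approx(
            0.5 * np.log2(3), abs=1e-3
        )
        # the frontier is flat in complexity beyond that point, so the
        # reward at the log2(3)-bit ceiling is still 0.5
        fr = pc.trace_frontier(sub, [20.0, 60.0])
        assert pc.frontier_reward_at(fr, np.log2(3)) == pytest.approx(0.5, abs=1e-6)

    def test_empty_restriction_rejected(self, exp_task):
        with pytest.raises(ValueError):
            pc.restrict_task(exp_task, set())


class TestSubsetEnumeration:
    def test_full_size_single_frontier_equals_full(self, exp_task):
        grid = np.geomspace(0.5, 20, 6)
        frs = pc.enumerate_subset_frontiers(exp_task, 7, "ignore", grid)
        assert list(frs) == [tuple(range(7))]
        full = pc.trace_frontier(exp_task, grid)
        assert frs[tuple(range(7))].rewards == pytest.approx(full.rewards, abs=1e-9)

    def test_size_one_including_safety_is_the_endpoint(self, exp_task):
        frs = pc.enumerate_subset_frontiers(exp_task, 1, "include", [1.0])
        (fr,) = frs.values()
        assert np.allclose(fr.rewards, 0.2) and np.allclose(fr.complexities, 0.0)

    def test_safety_pairs_identical_by_symmetry(self, exp_task):
        grid = np.geomspace(0.5, 20, 6)
        frs = pc.enumerate_subset_frontiers(exp_task, 2, "include", grid)
        assert len(frs) == 6
        rewards = [fr.rewards for fr in frs.values()]
        for r in rewards[1:]:
            assert np.abs(r - rewards[0]).max() < 1e-9

    def test_enumeration_guard(self):
        t = pc.make_random_task(2, 40, 0)
        with pytest.raises(ValueError, match="guard"):
            pc.enumerate_subset_frontiers(t, 20, "ignore", [1.0])

    def test_subsets_dominated_and_capped(self, exp_task, exp_frontier):
        """Every 3-action frontier stays below the full frontier and under
        the log2(Na) complexity ceiling."""
        grid = np.geomspace(0.5, 30, 8)
        cap = pc.max_complexity_bound(3, exp_task.n_states)
        for fr in pc.enumerate_subset_frontiers(exp_task, 3, "ignore", grid).values():
            assert fr.complexities.max() <= cap + 1e-9
            excess = fr.rewards - pc.frontier_upper_bound(exp_frontier, fr.complexities)
            assert excess.max() < 1e-6


class TestNaSpecificFrontier:
    def test_full_size_matches_full_frontier(self, exp_task, exp_frontier):
        na = pc.na_specific_frontier(exp_task, 7)
        # the winning branch is the full task itself, so at the combined
        # curve's own knots the values coincide with the full frontier
        assert na.rewards == pytest.approx(
            pc.frontier_reward_at(exp_frontier, na.complexities), abs=1e-9
        )

    def test_size_one_is_safety_point(self, exp_task):
        na = pc.na_specific_frontier(exp_task, 1)
        assert np.allclose(na.rewards, 0.2) and np.allclose(na.complexities, 0.0)

    def test_size_four_branches_cross(self, exp_task):
        """The safety-including branch extends to higher complexity at lower
        reward, producing the branch switch behind the frontier's kink."""
        grid = pc.default_beta_grid(0.1, 50, 40)
        from polcomp.consideration import _branch_frontier

        inc = _branch_frontier(exp_task, 4, True, grid, True)
        exc = _branch_frontier(exp_task, 4, False, grid, True)
        assert inc.complexities.max() > exc.complexities.max() + 0.1
        # at moderate complexity the excluding branch pays more
        mid = 0.8 * exc.complexities.max()
        assert pc.frontier_reward_at(exc, mid) > pc.frontier_reward_at(inc, mid)
        # the combined pointwise max is still non-decreasing (validated on
        # construction) and matches each branch where that branch wins
        na = pc.na_specific_frontier(exp_task, 4, grid)
        assert np.all(np.diff(na.rewards) >= -1e-9)
        assert pc.frontier_reward_at(na, mid) == pytest.approx(
            pc.frontier_reward_at(exc, mid), abs=1e-4
        )

    def test_symmetry_shortcut_matches_enumeration(self, exp_task):
        grid = np.geomspace(0.5, 20, 6)
        fast = pc.na_specific_frontier(exp_task, 3, grid, exploit_symmetry=True)
        slow = pc.na_specific_frontier(exp_task, 3, grid, exploit_symmetry=False)
        probe = np.linspace(0, fast.complexities.max(), 32)
        assert pc.frontier_reward_at(fast, probe) == pytest.approx(
            pc.frontier_reward_at(slow, probe), abs=1e-6
        )

    def test_requires_safety_index(self):
        with pytest.raises(ValueError):
            pc.na_specific_frontier(pc.make_symmetric_task(6), 3)


@pytest.mark.parametrize(
    "set_size,n_states,expected",
    [(2, 6, 1.0), (7, 6, np.log2(6)), (1, 6, 0.0), (8, 3, np.log2(3))],
)
def test_max_complexity_bound(set_size, n_states, expected):
    assert pc.max_complexity_bound(set_size, n_states) == pytest.approx(expected)
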