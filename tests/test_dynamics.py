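"""Transition-kernel sub-models: unit branches, hand values, Monte-Carlo
agreement and analytic invariants."""
import math

import numpy as np
import pytest

from causact.domain import ground, reachable_states
from causact.dynamics import (
    ActionSelectionParams,
    CCBMState,
    DurationModel,
    GoalPrior,
    action_execution,
    action_selection_dist,
    enumerate_successors,
    goal_persistence,
    initial_distribution,
    sample_initial,
    sample_transition,
    start_time_update,
    termination_prob,
    transition_logprob,
)
from causact.errors import ApplicabilityError, CausactError


def _uniform_duration(a=0.0, b=10.0):
    return DurationModel(default=("uniform", a, b))


class TestActionExecution:
    def test_not_terminated_keeps_state(self, pair_problem):
        actions, _ = ground(pair_problem)
        out = action_execution(pair_problem.init, actions[0], terminated=False)
        assert out == pair_problem.init

    def test_terminated_applies_effect(self, pair_problem):
        actions, _ = ground(pair_problem)
        out = action_execution(pair_problem.init, actions[0], terminated=True)
        assert out != pair_problem.init
        assert out == actions[0].apply(pair_problem.init)

    def test_effect_free_action_identity(self, chain_problem):
        # action a applied twice: second application is effect-free in value
        actions, _ = ground(chain_problem)
        a = actions[0]
        s1 = a.apply(chain_problem.init)
        assert action_execution(s1, a, terminated=True) == s1

    def test_inapplicable_on_termination_raises(self, pair_problem):
        actions, _ = ground(pair_problem)
        a = actions[0]
        s1 = a.apply(pair_problem.init)  # (pa) now true; a inapplicable
        with pytest.raises(ApplicabilityError):
            action_execution(s1, a, terminated=True)


class TestStartTime:
    def test_terminated_resets_to_now(self):
        assert start_time_update(True, prev_start=3, now=7) == 7

    def test_not_terminated_keeps_prev(self):
        assert start_time_update(False, prev_start=3, now=7) == 3

    def test_now_equals_prev_start(self):
        assert start_time_update(True, 5, 5) == 5
        assert start_time_update(False, 5, 5) == 5

    def test_prev_after_now_rejected(self):
        with pytest.raises(CausactError):
            start_time_update(False, 8, 7)


class TestTerminationProb:
    def test_uniform_hand_value(self):
        # F uniform on [0,10]: (F(5)-F(4)) / (1-F(5)) = 0.1/0.5
        d = _uniform_duration(0, 10)
        p = termination_prob("x", start=0, prev_time=4, now=5, durations=d)
        assert p == pytest.approx(0.2)

    def test_zero_before_any_mass(self):
        d = _uniform_duration(5, 10)
        assert termination_prob("x", 0, 1, 2, d) == 0.0

    def test_full_cdf_certain_termination(self):
        d = _uniform_duration(0, 3)
        assert termination_prob("x", 0, 3, 4, d) == 1.0

    def test_standard_mode_denominator(self):
        d = _uniform_duration(0, 10)
        p = termination_prob("x", 0, 4, 5, d, hazard_mode="standard")
        assert p == pytest.approx(0.1 / 0.6)

    def test_geometric_memoryless_in_both_modes(self):
        d = DurationModel(default=("geometric", 0.3))
        for mode in ("printed", "standard"):
            vals = [
                termination_prob("x", 0, t, t + 1, d, hazard_mode=mode)
                for t in range(1, 6)
            ]
            assert max(vals) - min(vals) < 1e-12

    def test_undefined_family_raises(self):
        d = DurationModel(default=("weibull", 1.0))
        with pytest.raises(CausactError):
            termination_prob("x", 0, 1, 2, d)


class TestGoalModels:
    def test_goal_persists(self):
        assert goal_persistence(2) == 2

    def test_uniform_prior_four_goals(self):
        p = GoalPrior("uniform").probabilities(4)
        assert np.allclose(p, 0.25)

    def test_informed_prior_factor_two(self):
        # g other goals plus the target: mass factor/(factor + g)
        for n in (2, 4, 5):
            p = GoalPrior("informed", target=0, factor=2.0).probabilities(n)
            assert p[0] == pytest.approx(2.0 / (n + 1))
            assert p.sum() == pytest.approx(1.0)

    def test_informed_prior_multi_target(self):
        p = GoalPrior("informed", target=(0, 1), factor=2.0).probabilities(4)
        assert p[0] == p[1] == pytest.approx(2.0 / 6.0)


class TestActionSelection:
    def test_zero_weights_uniform(self, pair_problem):
        graph = reachable_states(pair_problem)
        params = ActionSelectionParams(lambda1=0.0, lambda2=0.0)
        dist = action_selection_dist(0, pair_problem.init, params, graph, pair_problem)
        assert len(dist) == 2
        assert all(v == pytest.approx(0.5) for v in dist.values())

    def test_softmax_hand_value_quarter_three_quarters(self, pair_problem):
        graph = reachable_states(pair_problem)

        def bonus(action, goal, world):
            return math.log(3) if action.name == "b" else 0.0

        params = ActionSelectionParams(
            lambda1=0.0, lambda2=0.0, extra_features=((1.0, bonus),)
        )
        dist = action_selection_dist(0, pair_problem.init, params, graph, pair_problem)
        by_name = {a.name: v for a, v in dist.items()}
        assert by_name["a"] == pytest.approx(0.25)
        assert by_name["b"] == pytest.approx(0.75)

    def test_shift_invariance(self, pair_problem):
        graph = reachable_states(pair_problem)

        def shifted(action, goal, world):
            return 17.3  # same constant for every action

        base = action_selection_dist(
            0, pair_problem.init, ActionSelectionParams(), graph, pair_problem
        )
        shift = action_selection_dist(
            0,
            pair_problem.init,
            ActionSelectionParams(extra_features=((1.0, shifted),)),
            graph,
            pair_problem,
        )
        for a in base:
            assert base[a] == pytest.approx(shift[a])

    def test_support_is_applicable_set(self, chain_problem):
        graph = reachable_states(chain_problem)
        dist = action_selection_dist(
            0, chain_problem.init, ActionSelectionParams(), graph, chain_problem
        )
        assert {a.name for a in dist} == {"a"}  # only a applicable at init

    def test_lambda1_monotonicity(self, chain_problem):
        # from state {p1}: action b decreases goal distance, a leaves it
        graph = reachable_states(chain_problem)
        actions, _ = ground(chain_problem)
        a = next(x for x in actions if x.name == "a")
        s1 = a.apply(chain_problem.init)
        prev = None
        for lam in (0.0, 0.5, 1.0, 2.0):
            dist = action_selection_dist(
                0, s1, ActionSelectionParams(lambda1=lam, lambda2=0.0), graph, chain_problem
            )
            p_b = next(v for act, v in dist.items() if act.name == "b")
            if prev is not None:
                assert p_b > prev
            prev = p_b


class TestSampling:
    def test_degenerate_deterministic_successor(self, chain_problem):
        # printed-mode geometric(0.5) hazard is exactly 1: always terminate;
        # only action a is applicable at init
        graph = reachable_states(chain_problem)
        durations = DurationModel(default=("geometric", 0.5))
        params = ActionSelectionParams(lambda1=0.0, lambda2=0.0, hazard_mode="printed")
        state = sample_initial(
            chain_problem, graph, params, GoalPrior(), np.random.default_rng(0)
        )
        assert state.action.name == "a"
        succs = enumerate_successors(state, chain_problem, graph, params, durations)
        assert all(s.terminated for s, _ in succs)

    def test_monte_carlo_matches_analytic(self, pair_problem):
        graph = reachable_states(pair_problem)
        durations = DurationModel(default=("geometric", 0.3))
        params = ActionSelectionParams(hazard_mode="standard")
        state = sample_initial(
            pair_problem, graph, params, GoalPrior(), np.random.default_rng(1)
        )
        succs = enumerate_successors(state, pair_problem, graph, params, durations)
        assert sum(p for _, p in succs) == pytest.approx(1.0)
        rng = np.random.default_rng(42)
        n = 10_000
        counts = {}
        for _ in range(n):
            s = sample_transition(state, pair_problem, graph, params, durations, rng)
            k = (s.action.name, s.terminated, str(s.world))
            counts[k] = counts.get(k, 0) + 1
        for s, p in succs:
            k = (s.action.name, s.terminated, str(s.world))
            freq = counts.get(k, 0) / n
            se = math.sqrt(p * (1 - p) / n)
            assert abs(freq - p) < 3 * se + 1e-9

    def test_goal_constant_over_samples(self, toggle_problem):
        # toggle domain always has exactly one applicable action: no dead ends
        graph = reachable_states(toggle_problem)
        durations = DurationModel(default=("geometric", 0.5))
        params = ActionSelectionParams(hazard_mode="standard")
        rng = np.random.default_rng(7)
        state = sample_initial(toggle_problem, graph, params, GoalPrior(), rng)
        g0 = state.goal
        for _ in range(200):
            state = sample_transition(state, toggle_problem, graph, params, durations, rng)
            assert state.goal == g0

    def test_reproducible_under_seed(self, toggle_problem):
        graph = reachable_states(toggle_problem)
        durations = DurationModel(default=("geometric", 0.4))
        params = ActionSelectionParams(hazard_mode="standard")

        def walk(seed):
            rng = np.random.default_rng(seed)
            s = sample_initial(toggle_problem, graph, params, GoalPrior(), rng)
            out = []
            for _ in range(10):
                s = sample_transition(s, toggle_problem, graph, params, durations, rng)
                out.append((str(s.action), s.terminated, s.start))
            return out

        assert walk(5) == walk(5)


class TestTransitionLogprob:
    def _setup(self, problem):
        graph = reachable_states(problem)
        durations = DurationModel(default=("geometric", 0.3))
        params = ActionSelectionParams(hazard_mode="standard")
        state = sample_initial(problem, graph, params, GoalPrior(), np.random.default_rng(3))
        return graph, durations, params, state

    def test_world_changed_without_termination_impossible(self, pair_problem):
        graph, durations, params, state = self._setup(pair_problem)
        actions, _ = ground(pair_problem)
        other = next(a for a in actions if a.name != state.action.name)
        bad = CCBMState(
            action=state.action,
            terminated=False,
            goal=state.goal,
            world=other.apply(state.world),
            start=state.start,
            time=state.time + 1,
        )
        lp = transition_logprob(state, bad, pair_problem, graph, params, durations)
        assert lp == float("-inf")

    def test_exp_sums_to_one_over_successors(self, pair_problem):
        graph, durations, params, state = self._setup(pair_problem)
        succs = enumerate_successors(state, pair_problem, graph, params, durations)
        total = 0.0
        for s, p in succs:
            lp = transition_logprob(state, s, pair_problem, graph, params, durations)
            assert math.exp(lp) == pytest.approx(p, abs=1e-12)
            total += math.exp(lp)
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_normalization_over_reachable_toy_states(self, chain_problem):
        graph = reachable_states(chain_problem)
        durations = DurationModel(default=("uniform", 0, 4))
        params = ActionSelectionParams(hazard_mode="standard")
        frontier = [s for s, p in initial_distribution(chain_problem, graph, params, GoalPrior()) if p > 0]
        seen = 0
        for _ in range(3):  # a few layers deep
            nxt = []
            for st in frontier:
                succs = enumerate_successors(st, chain_problem, graph, params, durations)
                assert sum(p for _, p in succs) == pytest.approx(1.0, abs=1e-9)
                seen += 1
                nxt.extend(s for s, p in succs if p > 0)
            frontier = nxt[:20]
        assert seen > 5

    def test_not_terminated_keeps_action_with_probability_one(self, pair_problem):
        graph, durations, params, state = self._setup(pair_problem)
        succs = enumerate_successors(state, pair_problem, graph, params, durations)
        stay = [(s, p) for s, p in succs if not s.terminated]
        assert len(stay) == 1
        s, p = stay[0]
        assert s.action == state.action and s.world == state.world
        h = termination_prob(
            state.action, state.start, state.time, state.time + 1, durations, "standard"
        )
        assert p == pytest.approx(1.0 - h)
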