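"""Parser, grounding, state application and search services."""
import itertools
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from causact.domain import (
    GroundPredicate,
    Plan,
    WorldState,
    apply,
    enumerate_plans,
    goal_distance,
    ground,
    grounding_report,
    parse_problem,
    reachable_states,
    unsatisfied_goal_predicates,
)
from causact.errors import (
    ApplicabilityError,
    CausactError,
    ParseError,
    StateCapExceededError,
)
from tests.conftest import CHAIN_SRC, MOVE_SRC, PAIR_SRC, TOGGLE_SRC


class TestParser:
    def test_move_domain_grounds_to_concrete_move(self, move_problem):
        actions, _ = ground(move_problem)
        names = {str(a) for a in actions}
        assert "(move kitchen study)" in names

    def test_parameterless_template_yields_one_action(self, chain_problem):
        actions, _ = ground(chain_problem)
        assert len(actions) == 3  # a, b, c: one each

    def test_one_param_three_objects_three_actions(self):
        src = """
        (:types thing - object)
        (:objects x y z - thing)
        (:predicates (seen ?t - thing))
        (:action look :parameters (?t - thing) :effect (seen ?t) :observation get)
        """
        actions, _ = ground(parse_problem(src))
        # exhaustive substitution oracle: one action per object
        assert sorted(str(a) for a in actions) == ["(look x)", "(look y)", "(look z)"]

    def test_syntax_error_carries_location(self):
        with pytest.raises(ParseError) as exc:
            parse_problem("(:types\n  foo -)")
        assert exc.value.line == 2 and exc.value.column is not None

    def test_unknown_clause_rejected(self):
        src = "(:action a :zap (and))"
        with pytest.raises(ParseError, match="unknown action clause"):
            parse_problem(src)

    def test_unknown_section_rejected(self):
        with pytest.raises(ParseError, match="unknown section"):
            parse_problem("(:wibble foo)")

    def test_undeclared_type_rejected(self):
        with pytest.raises(ParseError, match="undeclared type"):
            parse_problem("(:objects a - ghost)")

    def test_undeclared_predicate_rejected(self):
        with pytest.raises(ParseError, match="undeclared predicate"):
            parse_problem("(:init (ghost))")

    def test_arity_mismatch_rejected(self):
        src = """
        (:types loc - object)
        (:objects here - loc)
        (:predicates (at ?l - loc))
        (:init (at here here))
        """
        with pytest.raises(ParseError, match="argument"):
            parse_problem(src)

    def test_unbalanced_parens(self):
        with pytest.raises(ParseError, match="unbalanced"):
            parse_problem("(:types")

    def test_free_variable_rejected(self):
        src = """
        (:types loc - object)
        (:objects a - loc)
        (:predicates (at ?l - loc))
        (:action go :parameters () :effect (at ?x) :observation move)
        """
        with pytest.raises(ParseError, match="not among :parameters"):
            parse_problem(src)

    def test_type_cycle_rejected(self):
        with pytest.raises(ParseError, match="cycle"):
            parse_problem("(:types a - b b - a)")

    def test_duration_families_parse(self):
        src = """
        (:types)
        (:objects)
        (:predicates (p))
        (:action n :duration (normal 30 5) :effect (p) :observation get)
        (:action g :duration (geometric 0.3) :effect (p) :observation get)
        (:action u :duration (uniform 0 10) :effect (p) :observation get)
        """
        problem = parse_problem(src)
        specs = {t.name: t.duration for t in problem.templates}
        assert specs == {
            "n": ("normal", 30.0, 5.0),
            "g": ("geometric", 0.3),
            "u": ("uniform", 0.0, 10.0),
        }


class TestGrounding:
    def test_self_move_filtered_by_equality(self, move_problem):
        actions, _ = ground(move_problem)
        # oracle: enumerate the 2x2 pairs, filter (= ?from ?to)
        locs = ["kitchen", "study"]
        expected = {
            f"(move {a} {b})" for a, b in itertools.product(locs, locs) if a != b
        }
        assert {str(a) for a in actions} == expected

    def test_cartesian_product_count(self):
        src = """
        (:types item - object meal - object)
        (:objects i1 i2 - item m1 m2 m3 - meal)
        (:predicates (got ?i - item ?m - meal))
        (:action get :parameters (?i - item ?m - meal)
                 :effect (got ?i ?m) :observation get)
        """
        actions, _ = ground(parse_problem(src))
        assert len(actions) == 6  # 2 items x 3 meals

    def test_zero_objects_of_type_zero_actions(self):
        src = """
        (:types meal - object)
        (:predicates (made ?m - meal))
        (:action mk :parameters (?m - meal) :effect (made ?m) :observation prepare)
        """
        actions, _ = ground(parse_problem(src))
        assert actions == []

    def test_ordering_deterministic_and_stable(self, move_problem):
        a1, _ = ground(move_problem)
        a2, _ = ground(move_problem)
        assert [str(a) for a in a1] == [str(a) for a in a2]

    @given(
        n_items=st.integers(min_value=0, max_value=5),
        n_meals=st.integers(min_value=0, max_value=5),
    )
    @settings(max_examples=20, deadline=None)
    def test_grounding_count_matches_substitution_oracle(self, n_items, n_meals):
        items = " ".join(f"i{k}" for k in range(n_items))
        meals = " ".join(f"m{k}" for k in range(n_meals))
        obj_lines = []
        if n_items:
            obj_lines.append(f"{items} - item")
        if n_meals:
            obj_lines.append(f"{meals} - meal")
        src = f"""
        (:types item - object meal - object)
        (:objects {' '.join(obj_lines)})
        (:predicates (got ?i - item ?m - meal))
        (:action get :parameters (?i - item ?m - meal)
                 :effect (got ?i ?m) :observation get)
        """
        actions, _ = ground(parse_problem(src))
        assert len(actions) == n_items * n_meals

    def test_grounding_report_format(self, move_problem):
        actions, _ = ground(move_problem)
        report = grounding_report(actions)
        lines = report.strip().split("\n")
        assert lines[0] == "action\tclass\targuments"
        assert "move\tmove\tkitchen study" in lines


class TestApply:
    def test_empty_effect_is_identity(self):
        src = """
        (:types)
        (:objects)
        (:predicates (p))
        (:action idle :observation unknown)
        (:init (p))
        """
        problem = parse_problem(src)
        actions, _ = ground(problem)
        assert apply(problem.init, actions[0]) == problem.init

    def test_move_effect_hand_application(self, move_problem):
        actions, _ = ground(move_problem)
        mv = next(a for a in actions if str(a) == "(move kitchen study)")
        result = apply(move_problem.init, mv)
        assert not result.value(GroundPredicate("at", ("kitchen",)))
        assert result.value(GroundPredicate("at", ("study",)))
        # input untouched
        assert move_problem.init.value(GroundPredicate("at", ("kitchen",)))

    def test_inapplicable_raises(self, move_problem):
        actions, _ = ground(move_problem)
        mv = next(a for a in actions if str(a) == "(move study kitchen)")
        with pytest.raises(ApplicabilityError):
            apply(move_problem.init, mv)

    def test_add_and_delete_same_atom_add_wins(self):
        src = """
        (:types)
        (:objects)
        (:predicates (p))
        (:action both :effect (and (not (p)) (p)) :observation unknown)
        (:init (p))
        """
        problem = parse_problem(src)
        actions, _ = ground(problem)
        out = apply(problem.init, actions[0])
        assert out.value(GroundPredicate("p"))

    def test_inverse_effect_restores_state(self, toggle_problem):
        actions, _ = ground(toggle_problem)
        on = next(a for a in actions if a.name == "on")
        off = next(a for a in actions if a.name == "off")
        s0 = toggle_problem.init
        assert apply(apply(s0, on), off) == s0


class TestReachability:
    def test_toggle_two_states_two_edges(self, toggle_problem):
        sg = reachable_states(toggle_problem)
        assert sg.n_states == 2
        assert sg.graph.number_of_edges() == 2

    def test_three_predicate_domain_matches_dfs_oracle(self, chain_problem):
        sg = reachable_states(chain_problem)

        # independent DFS oracle over hand-applied effects
        def oracle():
            seen = set()
            effects = {"a": "p1", "b": "p2", "c": "p3"}
            pres = {"a": None, "b": "p1", "c": "p2"}

            def dfs(state):
                if state in seen:
                    return
                seen.add(state)
                for act, add in effects.items():
                    pre = pres[act]
                    if pre is None or pre in state:
                        dfs(state | {add})

            dfs(frozenset())
            return seen

        assert sg.n_states == len(oracle())

    def test_sink_node(self, chain_problem):
        sg = reachable_states(chain_problem)
        goal_state = WorldState(
            {GroundPredicate("p1"), GroundPredicate("p2"), GroundPredicate("p3")}
        )
        assert goal_state in sg
        # all effects already applied: every action self-loops or is inapplicable
        succs = {v for _, v in sg.graph.out_edges(goal_state)}
        assert succs <= {goal_state}

    def test_cap_exceeded_carries_partial_graph(self, chain_problem):
        with pytest.raises(StateCapExceededError) as exc:
            reachable_states(chain_problem, max_states=2)
        assert exc.value.graph is not None
        assert exc.value.graph.n_states == 2
        assert exc.value.frontier

    def test_graph_deterministic_across_runs(self, pair_problem):
        g1 = reachable_states(pair_problem)
        g2 = reachable_states(pair_problem)
        assert list(map(str, g1.graph.nodes)) == list(map(str, g2.graph.nodes))


class TestPlans:
    def test_two_order_independent_actions_two_plans(self, pair_problem):
        plans, truncated = enumerate_plans(pair_problem, 0, max_length=4)
        assert not truncated
        assert sorted(str(p) for p in plans) == ["(a) (b)", "(b) (a)"]

    def test_goal_satisfied_by_init_one_empty_plan(self):
        src = """
        (:types)
        (:objects)
        (:predicates (p))
        (:action set :precondition (not (p)) :effect (p) :observation get)
        (:init (p))
        (:goal g (and (p)))
        """
        plans, _ = enumerate_plans(parse_problem(src), 0, max_length=3)
        assert len(plans) == 1 and len(plans[0]) == 0

    def test_chain_domain_single_plan(self, chain_problem):
        plans, _ = enumerate_plans(chain_problem, 0, max_length=3)
        assert [str(p) for p in plans] == ["(a) (b) (c)"]

    def test_unreachable_goal_empty_not_error(self):
        src = """
        (:types)
        (:objects)
        (:predicates (p) (q))
        (:action set :effect (p) :observation get)
        (:goal g (and (q)))
        """
        plans, truncated = enumerate_plans(parse_problem(src), 0, max_length=5)
        assert plans == [] and not truncated

    def test_truncation_flag(self, pair_problem):
        plans, truncated = enumerate_plans(pair_problem, 0, max_length=4, max_plans=1)
        assert truncated and len(plans) == 1

    def test_replay_validity(self, pair_problem):
        plans, _ = enumerate_plans(pair_problem, 0, max_length=4)
        goal = pair_problem.goals[0]
        for p in plans:
            assert goal.satisfied(p.replay(pair_problem.init))

    def test_count_stable_across_runs(self, pair_problem):
        c1 = len(enumerate_plans(pair_problem, 0, max_length=4)[0])
        c2 = len(enumerate_plans(pair_problem, 0, max_length=4)[0])
        assert c1 == c2


class TestGoalDistance:
    def test_zero_when_in_goal_set(self, chain_problem):
        sg = reachable_states(chain_problem)
        goal_state = WorldState(
            {GroundPredicate("p1"), GroundPredicate("p2"), GroundPredicate("p3")}
        )
        assert goal_distance(goal_state, 0, sg, chain_problem) == 0

    def test_linear_chain_bfs_oracle(self, chain_problem):
        sg = reachable_states(chain_problem)
        assert goal_distance(chain_problem.init, 0, sg, chain_problem) == 3

    def test_unreachable_goal_infinite_sentinel(self):
        src = """
        (:types)
        (:objects)
        (:predicates (p) (q))
        (:action set :effect (p) :observation get)
        (:goal g (and (q)))
        """
        problem = parse_problem(src)
        sg = reachable_states(problem)
        assert goal_distance(problem.init, 0, sg, problem) == math.inf

    def test_state_not_in_graph_raises(self, chain_problem):
        sg = reachable_states(chain_problem)
        stray = WorldState({GroundPredicate("p3")})
        with pytest.raises(CausactError):
            goal_distance(stray, 0, sg, chain_problem)

    def test_monotone_along_shortest_plan(self, chain_problem):
        sg = reachable_states(chain_problem)
        plans, _ = enumerate_plans(chain_problem, 0, max_length=3)
        state = chain_problem.init
        d = goal_distance(state, 0, sg, chain_problem)
        for a in plans[0].actions:
            state = apply(state, a)
            d_next = goal_distance(state, 0, sg, chain_problem)
            assert d_next == d - 1  # shortest plan decreases by exactly 1
            d = d_next


class TestUnsatisfiedGoalPredicates:
    def test_all_satisfied_zero(self, chain_problem):
        state = WorldState(
            {GroundPredicate("p1"), GroundPredicate("p2"), GroundPredicate("p3")}
        )
        assert unsatisfied_goal_predicates(state, 0, chain_problem) == 0

    def test_direct_count(self):
        src = """
        (:types)
        (:objects)
        (:predicates (p1) (p2) (p3))
        (:init (p1))
        (:goal g (and (p1) (p2) (p3)))
        """
        problem = parse_problem(src)
        assert unsatisfied_goal_predicates(problem.init, 0, problem) == 2

    def test_empty_goal_spec_zero(self):
        src = """
        (:types)
        (:objects)
        (:predicates (p))
        (:goal g (and))
        """
        problem = parse_problem(src)
        assert unsatisfied_goal_predicates(problem.init, 0, problem) == 0
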