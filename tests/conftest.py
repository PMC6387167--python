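"""Shared fixtures: toy domains with enumerable state spaces, and a small
two-meal kitchen whose exact filter runs in well under a second."""
import warnings

import pytest

from causact.domain import parse_problem, reachable_states
from causact.dynamics import ActionSelectionParams, DurationModel
from causact.kitchen import KitchenConfig, ScenarioConfig, build_kitchen_problem

warnings.filterwarnings("ignore", message="class .* absent from training data")


# a 2x2 location move domain (the classic two-room example)
MOVE_SRC = """
(:types location - object)
(:objects kitchen study - location)
(:predicates (at ?l - location))
(:action move
  :parameters (?from ?to - location)
  :duration (normal 30 5)
  :observation move
  :precondition (and (at ?from) (not (= ?from ?to)))
  :effect (and (not (at ?from)) (at ?to)))
(:init (at kitchen))
(:goal study (and (at study)))
"""

# chain domain: a then b then c
CHAIN_SRC = """
(:types)
(:objects)
(:predicates (p1) (p2) (p3))
(:action a :precondition (and) :effect (p1) :observation get)
(:action b :precondition (p1) :effect (p2) :observation prepare)
(:action c :precondition (p2) :effect (p3) :observation eat)
(:goal done (and (p3)))
"""

# two order-independent actions both required by the goal
PAIR_SRC = """
(:types)
(:objects)
(:predicates (pa) (pb))
(:action a :precondition (not (pa)) :effect (pa) :observation get)
(:action b :precondition (not (pb)) :effect (pb) :observation put)
(:goal both (and (pa) (pb)))
"""

# single-predicate on/off automaton
TOGGLE_SRC = """
(:types)
(:objects)
(:predicates (p))
(:action on :precondition (not (p)) :effect (p) :observation get)
(:action off :precondition (p) :effect (not (p)) :observation put)
(:goal on-goal (and (p)))
"""


@pytest.fixture(scope="session")
def move_problem():
    return parse_problem(MOVE_SRC)


@pytest.fixture(scope="session")
def chain_problem():
    return parse_problem(CHAIN_SRC)


@pytest.fixture(scope="session")
def pair_problem():
    return parse_problem(PAIR_SRC)


@pytest.fixture(scope="session")
def toggle_problem():
    return parse_problem(TOGGLE_SRC)


@pytest.fixture(scope="session")
def small_kitchen():
    """One food, one beverage: 324 world states."""
    config = KitchenConfig(foods=(("pasta", True),), beverages=(("coffee", False),))
    problem = build_kitchen_problem(config)
    graph = reachable_states(problem)
    return config, problem, graph


@pytest.fixture(scope="session")
def small_scenario(small_kitchen):
    config, problem, graph = small_kitchen
    return ScenarioConfig(kitchen=config, max_steps=60)


@pytest.fixture(scope="session")
def full_kitchen():
    """The default four-meal kitchen (26k world states); session-scoped
    because the reachability closure takes a few seconds."""
    config = KitchenConfig()
    problem = build_kitchen_problem(config)
    graph = reachable_states(problem)
    return config, problem, graph


@pytest.fixture(scope="session")
def standard_params():
    return ActionSelectionParams(hazard_mode="standard")


@pytest.fixture
def durations_for():
    def make(graph):
        return DurationModel.from_actions(graph.actions)

    return make
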