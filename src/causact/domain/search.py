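"""State-space services: reachability closure, plan enumeration, goal
distance and the unsatisfied-predicate goal surrogate."""
from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass

import networkx as nx

from causact.domain.ground import ground
from causact.domain.model import GroundAction, Plan, Problem, WorldState
from causact.errors import CausactError, StateCapExceededError

__all__ = [
    "StateGraph",
    "reachable_states",
    "enumerate_plans",
    "goal_distance",
    "unsatisfied_goal_predicates",
]

DEFAULT_STATE_CAP = 1_000_000


@dataclass
class StateGraph:
    """Breadth-first closure of the world-state space from the initial state.

    ``graph`` is a :class:`networkx.MultiDiGraph` whose nodes are
    :class:`WorldState` and whose edges carry the ground action under key
    ``action``. ``actions`` is the stable grounded action list.
    """

    graph: nx.MultiDiGraph
    actions: list[GroundAction]
    initial: WorldState

    def __contains__(self, state: WorldState) -> bool:
        return state in self.graph

    @property
    def n_states(self) -> int:
        return self.graph.number_of_nodes()

    def applicable(self, state: WorldState) -> list[GroundAction]:
        return [a for a in self.actions if a.applicable(state)]


def reachable_states(problem: Problem, max_states: int = DEFAULT_STATE_CAP) -> StateGraph:
    """BFS closure from the initial state; nodes deduplicated by state
    equality, edges labelled with actions. Deterministic across runs.

    Raises :class:`StateCapExceededError` (carrying the partial graph and
    the frontier) when more than ``max_states`` states are discovered.
    """
    actions, _ = ground(problem)
    g = nx.MultiDiGraph()
    g.add_node(problem.init)
    frontier: deque[WorldState] = deque([problem.init])
    while frontier:
        state = frontier.popleft()
        for action in actions:
            if not action.applicable(state):
                continue
            nxt = action.apply(state)
            if nxt not in g:
                if g.number_of_nodes() >= max_states:
                    raise StateCapExceededError(
                        f"state cap {max_states} exceeded",
                        graph=StateGraph(g, actions, problem.init),
                        frontier=list(frontier) + [state],
                    )
                g.add_node(nxt)
                frontier.append(nxt)
            g.add_edge(state, nxt, action=action)
    return StateGraph(g, actions, problem.init)


def enumerate_plans(
    problem: Problem,
    goal_index: int,
    max_length: int,
    max_plans: int = 100_000,
    idle_cap: int = 0,
) -> tuple[list[Plan], bool]:
    """All valid plans from the initial state into the goal set.

    A plan ends at its first goal hit (no proper prefix achieves the goal),
    which keeps the set finite together with ``max_length``. Effect-free
    always-applicable actions (the idle/"unknown" class) may repeat at most
    ``idle_cap`` times per plan (default: excluded). Returns the plan list
    and a truncation flag raised when ``max_plans`` was hit.

    An unreachable goal yields an empty list, not an error.
    """
    goal = problem.goals[goal_index]
    actions, _ = ground(problem)
    idle = {
        (a.name, a.args) for a in actions if not a.add and not a.delete and not a.pre_pos and not a.pre_neg
    }
    plans: list[Plan] = []
    truncated = False

    def dfs(state: WorldState, prefix: list[GroundAction], idle_used: int) -> None:
        nonlocal truncated
        if truncated:
            return
        if goal.satisfied(state):
            plans.append(Plan(tuple(prefix)))
            if len(plans) >= max_plans:
                truncated = True
            return
        if len(prefix) >= max_length:
            return
        for action in actions:
            is_idle = (action.name, action.args) in idle
            if is_idle and idle_used >= idle_cap:
                continue
            if action.applicable(state):
                prefix.append(action)
                dfs(action.apply(state), prefix, idle_used + is_idle)
                prefix.pop()

    dfs(problem.init, [], 0)
    for p in plans:  # replay validation, cheap on toy domains
        assert goal.satisfied(p.replay(problem.init))
    return plans, truncated


def goal_distance(state: WorldState, goal_index: int, graph: StateGraph, problem: Problem) -> float:
    """Length of the shortest action sequence from ``state`` to any state in
    the goal set, computed on the reachability graph; ``math.inf`` when the
    goal set is unreachable from ``state``."""
    if state not in graph:
        raise CausactError("state not in the reachability graph")
    goal = problem.goals[goal_index]
    # backward BFS from all goal states; cache keyed by the goal spec itself
    # so a graph may be shared across problems differing only in goals
    key = ("_goal_dist_cache", goal)
    cache = graph.graph.graph.get(key)
    if cache is None:
        rev = graph.graph.reverse(copy=False)
        dist: dict[WorldState, int] = {}
        frontier = deque()
        for node in graph.graph.nodes:
            if goal.satisfied(node):
                dist[node] = 0
                frontier.append(node)
        while frontier:
            cur = frontier.popleft()
            for pred in rev.successors(cur):
                if pred not in dist:
                    dist[pred] = dist[cur] + 1
                    frontier.append(pred)
        cache = dist
        graph.graph.graph[key] = cache
    return cache.get(state, math.inf)


def unsatisfied_goal_predicates(state: WorldState, goal_index: int, problem: Problem) -> int:
    """Number of goal literals whose required value the state misses
    (cheap landmark-style surrogate for the goal distance)."""
    return problem.goals[goal_index].unsatisfied_count(state)
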