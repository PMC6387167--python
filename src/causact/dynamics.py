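"""Probabilistic semantics over the symbolic layer.

The latent state is the tuple (action, termination flag, goal, world state,
action start time, clock). Its transition kernel factors into five
sub-models: action execution, action selection, start-time bookkeeping,
duration-driven termination, and goal persistence. Time is the discrete
window index produced by preprocessing.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from causact.domain.model import GroundAction, Problem, WorldState
from causact.domain.search import (
    StateGraph,
    goal_distance,
    unsatisfied_goal_predicates,
)
from causact.errors import CausactError, DeadEndError

__all__ = [
    "CCBMState",
    "DurationModel",
    "ActionSelectionParams",
    "GoalPrior",
    "action_execution",
    "start_time_update",
    "termination_prob",
    "goal_persistence",
    "action_selection_dist",
    "initial_distribution",
    "sample_initial",
    "sample_transition",
    "transition_logprob",
    "enumerate_successors",
]

# f1 fallback when the goal is unreachable from a successor state: use the
# unsatisfied-predicate surrogate shifted down by a large constant so the
# support stays positive but such actions are strongly dispreferred.
UNREACHABLE_PENALTY = 1000.0

NEG_INF = float("-inf")


@dataclass(frozen=True)
class CCBMState:
    """Joint latent state at one time step.

    ``start`` is the step at which ``action`` began; ``time`` the current
    step; ``terminated`` records whether a new action was selected at this
    step (true at the initial step by convention).
    """

    action: GroundAction
    terminated: bool
    goal: int
    world: WorldState
    start: int
    time: int

    def __post_init__(self):
        if self.start > self.time:
            raise CausactError("action start time exceeds current time")

    @property
    def elapsed(self) -> int:
        return self.time - self.start


class DurationModel:
    """Per-action CDF over elapsed time driving the termination hazard.

    Families: ``("normal", mu, sd)``, ``("geometric", p)``,
    ``("uniform", a, b)`` and ``("empirical", samples)`` (a histogram CDF
    built from annotation inter-label gaps). The CDF is conditioned on the
    action's start time: ``F(v | a, u)`` evaluates the family CDF at
    ``v - u``; negative elapsed time has mass zero.
    """

    def __init__(self, specs: dict[str, tuple] | None = None, default: tuple = ("geometric", 0.5)):
        self.specs = dict(specs or {})
        self.default = default
        self._cache: dict[tuple, float] = {}

    @classmethod
    def from_actions(cls, actions: Sequence[GroundAction], default: tuple = ("geometric", 0.5)) -> "DurationModel":
        return cls({str(a): a.duration for a in actions}, default=default)

    @classmethod
    def from_durations(
        cls, durations: dict[str, Sequence[float]], default: tuple = ("geometric", 0.5)
    ) -> "DurationModel":
        """Empirical model from observed per-action duration samples."""
        return cls(
            {key: ("empirical", tuple(sorted(vals))) for key, vals in durations.items()},
            default=default,
        )

    def spec_for(self, action: GroundAction | str) -> tuple:
        key = action if isinstance(action, str) else str(action)
        return self.specs.get(key, self.default)

    def cdf(self, action: GroundAction | str, elapsed: float) -> float:
        """F(elapsed) for the action's duration family."""
        if elapsed < 0:
            return 0.0
        spec = self.spec_for(action)
        ck = (spec, elapsed)
        hit = self._cache.get(ck)
        if hit is not None:
            return hit
        out = self._cdf(spec, elapsed)
        self._cache[ck] = out
        return out

    def _cdf(self, spec: tuple, elapsed: float) -> float:
        fam = spec[0]
        if fam == "normal":
            mu, sd = spec[1], spec[2]
            return float(stats.norm.cdf(elapsed, loc=mu, scale=sd))
        if fam == "geometric":
            # support {1, 2, ...}: F(k) = 1 - (1-p)^floor(k)
            p = spec[1]
            return float(stats.geom.cdf(math.floor(elapsed), p))
        if fam == "uniform":
            a, b = spec[1], spec[2]
            return float(stats.uniform.cdf(elapsed, loc=a, scale=b - a))
        if fam == "empirical":
            samples = np.asarray(spec[1], dtype=float)
            if samples.size == 0:
                raise CausactError("empirical duration family with no samples")
            return float(np.mean(samples <= elapsed))
        raise CausactError(f"undefined duration family {fam!r}")


@dataclass
class ActionSelectionParams:
    """Log-linear action-selection configuration.

    ``lambda1`` weights the (negated) graph goal distance, ``lambda2`` the
    (negated) unsatisfied-goal-predicate surrogate. ``hazard_mode``
    selects the termination-probability denominator: ``"printed"`` uses
    1 - F(now); ``"standard"`` the textbook hazard 1 - F(prev).
    """

    lambda1: float = 1.0
    lambda2: float = 1.0
    hazard_mode: str = "printed"
    extra_features: tuple[tuple[float, Callable], ...] = ()

    def __post_init__(self):
        if self.hazard_mode not in ("printed", "standard"):
            raise CausactError(f"unknown hazard_mode {self.hazard_mode!r}")
        if not (math.isfinite(self.lambda1) and math.isfinite(self.lambda2)):
            raise CausactError("selection weights must be finite")


@dataclass
class GoalPrior:
    """Prior over goals; ``informed`` gives each target exactly ``factor``
    times every other goal's mass before normalisation. ``target`` is a
    goal index or a tuple of indices (multi-goal runs)."""

    mode: str = "uniform"
    target: int | tuple[int, ...] | None = None
    factor: float = 2.0

    def probabilities(self, n_goals: int) -> np.ndarray:
        if n_goals < 1:
            raise CausactError("need at least one goal")
        if self.mode == "uniform":
            return np.full(n_goals, 1.0 / n_goals)
        if self.mode == "informed":
            targets = self.target if isinstance(self.target, tuple) else (self.target,)
            if any(t is None or not 0 <= t < n_goals for t in targets):
                raise CausactError("informed prior needs valid target goal indices")
            w = np.ones(n_goals)
            for t in targets:
                w[t] = self.factor
            return w / w.sum()
        raise CausactError(f"unknown goal prior mode {self.mode!r}")


# ---------------------------------------------------------------------------
# the five sub-models


def action_execution(prev_world: WorldState, action: GroundAction, terminated: bool) -> WorldState:
    """Deterministic world update: unchanged unless a new action fired, in
    which case its effect is applied (probability mass exactly {0, 1})."""
    if not terminated:
        return prev_world
    return action.apply(prev_world)


def start_time_update(terminated: bool, prev_start: int, now: int) -> int:
    """Start-time bookkeeping: reset to the clock on termination."""
    if prev_start > now:
        raise CausactError("prev_start exceeds current time")
    return now if terminated else prev_start


def termination_prob(
    action: GroundAction | str,
    start: int,
    prev_time: int,
    now: int,
    durations: DurationModel,
    hazard_mode: str = "printed",
) -> float:
    """Probability that the running action terminates at ``now``.

    The printed form is (F(now) - F(prev)) / (1 - F(now)) with F conditioned
    on (action, start); ``standard`` swaps the denominator to 1 - F(prev).
    Values are clipped to [0, 1] and F(now) -> 1 means certain termination.
    """
    f_now = durations.cdf(action, now - start)
    f_prev = durations.cdf(action, prev_time - start)
    if f_now >= 1.0:
        return 1.0
    den = (1.0 - f_now) if hazard_mode == "printed" else (1.0 - f_prev)
    if den <= 0.0:
        return 1.0
    return min(1.0, max(0.0, (f_now - f_prev) / den))


def goal_persistence(prev_goal: int) -> int:
    """Once selected, the goal never changes."""
    return prev_goal


def _feature_sum(
    action: GroundAction,
    goal: int,
    prev_world: WorldState,
    params: ActionSelectionParams,
    graph: StateGraph,
    problem: Problem,
) -> float:
    succ = action.apply(prev_world)
    f2 = -float(unsatisfied_goal_predicates(succ, goal, problem))
    if succ in graph:
        d = goal_distance(succ, goal, graph, problem)
        f1 = -d if math.isfinite(d) else f2 - UNREACHABLE_PENALTY
    else:
        f1 = f2 - UNREACHABLE_PENALTY
    total = params.lambda1 * f1 + params.lambda2 * f2
    for lam, fn in params.extra_features:
        total += lam * fn(action, goal, prev_world)
    return total


def action_selection_dist(
    goal: int,
    prev_world: WorldState,
    params: ActionSelectionParams,
    graph: StateGraph,
    problem: Problem,
) -> dict[GroundAction, float]:
    """Softmax over applicable actions: mass proportional to
    exp(lambda1*f1 + lambda2*f2). Support is exactly the applicable set.

    Results are memoised on the graph keyed by (goal spec, world, weights),
    which stays valid across problems that share the grounding and differ
    only in their goal lists. Custom extra features bypass the cache.
    """
    cache_key = None
    if not params.extra_features:
        cache_key = (
            "_sel_cache",
            problem.goals[goal],
            prev_world,
            params.lambda1,
            params.lambda2,
        )
        hit = graph.graph.graph.get(cache_key)
        if hit is not None:
            return hit
    applicable = graph.applicable(prev_world)
    if not applicable:
        raise DeadEndError(f"no applicable action in {prev_world}")
    sums = np.array(
        [_feature_sum(a, goal, prev_world, params, graph, problem) for a in applicable]
    )
    sums -= sums.max()  # shift invariance
    w = np.exp(sums)
    w /= w.sum()
    out = dict(zip(applicable, w))
    if cache_key is not None:
        graph.graph.graph[cache_key] = out
    return out


# ---------------------------------------------------------------------------
# composed kernel


def initial_distribution(
    problem: Problem,
    graph: StateGraph,
    params: ActionSelectionParams,
    goal_prior: GoalPrior,
) -> list[tuple[CCBMState, float]]:
    """Joint distribution of the state at t=0: goal from the prior, first
    action from the selection model in the initial world, effect applied."""
    out = []
    gp = goal_prior.probabilities(len(problem.goals))
    for g, pg in enumerate(gp):
        dist = action_selection_dist(g, problem.init, params, graph, problem)
        for a, pa in dist.items():
            state = CCBMState(
                action=a,
                terminated=True,
                goal=g,
                world=a.apply(problem.init),
                start=0,
                time=0,
            )
            out.append((state, float(pg * pa)))
    return out


def sample_initial(
    problem: Problem,
    graph: StateGraph,
    params: ActionSelectionParams,
    goal_prior: GoalPrior,
    rng: np.random.Generator,
) -> CCBMState:
    states, probs = zip(*initial_distribution(problem, graph, params, goal_prior))
    idx = rng.choice(len(states), p=np.asarray(probs) / np.sum(probs))
    return states[idx]


def sample_transition(
    state: CCBMState,
    problem: Problem,
    graph: StateGraph,
    params: ActionSelectionParams,
    durations: DurationModel,
    rng: np.random.Generator,
) -> CCBMState:
    """Draw the successor state: termination, then goal persistence, action
    selection, action execution and start-time update, in dependency order."""
    now = state.time + 1
    h = termination_prob(
        state.action, state.start, state.time, now, durations, params.hazard_mode
    )
    terminated = bool(rng.random() < h)
    goal = goal_persistence(state.goal)
    if terminated:
        dist = action_selection_dist(goal, state.world, params, graph, problem)
        actions = list(dist)
        action = actions[rng.choice(len(actions), p=np.array([dist[a] for a in actions]))]
    else:
        action = state.action
    world = action_execution(state.world, action, terminated)
    start = start_time_update(terminated, state.start, now)
    return CCBMState(action=action, terminated=terminated, goal=goal, world=world, start=start, time=now)


def enumerate_successors(
    state: CCBMState,
    problem: Problem,
    graph: StateGraph,
    params: ActionSelectionParams,
    durations: DurationModel,
) -> list[tuple[CCBMState, float]]:
    """All successor states with their exact transition probabilities."""
    now = state.time + 1
    h = termination_prob(
        state.action, state.start, state.time, now, durations, params.hazard_mode
    )
    out: list[tuple[CCBMState, float]] = []
    if h < 1.0:
        out.append(
            (
                replace(state, terminated=False, time=now),
                1.0 - h,
            )
        )
    if h > 0.0:
        dist = action_selection_dist(state.goal, state.world, params, graph, problem)
        for a, pa in dist.items():
            if pa <= 0.0:
                continue
            out.append(
                (
                    CCBMState(
                        action=a,
                        terminated=True,
                        goal=state.goal,
                        world=a.apply(state.world),
                        start=now,
                        time=now,
                    ),
                    h * pa,
                )
            )
    return out


def transition_logprob(
    prev: CCBMState,
    next_state: CCBMState,
    problem: Problem,
    graph: StateGraph,
    params: ActionSelectionParams,
    durations: DurationModel,
) -> float:
    """Log probability of one transition: the sum of the five sub-model log
    terms; -inf for causally impossible transitions."""
    if next_state.time != prev.time + 1:
        return NEG_INF
    if next_state.goal != goal_persistence(prev.goal):
        return NEG_INF
    now = next_state.time
    h = termination_prob(
        prev.action, prev.start, prev.time, now, durations, params.hazard_mode
    )
    if next_state.terminated:
        if h <= 0.0:
            return NEG_INF
        dist = action_selection_dist(prev.goal, prev.world, params, graph, problem)
        pa = dist.get(next_state.action, 0.0)
        if pa <= 0.0:
            return NEG_INF
        if next_state.world != action_execution(prev.world, next_state.action, True):
            return NEG_INF
        if next_state.start != now:
            return NEG_INF
        return math.log(h) + math.log(pa)
    # not terminated: everything copied
    if h >= 1.0:
        return NEG_INF
    if (
        next_state.action != prev.action
        or next_state.world != prev.world
        or next_state.start != prev.start
    ):
        return NEG_INF
    return math.log(1.0 - h)
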