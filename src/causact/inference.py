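"""Bayesian filtering over the structured latent space.

Two engines are provided: an exact marginal filter that tracks the full
support of (action, goal, world, elapsed-time) tuples lazily, and a
particle filter with systematic resampling for spaces where the exact
support grows too large. Both consume per-step action-class likelihoods
from the observation model and emit per-step class and goal marginals.

The start-time variable is collapsed to elapsed time (clock minus start)
with a configurable maximum lag, which bounds the exact state space.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from causact.domain.model import Problem, WorldState
from causact.domain.search import StateGraph
from causact.dynamics import (
    ActionSelectionParams,
    CCBMState,
    DurationModel,
    GoalPrior,
    action_selection_dist,
    initial_distribution,
    sample_initial,
    sample_transition,
    termination_prob,
)
from causact.errors import CausactError, DegeneracyError
from causact.observation import ClassDistribution, state_weight

__all__ = [
    "FilterPosterior",
    "GoalEstimate",
    "ParticleSet",
    "exact_filter",
    "particle_filter",
    "decode_actions",
    "multigoal_estimate",
    "pooled_goal_recognised",
]

DEFAULT_MAX_LAG = 500
DEFAULT_SUPPORT_CAP = 2_000_000


@dataclass
class FilterPosterior:
    """Per-step filtered marginals over action classes and goals."""

    classes: tuple[str, ...]
    goal_names: tuple[str, ...]
    class_marginals: np.ndarray  # (T, n_classes)
    goal_marginals: np.ndarray  # (T, n_goals)
    support: list | None = None  # optional per-step [(key, weight), ...]

    def __post_init__(self):
        if self.class_marginals.shape[0] != self.goal_marginals.shape[0]:
            raise CausactError("marginal tracks differ in length")
        for m in (self.class_marginals, self.goal_marginals):
            if m.size and (np.any(m < -1e-12) or np.any(np.abs(m.sum(axis=1) - 1) > 1e-9)):
                raise CausactError("marginals must be distributions at every step")

    @property
    def n_steps(self) -> int:
        return self.class_marginals.shape[0]

    def goal_mode(self, t: int) -> int:
        """Posterior mode goal at step t; ties broken by goal order."""
        return int(np.argmax(self.goal_marginals[t]))


@dataclass
class GoalEstimate:
    """Multiple-goals evaluation of one run: the set of goals recognised at
    least once, the true set, and |est ∩ truth| / |est|."""

    est: frozenset[str]
    truth: frozenset[str]
    performance: float


@dataclass
class ParticleSet:
    states: list[CCBMState]
    weights: np.ndarray
    ess: float
    seed: int | None = None


# ---------------------------------------------------------------------------
# exact filter

# Collapsed exact-filter key: (action, goal, world, elapsed). Elapsed time 0
# marks a freshly selected action, so the termination flag is recoverable.
_Key = tuple


def _hazard(action, elapsed, durations, hazard_mode) -> float:
    # termination probability for the step elapsed -> elapsed + 1
    return termination_prob(action, 0, elapsed, elapsed + 1, durations, hazard_mode)


def exact_filter(
    problem: Problem,
    graph: StateGraph,
    params: ActionSelectionParams,
    durations: DurationModel,
    goal_prior: GoalPrior,
    observations: Sequence[ClassDistribution],
    env_likelihood: Callable[[WorldState], float] | None = None,
    max_lag: int = DEFAULT_MAX_LAG,
    support_cap: int = DEFAULT_SUPPORT_CAP,
    keep_support: bool = False,
) -> FilterPosterior:
    """Forward recursion over the collapsed latent support.

    Predict with the exact transition kernel, update with the action-class
    likelihood (environment factor optional), renormalise each step.
    Deterministic. Raises when the support exceeds ``support_cap``
    (fall back to :func:`particle_filter`) or when all weights vanish.
    """
    if not observations:
        raise CausactError("empty observation sequence")
    classes = observations[0].classes
    n_goals = len(problem.goals)
    goal_names = tuple(g.name for g in problem.goals)

    sel_cache: dict[tuple[int, WorldState], list] = {}

    def selection(goal: int, world: WorldState) -> list:
        """[(action, prob, successor world), ...] memoised per (goal, world)."""
        key = (goal, world)
        if key not in sel_cache:
            dist = action_selection_dist(goal, world, params, graph, problem)
            sel_cache[key] = [(a, pa, a.apply(world)) for a, pa in dist.items() if pa > 0.0]
        return sel_cache[key]

    belief: dict[_Key, float] = {}
    for st, p in initial_distribution(problem, graph, params, goal_prior):
        if p > 0:
            key = (st.action, st.goal, st.world, 0)
            belief[key] = belief.get(key, 0.0) + p

    class_marginals = []
    goal_marginals = []
    support_track = [] if keep_support else None

    for t, obs in enumerate(observations):
        if t > 0:
            nxt: dict[_Key, float] = {}
            # successors of the termination branch depend only on
            # (goal, world): accumulate terminating mass first, then expand
            # each bucket once over the selection distribution
            term_mass: dict[tuple[int, WorldState], float] = {}
            for (action, goal, world, elapsed), p in belief.items():
                h = _hazard(action, elapsed, durations, params.hazard_mode)
                if h < 1.0:
                    k = (action, goal, world, min(elapsed + 1, max_lag))
                    nxt[k] = nxt.get(k, 0.0) + p * (1.0 - h)
                if h > 0.0:
                    bk = (goal, world)
                    term_mass[bk] = term_mass.get(bk, 0.0) + p * h
            for (goal, world), mass in term_mass.items():
                for a, pa, succ in selection(goal, world):
                    k = (a, goal, succ, 0)
                    nxt[k] = nxt.get(k, 0.0) + mass * pa
            belief = nxt
            if len(belief) > support_cap:
                raise CausactError(
                    f"exact-filter support {len(belief)} exceeds cap {support_cap}; "
                    "use particle_filter instead"
                )
        # update
        total = 0.0
        for key in list(belief):
            action, goal, world, elapsed = key
            w = obs[action.action_class]
            if env_likelihood is not None:
                w *= float(env_likelihood(world))
            belief[key] *= w
            total += belief[key]
        if total <= 0.0:
            raise DegeneracyError("all filtering weights vanished", step=t)
        for key in belief:
            belief[key] /= total

        cm = np.zeros(len(classes))
        gm = np.zeros(n_goals)
        for (action, goal, _w, _e), p in belief.items():
            cm[classes.index(action.action_class)] += p
            gm[goal] += p
        class_marginals.append(cm)
        goal_marginals.append(gm)
        if keep_support:
            support_track.append(sorted(((str(k[0]), k[1], k[3]), v) for k, v in belief.items()))

    return FilterPosterior(
        classes=tuple(classes),
        goal_names=goal_names,
        class_marginals=np.array(class_marginals),
        goal_marginals=np.array(goal_marginals),
        support=support_track,
    )


# ---------------------------------------------------------------------------
# particle filter


def _systematic_resample(weights: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = len(weights)
    positions = (rng.random() + np.arange(n)) / n
    return np.searchsorted(np.cumsum(weights), positions).clip(max=n - 1)


def particle_filter(
    problem: Problem,
    graph: StateGraph,
    params: ActionSelectionParams,
    durations: DurationModel,
    goal_prior: GoalPrior,
    observations: Sequence[ClassDistribution],
    n_particles: int,
    seed: int,
    env_likelihood: Callable[[WorldState], float] | None = None,
    ess_threshold: float = 0.5,
) -> FilterPosterior:
    """Bootstrap particle filter with systematic resampling triggered when
    the effective sample size drops below ``ess_threshold * n_particles``.
    Reproducible under a fixed seed; converges to :func:`exact_filter`
    marginals as ``n_particles`` grows."""
    if n_particles < 1:
        raise CausactError("need at least one particle")
    if not observations:
        raise CausactError("empty observation sequence")
    rng = np.random.default_rng(seed)
    classes = observations[0].classes
    n_goals = len(problem.goals)

    particles = [
        sample_initial(problem, graph, params, goal_prior, rng) for _ in range(n_particles)
    ]
    weights = np.full(n_particles, 1.0 / n_particles)

    class_marginals = []
    goal_marginals = []

    for t, obs in enumerate(observations):
        if t > 0:
            particles = [
                sample_transition(p, problem, graph, params, durations, rng)
                for p in particles
            ]
        lik = np.array(
            [state_weight(obs, p, env_likelihood=env_likelihood) for p in particles]
        )
        weights = weights * lik
        total = weights.sum()
        if total <= 0.0:
            raise DegeneracyError(
                "all particle weights vanished (model-data contradiction)", step=t
            )
        weights = weights / total

        cm = np.zeros(len(classes))
        gm = np.zeros(n_goals)
        for p, w in zip(particles, weights):
            cm[classes.index(p.action.action_class)] += w
            gm[p.goal] += w
        class_marginals.append(cm)
        goal_marginals.append(gm)

        ess = 1.0 / np.sum(weights**2)
        if ess < ess_threshold * n_particles:
            idx = _systematic_resample(weights, rng)
            particles = [particles[i] for i in idx]
            weights = np.full(n_particles, 1.0 / n_particles)

    return FilterPosterior(
        classes=tuple(classes),
        goal_names=tuple(g.name for g in problem.goals),
        class_marginals=np.array(class_marginals),
        goal_marginals=np.array(goal_marginals),
    )


# ---------------------------------------------------------------------------
# decoding and goal estimation


def decode_actions(posterior: FilterPosterior) -> list[str]:
    """Per-step argmax class; ties broken by alphabetical class order."""
    out = []
    for t in range(posterior.n_steps):
        row = posterior.class_marginals[t]
        best = row.max()
        winners = [posterior.classes[i] for i in range(len(row)) if row[i] == best]
        out.append(min(winners))
    return out


def multigoal_estimate(
    posterior: FilterPosterior,
    truth: set[str] | frozenset[str],
    threshold: float | None = None,
) -> GoalEstimate:
    """Multiple-goals strategy: collect every goal recognised at least once
    (per-step posterior mode, or mass above ``threshold`` when given) and
    score |est ∩ truth| / |est|."""
    est: set[str] = set()
    for t in range(posterior.n_steps):
        if threshold is None:
            est.add(posterior.goal_names[posterior.goal_mode(t)])
        else:
            for g, mass in zip(posterior.goal_names, posterior.goal_marginals[t]):
                if mass > threshold:
                    est.add(g)
    if not est:
        raise CausactError("empty goal estimate")
    truth = frozenset(truth)
    return GoalEstimate(
        est=frozenset(est),
        truth=truth,
        performance=len(est & truth) / len(est),
    )


def pooled_goal_recognised(
    posterior: FilterPosterior,
    truth: str,
    persistence: int = 1,
) -> bool:
    """Pooled-goals strategy: the run counts as recognised when the goal
    posterior mode equals the true pooled goal at the final step and has
    held for the last ``persistence`` steps."""
    if persistence < 1:
        raise CausactError("persistence window must be >= 1")
    if posterior.n_steps < persistence:
        return False
    target = posterior.goal_names.index(truth)
    return all(
        posterior.goal_mode(t) == target
        for t in range(posterior.n_steps - persistence, posterior.n_steps)
    )
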