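"""Synthetic kitchen corpus: forward-simulates goal-directed cooking runs
from the causal dynamics and emits noisy sensor tables plus ground-truth
annotation, mirroring a 15-run corpus with per-run goal sets.

None of the emission defaults claim fidelity to any particular hardware;
they encode the qualitative sensor rationale (fetching raises fridge and
cupboard activations, preparing raises temperature/humidity, cleaning
raises water flow, moving toggles the movement sensor) and every value is
configurable.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace as dc_replace
from pathlib import Path

import numpy as np
import pandas as pd

from causact.domain.model import GoalSpec, GroundPredicate, Plan, Problem
from causact.domain.parser import parse_problem
from causact.domain.search import StateGraph, reachable_states
from causact.dynamics import (
    ActionSelectionParams,
    CCBMState,
    DurationModel,
    action_selection_dist,
    sample_transition,
)
from causact.errors import CausactError
from causact.observation import ACTION_CLASSES
from causact.preprocessing import AnnotationTrack

__all__ = [
    "SENSOR_CHANNELS",
    "COORD_CHANNELS",
    "KitchenConfig",
    "ScenarioConfig",
    "SimulatedRun",
    "kitchen_source",
    "build_kitchen_problem",
    "pooled_problem",
    "goal_categories",
    "simulate_run",
    "generate_corpus",
    "write_corpus",
]

SENSOR_CHANNELS = (
    "fridge",
    "kettle",
    "cupboard_top_left",
    "cupboard_top_right",
    "cupboard_sink",
    "drawer_middle",
    "drawer_bottom",
    "temperature",
    "humidity",
    "movement",
    "water_hot",
    "water_cold",
)
COORD_CHANNELS = ("x", "y", "z")

# channels raised by each action class; distinct signatures so that a
# zero-noise corpus is perfectly separable ("unknown" raises none)
DEFAULT_SIGNATURES = {
    "clean": ("water_hot", "water_cold"),
    "drink": ("kettle",),
    "eat": ("drawer_bottom",),
    "get": ("fridge", "cupboard_top_left"),
    "move": ("movement",),
    "prepare": ("temperature", "humidity"),
    "put": ("cupboard_sink", "drawer_middle"),
    "unknown": (),
}

LOCATION_CENTRES = {"kitchen": (1.0, 0.5, 1.0), "study": (4.0, 0.5, 2.5)}


@dataclass(frozen=True)
class KitchenConfig:
    """Which meals exist and whether each is healthy."""

    foods: tuple[tuple[str, bool], ...] = (("pasta", True), ("toast", False))
    beverages: tuple[tuple[str, bool], ...] = (("tea", True), ("coffee", False))

    @property
    def meals(self) -> tuple[str, ...]:
        return tuple(m for m, _ in self.foods + self.beverages)


def kitchen_source(config: KitchenConfig = KitchenConfig()) -> str:
    """Model source for the kitchen domain in the s-expression dialect."""
    foods = " ".join(m for m, _ in config.foods)
    beverages = " ".join(m for m, _ in config.beverages)
    goal_forms = "\n".join(
        f"(:goal {m} (and (consumed {m}) (cleaned)))" for m in config.meals
    )
    return f"""
(:types location - object item - object meal - object
        food - meal beverage - meal)
(:objects kitchen study - location
          ingredients tools - item
          {foods} - food
          {beverages} - beverage)
(:predicates (at ?l - location)
             (has ?i - item ?m - meal)
             (prepared ?m - meal)
             (consumed ?m - meal)
             (cleaned))
(:action move
  :parameters (?from ?to - location)
  :duration (geometric 0.5)
  :observation move
  :precondition (and (at ?from) (not (= ?from ?to)))
  :effect (and (not (at ?from)) (at ?to)))
(:action get
  :parameters (?i - item ?m - meal)
  :duration (geometric 0.5)
  :observation get
  :precondition (and (at kitchen) (not (has ?i ?m)) (not (prepared ?m)))
  :effect (has ?i ?m))
(:action put
  :parameters (?i - item ?m - meal)
  :duration (geometric 0.5)
  :observation put
  :precondition (and (at kitchen) (has ?i ?m) (consumed ?m))
  :effect (not (has ?i ?m)))
(:action prepare
  :parameters (?m - meal)
  :duration (uniform 0 4)
  :observation prepare
  :precondition (and (at kitchen) (has ingredients ?m) (has tools ?m)
                     (not (prepared ?m)))
  :effect (prepared ?m))
(:action eat
  :parameters (?m - food)
  :duration (normal 3 1)
  :observation eat
  :precondition (and (prepared ?m) (not (consumed ?m)))
  :effect (consumed ?m))
(:action drink
  :parameters (?m - beverage)
  :duration (normal 2 1)
  :observation drink
  :precondition (and (prepared ?m) (not (consumed ?m)))
  :effect (consumed ?m))
(:action clean
  :duration (geometric 0.5)
  :observation clean
  :precondition (and (at kitchen) (not (cleaned)))
  :effect (cleaned))
(:action unknown
  :duration (geometric 0.5)
  :observation unknown)
(:init (at kitchen))
{goal_forms}
"""


def build_kitchen_problem(config: KitchenConfig = KitchenConfig()) -> Problem:
    """Parse the kitchen domain: eight action classes over items, the two
    locations and the configured meal list, with one named goal per meal."""
    return parse_problem(kitchen_source(config))


def goal_categories(config: KitchenConfig = KitchenConfig()) -> dict[str, tuple[str, ...]]:
    """Healthy/unhealthy pools: category name -> member meal-goal names."""
    return {
        "healthy_meal": tuple(m for m, h in config.foods if h),
        "unhealthy_meal": tuple(m for m, h in config.foods if not h),
        "healthy_drink": tuple(m for m, h in config.beverages if h),
        "unhealthy_drink": tuple(m for m, h in config.beverages if not h),
    }


def pooled_problem(problem: Problem, goal_sets: list[frozenset[str]]) -> Problem:
    """Replace the goal list with one conjunction goal per distinct goal
    set (the pooled-goals targets). The pooled goal named ``"a+b"``
    requires every member meal consumed, plus the cleaned atom."""
    goals = []
    for gs in goal_sets:
        members = sorted(gs)
        goals.append(
            GoalSpec(
                name="+".join(members),
                pos=frozenset(
                    {GroundPredicate("consumed", (m,)) for m in members}
                    | {GroundPredicate("cleaned")}
                ),
            )
        )
    out = Problem(
        hierarchy=problem.hierarchy,
        objects=problem.objects,
        predicates=problem.predicates,
        templates=problem.templates,
        init=problem.init,
        goals=goals,
    )
    return out


@dataclass
class ScenarioConfig:
    """Simulation configuration for one corpus."""

    kitchen: KitchenConfig = field(default_factory=KitchenConfig)
    max_steps: int = 80
    noise: float = 0.05
    signatures: dict = field(default_factory=lambda: dict(DEFAULT_SIGNATURES))
    include_coords: bool = False
    coord_sd: float = 0.3
    selection: ActionSelectionParams = field(default_factory=lambda: ActionSelectionParams(hazard_mode="standard"))
    multi_goal: bool = True
    complete_first_run: bool = False

    def __post_init__(self):
        if not 0 <= self.noise <= 1:
            raise CausactError("noise level must be in [0, 1]")
        for cls, chans in self.signatures.items():
            if cls not in ACTION_CLASSES:
                raise CausactError(f"signature for unknown class {cls!r}")
            for c in chans:
                if c not in SENSOR_CHANNELS:
                    raise CausactError(f"unknown sensor channel {c!r}")


@dataclass
class SimulatedRun:
    """One simulated run: sensors, annotation, ground truth."""

    sensors: pd.DataFrame  # one row per step
    labels: list[str]  # action class per step
    annotation: AnnotationTrack
    plan: Plan
    goals: frozenset[str]  # true meal-goal set
    goal_name: str  # the problem goal the simulation pursued
    seed: int

    def table(self) -> pd.DataFrame:
        """Sensors plus a label column (for observation-model training)."""
        out = self.sensors.copy()
        out["label"] = self.labels
        return out


def _current_location(world) -> str:
    for loc in LOCATION_CENTRES:
        if world.value(GroundPredicate("at", (loc,))):
            return loc
    return "kitchen"


def _emit_row(config: ScenarioConfig, action_class: str, world, rng) -> dict[str, float]:
    active = set(config.signatures.get(action_class, ()))
    row = {}
    for ch in SENSOR_CHANNELS:
        p = 1.0 - config.noise if ch in active else config.noise
        row[ch] = float(rng.random() < p)
    if config.include_coords:
        centre = LOCATION_CENTRES[_current_location(world)]
        for ch, mu in zip(COORD_CHANNELS, centre):
            row[ch] = float(rng.normal(mu, config.coord_sd))
    return row


def simulate_run(
    config: ScenarioConfig,
    goal: str | int,
    seed: int,
    problem: Problem | None = None,
    graph: StateGraph | None = None,
    durations: DurationModel | None = None,
) -> SimulatedRun:
    """Sample one trajectory pursuing ``goal`` until its goal set is reached.

    Sensors are emitted from the per-class signature map; the annotation
    records every action start. Reproducible under ``seed``. Raises when
    the goal is not reached within ``config.max_steps``.
    """
    if problem is None:
        problem = build_kitchen_problem(config.kitchen)
    if graph is None:
        graph = reachable_states(problem)
    if durations is None:
        durations = DurationModel.from_actions(graph.actions)
    goal_index = goal if isinstance(goal, int) else problem.goal_index(goal)
    goal_spec = problem.goals[goal_index]
    rng = np.random.default_rng(seed)

    # initial action at t=0 for the fixed goal
    dist = action_selection_dist(goal_index, problem.init, config.selection, graph, problem)
    actions = list(dist)
    a0 = actions[rng.choice(len(actions), p=np.array([dist[a] for a in actions]))]
    state = CCBMState(
        action=a0, terminated=True, goal=goal_index, world=a0.apply(problem.init), start=0, time=0
    )

    rows = [_emit_row(config, a0.action_class, state.world, rng)]
    labels = [a0.action_class]
    entries = [(0, str(a0))]
    plan_actions = [a0]

    while not goal_spec.satisfied(state.world):
        if state.time >= config.max_steps:
            raise CausactError(
                f"goal {goal_spec.name!r} not reached within {config.max_steps} steps"
            )
        state = sample_transition(state, problem, graph, config.selection, durations, rng)
        if state.terminated:
            entries.append((state.time * 1000, str(state.action)))
            plan_actions.append(state.action)
        rows.append(_emit_row(config, state.action.action_class, state.world, rng))
        labels.append(state.action.action_class)

    return SimulatedRun(
        sensors=pd.DataFrame(rows),
        labels=labels,
        annotation=AnnotationTrack(entries=entries),
        plan=Plan(tuple(plan_actions)),
        goals=frozenset(_goal_members(goal_spec)),
        goal_name=goal_spec.name,
        seed=seed,
    )


def _goal_members(goal: GoalSpec) -> list[str]:
    return [a.args[0] for a in goal.pos if a.name == "consumed"]


def _complete_goal(problem: Problem, config: KitchenConfig) -> GoalSpec:
    """An everything goal for the designated first run: consume one food
    and one beverage, clean up, put things back and end in the study, so
    that every action class can occur."""
    food = config.foods[0][0]
    bev = config.beverages[0][0]
    return GoalSpec(
        name=f"{bev}+{food}",
        pos=frozenset(
            {
                GroundPredicate("consumed", (food,)),
                GroundPredicate("consumed", (bev,)),
                GroundPredicate("cleaned"),
                GroundPredicate("at", ("study",)),
            }
        ),
        neg=frozenset(
            {
                GroundPredicate("has", ("ingredients", food)),
                GroundPredicate("has", ("tools", food)),
            }
        ),
    )


def generate_corpus(
    config: ScenarioConfig, n_runs: int, seed: int
) -> tuple[list[SimulatedRun], list[dict]]:
    """Simulate a corpus of runs with varied goals and a manifest.

    Goals cycle through the meal list; with ``multi_goal`` every fifth run
    pursues a two-meal goal set. With ``complete_first_run`` the first run
    is resimulated (bounded retries) until all eight action classes occur.
    Returns ``(runs, manifest)``.
    """
    if n_runs < 1:
        raise CausactError("need at least one run")
    base = build_kitchen_problem(config.kitchen)
    graph = reachable_states(base)
    durations = DurationModel.from_actions(graph.actions)
    meals = config.kitchen.meals
    ss = np.random.SeedSequence(seed)
    run_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_runs + 64)]

    runs: list[SimulatedRun] = []
    manifest: list[dict] = []
    spare = n_runs  # index into extra spawned seeds for retries
    for i in range(n_runs):
        if i == 0 and config.complete_first_run:
            goal = _complete_goal(base, config.kitchen)
            problem = dc_replace_goals(base, [goal])
        elif config.multi_goal and i % 5 == 0:
            pair = frozenset({meals[i % len(meals)], meals[(i + 1) % len(meals)]})
            problem = pooled_problem(base, [pair])
        else:
            problem = base
        goal_name = problem.goals[0].name if problem is not base else meals[i % len(meals)]
        run = None
        attempts = 0
        while run is None:
            s = run_seeds[i] if attempts == 0 else run_seeds[spare]
            if attempts > 0:
                spare += 1
                if spare >= len(run_seeds):
                    raise CausactError("corpus generation exhausted retry seeds")
            try:
                cand = simulate_run(
                    config,
                    problem.goal_index(goal_name),
                    s,
                    problem=problem,
                    graph=graph,  # goal-independent; distance caches key on the goal spec
                    durations=durations,
                )
            except CausactError:
                attempts += 1
                continue
            if i == 0 and config.complete_first_run and set(cand.labels) != set(ACTION_CLASSES):
                attempts += 1
                continue
            run = cand
        runs.append(run)
        manifest.append(
            {
                "run": i,
                "goal_name": run.goal_name,
                "goals": sorted(run.goals),
                "length": len(run.labels),
                "seed": run.seed,
            }
        )
    return runs, manifest


def dc_replace_goals(problem: Problem, goals: list[GoalSpec]) -> Problem:
    return Problem(
        hierarchy=problem.hierarchy,
        objects=problem.objects,
        predicates=problem.predicates,
        templates=problem.templates,
        init=problem.init,
        goals=goals,
    )


def write_corpus(runs: list[SimulatedRun], manifest: list[dict], out_dir) -> None:
    """Write per-run sensors.csv, annotation.csv and truth.json plus a
    corpus manifest.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, run in enumerate(runs):
        d = out / f"run{i:02d}"
        d.mkdir(exist_ok=True)
        run.sensors.to_csv(d / "sensors.csv", index=False)
        run.annotation.to_frame().to_csv(d / "annotation.csv", index=False)
        (d / "truth.json").write_text(
            json.dumps(
                {
                    "goals": sorted(run.goals),
                    "goal_name": run.goal_name,
                    "plan": [str(a) for a in run.plan.actions],
                    "labels": run.labels,
                    "seed": run.seed,
                },
                indent=1,
            )
        )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
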