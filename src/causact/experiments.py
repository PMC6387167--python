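"""Evaluation harness: per-class accuracy, exhaustive feature-subset
selection with with/without-feature means, leave-one-out cross-validation,
the factorial activity-recognition (10 cells) and goal-recognition
(16 cells) designs, and paired Wilcoxon comparison between cells."""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from causact.dynamics import ActionSelectionParams, DurationModel, GoalPrior
from causact.domain.search import reachable_states
from causact.errors import CausactError
from causact.hmm import (
    build_joint_hmm,
    estimate_transitions,
    hmm_filter,
    joint_goal_posterior,
)
from causact.inference import (
    decode_actions,
    multigoal_estimate,
    particle_filter,
    pooled_goal_recognised,
)
from causact.kitchen import (
    ScenarioConfig,
    SimulatedRun,
    build_kitchen_problem,
    dc_replace_goals,
    goal_categories,
    pooled_problem,
)
from causact.observation import (
    ACTION_CLASSES,
    ClassDistribution,
    ObservationModel,
    ObservationModelSpec,
    train_observation_model,
)

__all__ = [
    "AccuracyMetric",
    "FeatureSweepResult",
    "FactorialResult",
    "HarnessConfig",
    "accuracy",
    "feature_sweep",
    "loocv",
    "ar_cells",
    "gr_cells",
    "factorial_ar",
    "factorial_gr",
    "paired_compare",
]


# ---------------------------------------------------------------------------
# accuracy


@dataclass
class AccuracyMetric:
    """Sum over classes of correctly recognised instances, divided by the
    total instance count; per-class counts retained."""

    per_class: dict[str, int]
    classes: tuple[str, ...]
    n: int
    value: float


def accuracy(predicted: Sequence[str], true: Sequence[str]) -> AccuracyMetric:
    if len(predicted) != len(true):
        raise CausactError("predicted and true label sequences differ in length")
    classes = tuple(sorted(set(true) | set(predicted)))
    per_class = {c: 0 for c in classes}
    for p, t in zip(predicted, true):
        if p == t:
            per_class[t] += 1
    n = len(true)
    value = sum(per_class.values()) / n if n else float("nan")
    return AccuracyMetric(per_class=per_class, classes=classes, n=n, value=value)


# ---------------------------------------------------------------------------
# feature selection


@dataclass
class FeatureSweepResult:
    features: tuple[str, ...]
    per_subset: dict[frozenset, float]
    with_mean: dict[str, float]
    without_mean: dict[str, float]
    best_subset: tuple[str, ...]
    best_value: float

    @property
    def n_subsets(self) -> int:
        return len(self.per_subset)


def feature_sweep(
    features: Sequence[str], evaluate: Callable[[tuple[str, ...]], float]
) -> FeatureSweepResult:
    """Evaluate every inclusion/exclusion subset (2^n, empty included).

    For each feature the mean accuracy over subsets containing it and over
    subsets lacking it is reported; the best subset is chosen by value,
    then smallest size, then lexicographic feature order.
    """
    features = tuple(features)
    if not features:
        raise CausactError("need at least one feature")
    per_subset: dict[frozenset, float] = {}
    for r in range(len(features) + 1):
        for combo in itertools.combinations(features, r):
            per_subset[frozenset(combo)] = float(evaluate(combo))
    with_mean = {}
    without_mean = {}
    for f in features:
        inn = [v for s, v in per_subset.items() if f in s]
        out = [v for s, v in per_subset.items() if f not in s]
        with_mean[f] = float(np.mean(inn))
        without_mean[f] = float(np.mean(out))
    best = max(
        per_subset.items(),
        key=lambda kv: (kv[1], -len(kv[0]), tuple(reversed(sorted(kv[0], reverse=True)))),
    )
    # tie-break deterministically: value desc, size asc, lexicographic asc
    candidates = [s for s, v in per_subset.items() if v == best[1]]
    chosen = min(candidates, key=lambda s: (len(s), tuple(sorted(s))))
    return FeatureSweepResult(
        features=features,
        per_subset=per_subset,
        with_mean=with_mean,
        without_mean=without_mean,
        best_subset=tuple(sorted(chosen)),
        best_value=best[1],
    )


def loocv(runs: Sequence, evaluate: Callable[[list, object], float]) -> float:
    """Mean over i of evaluate(train=all runs but i, test=run i)."""
    runs = list(runs)
    if len(runs) < 2:
        raise CausactError("leave-one-out needs at least two runs")
    scores = []
    for i, test in enumerate(runs):
        train = runs[:i] + runs[i + 1 :]
        scores.append(float(evaluate(train, test)))
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# factorial designs


@dataclass
class FactorialResult:
    design: str  # "ar" or "gr"
    cells: dict[tuple, dict]  # cell key -> {"per_run": [...], "summary": float, ...}

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key, res in self.cells.items():
            for i, v in enumerate(res["per_run"]):
                rows.append({"cell": "/".join(str(k) for k in key), "run": i, "value": v})
        return pd.DataFrame(rows)


@dataclass
class HarnessConfig:
    """Engine knobs for the factorial harness."""

    n_particles: int = 300
    seed: int = 0
    informed_factor: float = 2.0
    lambda1: float = 1.0
    lambda2: float = 1.0
    hazard_mode: str = "standard"
    persistence: int = 1


def ar_cells() -> list[tuple]:
    """The activity-recognition design: DT without the system-model factor,
    HMM and the causal model each in general/specialised variants, all
    crossed with the two observation-model protocols."""
    cells: list[tuple] = [("dt", None, om) for om in ("optimistic", "pessimistic")]
    for alg in ("hmm", "ccbm"):
        for sysmodel in ("general", "specialised"):
            for om in ("optimistic", "pessimistic"):
                cells.append((alg, sysmodel, om))
    return cells


def gr_cells() -> list[tuple]:
    """The goal-recognition design: algorithm x goal target x multigoal
    strategy x prior type."""
    return [
        (alg, target, strategy, prior)
        for alg in ("hmm", "ccbm")
        for target in ("meal", "healthy")
        for strategy in ("multiple", "pooled")
        for prior in ("informed", "uninformed")
    ]


def _train_oms(runs: Sequence[SimulatedRun]) -> dict[str, ObservationModel]:
    tables = [r.table() for r in runs]
    return {
        "optimistic": train_observation_model(tables, ObservationModelSpec("optimistic")),
        "pessimistic": train_observation_model(tables, ObservationModelSpec("pessimistic")),
    }


def _likelihoods(om: ObservationModel, run: SimulatedRun) -> list[ClassDistribution]:
    return om.predict_sequence(run.sensors)


def _run_problem(base, run: SimulatedRun):
    """Single-goal problem for a specialised model of one run."""
    if len(run.goals) > 1 or run.goal_name not in [g.name for g in base.goals]:
        return pooled_problem(base, [run.goals])
    return dc_replace_goals(base, [base.goals[base.goal_index(run.goal_name)]])


def factorial_ar(
    runs: Sequence[SimulatedRun],
    scenario: ScenarioConfig,
    config: HarnessConfig = HarnessConfig(),
) -> FactorialResult:
    """Evaluate all 10 activity-recognition cells on a corpus; each cell
    yields one accuracy per run."""
    runs = list(runs)
    oms = _train_oms(runs)
    base = build_kitchen_problem(scenario.kitchen)
    graph = reachable_states(base)
    durations = DurationModel.from_actions(graph.actions)
    params = ActionSelectionParams(
        lambda1=config.lambda1, lambda2=config.lambda2, hazard_mode=config.hazard_mode
    )

    hmm_general = estimate_transitions(
        [r.labels for r in runs], states=ACTION_CLASSES, flavour="general"
    )

    cells: dict[tuple, dict] = {}
    for cell in ar_cells():
        alg, sysmodel, om_name = cell
        om = oms[om_name]
        per_run = []
        for ridx, run in enumerate(runs):
            lik = _likelihoods(om, run)
            if alg == "dt":
                pred = [d.argmax() for d in lik]
            elif alg == "hmm":
                spec = (
                    hmm_general
                    if sysmodel == "general"
                    else estimate_transitions([run.labels], states=ACTION_CLASSES, flavour="specialised")
                )
                post = hmm_filter(spec, lik)
                pred = [
                    min(
                        c
                        for j, c in enumerate(spec.states)
                        if post[t, j] == post[t].max()
                    )
                    for t in range(len(lik))
                ]
            else:  # ccbm
                problem = base if sysmodel == "general" else _run_problem(base, run)
                posterior = particle_filter(
                    problem,
                    graph,
                    params,
                    durations,
                    GoalPrior("uniform"),
                    lik,
                    n_particles=config.n_particles,
                    seed=config.seed + 1000 * ridx,
                )
                pred = decode_actions(posterior)
            per_run.append(accuracy(pred, run.labels).value)
        cells[cell] = {"per_run": per_run, "summary": float(np.mean(per_run))}
    return FactorialResult(design="ar", cells=cells)


def _category_posterior(goal_marginals, goal_names, categories):
    cat_names = tuple(categories)
    out = np.zeros((goal_marginals.shape[0], len(cat_names)))
    for j, c in enumerate(cat_names):
        members = [goal_names.index(m) for m in categories[c] if m in goal_names]
        if members:
            out[:, j] = goal_marginals[:, members].sum(axis=1)
    return cat_names, out


def _mode_set(names, marginals) -> set[str]:
    return {names[int(np.argmax(row))] for row in marginals}


def factorial_gr(
    runs: Sequence[SimulatedRun],
    scenario: ScenarioConfig,
    config: HarnessConfig = HarnessConfig(),
    om_protocol: str = "pessimistic",
) -> FactorialResult:
    """Evaluate all 16 goal-recognition cells.

    ``multiple`` cells report the per-run set-overlap performance;
    ``pooled`` cells report a per-run recognised indicator (summary = count
    of recognised runs).
    """
    runs = list(runs)
    oms = _train_oms(runs)
    om = oms[om_protocol]
    base = build_kitchen_problem(scenario.kitchen)
    graph = reachable_states(base)
    durations = DurationModel.from_actions(graph.actions)
    params = ActionSelectionParams(
        lambda1=config.lambda1, lambda2=config.lambda2, hazard_mode=config.hazard_mode
    )
    categories = goal_categories(scenario.kitchen)
    meal_to_cat = {m: c for c, ms in categories.items() for m in ms}

    # distinct true goal sets define the pooled targets
    goal_sets = sorted({run.goals for run in runs}, key=lambda s: sorted(s))
    pooled = pooled_problem(base, list(goal_sets))
    pooled_names = tuple(g.name for g in pooled.goals)

    meal_names = tuple(g.name for g in base.goals)
    # per-goal HMM sub-models: trained on all runs where the goal occurs
    submodels = {}
    for m in meal_names:
        seqs = [r.labels for r in runs if m in r.goals]
        if seqs:
            submodels[m] = estimate_transitions(seqs, states=ACTION_CLASSES)
    sub_names = tuple(submodels)
    pooled_submodels = {}
    for gs in goal_sets:
        name = "+".join(sorted(gs))
        seqs = [r.labels for r in runs if r.goals == gs]
        pooled_submodels[name] = estimate_transitions(seqs, states=ACTION_CLASSES)

    def prior_vector(names: tuple[str, ...], targets: set[str], informed: bool) -> np.ndarray:
        w = np.ones(len(names))
        if informed:
            for i, nm in enumerate(names):
                if nm in targets:
                    w[i] = config.informed_factor
        return w / w.sum()

    lik_cache = {ridx: _likelihoods(om, run) for ridx, run in enumerate(runs)}

    cells: dict[tuple, dict] = {}
    for cell in gr_cells():
        alg, target, strategy, prior = cell
        informed = prior == "informed"
        per_run = []
        for ridx, run in enumerate(runs):
            lik = lik_cache[ridx]
            pooled_truth = "+".join(sorted(run.goals))
            if strategy == "pooled":
                names = pooled_names
                truth_names = {pooled_truth}
            else:
                names = meal_names if alg == "ccbm" else sub_names
                truth_names = set(run.goals)
            if alg == "hmm":
                if strategy == "pooled":
                    subs = [pooled_submodels[n] for n in pooled_names]
                    gp = prior_vector(pooled_names, truth_names, informed)
                    joint = build_joint_hmm(subs, pooled_names, gp)
                    gpost, _ = joint_goal_posterior(joint, lik)
                    names_used = pooled_names
                else:
                    subs = [submodels[n] for n in sub_names]
                    gp = prior_vector(sub_names, truth_names, informed)
                    joint = build_joint_hmm(subs, sub_names, gp)
                    gpost, _ = joint_goal_posterior(joint, lik)
                    names_used = sub_names
            else:  # ccbm
                problem = pooled if strategy == "pooled" else base
                names_used = pooled_names if strategy == "pooled" else meal_names
                if informed:
                    targets = tuple(
                        i for i, nm in enumerate(names_used) if nm in truth_names
                    )
                    gp = GoalPrior("informed", target=targets, factor=config.informed_factor)
                else:
                    gp = GoalPrior("uniform")
                posterior = particle_filter(
                    problem,
                    graph,
                    params,
                    durations,
                    gp,
                    lik,
                    n_particles=config.n_particles,
                    seed=config.seed + 1000 * ridx,
                )
                gpost = posterior.goal_marginals

            if strategy == "pooled":
                final_ok = all(
                    names_used[int(np.argmax(gpost[t]))] == pooled_truth
                    for t in range(
                        max(0, gpost.shape[0] - config.persistence), gpost.shape[0]
                    )
                )
                per_run.append(1.0 if final_ok else 0.0)
            else:
                if target == "healthy":
                    cat_names, cat_post = _category_posterior(gpost, list(names_used), categories)
                    est = _mode_set(cat_names, cat_post)
                    truth = {meal_to_cat[m] for m in run.goals if m in meal_to_cat}
                else:
                    est = _mode_set(list(names_used), gpost)
                    truth = set(run.goals)
                per_run.append(len(est & truth) / len(est) if est else 0.0)
        summary = float(np.sum(per_run)) if strategy == "pooled" else float(np.mean(per_run))
        cells[cell] = {"per_run": per_run, "summary": summary}
    return FactorialResult(design="gr", cells=cells)


# ---------------------------------------------------------------------------
# paired comparison


def paired_compare(cell_a: Sequence[float], cell_b: Sequence[float]) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired per-run values.

    Returns ``(signed_statistic, p_value)`` where the statistic is
    W+ - W- (positive when ``cell_a`` tends to exceed ``cell_b``); swapping
    the cells flips its sign. All-tied pairs yield (0.0, 1.0).
    """
    a = np.asarray(cell_a, dtype=float)
    b = np.asarray(cell_b, dtype=float)
    if a.shape != b.shape:
        raise CausactError("paired cells differ in length")
    diffs = a - b
    nz = diffs[diffs != 0]
    if nz.size == 0:
        return 0.0, 1.0
    w_plus = float(sstats.wilcoxon(a, b, alternative="greater", zero_method="wilcox").statistic)
    m = nz.size
    signed = 2.0 * w_plus - m * (m + 1) / 2.0
    p = float(sstats.wilcoxon(a, b, alternative="two-sided", zero_method="wilcox").pvalue)
    return signed, p
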