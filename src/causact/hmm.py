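"""Comparison models: an HMM over the eight action classes with transitions
and priors estimated by counting from annotation, and a joint HMM that
merges per-goal sub-models through a common start state for goal
recognition."""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from causact.errors import CausactError, DegeneracyError
from causact.observation import ClassDistribution

__all__ = [
    "HmmSpec",
    "JointHmm",
    "estimate_transitions",
    "hmm_filter",
    "build_joint_hmm",
    "joint_goal_posterior",
]


@dataclass
class HmmSpec:
    """States are action classes; rows of ``transition`` and the ``prior``
    each sum to 1."""

    states: tuple[str, ...]
    transition: np.ndarray
    prior: np.ndarray
    flavour: str = "general"  # "general" (pooled runs) or "specialised" (per run)

    def __post_init__(self):
        n = len(self.states)
        if self.transition.shape != (n, n) or self.prior.shape != (n,):
            raise CausactError("transition/prior shape does not match the state set")
        if np.any(np.abs(self.transition.sum(axis=1) - 1) > 1e-9) or abs(self.prior.sum() - 1) > 1e-9:
            raise CausactError("transition rows and prior must sum to 1")

    def to_frames(self) -> tuple[pd.DataFrame, pd.Series]:
        t = pd.DataFrame(self.transition, index=self.states, columns=self.states)
        p = pd.Series(self.prior, index=self.states, name="prior")
        return t, p


def estimate_transitions(
    annotations: Sequence[Sequence[str]],
    states: Sequence[str] | None = None,
    smoothing: float = 0.0,
    flavour: str = "general",
) -> HmmSpec:
    """Count-based estimation from one or more label sequences.

    transition(i, j) = count(i -> j) / count(i -> any); a state never left
    in the data keeps a self-loop of probability 1 (documented empty-row
    rule). Priors are proportional to state occurrence counts. ``smoothing``
    adds alpha to every transition count before normalising (default 0:
    raw counting).
    """
    seqs = [list(s) for s in annotations]
    if not seqs or all(len(s) == 0 for s in seqs):
        raise CausactError("empty annotation input")
    if states is None:
        states = tuple(sorted({lab for s in seqs for lab in s}))
    else:
        states = tuple(states)
    idx = {s: i for i, s in enumerate(states)}
    for s in seqs:
        for lab in s:
            if lab not in idx:
                raise CausactError(f"label {lab!r} outside the state set")

    n = len(states)
    counts = np.full((n, n), float(smoothing))
    occ = np.zeros(n)
    for s in seqs:
        for lab in s:
            occ[idx[lab]] += 1
        for a, b in zip(s, s[1:]):
            counts[idx[a], idx[b]] += 1
    transition = np.zeros((n, n))
    for i in range(n):
        row = counts[i]
        if row.sum() > 0:
            transition[i] = row / row.sum()
        else:
            transition[i, i] = 1.0  # empty-row rule: self-loop
    if occ.sum() == 0:
        raise CausactError("no observed states")
    prior = occ / occ.sum()
    return HmmSpec(states=states, transition=transition, prior=prior, flavour=flavour)


def _likelihood_matrix(
    observations: Sequence[ClassDistribution], states: tuple[str, ...]
) -> np.ndarray:
    out = np.empty((len(observations), len(states)))
    for t, obs in enumerate(observations):
        for j, s in enumerate(states):
            out[t, j] = obs[s]
    return out


def hmm_filter(spec: HmmSpec, observations: Sequence[ClassDistribution]) -> np.ndarray:
    """Standard forward recursion with per-step normalisation.

    Returns the (T, n_states) filtered posterior. Raises on an all-zero
    step likelihood.
    """
    lik = _likelihood_matrix(observations, spec.states)
    T, n = lik.shape
    post = np.empty((T, n))
    alpha = spec.prior * lik[0]
    for t in range(T):
        if t > 0:
            alpha = (post[t - 1] @ spec.transition) * lik[t]
        total = alpha.sum()
        if total <= 0.0:
            raise DegeneracyError("all forward weights vanished", step=t)
        post[t] = alpha / total
    return post


@dataclass
class JointHmm:
    """Per-goal sub-models merged through a common start state.

    Joint states are (action class, goal) tuples; there are no transitions
    between different goals' blocks. Start transitions are the goal prior
    times each sub-model's normalised state priors.
    """

    goals: tuple[str, ...]
    submodels: tuple[HmmSpec, ...]
    start_probs: tuple[np.ndarray, ...]  # per goal, over that goal's states

    @property
    def joint_states(self) -> list[tuple[str, str]]:
        return [(s, g) for g, m in zip(self.goals, self.submodels) for s in m.states]


def build_joint_hmm(
    submodels: Sequence[HmmSpec],
    goal_names: Sequence[str],
    goal_prior: np.ndarray | None = None,
) -> JointHmm:
    """Combine per-goal HMMs; sub-models may have different state subsets.

    ``goal_prior`` defaults to uniform; outgoing start-state probabilities
    sum to 1.
    """
    if not submodels:
        raise CausactError("need at least one sub-model")
    if len(submodels) != len(goal_names):
        raise CausactError("sub-model and goal-name counts differ")
    k = len(submodels)
    if goal_prior is None:
        goal_prior = np.full(k, 1.0 / k)
    goal_prior = np.asarray(goal_prior, dtype=float)
    if abs(goal_prior.sum() - 1.0) > 1e-9:
        raise CausactError("goal prior must sum to 1")
    start = tuple(gp * (m.prior / m.prior.sum()) for gp, m in zip(goal_prior, submodels))
    return JointHmm(goals=tuple(goal_names), submodels=tuple(submodels), start_probs=start)


def joint_goal_posterior(
    joint: JointHmm, observations: Sequence[ClassDistribution]
) -> tuple[np.ndarray, np.ndarray]:
    """Forward filter over the joint states, then marginalise each step's
    mass within every goal block.

    Returns ``(goal_posterior, state_posterior)`` of shapes (T, n_goals)
    and (T, n_joint_states).
    """
    blocks = []
    offset = 0
    for m in joint.submodels:
        blocks.append((offset, offset + len(m.states)))
        offset += len(m.states)
    n = offset
    prior = np.concatenate(joint.start_probs)
    transition = np.zeros((n, n))
    for (lo, hi), m in zip(blocks, joint.submodels):
        transition[lo:hi, lo:hi] = m.transition

    lik = np.concatenate(
        [_likelihood_matrix(observations, m.states) for m in joint.submodels], axis=1
    )
    T = lik.shape[0]
    state_post = np.empty((T, n))
    for t in range(T):
        alpha = (prior if t == 0 else state_post[t - 1] @ transition) * lik[t]
        total = alpha.sum()
        if total <= 0.0:
            raise DegeneracyError("all forward weights vanished", step=t)
        state_post[t] = alpha / total
    goal_post = np.stack([state_post[:, lo:hi].sum(axis=1) for lo, hi in blocks], axis=1)
    return goal_post, state_post
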