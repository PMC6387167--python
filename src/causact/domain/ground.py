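"""Grounding: instantiate templates and predicate schemas with concrete
objects, producing duplicate-free, deterministically ordered sets."""
from __future__ import annotations

import itertools
from typing import Iterable

from causact.domain.model import (
    GroundAction,
    GroundPredicate,
    Problem,
    WorldState,
    conjunction_literals,
)
from causact.errors import ApplicabilityError

__all__ = ["ground", "ground_predicates", "apply", "grounding_report"]


def ground_predicates(problem: Problem) -> list[GroundPredicate]:
    """All ground predicates P, in declaration then lexicographic order."""
    out: list[GroundPredicate] = []
    for name, sig in problem.predicates.items():
        pools = [problem.objects_of_type(t) for t in sig]
        for combo in itertools.product(*pools):
            out.append(GroundPredicate(name, combo))
    return out


def _instantiate(template, binding: dict[str, str]) -> GroundAction | None:
    """Substitute a parameter binding; returns None when a static equality
    constraint in the precondition rules the instance out."""

    def sub(args: Iterable[str]) -> tuple[str, ...]:
        return tuple(binding.get(a, a) for a in args)

    pos, neg, eqs = conjunction_literals(template.precondition)
    for required, a, b in eqs:
        if (binding.get(a, a) == binding.get(b, b)) != required:
            return None
    add, delete, eff_eqs = conjunction_literals(template.effect)
    if eff_eqs:
        raise ApplicabilityError(
            f"equality atoms are not allowed in effects (action {template.name!r})"
        )
    return GroundAction(
        name=template.name,
        args=tuple(binding[v] for v, _ in template.params),
        pre_pos=frozenset(GroundPredicate(n, sub(a)) for n, a in pos),
        pre_neg=frozenset(GroundPredicate(n, sub(a)) for n, a in neg),
        add=frozenset(GroundPredicate(n, sub(a)) for n, a in add),
        delete=frozenset(GroundPredicate(n, sub(a)) for n, a in delete),
        duration=template.duration,
        action_class=template.action_class,
    )


def ground(problem: Problem) -> tuple[list[GroundAction], list[GroundPredicate]]:
    """Ground all templates with all type-compatible objects.

    Ordering is stable: template declaration order, then lexicographic
    argument order. Instances violating a static equality constraint of the
    precondition are filtered out.
    """
    actions: list[GroundAction] = []
    seen = set()
    for template in problem.templates:
        pools = [problem.objects_of_type(t) for _, t in template.params]
        names = [v for v, _ in template.params]
        for combo in itertools.product(*pools):
            ga = _instantiate(template, dict(zip(names, combo)))
            if ga is not None and (ga.name, ga.args) not in seen:
                seen.add((ga.name, ga.args))
                actions.append(ga)
    return actions, ground_predicates(problem)


def apply(state: WorldState, action: GroundAction) -> WorldState:
    """Successor of ``state`` under ``action``; delete first, add wins.

    Raises :class:`~causact.errors.ApplicabilityError` when the
    precondition does not hold. The input state is never modified.
    """
    return action.apply(state)


def grounding_report(actions: Iterable[GroundAction]) -> str:
    """Tab-separated report: action, class, arguments."""
    lines = ["action\tclass\targuments"]
    for a in actions:
        lines.append(f"{a.name}\t{a.action_class}\t{' '.join(a.args)}")
    return "\n".join(lines) + "\n"
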