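"""Core symbolic types: type hierarchy, predicates, action templates,
world states, problems and plans.

Formulas are represented as nested tuples:

* ``("atom", name, args)`` — predicate atom, args are variables or objects
* ``("=", a, b)`` — equality between two terms
* ``("not", sub)`` — negation
* ``("and", (sub, ...))`` — conjunction

Only conjunction/negation over atoms and equalities are supported.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from causact.errors import ApplicabilityError, ParseError

ROOT_TYPE = "object"

Formula = tuple  # see module docstring


@dataclass(frozen=True)
class GroundPredicate:
    """A predicate applied to concrete objects, e.g. ``(at kitchen)``."""

    name: str
    args: tuple[str, ...] = ()

    def __str__(self) -> str:
        inner = " ".join((self.name,) + self.args)
        return f"({inner})"


class TypeHierarchy:
    """Forest of type names rooted at ``object``.

    ``parent`` maps each declared type to its father class; ``object`` is
    implicit and has no parent.
    """

    def __init__(self, parent: Mapping[str, str] | None = None):
        self.parent: dict[str, str] = dict(parent or {})
        self._check()

    def _check(self) -> None:
        for child, father in self.parent.items():
            if father != ROOT_TYPE and father not in self.parent:
                raise ParseError(f"undeclared parent type {father!r} of {child!r}")
            # cycle check: walk to root
            seen = {child}
            cur = father
            while cur != ROOT_TYPE:
                if cur in seen:
                    raise ParseError(f"type hierarchy has a cycle through {cur!r}")
                seen.add(cur)
                cur = self.parent[cur]

    @property
    def types(self) -> set[str]:
        return set(self.parent) | {ROOT_TYPE}

    def is_subtype(self, t: str, ancestor: str) -> bool:
        """True if ``t`` equals ``ancestor`` or is (transitively) below it."""
        while True:
            if t == ancestor:
                return True
            if t == ROOT_TYPE:
                return False
            t = self.parent[t]


@dataclass(frozen=True)
class ActionTemplate:
    """Lifted action rule: parameters, precondition, add/delete effects,
    a duration spec and an observation hook (the action-class name)."""

    name: str
    params: tuple[tuple[str, str], ...]  # (variable, type)
    precondition: Formula
    effect: Formula
    duration: tuple = ("geometric", 0.5)
    observation: str | None = None

    def __post_init__(self):
        declared = {v for v, _ in self.params}
        for f, label in ((self.precondition, "precondition"), (self.effect, "effect")):
            for v in _variables(f):
                if v not in declared:
                    raise ParseError(
                        f"variable {v!r} in {label} of action {self.name!r} "
                        "not among :parameters"
                    )

    @property
    def action_class(self) -> str:
        return self.observation if self.observation is not None else self.name


def _variables(formula: Formula) -> Iterable[str]:
    kind = formula[0]
    if kind == "atom":
        yield from (a for a in formula[2] if a.startswith("?"))
    elif kind == "=":
        yield from (a for a in formula[1:] if a.startswith("?"))
    elif kind == "not":
        yield from _variables(formula[1])
    elif kind == "and":
        for sub in formula[1]:
            yield from _variables(sub)
    else:  # pragma: no cover - parser rejects earlier
        raise ParseError(f"unknown formula kind {kind!r}")


@dataclass(frozen=True)
class GroundAction:
    """Fully instantiated action with a materialised precondition/effect.

    ``pre_pos``/``pre_neg`` are the atoms that must be true/false;
    ``add``/``delete`` the effect atoms. ``action_class`` is one of the
    coarse classes used by the observation model.
    """

    name: str
    args: tuple[str, ...]
    pre_pos: frozenset[GroundPredicate]
    pre_neg: frozenset[GroundPredicate]
    add: frozenset[GroundPredicate]
    delete: frozenset[GroundPredicate]
    duration: tuple = ("geometric", 0.5)
    action_class: str = ""

    def __str__(self) -> str:
        inner = " ".join((self.name,) + self.args)
        return f"({inner})"

    def applicable(self, state: "WorldState") -> bool:
        return all(state.value(p) for p in self.pre_pos) and not any(
            state.value(p) for p in self.pre_neg
        )

    def apply(self, state: "WorldState") -> "WorldState":
        """Successor state; raises if the precondition fails.

        Delete atoms are removed first, then add atoms inserted, so an atom
        that is both deleted and added ends up true.
        """
        if not self.applicable(state):
            raise ApplicabilityError(f"action {self} not applicable in {state}")
        return WorldState((state.true_atoms - self.delete) | self.add)


@dataclass(frozen=True)
class WorldState:
    """Truth assignment over the ground predicate set, stored as the set of
    true atoms (everything else is false). Hashable for deduplication."""

    true_atoms: frozenset[GroundPredicate]

    def __init__(self, true_atoms: Iterable[GroundPredicate] = ()):
        object.__setattr__(self, "true_atoms", frozenset(true_atoms))

    def value(self, atom: GroundPredicate) -> bool:
        return atom in self.true_atoms

    def __str__(self) -> str:
        inner = " ".join(sorted(str(a) for a in self.true_atoms))
        return f"{{{inner}}}"


@dataclass(frozen=True)
class GoalSpec:
    """A named goal: a partial assignment (conjunction of literals) that
    defines the goal-state set."""

    name: str
    pos: frozenset[GroundPredicate] = frozenset()
    neg: frozenset[GroundPredicate] = frozenset()

    def satisfied(self, state: WorldState) -> bool:
        return all(state.value(a) for a in self.pos) and not any(
            state.value(a) for a in self.neg
        )

    def unsatisfied_count(self, state: WorldState) -> int:
        """Number of goal literals whose required value the state misses."""
        return sum(1 for a in self.pos if not state.value(a)) + sum(
            1 for a in self.neg if state.value(a)
        )


@dataclass
class Problem:
    """A parsed and type-checked planning problem."""

    hierarchy: TypeHierarchy
    objects: dict[str, str]  # object -> type
    predicates: dict[str, tuple[str, ...]]  # name -> parameter types
    templates: list[ActionTemplate]
    init: WorldState
    goals: list[GoalSpec] = field(default_factory=list)

    def objects_of_type(self, t: str) -> list[str]:
        """Declared objects whose type is ``t`` or a subtype, sorted."""
        return sorted(
            o for o, ot in self.objects.items() if self.hierarchy.is_subtype(ot, t)
        )

    def goal_index(self, name: str) -> int:
        for i, g in enumerate(self.goals):
            if g.name == name:
                return i
        raise KeyError(name)


@dataclass(frozen=True)
class Plan:
    """An ordered, causally valid action sequence."""

    actions: tuple[GroundAction, ...]

    def __len__(self) -> int:
        return len(self.actions)

    def replay(self, state: WorldState) -> WorldState:
        """Execute the plan from ``state``; raises on any inapplicable step."""
        for a in self.actions:
            state = a.apply(state)
        return state

    def __str__(self) -> str:
        return " ".join(str(a) for a in self.actions)


def conjunction_literals(
    formula: Formula,
) -> tuple[list[tuple[str, tuple[str, ...]]], list[tuple[str, tuple[str, ...]]], list[tuple[bool, str, str]]]:
    """Flatten a conjunction/negation formula into positive atoms, negative
    atoms and (signed) equality constraints.

    Returns ``(pos, neg, eqs)`` where each atom is ``(name, args)`` and each
    equality is ``(required_truth, a, b)``.
    """
    pos: list[tuple[str, tuple[str, ...]]] = []
    neg: list[tuple[str, tuple[str, ...]]] = []
    eqs: list[tuple[bool, str, str]] = []

    def walk(f: Formula, negated: bool) -> None:
        kind = f[0]
        if kind == "atom":
            (neg if negated else pos).append((f[1], f[2]))
        elif kind == "=":
            eqs.append((not negated, f[1], f[2]))
        elif kind == "not":
            walk(f[1], not negated)
        elif kind == "and":
            if negated:
                raise ParseError("negated conjunctions are not supported")
            for sub in f[1]:
                walk(sub, False)
        else:  # pragma: no cover
            raise ParseError(f"unknown formula kind {kind!r}")

    walk(formula, False)
    return pos, neg, eqs
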