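"""Reader for the s-expression model dialect.

A model file is a sequence of top-level sections (optionally wrapped in a
single ``(define ...)`` form)::

    (:types location - object meal - object)
    (:objects kitchen study - location pasta tea - meal)
    (:predicates (at ?l - location) (prepared ?m - meal))
    (:action move
      :parameters (?from ?to - location)
      :duration (normal 30 5)
      :observation move
      :precondition (and (at ?from) (not (= ?from ?to)))
      :effect (and (not (at ?from)) (at ?to)))
    (:init (at kitchen))
    (:goal pasta (and (prepared pasta)))

Supported clauses are exactly ``:parameters``, ``:precondition`` (and/not
over atoms plus ``(= ?x ?y)`` equality atoms), ``:effect`` (and/not),
``:duration`` (``normal MEAN SD``, ``empirical FILE``, ``geometric P`` or
``uniform A B``) and ``:observation``. Anything else is rejected.
"""
from __future__ import annotations

from dataclasses import dataclass

from causact.domain.model import (
    ActionTemplate,
    Formula,
    GoalSpec,
    GroundPredicate,
    Problem,
    TypeHierarchy,
    WorldState,
)
from causact.errors import ParseError

__all__ = ["parse_problem", "tokenize"]


@dataclass(frozen=True)
class Token:
    text: str
    line: int
    column: int


def tokenize(text: str) -> list[Token]:
    """Split source into parens and symbols, tracking 1-based line/column.

    ``;`` starts a comment running to end of line.
    """
    tokens: list[Token] = []
    line, col = 1, 1
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c == "\n":
            line += 1
            col = 1
            i += 1
        elif c.isspace():
            col += 1
            i += 1
        elif c == ";":
            while i < n and text[i] != "\n":
                i += 1
        elif c in "()":
            tokens.append(Token(c, line, col))
            col += 1
            i += 1
        else:
            start = i
            start_col = col
            while i < n and not text[i].isspace() and text[i] not in "();":
                i += 1
                col += 1
            tokens.append(Token(text[start:i], line, start_col))
    return tokens


def _read_sexprs(tokens: list[Token]):
    """Parse a token stream into nested lists; atoms stay as Tokens."""
    forms = []
    stack: list[list] = []
    for tok in tokens:
        if tok.text == "(":
            stack.append([])
        elif tok.text == ")":
            if not stack:
                raise ParseError("unbalanced ')'", tok.line, tok.column)
            done = stack.pop()
            (stack[-1] if stack else forms).append(done)
        else:
            (stack[-1] if stack else forms).append(tok)
    if stack:
        raise ParseError("unbalanced '(': missing closing paren")
    return forms


def _sym(item, what: str = "symbol") -> Token:
    if not isinstance(item, Token):
        raise ParseError(f"expected {what}, got a list")
    return item


def _typed_list(items: list, what: str) -> list[tuple[str, str]]:
    """Parse ``a b - t c - u`` into [(a, t), (b, t), (c, u)]."""
    out: list[tuple[str, str]] = []
    pending: list[Token] = []
    i = 0
    while i < len(items):
        tok = _sym(items[i], what)
        if tok.text == "-":
            if not pending:
                raise ParseError(f"dangling '-' in {what} list", tok.line, tok.column)
            if i + 1 >= len(items):
                raise ParseError(f"missing type after '-' in {what} list", tok.line, tok.column)
            tname = _sym(items[i + 1]).text
            out.extend((p.text, tname) for p in pending)
            pending = []
            i += 2
        else:
            pending.append(tok)
            i += 1
    if pending:
        raise ParseError(
            f"untyped names in {what} list: {[p.text for p in pending]}",
            pending[0].line,
            pending[0].column,
        )
    return out


def _formula(form) -> Formula:
    if isinstance(form, Token):
        raise ParseError(f"expected a formula, got {form.text!r}", form.line, form.column)
    if not form:
        return ("and", ())
    head = _sym(form[0], "formula head")
    if head.text == "and":
        return ("and", tuple(_formula(f) for f in form[1:]))
    if head.text == "not":
        if len(form) != 2:
            raise ParseError("'not' takes exactly one argument", head.line, head.column)
        return ("not", _formula(form[1]))
    if head.text == "=":
        if len(form) != 3:
            raise ParseError("'=' takes exactly two arguments", head.line, head.column)
        return ("=", _sym(form[1]).text, _sym(form[2]).text)
    args = tuple(_sym(a, "atom argument").text for a in form[1:])
    return ("atom", head.text, args)


_DURATION_ARITY = {"normal": 2, "empirical": 1, "geometric": 1, "uniform": 2}


def _duration(form) -> tuple:
    head = _sym(form[0], "duration family")
    fam = head.text
    if fam not in _DURATION_ARITY:
        raise ParseError(f"unknown duration family {fam!r}", head.line, head.column)
    args = form[1:]
    if len(args) != _DURATION_ARITY[fam]:
        raise ParseError(
            f"duration family {fam!r} takes {_DURATION_ARITY[fam]} argument(s)",
            head.line,
            head.column,
        )
    if fam == "empirical":
        return (fam, _sym(args[0]).text)
    vals = []
    for a in args:
        tok = _sym(a)
        try:
            vals.append(float(tok.text))
        except ValueError:
            raise ParseError(f"expected a number, got {tok.text!r}", tok.line, tok.column)
    return (fam, *vals)


_ACTION_CLAUSES = {":parameters", ":precondition", ":effect", ":duration", ":observation"}


def _action(form) -> ActionTemplate:
    name = _sym(form[1], "action name").text
    clauses: dict[str, object] = {}
    i = 2
    while i < len(form):
        key = _sym(form[i], "clause keyword")
        if key.text not in _ACTION_CLAUSES:
            raise ParseError(f"unknown action clause {key.text!r}", key.line, key.column)
        if key.text in clauses:
            raise ParseError(f"duplicate clause {key.text!r}", key.line, key.column)
        if i + 1 >= len(form):
            raise ParseError(f"clause {key.text!r} missing its value", key.line, key.column)
        clauses[key.text] = form[i + 1]
        i += 2

    params: tuple[tuple[str, str], ...] = ()
    if ":parameters" in clauses:
        plist = clauses[":parameters"]
        if isinstance(plist, Token):
            raise ParseError(":parameters must be a list", plist.line, plist.column)
        params = tuple(_typed_list(plist, "parameter"))
        for v, _ in params:
            if not v.startswith("?"):
                raise ParseError(f"parameter {v!r} must start with '?'")

    pre = _formula(clauses[":precondition"]) if ":precondition" in clauses else ("and", ())
    eff = _formula(clauses[":effect"]) if ":effect" in clauses else ("and", ())
    dur = _duration(clauses[":duration"]) if ":duration" in clauses else ("geometric", 0.5)
    obs = _sym(clauses[":observation"]).text if ":observation" in clauses else None
    return ActionTemplate(
        name=name, params=params, precondition=pre, effect=eff, duration=dur, observation=obs
    )


def parse_problem(text: str) -> Problem:
    """Parse a model source string into a fully typed :class:`Problem`.

    Raises :class:`~causact.errors.ParseError` with line/column on syntax
    errors, undeclared names, or arity mismatches.
    """
    forms = _read_sexprs(tokenize(text))
    # unwrap a single (define ...) wrapper if present
    if (
        len(forms) == 1
        and forms[0]
        and isinstance(forms[0][0], Token)
        and forms[0][0].text == "define"
    ):
        forms = forms[0][1:]

    parent: dict[str, str] = {}
    objects: dict[str, str] = {}
    predicates: dict[str, tuple[str, ...]] = {}
    templates: list[ActionTemplate] = []
    init_atoms: list[GroundPredicate] = []
    goals: list[GoalSpec] = []

    for form in forms:
        if isinstance(form, Token):
            raise ParseError(f"unexpected top-level symbol {form.text!r}", form.line, form.column)
        if not form:
            raise ParseError("empty top-level form")
        head = _sym(form[0], "section keyword")
        if head.text == ":types":
            for child, father in _typed_list(form[1:], "type"):
                parent[child] = father
        elif head.text == ":objects":
            for name, tname in _typed_list(form[1:], "object"):
                objects[name] = tname
        elif head.text == ":predicates":
            for p in form[1:]:
                if isinstance(p, Token):
                    raise ParseError("predicate declaration must be a list", p.line, p.column)
                pname = _sym(p[0], "predicate name").text
                sig = tuple(t for _, t in _typed_list(p[1:], "predicate parameter"))
                predicates[pname] = sig
        elif head.text == ":action":
            templates.append(_action(form))
        elif head.text == ":init":
            for a in form[1:]:
                f = _formula(a)
                if f[0] != "atom":
                    raise ParseError(":init entries must be plain atoms")
                init_atoms.append(GroundPredicate(f[1], f[2]))
        elif head.text == ":goal":
            gname = _sym(form[1], "goal name").text
            body = _formula(form[2]) if len(form) > 2 else ("and", ())
            from causact.domain.model import conjunction_literals

            pos, neg, eqs = conjunction_literals(body)
            if eqs:
                raise ParseError("equality atoms are not allowed in goals")
            goals.append(
                GoalSpec(
                    name=gname,
                    pos=frozenset(GroundPredicate(n, a) for n, a in pos),
                    neg=frozenset(GroundPredicate(n, a) for n, a in neg),
                )
            )
        else:
            raise ParseError(f"unknown section {head.text!r}", head.line, head.column)

    hierarchy = TypeHierarchy(parent)
    for name, tname in objects.items():
        if tname not in hierarchy.types:
            raise ParseError(f"object {name!r} has undeclared type {tname!r}")
    for pname, sig in predicates.items():
        for t in sig:
            if t not in hierarchy.types:
                raise ParseError(f"predicate {pname!r} uses undeclared type {t!r}")

    problem = Problem(
        hierarchy=hierarchy,
        objects=objects,
        predicates=predicates,
        templates=templates,
        init=WorldState(init_atoms),
        goals=goals,
    )
    _typecheck(problem, init_atoms)
    return problem


def _typecheck(problem: Problem, init_atoms: list[GroundPredicate]) -> None:
    """Validate atoms in templates, init and goals against declarations."""

    def check_ground_atom(atom: GroundPredicate, where: str) -> None:
        if atom.name not in problem.predicates:
            raise ParseError(f"undeclared predicate {atom.name!r} in {where}")
        sig = problem.predicates[atom.name]
        if len(atom.args) != len(sig):
            raise ParseError(
                f"predicate {atom.name!r} takes {len(sig)} argument(s), "
                f"got {len(atom.args)} in {where}"
            )
        for obj, t in zip(atom.args, sig):
            if obj not in problem.objects:
                raise ParseError(f"undeclared object {obj!r} in {where}")
            if not problem.hierarchy.is_subtype(problem.objects[obj], t):
                raise ParseError(
                    f"object {obj!r} of type {problem.objects[obj]!r} does not "
                    f"fit parameter type {t!r} of predicate {atom.name!r} in {where}"
                )

    def check_formula(f: Formula, env: dict[str, str], where: str) -> None:
        kind = f[0]
        if kind == "atom":
            name, args = f[1], f[2]
            if name not in problem.predicates:
                raise ParseError(f"undeclared predicate {name!r} in {where}")
            sig = problem.predicates[name]
            if len(args) != len(sig):
                raise ParseError(
                    f"predicate {name!r} takes {len(sig)} argument(s), "
                    f"got {len(args)} in {where}"
                )
            for a, t in zip(args, sig):
                if a.startswith("?"):
                    at = env[a]
                    ok = problem.hierarchy.is_subtype(at, t) or problem.hierarchy.is_subtype(t, at)
                else:
                    if a not in problem.objects:
                        raise ParseError(f"undeclared object {a!r} in {where}")
                    ok = problem.hierarchy.is_subtype(problem.objects[a], t)
                if not ok:
                    raise ParseError(
                        f"argument {a!r} does not fit type {t!r} of predicate "
                        f"{name!r} in {where}"
                    )
        elif kind == "not":
            check_formula(f[1], env, where)
        elif kind == "and":
            for sub in f[1]:
                check_formula(sub, env, where)
        # "=" needs no predicate check

    for tmpl in problem.templates:
        for _, t in tmpl.params:
            if t not in problem.hierarchy.types:
                raise ParseError(
                    f"parameter type {t!r} of action {tmpl.name!r} is undeclared"
                )
        env = dict(tmpl.params)
        check_formula(tmpl.precondition, env, f"precondition of {tmpl.name!r}")
        check_formula(tmpl.effect, env, f"effect of {tmpl.name!r}")
    for atom in init_atoms:
        check_ground_atom(atom, ":init")
    for goal in problem.goals:
        for atom in goal.pos | goal.neg:
            check_ground_atom(atom, f"goal {goal.name!r}")
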