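"""Rule condition expressions and their compact prefix notation.

A rule's condition is a finite tree whose leaves are atomic predicates over a
patient evaluation state and whose inner nodes are AND / OR / NOT.  The
on-disk form is a prefix-notation string, e.g.::

    AND(AGE_GE[12 mo], DOSE_COUNT_EQ[0])
    AND(DOSE_COUNT_EQ[1], NOT(PRIOR_DOSE_VALID[2]), INTERVAL_SINCE_DOSE_GE[1, 28 d])
    CONDITION_PRESENT[PREGNANCY]

Comparators are part of the atom name (``AGE_GE`` vs ``AGE_GT``) so that the
>= / > distinction is explicit in the stored rule and can never be silently
coerced.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Optional, Tuple

from .errors import LogicParseError
from .quantities import Duration

__all__ = [
    "PredicateKind", "Comparator", "AtomicPredicate",
    "Expr", "Atom", "Not", "And", "Or",
    "parse_logic", "format_logic", "iter_atoms", "conjunctive_literals",
]


class PredicateKind(str, Enum):
    AGE_CMP = "AGE"
    DOSE_COUNT_CMP = "DOSE_COUNT"
    INTERVAL_SINCE_DOSE_CMP = "INTERVAL_SINCE_DOSE"
    CONDITION_PRESENT = "CONDITION_PRESENT"
    CONDITION_ABSENT = "CONDITION_ABSENT"
    PRIOR_DOSE_VALID = "PRIOR_DOSE_VALID"
    SEASON_WINDOW = "SEASON_WINDOW"


class Comparator(str, Enum):
    GE = "GE"
    GT = "GT"
    LE = "LE"
    LT = "LT"
    EQ = "EQ"


#: kinds whose atoms must carry a comparator
COMPARATOR_KINDS = frozenset({
    PredicateKind.AGE_CMP,
    PredicateKind.DOSE_COUNT_CMP,
    PredicateKind.INTERVAL_SINCE_DOSE_CMP,
})

_MMDD_RE = re.compile(r"^(0[1-9]|1[0-2])-(0[1-9]|[12]\d|3[01])$")


@dataclass(frozen=True)
class AtomicPredicate:
    kind: PredicateKind
    comparator: Optional[Comparator] = None
    threshold: Optional[Duration] = None   # AGE / INTERVAL thresholds
    count: Optional[int] = None            # DOSE_COUNT threshold
    code: Optional[str] = None             # condition / allergy code
    reference_dose: Optional[int] = None   # 1-based administered-dose index
    season: Optional[Tuple[str, str]] = None  # (MM-DD, MM-DD), inclusive

    def __post_init__(self):
        if self.kind in COMPARATOR_KINDS and self.comparator is None:
            raise ValueError(f"{self.kind.name} requires a comparator")
        if self.kind is PredicateKind.INTERVAL_SINCE_DOSE_CMP:
            if self.reference_dose is None or self.reference_dose < 1:
                raise ValueError("interval predicate needs reference_dose >= 1")
        if self.kind is PredicateKind.PRIOR_DOSE_VALID:
            if self.reference_dose is None or self.reference_dose < 1:
                raise ValueError("PRIOR_DOSE_VALID needs reference_dose >= 1")
        if self.kind in (PredicateKind.CONDITION_PRESENT, PredicateKind.CONDITION_ABSENT):
            if not self.code:
                raise ValueError("condition predicate needs a non-empty code")
        if self.kind is PredicateKind.SEASON_WINDOW:
            if self.season is None or not all(_MMDD_RE.match(s) for s in self.season):
                raise ValueError("season window needs two MM-DD bounds")


# --- expression tree --------------------------------------------------------

class Expr:
    """Base class; concrete nodes are Atom / Not / And / Or."""

    __slots__ = ()


@dataclass(frozen=True)
class Atom(Expr):
    pred: AtomicPredicate


@dataclass(frozen=True)
class Not(Expr):
    child: Expr


@dataclass(frozen=True)
class And(Expr):
    children: Tuple[Expr, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if len(self.children) < 2:
            raise ValueError("AND needs >= 2 children")


@dataclass(frozen=True)
class Or(Expr):
    children: Tuple[Expr, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if len(self.children) < 2:
            raise ValueError("OR needs >= 2 children")


def iter_atoms(expr: Expr, _path: Tuple[int, ...] = ()) -> Iterator[Tuple[Tuple[int, ...], AtomicPredicate]]:
    """Yield (path, predicate) for every leaf, in left-to-right order.

    The path is the sequence of child indices from the root; it identifies a
    leaf stably for test-case perturbation.
    """
    if isinstance(expr, Atom):
        yield _path, expr.pred
    elif isinstance(expr, Not):
        yield from iter_atoms(expr.child, _path + (0,))
    elif isinstance(expr, (And, Or)):
        for i, c in enumerate(expr.children):
            yield from iter_atoms(c, _path + (i,))
    else:  # pragma: no cover
        raise TypeError(type(expr))


def conjunctive_literals(expr: Expr):
    """Decompose an AND-of-literals expression.

    Returns a list of ``(path, predicate, negated)``.  Raises ``ValueError``
    for expressions that are not a conjunction of (possibly negated) atoms;
    executable rules in the shipped rulebase are kept in this shape so that
    boundary fixtures can be constructed mechanically.
    """
    def literal(e: Expr, path):
        if isinstance(e, Atom):
            return path, e.pred, False
        if isinstance(e, Not) and isinstance(e.child, Atom):
            return path + (0,), e.child.pred, True
        raise ValueError("not a conjunction of literals")

    if isinstance(e := expr, And):
        return [literal(c, (i,)) for i, c in enumerate(e.children)]
    return [literal(expr, ())]


# --- prefix-notation serialization -----------------------------------------

def format_atom(p: AtomicPredicate) -> str:
    if p.kind is PredicateKind.AGE_CMP:
        return f"AGE_{p.comparator.value}[{p.threshold}]"
    if p.kind is PredicateKind.DOSE_COUNT_CMP:
        return f"DOSE_COUNT_{p.comparator.value}[{p.count}]"
    if p.kind is PredicateKind.INTERVAL_SINCE_DOSE_CMP:
        return f"INTERVAL_SINCE_DOSE_{p.comparator.value}[{p.reference_dose}, {p.threshold}]"
    if p.kind is PredicateKind.CONDITION_PRESENT:
        return f"CONDITION_PRESENT[{p.code}]"
    if p.kind is PredicateKind.CONDITION_ABSENT:
        return f"CONDITION_ABSENT[{p.code}]"
    if p.kind is PredicateKind.PRIOR_DOSE_VALID:
        return f"PRIOR_DOSE_VALID[{p.reference_dose}]"
    if p.kind is PredicateKind.SEASON_WINDOW:
        return f"SEASON_WINDOW[{p.season[0]}, {p.season[1]}]"
    raise ValueError(p.kind)  # pragma: no cover


def format_logic(expr: Expr) -> str:
    if isinstance(expr, Atom):
        return format_atom(expr.pred)
    if isinstance(expr, Not):
        return f"NOT({format_logic(expr.child)})"
    if isinstance(expr, And):
        return "AND(" + ", ".join(format_logic(c) for c in expr.children) + ")"
    if isinstance(expr, Or):
        return "OR(" + ", ".join(format_logic(c) for c in expr.children) + ")"
    raise TypeError(type(expr))  # pragma: no cover


_ATOM_RE = re.compile(
    r"^(AGE|DOSE_COUNT|INTERVAL_SINCE_DOSE)_(GE|GT|LE|LT|EQ)$|"
    r"^(CONDITION_PRESENT|CONDITION_ABSENT|PRIOR_DOSE_VALID|SEASON_WINDOW)$"
)


def _parse_atom(name: str, args: str) -> AtomicPredicate:
    m = _ATOM_RE.match(name)
    if not m:
        raise LogicParseError(f"unknown predicate {name!r}")
    parts = [a.strip() for a in args.split(",")] if args.strip() else []
    try:
        if m.group(1) == "AGE":
            (thr,) = parts
            return AtomicPredicate(PredicateKind.AGE_CMP, Comparator(m.group(2)),
                                   threshold=Duration.parse(thr))
        if m.group(1) == "DOSE_COUNT":
            (n,) = parts
            return AtomicPredicate(PredicateKind.DOSE_COUNT_CMP, Comparator(m.group(2)),
                                   count=int(n))
        if m.group(1) == "INTERVAL_SINCE_DOSE":
            ref, thr = parts
            return AtomicPredicate(PredicateKind.INTERVAL_SINCE_DOSE_CMP, Comparator(m.group(2)),
                                   threshold=Duration.parse(thr), reference_dose=int(ref))
        kind = m.group(3)
        if kind in ("CONDITION_PRESENT", "CONDITION_ABSENT"):
            (code,) = parts
            return AtomicPredicate(PredicateKind(kind), code=code)
        if kind == "PRIOR_DOSE_VALID":
            (ref,) = parts
            return AtomicPredicate(PredicateKind.PRIOR_DOSE_VALID, reference_dose=int(ref))
        start, end = parts
        return AtomicPredicate(PredicateKind.SEASON_WINDOW, season=(start, end))
    except LogicParseError:
        raise
    except (ValueError, TypeError) as exc:
        raise LogicParseError(f"bad arguments for {name}[{args}]: {exc}") from exc


_TOKEN_RE = re.compile(r"\s*([A-Z_]+|\(|\)|,)")


def parse_logic(text: str) -> Expr:
    """Parse the prefix notation back into an expression tree."""
    pos = 0
    n = len(text)

    def error(msg):
        raise LogicParseError(f"{msg} at offset {pos} in {text!r}")

    def skip_ws():
        nonlocal pos
        while pos < n and text[pos].isspace():
            pos += 1

    def parse_expr():
        nonlocal pos
        m = _TOKEN_RE.match(text, pos)
        if not m or m.group(1) in ("(", ")", ","):
            error("expected a predicate or operator")
        name = m.group(1)
        pos = m.end()
        if name in ("AND", "OR", "NOT"):
            skip_ws()
            if pos >= n or text[pos] != "(":
                error(f"expected '(' after {name}")
            pos += 1
            children = [parse_expr()]
            skip_ws()
            while pos < n and text[pos] == ",":
                pos += 1
                children.append(parse_expr())
                skip_ws()
            if pos >= n or text[pos] != ")":
                error("expected ')'")
            pos += 1
            try:
                if name == "NOT":
                    if len(children) != 1:
                        error("NOT takes exactly one child")
                    return Not(children[0])
                return (And if name == "AND" else Or)(tuple(children))
            except ValueError as exc:
                error(str(exc))
        # atom: NAME[args]
        skip_ws()
        if pos >= n or text[pos] != "[":
            error(f"expected '[' after {name}")
        close = text.find("]", pos)
        if close < 0:
            error("unterminated '['")
        args = text[pos + 1:close]
        pos = close + 1
        return Atom(_parse_atom(name, args))

    expr = parse_expr()
    if text[pos:].strip():
        error("trailing input")
    return expr
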