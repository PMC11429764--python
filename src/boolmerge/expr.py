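"""Boolean update-rule expressions.

A rule is an immutable expression tree over named regulators with the three
logical connectives used throughout the Boolean-network literature: NOT
(``!``), AND (``&``) and OR (``|``), plus the constants ``0``/``1`` so that a
clamped (mutated) node is itself representable as a rule.

The concrete syntax follows the common BoolNet/GINsim convention: precedence
``!`` > ``&`` > ``|``, left-associative, parentheses allowed, whitespace
ignored, case-sensitive symbols matching ``[A-Za-z0-9_.-]+``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Mapping

import numpy as np

from .errors import CapExceededError, MissingVariableError, RuleSyntaxError

__all__ = [
    "BoolExpr",
    "Var",
    "Not",
    "And",
    "Or",
    "Const",
    "InfluenceSign",
    "parse_rule",
    "render",
    "evaluate",
    "support",
    "truth_table",
    "classify_influence",
    "exprs_equivalent",
]

_NAME_RE = re.compile(r"[A-Za-z0-9_.-]+")

DEFAULT_SIGN_CAP = 16
DEFAULT_EQUIV_CAP = 20


class InfluenceSign(Enum):
    """Sign of a regulator's influence on a Boolean function.

    ACTIVATOR: flipping the regulator 0->1 never lowers the output and raises
    it in at least one context. INHIBITOR: the mirror image. DUAL: raises it
    in some context and lowers it in another (non-monotone). NONE: the
    regulator is fictitious — it never changes the output.
    """

    ACTIVATOR = "activator"
    INHIBITOR = "inhibitor"
    DUAL = "dual"
    NONE = "none"


@dataclass(frozen=True)
class BoolExpr:
    """Immutable node of a rule tree.

    kind is one of VAR, NOT, AND, OR, CONST. VAR carries ``name``, CONST
    carries ``value`` (0/1); NOT has one child, AND/OR at least two.
    """

    kind: str
    name: str | None = None
    value: int | None = None
    children: tuple["BoolExpr", ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.kind == "VAR":
            if not self.name or not _NAME_RE.fullmatch(self.name):
                raise ValueError(f"invalid regulator name {self.name!r}")
            if self.children:
                raise ValueError("VAR takes no children")
        elif self.kind == "CONST":
            if self.value not in (0, 1):
                raise ValueError(f"CONST value must be 0 or 1, got {self.value!r}")
            if self.children:
                raise ValueError("CONST takes no children")
        elif self.kind == "NOT":
            if len(self.children) != 1:
                raise ValueError("NOT takes exactly one child")
        elif self.kind in ("AND", "OR"):
            if len(self.children) < 2:
                raise ValueError(f"{self.kind} takes at least two children")
        else:
            raise ValueError(f"unknown expression kind {self.kind!r}")

    def __str__(self) -> str:
        return render(self)

    def walk(self) -> Iterator["BoolExpr"]:
        yield self
        for child in self.children:
            yield from child.walk()


def Var(name: str) -> BoolExpr:
    return BoolExpr("VAR", name=name)


def Const(value: int) -> BoolExpr:
    return BoolExpr("CONST", value=int(value))


def Not(child: BoolExpr) -> BoolExpr:
    return BoolExpr("NOT", children=(child,))


def And(*children: BoolExpr) -> BoolExpr:
    if len(children) == 1:
        return children[0]
    return BoolExpr("AND", children=tuple(children))


def Or(*children: BoolExpr) -> BoolExpr:
    if len(children) == 1:
        return children[0]
    return BoolExpr("OR", children=tuple(children))


# --- parsing -----------------------------------------------------------------

_TOKEN_RE = re.compile(r"\s*(?:(?P<name>[A-Za-z0-9_.-]+)|(?P<op>[!&|()]))")


class _Parser:
    """Recursive-descent parser for the ``! > & > |`` grammar."""

    def __init__(self, text: str):
        self.text = text
        self.pos = 0
        self.tokens: list[tuple[str, int]] = []
        pos = 0
        while pos < len(text):
            if text[pos].isspace():
                pos += 1
                continue
            m = _TOKEN_RE.match(text, pos)
            if m is None:
                raise RuleSyntaxError(f"unexpected character {text[pos]!r}", pos)
            if m.group("name") is not None:
                self.tokens.append((m.group("name"), m.start("name")))
            elif m.group("op") is not None:
                self.tokens.append((m.group("op"), m.start("op")))
            pos = m.end()
        self.index = 0

    def peek(self) -> str | None:
        if self.index < len(self.tokens):
            return self.tokens[self.index][0]
        return None

    def here(self) -> int:
        if self.index < len(self.tokens):
            return self.tokens[self.index][1]
        return len(self.text)

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise RuleSyntaxError("unexpected end of rule", len(self.text))
        self.index += 1
        return tok

    def parse(self) -> BoolExpr:
        if not self.tokens:
            raise RuleSyntaxError("empty rule", 0)
        expr = self.disjunction()
        if self.peek() is not None:
            raise RuleSyntaxError(f"unexpected token {self.peek()!r}", self.here())
        return expr

    def disjunction(self) -> BoolExpr:
        terms = [self.conjunction()]
        while self.peek() == "|":
            self.take()
            terms.append(self.conjunction())
        return Or(*terms)

    def conjunction(self) -> BoolExpr:
        factors = [self.factor()]
        while self.peek() == "&":
            self.take()
            factors.append(self.factor())
        return And(*factors)

    def factor(self) -> BoolExpr:
        tok = self.peek()
        if tok is None:
            raise RuleSyntaxError("unexpected end of rule", len(self.text))
        if tok == "!":
            self.take()
            return Not(self.factor())
        if tok == "(":
            open_at = self.here()
            self.take()
            inner = self.disjunction()
            if self.peek() != ")":
                raise RuleSyntaxError("unclosed parenthesis", open_at)
            self.take()
            return inner
        if tok in (")", "&", "|"):
            raise RuleSyntaxError(f"unexpected token {tok!r}", self.here())
        self.take()
        if tok in ("0", "1"):
            return Const(int(tok))
        return Var(tok)


def parse_rule(text: str) -> BoolExpr:
    """Parse a rule string into a :class:`BoolExpr`.

    Raises :class:`RuleSyntaxError` (with the offending position) on
    malformed or empty input.
    """
    if not isinstance(text, str):
        raise TypeError("rule must be a string")
    return _Parser(text).parse()


_PRECEDENCE = {"OR": 1, "AND": 2, "NOT": 3, "VAR": 4, "CONST": 4}


def render(expr: BoolExpr) -> str:
    """Serialize an expression; ``parse_rule(render(e))`` is equivalent to e."""

    def go(e: BoolExpr, parent_prec: int) -> str:
        prec = _PRECEDENCE[e.kind]
        if e.kind == "VAR":
            out = e.name  # type: ignore[assignment]
        elif e.kind == "CONST":
            out = str(e.value)
        elif e.kind == "NOT":
            out = "!" + go(e.children[0], prec)
        else:
            sep = " & " if e.kind == "AND" else " | "
            out = sep.join(go(c, prec) for c in e.children)
        if prec < parent_prec:
            return "(" + out + ")"
        return out  # type: ignore[return-value]

    return go(expr, 0)


# --- semantics ---------------------------------------------------------------

def evaluate(expr: BoolExpr, state: Mapping[str, int]) -> int:
    """Evaluate under an assignment; raises MissingVariableError if a
    regulator in the support is absent from ``state``."""
    if expr.kind == "CONST":
        return expr.value  # type: ignore[return-value]
    if expr.kind == "VAR":
        try:
            return 1 if state[expr.name] else 0  # type: ignore[index]
        except KeyError:
            raise MissingVariableError(expr.name) from None  # type: ignore[arg-type]
    if expr.kind == "NOT":
        return 1 - evaluate(expr.children[0], state)
    if expr.kind == "AND":
        result = 1
        for child in expr.children:  # total: no short-circuit, so missing vars surface
            result &= evaluate(child, state)
        return result
    result = 0
    for child in expr.children:
        result |= evaluate(child, state)
    return result


def support(expr: BoolExpr) -> frozenset[str]:
    """The set of regulator names appearing in the tree."""
    return frozenset(e.name for e in expr.walk() if e.kind == "VAR")  # type: ignore[misc]


def truth_table(expr: BoolExpr, variables: list[str]) -> np.ndarray:
    """Boolean vector of length 2**len(variables).

    Row index i assigns variables[j] the bit ``(i >> j) & 1`` (first variable
    = least-significant bit). Vectorized so exhaustive checks stay cheap.
    """
    n = len(variables)
    index = {v: j for j, v in enumerate(variables)}
    size = 1 << n
    arange = np.arange(size, dtype=np.int64)

    def go(e: BoolExpr) -> np.ndarray:
        if e.kind == "CONST":
            return np.full(size, bool(e.value))
        if e.kind == "VAR":
            if e.name not in index:
                raise MissingVariableError(e.name)  # type: ignore[arg-type]
            return ((arange >> index[e.name]) & 1).astype(bool)
        if e.kind == "NOT":
            return ~go(e.children[0])
        tables = [go(c) for c in e.children]
        out = tables[0].copy()
        for t in tables[1:]:
            if e.kind == "AND":
                out &= t
            else:
                out |= t
        return out

    return go(expr)


def classify_influence(
    expr: BoolExpr, var: str, cap: int = DEFAULT_SIGN_CAP
) -> InfluenceSign:
    """Sign of ``var``'s influence on ``expr`` by exhaustive context check.

    Enumerates all assignments of the other regulators; compares the output
    with var=0 vs var=1 in each context.
    """
    sup = support(expr)
    if var not in sup:
        raise MissingVariableError(var)
    if len(sup) > cap:
        raise CapExceededError(
            f"support size {len(sup)} exceeds influence-classification cap {cap}"
        )
    variables = sorted(sup)
    variables.remove(var)
    variables.append(var)  # var = most-significant bit: table splits in halves
    table = truth_table(expr, variables)
    half = table.size // 2
    low, high = table[:half], table[half:]
    raises = bool(np.any(high & ~low))
    lowers = bool(np.any(low & ~high))
    if raises and lowers:
        return InfluenceSign.DUAL
    if raises:
        return InfluenceSign.ACTIVATOR
    if lowers:
        return InfluenceSign.INHIBITOR
    return InfluenceSign.NONE


def exprs_equivalent(
    e1: BoolExpr, e2: BoolExpr, cap: int = DEFAULT_EQUIV_CAP
) -> bool:
    """True iff the truth tables over the union support agree everywhere."""
    union = sorted(support(e1) | support(e2))
    if len(union) > cap:
        raise CapExceededError(
            f"union support size {len(union)} exceeds equivalence cap {cap}"
        )
    return bool(np.array_equal(truth_table(e1, union), truth_table(e2, union)))
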