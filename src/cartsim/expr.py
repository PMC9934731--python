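"""Boolean rule expressions: AST, parser, evaluator, serializer.

Update functions are plain Boolean formulas over node names with the
operators ``!`` (NOT), ``&`` (AND) and ``|`` (OR), the literals ``0``/``1``
and parentheses.  Precedence is ``!`` > ``&`` > ``|``; the binary operators
are left-associative and n-ary chains are flattened, so ``A & B & C`` parses
to a single AND node with three children.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Mapping

__all__ = [
    "Kind",
    "BoolExpr",
    "ParseError",
    "EvalError",
    "parse_expression",
    "eval_expr",
    "CONST",
    "VAR",
    "NOT",
    "AND",
    "OR",
]

_IDENT_RE = re.compile(r"[A-Za-z][A-Za-z0-9_]*")


class Kind(Enum):
    CONST = "const"
    VAR = "var"
    NOT = "not"
    AND = "and"
    OR = "or"


class ParseError(ValueError):
    """Raised on malformed rule text; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class EvalError(KeyError):
    """Raised when a rule references a name absent from the state."""


@dataclass(frozen=True)
class BoolExpr:
    """Immutable node of a Boolean-formula syntax tree."""

    kind: Kind
    value: int | None = None  # CONST only
    name: str | None = None  # VAR only
    children: tuple["BoolExpr", ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.kind is Kind.CONST:
            if self.value not in (0, 1):
                raise ValueError(f"CONST value must be 0 or 1, got {self.value!r}")
        elif self.kind is Kind.VAR:
            if not (self.name and _IDENT_RE.fullmatch(self.name)):
                raise ValueError(f"invalid variable name {self.name!r}")
        elif self.kind is Kind.NOT:
            if len(self.children) != 1:
                raise ValueError("NOT takes exactly one child")
        else:  # AND / OR
            if len(self.children) < 2:
                raise ValueError(f"{self.kind.name} needs at least two children")

    # -- queries ----------------------------------------------------------

    def variables(self) -> set[str]:
        """Names of all variables appearing in the expression."""
        return {e.name for e in self.walk() if e.kind is Kind.VAR}  # type: ignore[misc]

    def walk(self) -> Iterator["BoolExpr"]:
        yield self
        for c in self.children:
            yield from c.walk()

    def is_const(self) -> bool:
        return self.kind is Kind.CONST

    # -- rendering --------------------------------------------------------

    def unparse(self) -> str:
        """Serialize back to rule text (parses to an equivalent AST)."""
        return _unparse(self, parent_prec=0)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.unparse()


# Constructor helpers; AND/OR flatten nested same-kind operands.

def CONST(v: int) -> BoolExpr:
    return BoolExpr(Kind.CONST, value=int(v))


def VAR(name: str) -> BoolExpr:
    return BoolExpr(Kind.VAR, name=name)


def NOT(e: BoolExpr) -> BoolExpr:
    return BoolExpr(Kind.NOT, children=(e,))


def _nary(kind: Kind, args: tuple[BoolExpr, ...]) -> BoolExpr:
    flat: list[BoolExpr] = []
    for a in args:
        if a.kind is kind:
            flat.extend(a.children)
        else:
            flat.append(a)
    if len(flat) == 1:
        return flat[0]
    return BoolExpr(kind, children=tuple(flat))


def AND(*args: BoolExpr) -> BoolExpr:
    return _nary(Kind.AND, args)


def OR(*args: BoolExpr) -> BoolExpr:
    return _nary(Kind.OR, args)


# ---------------------------------------------------------------------------
# Tokenizer / recursive-descent parser


_TOKEN_RE = re.compile(
    r"\s*(?:(?P<ident>[A-Za-z][A-Za-z0-9_]*)|(?P<lit>[01])|(?P<op>[!&|()]))"
)


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens: list[tuple[str, str, int]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            stripped = text[pos:].lstrip()
            if not stripped:
                break
            raise ParseError(
                f"illegal token {stripped[0]!r}", pos + (len(text[pos:]) - len(stripped))
            )
        if m.lastgroup == "ident":
            tokens.append(("ident", m.group("ident"), m.start("ident")))
        elif m.lastgroup == "lit":
            tokens.append(("lit", m.group("lit"), m.start("lit")))
        else:
            tokens.append(("op", m.group("op"), m.start("op")))
        pos = m.end()
    return tokens


class _Parser:
    """Strict recursive-descent parser; no silent repair of defects."""

    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self) -> tuple[str, str, int] | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> tuple[str, str, int]:
        tok = self.peek()
        if tok is None:
            raise ParseError("unexpected end of expression", len(self.text))
        self.i += 1
        return tok

    def parse(self) -> BoolExpr:
        expr = self.parse_or()
        tok = self.peek()
        if tok is not None:
            what = "unbalanced parenthesis" if tok[1] == ")" else f"unexpected {tok[1]!r}"
            raise ParseError(what, tok[2])
        return expr

    def parse_or(self) -> BoolExpr:
        terms = [self.parse_and()]
        while (tok := self.peek()) is not None and tok[1] == "|":
            self.next()
            terms.append(self.parse_and())
        return OR(*terms) if len(terms) > 1 else terms[0]

    def parse_and(self) -> BoolExpr:
        factors = [self.parse_not()]
        while (tok := self.peek()) is not None and tok[1] == "&":
            self.next()
            factors.append(self.parse_not())
        return AND(*factors) if len(factors) > 1 else factors[0]

    def parse_not(self) -> BoolExpr:
        tok = self.peek()
        if tok is not None and tok[1] == "!":
            self.next()
            return NOT(self.parse_not())
        return self.parse_atom()

    def parse_atom(self) -> BoolExpr:
        kind, value, pos = self.next()
        if kind == "ident":
            return VAR(value)
        if kind == "lit":
            return CONST(int(value))
        if value == "(":
            inner = self.parse_or()
            tok = self.peek()
            if tok is None or tok[1] != ")":
                raise ParseError("unbalanced parenthesis", pos)
            self.next()
            return inner
        raise ParseError(f"dangling operator {value!r}", pos)


def parse_expression(text: str) -> BoolExpr:
    """Parse rule text into a :class:`BoolExpr`.

    Whitespace-insensitive.  Raises :class:`ParseError` (with the offending
    character position) on unbalanced parentheses, dangling operators or
    illegal tokens; empty input is also rejected.
    """
    if not text or not text.strip():
        raise ParseError("empty expression", 0)
    return _Parser(text).parse()


def eval_expr(expr: BoolExpr, state: Mapping[str, int]) -> int:
    """Evaluate ``expr`` against a complete name->bit assignment.

    Pure function; returns 0 or 1.  Raises :class:`EvalError` naming the
    variable if one is missing from ``state``.
    """
    k = expr.kind
    if k is Kind.CONST:
        return expr.value  # type: ignore[return-value]
    if k is Kind.VAR:
        try:
            return 1 if state[expr.name] else 0  # type: ignore[index]
        except KeyError:
            raise EvalError(f"variable {expr.name!r} not present in state") from None
    if k is Kind.NOT:
        return 1 - eval_expr(expr.children[0], state)
    if k is Kind.AND:
        for c in expr.children:
            if not eval_expr(c, state):
                return 0
        return 1
    # OR
    for c in expr.children:
        if eval_expr(c, state):
            return 1
    return 0


_PREC = {Kind.OR: 1, Kind.AND: 2, Kind.NOT: 3}


def _unparse(expr: BoolExpr, parent_prec: int) -> str:
    if expr.kind is Kind.CONST:
        return str(expr.value)
    if expr.kind is Kind.VAR:
        return expr.name  # type: ignore[return-value]
    if expr.kind is Kind.NOT:
        return "!" + _unparse(expr.children[0], _PREC[Kind.NOT])
    op = " & " if expr.kind is Kind.AND else " | "
    prec = _PREC[expr.kind]
    body = op.join(_unparse(c, prec) for c in expr.children)
    return f"({body})" if prec < parent_prec else body
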