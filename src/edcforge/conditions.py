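"""Display-condition (skip logic) expression trees.

A condition decides when a form field is shown. The grammar is a small
boolean tree: ``ALL(...)`` and ``ANY(...)`` combinators over comparison
atoms. The canonical text form, used in CSV exports and on the CLI, is

    age ge 18
    sex eq "f"
    dx in_set ["j45", "j44"]
    note is_empty
    ALL(age ge 18, ANY(sex eq "f", smoker eq true))

Comparison literals are JSON values, which makes the serialization
unambiguous and locale-free (strings quoted, booleans lowercase, sets as
arrays). ``is_empty`` / ``not_empty`` take no literal.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Union

OPERATORS = ("eq", "ne", "lt", "le", "gt", "ge", "in_set", "is_empty", "not_empty")
NULLARY_OPERATORS = frozenset({"is_empty", "not_empty"})
ORDERING_OPERATORS = frozenset({"lt", "le", "gt", "ge"})

_IDENT_RE = re.compile(r"[a-z][a-z0-9_]{0,63}")
_JSON = json.JSONDecoder()


def _freeze_literal(value):
    if isinstance(value, list):
        return tuple(value)
    return value


@dataclass(frozen=True)
class Atom:
    variable_id: str
    operator: str
    literal: object = None

    def __post_init__(self):
        object.__setattr__(self, "literal", _freeze_literal(self.literal))


@dataclass(frozen=True)
class AllOf:
    children: tuple = field(default=())

    def __post_init__(self):
        object.__setattr__(self, "children", tuple(self.children))


@dataclass(frozen=True)
class AnyOf:
    children: tuple = field(default=())

    def __post_init__(self):
        object.__setattr__(self, "children", tuple(self.children))


ConditionExpr = Union[Atom, AllOf, AnyOf]


def referenced_variables(expr: ConditionExpr) -> set[str]:
    """All variable_ids an expression reads."""
    if isinstance(expr, Atom):
        return {expr.variable_id}
    out: set[str] = set()
    for child in expr.children:
        out |= referenced_variables(child)
    return out


def rename_variables(expr: ConditionExpr, mapping: dict[str, str]) -> ConditionExpr:
    """Rewrite variable references (used when library imports rename on collision)."""
    if isinstance(expr, Atom):
        return Atom(mapping.get(expr.variable_id, expr.variable_id), expr.operator, expr.literal)
    cls = type(expr)
    return cls(tuple(rename_variables(c, mapping) for c in expr.children))


def serialize_condition(expr: ConditionExpr) -> str:
    if isinstance(expr, Atom):
        if expr.operator in NULLARY_OPERATORS:
            return f"{expr.variable_id} {expr.operator}"
        literal = expr.literal
        if isinstance(literal, tuple):
            literal = list(literal)
        return f"{expr.variable_id} {expr.operator} " + json.dumps(
            literal, ensure_ascii=False, separators=(", ", ": ")
        )
    name = "ALL" if isinstance(expr, AllOf) else "ANY"
    return f"{name}(" + ", ".join(serialize_condition(c) for c in expr.children) + ")"


class ConditionParseError(ValueError):
    pass


def parse_condition(text: str) -> ConditionExpr:
    """Parse the canonical text form back into an expression tree."""
    expr, pos = _parse(text, 0)
    pos = _skip_ws(text, pos)
    if pos != len(text):
        raise ConditionParseError(f"trailing input at position {pos}: {text[pos:]!r}")
    return expr


def _skip_ws(s: str, i: int) -> int:
    while i < len(s) and s[i] in " \t\r\n":
        i += 1
    return i


def _parse(s: str, i: int) -> tuple[ConditionExpr, int]:
    i = _skip_ws(s, i)
    for name, cls in (("ALL(", AllOf), ("ANY(", AnyOf)):
        if s.startswith(name, i):
            i += len(name)
            children = []
            i = _skip_ws(s, i)
            if i < len(s) and s[i] == ")":
                return cls(()), i + 1
            while True:
                child, i = _parse(s, i)
                children.append(child)
                i = _skip_ws(s, i)
                if i >= len(s):
                    raise ConditionParseError("unterminated combinator")
                if s[i] == ",":
                    i += 1
                    continue
                if s[i] == ")":
                    return cls(tuple(children)), i + 1
                raise ConditionParseError(f"expected ',' or ')' at position {i}")
    m = _IDENT_RE.match(s, i)
    if not m:
        raise ConditionParseError(f"expected variable identifier at position {i}")
    var = m.group(0)
    i = _skip_ws(s, m.end())
    op = None
    for candidate in sorted(OPERATORS, key=len, reverse=True):
        if s.startswith(candidate, i):
            nxt = i + len(candidate)
            if nxt == len(s) or not (s[nxt].isalnum() or s[nxt] == "_"):
                op = candidate
                i = nxt
                break
    if op is None:
        raise ConditionParseError(f"expected operator at position {i}")
    if op in NULLARY_OPERATORS:
        return Atom(var, op), i
    i = _skip_ws(s, i)
    try:
        literal, i = _JSON.raw_decode(s, i)
    except json.JSONDecodeError as exc:
        raise ConditionParseError(f"bad literal at position {i}: {exc}") from exc
    return Atom(var, op, _freeze_literal(literal)), i
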