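"""Post-analysis sorting and filtering via a boolean filter-string language.

Result rows can be selected with expressions like::

    p_combined < 0.05 & pertA ~ KRAS
    !(abs_mag_a < 100) | rel_mag_b >= 2

Comparisons (``<  <=  >  >=  =``) apply to numeric columns, ``~`` performs
a case-insensitive substring match, ``!`` negates, ``&`` (AND) binds
tighter than ``|`` (OR), and parentheses group.  Column names are the nine
canonical result columns: ``pertA, pertB, rel_mag_a, rel_mag_b, abs_mag_a,
abs_mag_b, p_a, p_b, p_combined``.

Rows with a missing value in a referenced column evaluate comparisons and
substring tests as false -- so a significance filter drops rows whose
p-value could not be computed, while the negated filter keeps them.

Additionally, the bottom fraction of rows by mean assay signal
(``abs_mag_a`` / ``abs_mag_b``) can be removed: low-abundance barcodes are
a major source of false positives, and dropping the bottom 5-10% of
signals is usually a satisfactory noise reduction.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pairscreen.screen_io import RESULT_COLUMNS, ResultTable

__all__ = [
    "FilterError",
    "FilterExpr",
    "Comparison",
    "Substring",
    "Not",
    "And",
    "Or",
    "parse_filter",
    "apply_filter",
    "bottom_signal_filter",
    "sort_results",
]

_COMPARE_OPS = {"<", "<=", ">", ">=", "="}


class FilterError(ValueError):
    """Syntax or column error in a filter string (position is 0-based)."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"syntax error at position {position}: {message}"
        super().__init__(message)


class FilterExpr:
    """Base class of filter expression nodes."""

    def evaluate(self, df: pd.DataFrame) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def pretty(self) -> str:  # pragma: no cover
        raise NotImplementedError

    def __str__(self) -> str:
        return self.pretty()


@dataclass(frozen=True)
class Comparison(FilterExpr):
    column: str
    op: str
    value: float

    def evaluate(self, df: pd.DataFrame) -> np.ndarray:
        col = pd.to_numeric(df[self.column], errors="coerce").to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if self.op == "<":
                out = col < self.value
            elif self.op == "<=":
                out = col <= self.value
            elif self.op == ">":
                out = col > self.value
            elif self.op == ">=":
                out = col >= self.value
            else:  # "=" -- exact numeric equality
                out = col == self.value
        out[np.isnan(col)] = False  # missing values never satisfy a comparison
        return out

    def pretty(self) -> str:
        return f"{self.column} {self.op} {self.value!r}"


@dataclass(frozen=True)
class Substring(FilterExpr):
    column: str
    pattern: str

    def evaluate(self, df: pd.DataFrame) -> np.ndarray:
        needle = self.pattern.lower()
        col = df[self.column]
        out = np.zeros(len(col), dtype=bool)
        for i, v in enumerate(col):
            if v is None or (isinstance(v, float) and math.isnan(v)):
                continue
            out[i] = needle in str(v).lower()
        return out

    def pretty(self) -> str:
        if re.fullmatch(r"[A-Za-z0-9_.\-]+", self.pattern):
            return f"{self.column} ~ {self.pattern}"
        return f'{self.column} ~ "{self.pattern}"'


@dataclass(frozen=True)
class Not(FilterExpr):
    child: FilterExpr

    def evaluate(self, df: pd.DataFrame) -> np.ndarray:
        return ~self.child.evaluate(df)

    def pretty(self) -> str:
        return f"!({self.child.pretty()})"


@dataclass(frozen=True)
class And(FilterExpr):
    children: tuple[FilterExpr, ...] = field(default_factory=tuple)

    def evaluate(self, df: pd.DataFrame) -> np.ndarray:
        out = np.ones(len(df), dtype=bool)
        for c in self.children:
            out &= c.evaluate(df)
        return out

    def pretty(self) -> str:
        parts = []
        for c in self.children:
            s = c.pretty()
            parts.append(f"({s})" if isinstance(c, Or) else s)
        return " & ".join(parts)


@dataclass(frozen=True)
class Or(FilterExpr):
    children: tuple[FilterExpr, ...] = field(default_factory=tuple)

    def evaluate(self, df: pd.DataFrame) -> np.ndarray:
        out = np.zeros(len(df), dtype=bool)
        for c in self.children:
            out |= c.evaluate(df)
        return out

    def pretty(self) -> str:
        return " | ".join(c.pretty() for c in self.children)


# ---------------------------------------------------------------------------
# lexer / parser


@dataclass(frozen=True)
class _Token:
    kind: str  # ident | number | string | op
    text: str
    pos: int


_TOKEN_RE = re.compile(
    r"""\s*(?:
        (?P<number>[0-9]+(?:\.[0-9]*)?(?:[eE][+-]?[0-9]+)?|\.[0-9]+(?:[eE][+-]?[0-9]+)?)
      | (?P<ident>[A-Za-z_][A-Za-z0-9_.\-]*)
      | (?P<string>"[^"]*"|'[^']*')
      | (?P<op><=|>=|<|>|=|~|!|&|\||\(|\))
    )""",
    re.VERBOSE,
)


def _tokenize(text: str) -> list[_Token]:
    tokens = []
    pos, n = 0, len(text)
    while pos < n:
        while pos < n and text[pos].isspace():
            pos += 1
        if pos >= n:
            break
        m = _TOKEN_RE.match(text, pos)
        if m is None or m.lastgroup is None:
            raise FilterError(f"unexpected character {text[pos]!r}", pos)
        kind = m.lastgroup
        tok_text = m.group(kind)
        tok_pos = m.end() - len(tok_text)
        if kind == "string":
            tok_text = tok_text[1:-1]
        tokens.append(_Token(kind, tok_text, tok_pos))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, text: str, columns: list[str]):
        self.text = text
        self.columns = columns
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self) -> _Token | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> _Token:
        tok = self.peek()
        if tok is None:
            raise FilterError("unexpected end of expression", len(self.text))
        self.i += 1
        return tok

    def expect_op(self, text: str) -> _Token:
        tok = self.next()
        if tok.kind != "op" or tok.text != text:
            raise FilterError(f"expected {text!r}, got {tok.text!r}", tok.pos)
        return tok

    def parse(self) -> FilterExpr:
        expr = self.parse_or()
        tok = self.peek()
        if tok is not None:
            raise FilterError(f"unexpected {tok.text!r}", tok.pos)
        return expr

    def parse_or(self) -> FilterExpr:
        parts = [self.parse_and()]
        while (tok := self.peek()) and tok.kind == "op" and tok.text == "|":
            self.next()
            parts.append(self.parse_and())
        return parts[0] if len(parts) == 1 else Or(tuple(parts))

    def parse_and(self) -> FilterExpr:
        parts = [self.parse_unary()]
        while (tok := self.peek()) and tok.kind == "op" and tok.text == "&":
            self.next()
            parts.append(self.parse_unary())
        return parts[0] if len(parts) == 1 else And(tuple(parts))

    def parse_unary(self) -> FilterExpr:
        tok = self.peek()
        if tok is None:
            raise FilterError("unexpected end of expression", len(self.text))
        if tok.kind == "op" and tok.text == "!":
            self.next()
            return Not(self.parse_unary())
        if tok.kind == "op" and tok.text == "(":
            self.next()
            inner = self.parse_or()
            self.expect_op(")")
            return inner
        return self.parse_atom()

    def parse_atom(self) -> FilterExpr:
        tok = self.next()
        if tok.kind != "ident":
            raise FilterError(f"expected a column name, got {tok.text!r}", tok.pos)
        if tok.text not in self.columns:
            raise FilterError(
                f"unknown column {tok.text!r}; valid columns: {', '.join(self.columns)}",
                tok.pos,
            )
        column = tok.text
        op_tok = self.next()
        if op_tok.kind != "op" or op_tok.text not in _COMPARE_OPS | {"~"}:
            raise FilterError(
                f"expected a comparison operator or '~', got {op_tok.text!r}",
                op_tok.pos,
            )
        if op_tok.text == "~":
            pat = self.next()
            if pat.kind not in ("ident", "string", "number"):
                raise FilterError(
                    f"expected a pattern after '~', got {pat.text!r}", pat.pos
                )
            return Substring(column, pat.text)
        num = self.next()
        if num.kind != "number":
            raise FilterError(f"expected a number, got {num.text!r}", num.pos)
        return Comparison(column, op_tok.text, float(num.text))


def parse_filter(text: str, columns: list[str] | None = None) -> FilterExpr:
    """Parse a filter string into an expression tree.

    ``&`` binds tighter than ``|``; ``!`` negates the following unary
    expression; whitespace is insignificant.  Unknown column names are
    rejected at parse time with the list of valid columns.
    """
    if not text or not text.strip():
        raise FilterError("empty filter expression")
    return _Parser(text, columns or RESULT_COLUMNS).parse()


# ---------------------------------------------------------------------------
# application


def _as_expr(expr: FilterExpr | str) -> FilterExpr:
    return parse_filter(expr) if isinstance(expr, str) else expr


def apply_filter(results: ResultTable, expr: FilterExpr | str) -> ResultTable:
    """Keep the rows on which the expression evaluates true."""
    expr = _as_expr(expr)
    mask = expr.evaluate(results.data)
    meta = dict(results.meta)
    meta.setdefault("filters", []).append(expr.pretty())
    return ResultTable(results.data[mask].copy(), meta)


def bottom_signal_filter(
    results: ResultTable, column: str = "abs_mag_a", fraction: float = 0.05
) -> ResultTable:
    """Drop the ``floor(n * fraction)`` rows with the smallest signal.

    ``column`` is one of the two mean-assay-signal columns; ties are
    broken by stable original order, so repeated runs remove the same rows.
    """
    if column not in ("abs_mag_a", "abs_mag_b"):
        raise ValueError("column must be 'abs_mag_a' or 'abs_mag_b'")
    if not 0 <= fraction <= 0.5:
        raise ValueError("fraction must lie in [0, 0.5]")
    df = results.data
    k = int(math.floor(len(df) * fraction))
    if k == 0:
        return ResultTable(df.copy(), dict(results.meta))
    order = np.argsort(df[column].to_numpy(dtype=float), kind="stable")
    drop = set(order[:k])
    keep = [i for i in range(len(df)) if i not in drop]
    meta = dict(results.meta)
    meta.setdefault("filters", []).append(f"bottom {fraction:g} of {column} removed")
    return ResultTable(df.iloc[keep].copy(), meta)


def sort_results(
    results: ResultTable, column: str, direction: str = "ascending"
) -> ResultTable:
    """Stable sort by one column; missing values always sort last."""
    if column not in RESULT_COLUMNS:
        raise ValueError(f"unknown column {column!r}")
    if direction not in ("ascending", "descending"):
        raise ValueError("direction must be 'ascending' or 'descending'")
    df = results.data.sort_values(
        column,
        ascending=direction == "ascending",
        kind="stable",
        na_position="last",
    )
    return ResultTable(df.copy(), dict(results.meta))
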