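"""Atom selection mini-language.

Supports the primitives a user needs to point the feature-selection stage at
a region of the protein:

    ``chain A B``            -- one or more chain ids
    ``name CA CB``           -- one or more atom names
    ``resid 5:20 33 40-50``  -- residue ids, single or ranges (inclusive)
    ``all``                  -- every atom

combined with ``and`` / ``or`` and parentheses, e.g.

    ``chain A and name CA and resid 10:60``
"""

from __future__ import annotations

import numpy as np
import pandas as pd

_KEYWORDS = {"chain", "name", "resid", "all", "and", "or", "(", ")"}


class SelectionError(ValueError):
    """Raised for unparseable expressions or selections that match nothing."""


def _tokenize(expression: str) -> list[str]:
    expr = expression.replace("(", " ( ").replace(")", " ) ")
    tokens = expr.split()
    if not tokens:
        raise SelectionError("empty selection expression")
    return tokens


class _Parser:
    """Recursive-descent parser producing a mask-evaluating AST."""

    def __init__(self, tokens: list[str]):
        self.tokens = tokens
        self.pos = 0

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of selection expression")
        self.pos += 1
        return tok

    def parse(self):
        node = self.parse_or()
        if self.peek() is not None:
            raise SelectionError(f"unexpected token {self.peek()!r}")
        return node

    def parse_or(self):
        left = self.parse_and()
        while self.peek() == "or":
            self.next()
            right = self.parse_and()
            left = ("or", left, right)
        return left

    def parse_and(self):
        left = self.parse_term()
        while self.peek() == "and":
            self.next()
            right = self.parse_term()
            left = ("and", left, right)
        return left

    def parse_term(self):
        tok = self.peek()
        if tok == "(":
            self.next()
            node = self.parse_or()
            if self.next() != ")":
                raise SelectionError("unbalanced parentheses")
            return node
        if tok == "all":
            self.next()
            return ("all",)
        if tok in ("chain", "name"):
            self.next()
            values = self._consume_values(tok)
            return (tok, values)
        if tok == "resid":
            self.next()
            values = self._consume_values("resid")
            return ("resid", [self._parse_range(v) for v in values])
        raise SelectionError(f"unexpected token {tok!r}")

    def _consume_values(self, keyword: str) -> list[str]:
        values: list[str] = []
        while self.peek() is not None and self.peek() not in _KEYWORDS:
            values.append(self.next())
        if not values:
            raise SelectionError(f"keyword {keyword!r} requires at least one value")
        return values

    @staticmethod
    def _parse_range(token: str) -> tuple[int, int]:
        for sep in (":", "-", "to"):
            if sep in token and not token.lstrip("-").isdigit():
                lo, hi = token.split(sep, 1)
                return int(lo), int(hi)
        value = int(token)
        return value, value


def _evaluate(node, atoms: pd.DataFrame) -> np.ndarray:
    op = node[0]
    if op == "all":
        return np.ones(len(atoms), dtype=bool)
    if op == "and":
        return _evaluate(node[1], atoms) & _evaluate(node[2], atoms)
    if op == "or":
        return _evaluate(node[1], atoms) | _evaluate(node[2], atoms)
    if op == "chain":
        return atoms["chain_id"].isin(node[1]).to_numpy()
    if op == "name":
        return atoms["atom_name"].isin(node[1]).to_numpy()
    if op == "resid":
        mask = np.zeros(len(atoms), dtype=bool)
        resid = atoms["res_id"].to_numpy()
        for lo, hi in node[1]:
            mask |= (resid >= lo) & (resid <= hi)
        return mask
    raise SelectionError(f"unknown node {op!r}")


class AtomSelection:
    """A parsed selection expression, resolvable against an atom table.

    Parameters
    ----------
    expression:
        Selection string in the mini-language described in the module
        docstring.  Parsing happens eagerly so syntax errors surface at
        construction time.
    """

    def __init__(self, expression: str):
        self.expression = expression
        self._ast = _Parser(_tokenize(expression)).parse()

    def mask(self, atoms: pd.DataFrame) -> np.ndarray:
        """Boolean mask over the rows of an atom table."""
        return _evaluate(self._ast, atoms)

    def resolve(self, atoms: pd.DataFrame) -> np.ndarray:
        """Schema-ordered atom indices matching the expression.

        Raises :class:`SelectionError` if nothing matches: a selection that
        silently resolves to zero atoms would propagate as an empty feature
        set downstream.
        """
        indices = np.flatnonzero(self.mask(atoms))
        if indices.size == 0:
            raise SelectionError(
                f"selection {self.expression!r} matches no atoms"
            )
        return indices

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"AtomSelection({self.expression!r})"
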