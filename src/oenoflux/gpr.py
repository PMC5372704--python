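"""Gene-protein-reaction (GPR) boolean rules.

Grammar: identifiers, AND, OR (case-insensitive keywords) and parentheses.
NOT is deliberately unsupported, matching genome-scale modelling practice.
An empty rule means the reaction has no gene requirement and can never be
silenced by a knockout.
"""

from __future__ import annotations

import re
from typing import FrozenSet, List, Set, Tuple

_TOKEN_RE = re.compile(r"\s*(\(|\)|[A-Za-z0-9_.\-]+)")
_KEYWORDS = {"and", "or"}


class GPRSyntaxError(ValueError):
    """Malformed GPR expression; carries the character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


def _tokenize(expr: str) -> List[Tuple[str, int]]:
    tokens: List[Tuple[str, int]] = []
    pos = 0
    while pos < len(expr):
        m = _TOKEN_RE.match(expr, pos)
        if m is None:
            stripped = expr[pos:].lstrip()
            if not stripped:
                break
            raise GPRSyntaxError(f"unexpected character {stripped[0]!r}", pos)
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


class _Parser:
    """Recursive-descent parser; OR binds looser than AND."""

    def __init__(self, expr: str):
        self.expr = expr
        self.tokens = _tokenize(expr)
        self.i = 0

    def _peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else (None, len(self.expr))

    def parse(self):
        if not self.tokens:
            return None
        node = self._or()
        tok, pos = self._peek()
        if tok is not None:
            raise GPRSyntaxError(f"unexpected token {tok!r}", pos)
        return node

    def _or(self):
        node = self._and()
        while True:
            tok, _ = self._peek()
            if tok is not None and tok.lower() == "or":
                self.i += 1
                node = ("or", node, self._and())
            else:
                return node

    def _and(self):
        node = self._atom()
        while True:
            tok, _ = self._peek()
            if tok is not None and tok.lower() == "and":
                self.i += 1
                node = ("and", node, self._atom())
            else:
                return node

    def _atom(self):
        tok, pos = self._peek()
        if tok is None:
            raise GPRSyntaxError("unexpected end of expression", pos)
        if tok == "(":
            self.i += 1
            node = self._or()
            tok, pos = self._peek()
            if tok != ")":
                raise GPRSyntaxError("expected ')'", pos)
            self.i += 1
            return node
        if tok == ")" or tok.lower() in _KEYWORDS:
            raise GPRSyntaxError(f"unexpected token {tok!r}", pos)
        self.i += 1
        return ("gene", tok)


def parse_gpr(expr: str):
    """Parse a GPR rule into an AST; ``None`` for an empty rule."""
    return _Parser(expr or "").parse()


def _eval(node, knocked_out: FrozenSet[str]) -> bool:
    op = node[0]
    if op == "gene":
        return node[1] not in knocked_out
    left = _eval(node[1], knocked_out)
    if op == "and":
        return left and _eval(node[2], knocked_out)
    return left or _eval(node[2], knocked_out)


def evaluate_gpr(expr: str, knocked_out: Set[str]) -> bool:
    """Is the reaction still catalysable when ``knocked_out`` genes are lost?

    Empty rules always evaluate active: a reaction with no gene
    association cannot be silenced by any knockout.
    """
    ast = parse_gpr(expr)
    if ast is None:
        return True
    return _eval(ast, frozenset(knocked_out))


def genes_in_gpr(expr: str) -> Set[str]:
    """All gene identifiers referenced by a rule."""
    ast = parse_gpr(expr)
    out: Set[str] = set()

    def walk(node):
        if node is None:
            return
        if node[0] == "gene":
            out.add(node[1])
        else:
            walk(node[1])
            walk(node[2])

    walk(ast)
    return out
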