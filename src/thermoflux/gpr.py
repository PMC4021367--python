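"""Gene-protein-reaction (GPR) boolean expressions.

A GPR rule links a reaction to the genes whose products catalyze it:
``and`` joins subunits of one enzyme complex (all required), ``or`` joins
isozymes (any suffices).  An empty rule marks a spontaneous or
non-gene-associated reaction, which remains active under every deletion.
"""

from __future__ import annotations

import re
from typing import FrozenSet, Iterable, Set, Tuple


class GprParseError(ValueError):
    """Raised for a malformed GPR rule string."""


class GprExpression:
    """Immutable AND/OR tree over gene locus tags.

    ``kind`` is one of ``"empty"``, ``"gene"``, ``"and"``, ``"or"``.
    Gene tokens are case-sensitive exact locus tags (e.g. ``TTC0049``).
    """

    __slots__ = ("kind", "gene", "children")

    def __init__(self, kind: str, gene: str | None = None,
                 children: Tuple["GprExpression", ...] = ()):
        if kind not in ("empty", "gene", "and", "or"):
            raise ValueError(f"unknown GPR node kind {kind!r}")
        if kind == "gene" and not gene:
            raise GprParseError("gene leaf requires a non-empty token")
        if kind in ("and", "or") and len(children) < 2:
            raise GprParseError(f"{kind!r} node requires >=2 children")
        self.kind = kind
        self.gene = gene
        self.children = tuple(children)

    # -- constructors -------------------------------------------------
    @classmethod
    def empty(cls) -> "GprExpression":
        return cls("empty")

    @classmethod
    def leaf(cls, gene: str) -> "GprExpression":
        return cls("gene", gene=gene)

    @classmethod
    def all_of(cls, *children: "GprExpression") -> "GprExpression":
        return cls("and", children=children)

    @classmethod
    def any_of(cls, *children: "GprExpression") -> "GprExpression":
        return cls("or", children=children)

    # -- semantics ----------------------------------------------------
    def is_empty(self) -> bool:
        return self.kind == "empty"

    def evaluate(self, deleted: Iterable[str]) -> bool:
        """Is the reaction still catalyzable after deleting ``deleted``?

        Empty rules evaluate True regardless of deletions.
        """
        deleted = set(deleted)
        if self.kind == "empty":
            return True
        if self.kind == "gene":
            return self.gene not in deleted
        if self.kind == "and":
            return all(c.evaluate(deleted) for c in self.children)
        return any(c.evaluate(deleted) for c in self.children)

    def genes(self) -> Set[str]:
        if self.kind == "empty":
            return set()
        if self.kind == "gene":
            return {self.gene}
        out: Set[str] = set()
        for c in self.children:
            out |= c.genes()
        return out

    # -- text form ----------------------------------------------------
    def to_string(self) -> str:
        if self.kind == "empty":
            return ""
        if self.kind == "gene":
            return self.gene  # type: ignore[return-value]
        sep = f" {self.kind} "
        parts = []
        for c in self.children:
            s = c.to_string()
            # parenthesize nested boolean nodes so the tree shape
            # (not just the truth table) survives a re-parse
            if c.kind in ("and", "or"):
                s = f"({s})"
            parts.append(s)
        return sep.join(parts)

    def __str__(self) -> str:
        return self.to_string()

    def __repr__(self) -> str:
        return f"GprExpression({self.to_string()!r})"

    def _key(self) -> tuple:
        if self.kind == "gene":
            return ("gene", self.gene)
        if self.kind == "empty":
            return ("empty",)
        return (self.kind, tuple(c._key() for c in self.children))

    def __eq__(self, other) -> bool:
        return isinstance(other, GprExpression) and self._key() == other._key()

    def __hash__(self) -> int:
        return hash(self._key())


_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def parse_gpr(text: str | None) -> GprExpression:
    """Parse a GPR rule like ``"(TTC0049 or TTC0045) and TTC0100"``.

    ``and``/``or`` keywords are case-insensitive; ``and`` binds tighter
    than ``or``.  Blank or None input yields the empty rule.
    """
    if text is None or not text.strip():
        return GprExpression.empty()
    tokens = _TOKEN_RE.findall(text)
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> GprExpression:
        nodes = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            take()
            nodes.append(parse_and())
        if len(nodes) == 1:
            return nodes[0]
        return GprExpression.any_of(*nodes)

    def parse_and() -> GprExpression:
        nodes = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            take()
            nodes.append(parse_atom())
        if len(nodes) == 1:
            return nodes[0]
        return GprExpression.all_of(*nodes)

    def parse_atom() -> GprExpression:
        tok = peek()
        if tok is None:
            raise GprParseError(f"unexpected end of GPR rule: {text!r}")
        if tok == "(":
            take()
            node = parse_or()
            if peek() != ")":
                raise GprParseError(f"unbalanced parenthesis in {text!r}")
            take()
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GprParseError(f"unexpected token {tok!r} in {text!r}")
        return GprExpression.leaf(take())

    node = parse_or()
    if pos != len(tokens):
        raise GprParseError(f"trailing tokens after position {pos} in {text!r}")
    return node
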