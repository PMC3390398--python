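"""Boolean gene-protein-reaction (GPR) rules as explicit ASTs.

A GPR rule states which gene products catalyze a reaction: ``OR`` joins
isozymes (either suffices), ``AND`` joins complex subunits (all required).
Rules are parsed into :class:`GPRNode` trees with AND binding tighter than
OR and associative operators flattened, so ``a or b or c`` is a single OR
node with three children.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import GPRParseError

GENE = "GENE"
AND = "AND"
OR = "OR"

_TOKEN_RE = re.compile(r"\s*(\(|\)|[^\s()]+)")


@dataclass(frozen=True)
class GPRNode:
    """One node of a GPR Boolean tree.

    ``kind`` is ``GENE`` (leaf, ``gene`` set) or ``AND``/``OR`` (internal,
    ``children`` holds >= 2 subtrees).  Nodes are immutable and hashable;
    equality is structural.
    """

    kind: str
    gene: str | None = None
    children: tuple["GPRNode", ...] = field(default_factory=tuple)

    def __post_init__(self):
        if self.kind == GENE:
            if not self.gene or self.children:
                raise GPRParseError("GENE node needs a gene id and no children")
        elif self.kind in (AND, OR):
            if len(self.children) < 2:
                raise GPRParseError(f"{self.kind} node needs >= 2 children")
        else:
            raise GPRParseError(f"unknown GPR node kind {self.kind!r}")

    @property
    def genes(self) -> frozenset[str]:
        """All gene identifiers appearing in the subtree."""
        if self.kind == GENE:
            return frozenset([self.gene])
        out: set[str] = set()
        for c in self.children:
            out.update(c.genes)
        return frozenset(out)

    def render(self) -> str:
        """Deterministic string form that :func:`parse_gpr` maps back to self."""
        if self.kind == GENE:
            return self.gene
        op = " and " if self.kind == AND else " or "
        parts = []
        for c in self.children:
            s = c.render()
            # parenthesize an OR child under AND; all else is unambiguous
            if self.kind == AND and c.kind == OR:
                s = f"({s})"
            parts.append(s)
        return op.join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


def gene(g: str) -> GPRNode:
    return GPRNode(GENE, gene=g)


def _flatten(kind: str, children: list[GPRNode]) -> GPRNode:
    flat: list[GPRNode] = []
    for c in children:
        if c.kind == kind:
            flat.extend(c.children)
        else:
            flat.append(c)
    if len(flat) == 1:
        return flat[0]
    return GPRNode(kind, children=tuple(flat))


def and_(*children: GPRNode) -> GPRNode:
    return _flatten(AND, list(children))


def or_(*children: GPRNode) -> GPRNode:
    return _flatten(OR, list(children))


def _tokenize(rule: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    pos = 0
    while pos < len(rule):
        m = _TOKEN_RE.match(rule, pos)
        if m is None:
            break
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


class _Parser:
    """Recursive-descent parser; precedence AND > OR, both left-flattened."""

    def __init__(self, rule: str):
        self.rule = rule
        self.tokens = _tokenize(rule)
        self.i = 0

    def peek(self) -> tuple[str, int] | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> tuple[str, int]:
        tok = self.peek()
        if tok is None:
            raise GPRParseError("unexpected end of rule", len(self.rule))
        self.i += 1
        return tok

    def parse(self) -> GPRNode:
        node = self.parse_or()
        tok = self.peek()
        if tok is not None:
            raise GPRParseError(f"unexpected token {tok[0]!r}", tok[1])
        return node

    def parse_or(self) -> GPRNode:
        children = [self.parse_and()]
        while True:
            tok = self.peek()
            if tok is None or tok[0].lower() != "or":
                break
            self.next()
            children.append(self.parse_and())
        return _flatten(OR, children)

    def parse_and(self) -> GPRNode:
        children = [self.parse_atom()]
        while True:
            tok = self.peek()
            if tok is None or tok[0].lower() != "and":
                break
            self.next()
            children.append(self.parse_atom())
        return _flatten(AND, children)

    def parse_atom(self) -> GPRNode:
        text, pos = self.next()
        if text == "(":
            node = self.parse_or()
            tok = self.peek()
            if tok is None or tok[0] != ")":
                raise GPRParseError("unbalanced parentheses", pos)
            self.next()
            return node
        if text == ")" or text.lower() in ("and", "or"):
            raise GPRParseError(f"dangling operator or parenthesis {text!r}", pos)
        return GPRNode(GENE, gene=text)


def parse_gpr(rule: str) -> GPRNode | None:
    """Parse a GPR rule string into a :class:`GPRNode` tree.

    Returns ``None`` for an empty or whitespace-only rule (a spontaneous
    or exchange reaction with no enzyme).  ``and``/``or`` are matched
    case-insensitively; any other token is a gene identifier.
    """
    if rule is None or not rule.strip():
        return None
    return _Parser(rule).parse()
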