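"""Gene-protein-reaction (GPR) Boolean rules.

A GPR rule states which gene products can catalyze a reaction: ``or``
joins alternative catalysts (isoenzymes, or redundant parental alleles in
a hybrid genome), ``and`` joins subunits of an obligate complex.  Rules
are plain Boolean expressions over gene identifiers, e.g. ::

    (PFK1_Scer or PFK1_Seub) and (PFK2_Scer or PFK2_Seub)

This module parses such strings into an expression tree (:class:`GPRNode`),
renders trees back to strings, evaluates rules under gene knockouts, and
aggregates per-gene expression levels into a single reaction capacity
(``or`` = sum of alternative catalysts, ``and`` = minimum over subunits).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

__all__ = [
    "GPRNode",
    "GPRParseError",
    "leaf",
    "and_",
    "or_",
    "parse_gpr",
    "format_gpr",
    "evaluate_boolean",
    "aggregate_expression",
    "genes_of",
]

LEAF = "leaf"
AND = "and"
OR = "or"


class GPRParseError(ValueError):
    """Raised for malformed GPR strings; carries the character position."""

    def __init__(self, message: str, position: int) -> None:
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class GPRNode:
    """Node of a GPR expression tree.

    ``kind`` is one of ``"leaf"``, ``"and"``, ``"or"``.  Leaves carry a
    ``gene_id`` and no children; operator nodes carry >= 2 children.
    """

    kind: str
    gene_id: str | None = None
    children: tuple["GPRNode", ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.kind == LEAF:
            if not self.gene_id:
                raise ValueError("leaf node requires a gene_id")
            if self.children:
                raise ValueError("leaf node cannot have children")
        elif self.kind in (AND, OR):
            if len(self.children) < 2:
                raise ValueError(f"{self.kind!r} node requires >= 2 children")
            if self.gene_id is not None:
                raise ValueError("operator node cannot carry a gene_id")
        else:
            raise ValueError(f"unknown GPR node kind {self.kind!r}")

    def __str__(self) -> str:  # pragma: no cover - convenience
        return format_gpr(self)


def leaf(gene_id: str) -> GPRNode:
    return GPRNode(LEAF, gene_id=gene_id)


def and_(*children: GPRNode) -> GPRNode:
    return GPRNode(AND, children=tuple(children))


def or_(*children: GPRNode) -> GPRNode:
    return GPRNode(OR, children=tuple(children))


# ---------------------------------------------------------------------------
# Parsing

_TOKEN_IDENT = "IDENT"
_TOKEN_LPAREN = "("
_TOKEN_RPAREN = ")"
_TOKEN_AND = "AND"
_TOKEN_OR = "OR"
_TOKEN_END = "END"

# Characters allowed in gene identifiers.  SBML SIds plus a few common
# extras seen in model gene names; whitespace and parens delimit tokens.
_IDENT_CHARS = set(
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789_.-:'"
)


def _tokenize(text: str) -> Iterator[tuple[str, str, int]]:
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if ch == "(":
            yield (_TOKEN_LPAREN, ch, i)
            i += 1
        elif ch == ")":
            yield (_TOKEN_RPAREN, ch, i)
            i += 1
        elif ch in _IDENT_CHARS:
            j = i
            while j < n and text[j] in _IDENT_CHARS:
                j += 1
            word = text[i:j]
            lowered = word.lower()
            if lowered == "and":
                yield (_TOKEN_AND, word, i)
            elif lowered == "or":
                yield (_TOKEN_OR, word, i)
            else:
                yield (_TOKEN_IDENT, word, i)
            i = j
        else:
            raise GPRParseError(f"unexpected character {ch!r}", i)
    yield (_TOKEN_END, "", n)


class _Parser:
    """Recursive-descent parser; ``and`` binds tighter than ``or``."""

    def __init__(self, text: str) -> None:
        self._tokens = list(_tokenize(text))
        self._pos = 0

    def _peek(self) -> tuple[str, str, int]:
        return self._tokens[self._pos]

    def _advance(self) -> tuple[str, str, int]:
        tok = self._tokens[self._pos]
        self._pos += 1
        return tok

    def parse(self) -> GPRNode:
        node = self._or_expr()
        kind, text, pos = self._peek()
        if kind != _TOKEN_END:
            raise GPRParseError(f"unexpected token {text!r}", pos)
        return node

    def _or_expr(self) -> GPRNode:
        terms = [self._and_expr()]
        while self._peek()[0] == _TOKEN_OR:
            self._advance()
            terms.append(self._and_expr())
        if len(terms) == 1:
            return terms[0]
        return GPRNode(OR, children=tuple(terms))

    def _and_expr(self) -> GPRNode:
        factors = [self._factor()]
        while self._peek()[0] == _TOKEN_AND:
            self._advance()
            factors.append(self._factor())
        if len(factors) == 1:
            return factors[0]
        return GPRNode(AND, children=tuple(factors))

    def _factor(self) -> GPRNode:
        kind, text, pos = self._advance()
        if kind == _TOKEN_IDENT:
            return GPRNode(LEAF, gene_id=text)
        if kind == _TOKEN_LPAREN:
            node = self._or_expr()
            kind2, text2, pos2 = self._advance()
            if kind2 != _TOKEN_RPAREN:
                raise GPRParseError("unbalanced parentheses", pos2)
            return node
        if kind == _TOKEN_END:
            raise GPRParseError("empty operand", pos)
        raise GPRParseError(f"unexpected token {text!r}", pos)


def parse_gpr(rule: str) -> GPRNode:
    """Parse a GPR rule string into an expression tree.

    Keywords ``and``/``or`` are case-insensitive; gene identifiers are
    case-sensitive.  ``and`` binds tighter than ``or``; parentheses group
    explicitly and nested groups of the same operator are preserved as
    written (``(a or b) or c`` stays nested).

    Raises
    ------
    GPRParseError
        On unbalanced parentheses, empty operands or stray characters,
        with the offending position.
    """
    if not rule or not rule.strip():
        raise GPRParseError("empty rule", 0)
    return _Parser(rule).parse()


def format_gpr(node: GPRNode) -> str:
    """Render a tree back to rule text; ``parse_gpr`` round-trips it.

    Parentheses are emitted only where needed to preserve structure:
    around ``or`` groups inside ``and``, and around same-operator
    children written as explicit groups.
    """
    if node.kind == LEAF:
        return node.gene_id  # type: ignore[return-value]
    sep = f" {node.kind} "
    parts = []
    for child in node.children:
        text = format_gpr(child)
        needs_parens = child.kind != LEAF and (
            child.kind == node.kind or (node.kind == AND and child.kind == OR)
        )
        parts.append(f"({text})" if needs_parens else text)
    return sep.join(parts)


# ---------------------------------------------------------------------------
# Evaluation

def evaluate_boolean(node: GPRNode, absent: set[str] | frozenset[str]) -> bool:
    """Is the rule satisfied when the genes in ``absent`` are deleted?

    A leaf is true iff its gene is not absent; ``and`` requires all
    children, ``or`` requires at least one.
    """
    if node.kind == LEAF:
        return node.gene_id not in absent
    if node.kind == AND:
        return all(evaluate_boolean(c, absent) for c in node.children)
    return any(evaluate_boolean(c, absent) for c in node.children)


def aggregate_expression(node: GPRNode, expr: Mapping[str, float]) -> float:
    """Aggregate per-gene expression into one reaction capacity.

    Alternative catalysts add up (``or`` = sum over children) while a
    complex is limited by its scarcest subunit (``and`` = min over
    children); the rule is applied recursively for mixed expressions.
    Genes missing from ``expr`` contribute 0.

    Raises
    ------
    ValueError
        If any referenced gene has a negative expression level.
    """
    if node.kind == LEAF:
        value = float(expr.get(node.gene_id, 0.0))  # type: ignore[arg-type]
        if value < 0:
            raise ValueError(
                f"negative expression level {value} for gene {node.gene_id!r}"
            )
        return value
    child_values = [aggregate_expression(c, expr) for c in node.children]
    if node.kind == AND:
        return min(child_values)
    return sum(child_values)


def genes_of(node: GPRNode) -> set[str]:
    """The set of gene identifiers appearing in the rule."""
    if node.kind == LEAF:
        return {node.gene_id}  # type: ignore[arg-type]
    out: set[str] = set()
    for child in node.children:
        out |= genes_of(child)
    return out
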