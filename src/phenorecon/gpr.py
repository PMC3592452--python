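"""Gene-protein-reaction (GPR) boolean rules.

A GPR rule states which gene products a reaction needs: ``and`` encodes an
enzyme complex (all subunits required), ``or`` encodes isozymes (any one
suffices).  An empty rule means the reaction is never gene-disabled
(spontaneous, orphan, or exchange reactions).

Rules are stored as small expression trees and support evaluation against a
set of knocked-out genes, canonical string round-tripping, and the structural
edits the reconciliation step needs (pruning isozyme branches, adding or
removing required genes).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator, Optional, Union


class GPRParseError(ValueError):
    """Raised for malformed GPR strings; message includes the position."""


@dataclass(frozen=True)
class GeneNode:
    gene: str


@dataclass(frozen=True)
class BoolNode:
    op: str  # "and" | "or"
    children: tuple["Node", ...]


Node = Union[GeneNode, BoolNode]

_TOKEN = re.compile(r"\s*(\(|\)|[^\s()]+)")


def _tokenize(text: str) -> Iterator[tuple[str, int]]:
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            break
        yield m.group(1), m.start(1)
        pos = m.end()


class _Parser:
    """Recursive descent: or-expr > and-expr > atom; 'and' binds tighter."""

    def __init__(self, text: str):
        self.text = text
        self.tokens = list(_tokenize(text))
        self.i = 0

    def peek(self) -> Optional[str]:
        return self.tokens[self.i][0] if self.i < len(self.tokens) else None

    def next(self) -> tuple[str, int]:
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def parse(self) -> Node:
        node = self.or_expr()
        if self.i < len(self.tokens):
            tok, pos = self.tokens[self.i]
            raise GPRParseError(f"unexpected token {tok!r} at position {pos}")
        return node

    def or_expr(self) -> Node:
        children = [self.and_expr()]
        while self.peek() is not None and self.peek().lower() == "or":
            self.next()
            children.append(self.and_expr())
        if len(children) == 1:
            return children[0]
        return BoolNode("or", tuple(children))

    def and_expr(self) -> Node:
        children = [self.atom()]
        while self.peek() is not None and self.peek().lower() == "and":
            self.next()
            children.append(self.atom())
        if len(children) == 1:
            return children[0]
        return BoolNode("and", tuple(children))

    def atom(self) -> Node:
        tok = self.peek()
        if tok is None:
            pos = len(self.text)
            raise GPRParseError(f"dangling operator at position {pos}")
        if tok == "(":
            _, pos = self.next()
            node = self.or_expr()
            if self.peek() != ")":
                raise GPRParseError(f"unbalanced parenthesis opened at position {pos}")
            self.next()
            return node
        if tok == ")":
            _, pos = self.tokens[self.i]
            raise GPRParseError(f"unbalanced ')' at position {pos}")
        if tok.lower() in ("and", "or"):
            _, pos = self.tokens[self.i]
            raise GPRParseError(f"dangling operator {tok!r} at position {pos}")
        tok, _ = self.next()
        return GeneNode(tok)


def _flatten(node: Node) -> Node:
    """Merge nested same-op nodes and sort children for a canonical form."""
    if isinstance(node, GeneNode):
        return node
    children: list[Node] = []
    for child in (_flatten(c) for c in node.children):
        if isinstance(child, BoolNode) and child.op == node.op:
            children.extend(child.children)
        else:
            children.append(child)
    # dedupe while keeping a deterministic sorted order
    uniq = sorted(set(children), key=_sort_key)
    if len(uniq) == 1:
        return uniq[0]
    return BoolNode(node.op, tuple(uniq))


def _sort_key(node: Node) -> str:
    return _to_string(node)


def _to_string(node: Node, parent_op: Optional[str] = None) -> str:
    if isinstance(node, GeneNode):
        return node.gene
    inner = f" {node.op} ".join(_to_string(c, node.op) for c in node.children)
    # parenthesize an or-group under an and-parent
    if parent_op == "and" and node.op == "or":
        return f"({inner})"
    if parent_op == "or" and node.op == "and":
        return f"({inner})"
    return inner


@dataclass(frozen=True)
class GPRRule:
    """A boolean gene requirement; ``root is None`` means no requirement."""

    root: Optional[Node] = None

    @property
    def is_empty(self) -> bool:
        return self.root is None

    def genes(self) -> frozenset[str]:
        if self.root is None:
            return frozenset()
        out: set[str] = set()
        stack: list[Node] = [self.root]
        while stack:
            node = stack.pop()
            if isinstance(node, GeneNode):
                out.add(node.gene)
            else:
                stack.extend(node.children)
        return frozenset(out)

    def evaluate(self, knocked: frozenset[str] | set[str]) -> bool:
        """True iff the reaction retains catalysis with ``knocked`` genes absent."""
        if self.root is None:
            return True
        return _eval(self.root, knocked)

    def to_string(self) -> str:
        if self.root is None:
            return ""
        return _to_string(_flatten(self.root))

    def canonical(self) -> "GPRRule":
        if self.root is None:
            return self
        return GPRRule(_flatten(self.root))

    # --- structural edits used by reconciliation -------------------------

    def without_genes(self, genes: set[str] | frozenset[str]) -> "GPRRule":
        """Drop the requirement for ``genes`` (treat them as always satisfied)."""
        if self.root is None:
            return self
        new = _substitute_true(self.root, frozenset(genes))
        return GPRRule(None if new is True else _flatten(new))

    def and_gene(self, gene: str) -> "GPRRule":
        node = GeneNode(gene)
        if self.root is None:
            return GPRRule(node)
        return GPRRule(_flatten(BoolNode("and", (self.root, node))))

    def or_gene(self, gene: str) -> "GPRRule":
        """Add an isozyme alternative at the top level."""
        node = GeneNode(gene)
        if self.root is None:
            return GPRRule(node)
        return GPRRule(_flatten(BoolNode("or", (self.root, node))))

    def top_or_branches(self) -> tuple[Node, ...]:
        """Top-level OR alternatives (the whole tree if not an OR)."""
        if self.root is None:
            return ()
        root = _flatten(self.root)
        if isinstance(root, BoolNode) and root.op == "or":
            return root.children
        return (root,)

    def without_branch(self, branch: Node) -> "GPRRule":
        """Remove one top-level OR alternative; errors if absent."""
        branches = self.top_or_branches()
        if branch not in branches:
            raise ValueError(f"branch {_to_string(branch)!r} not in rule {self.to_string()!r}")
        rest = tuple(b for b in branches if b != branch)
        if not rest:
            raise ValueError("cannot remove the only branch of a rule")
        if len(rest) == 1:
            return GPRRule(rest[0])
        return GPRRule(BoolNode("or", rest))

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


def _eval(node: Node, knocked: frozenset[str] | set[str]) -> bool:
    if isinstance(node, GeneNode):
        return node.gene not in knocked
    if node.op == "and":
        return all(_eval(c, knocked) for c in node.children)
    return any(_eval(c, knocked) for c in node.children)


def _substitute_true(node: Node, genes: frozenset[str]):
    """Replace leaves in ``genes`` by True and simplify; returns Node or True."""
    if isinstance(node, GeneNode):
        return True if node.gene in genes else node
    new_children = [_substitute_true(c, genes) for c in node.children]
    if node.op == "and":
        kept = tuple(c for c in new_children if c is not True)
        if not kept:
            return True
        if len(kept) == 1:
            return kept[0]
        return BoolNode("and", kept)
    # or: any True child makes the whole rule unconditional
    if any(c is True for c in new_children):
        return True
    if len(new_children) == 1:
        return new_children[0]
    return BoolNode("or", tuple(new_children))


def parse_gpr(text: str) -> GPRRule:
    """Parse a GPR string like ``"(g1 and g2) or g3"``.

    ``and``/``or`` are case-insensitive; an empty or whitespace-only string
    yields the empty rule.  Raises :class:`GPRParseError` with the offending
    position for unbalanced parentheses or dangling operators.
    """
    if text is None or not text.strip():
        return GPRRule(None)
    return GPRRule(_Parser(text).parse())
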