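"""Rooted, branch-length-annotated phylogenetic trees and Newick I/O.

Trees are consumed by the UniFrac distances in :mod:`microvar.diversity`.
They are treated as rooted exactly as written — no midpoint re-rooting is
ever applied, since phylogenetic distances depend on the root placement.
Polytomies are allowed. Unspecified branch lengths default to 0; the root
branch length is forced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

from .exceptions import NewickParseError, TreeError

__all__ = ["Node", "PhyloTree", "parse_newick", "postorder_branches"]


@dataclass
class Node:
    """A single tree node; leaves carry a label, internals may."""

    name: str | None = None
    length: float = 0.0
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """A rooted tree with non-negative branch lengths and unique leaf labels."""

    def __init__(self, root: Node):
        self.root = root
        self.root.length = 0.0
        self._validate()

    # -- construction / validation -------------------------------------

    def _validate(self) -> None:
        seen: set[str] = set()
        for node in self.postorder():
            if node.length < 0:
                raise TreeError(
                    f"negative branch length {node.length} on node {node.name!r}"
                )
            if node.is_leaf:
                if node.name is None or node.name == "":
                    raise TreeError("leaf without a label")
                if node.name in seen:
                    raise TreeError(f"duplicate leaf label {node.name!r}")
                seen.add(node.name)

    # -- traversal -----------------------------------------------------

    def postorder(self) -> Iterator[Node]:
        """Yield nodes children-first (root last), iteratively."""
        stack: list[tuple[Node, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]  # type: ignore[misc]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names())

    def total_branch_length(self) -> float:
        return sum(n.length for n in self.postorder() if n is not self.root)

    def copy(self) -> "PhyloTree":
        def clone(node: Node) -> Node:
            return Node(node.name, node.length, [clone(c) for c in node.children])

        return PhyloTree(clone(self.root))

    # -- serialization -------------------------------------------------

    def to_newick(self) -> str:
        parts: list[str] = []

        def write(node: Node, is_root: bool) -> None:
            if node.children:
                parts.append("(")
                for i, child in enumerate(node.children):
                    if i:
                        parts.append(",")
                    write(child, False)
                parts.append(")")
            if node.name is not None:
                parts.append(_quote_label(node.name))
            if not is_root:
                parts.append(f":{node.length!r}")

        write(self.root, True)
        parts.append(";")
        return "".join(parts)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<PhyloTree with {self.n_leaves} leaves>"

    # -- pruning -------------------------------------------------------

    def prune_to_taxa(self, taxa: set[str]) -> "PhyloTree":
        """Return a new tree whose leaves are exactly ``taxa``.

        Unary internal nodes left behind are collapsed with their branch
        lengths summed, so pairwise path lengths among retained leaves are
        preserved exactly.
        """
        known = set(self.leaf_names())
        unknown = sorted(set(taxa) - known)
        if unknown:
            raise TreeError(f"taxa not in tree: {unknown}")
        if not taxa:
            raise TreeError("cannot prune to an empty taxon set")

        def build(node: Node) -> Node | None:
            if node.is_leaf:
                if node.name in taxa:
                    return Node(node.name, node.length)
                return None
            kept = [c for c in (build(ch) for ch in node.children) if c is not None]
            if not kept:
                return None
            if len(kept) == 1:
                # collapse the unary node: fold this branch into the child
                child = kept[0]
                child.length += node.length
                return child
            return Node(node.name, node.length, kept)

        new_root = build(self.root)
        assert new_root is not None
        new_root.length = 0.0
        return PhyloTree(new_root)


def prune_to_taxa(tree: PhyloTree, taxa: set[str]) -> PhyloTree:
    """Functional alias for :meth:`PhyloTree.prune_to_taxa`."""
    return tree.prune_to_taxa(taxa)


def postorder_branches(tree: PhyloTree) -> list[tuple[float, frozenset[str]]]:
    """List every non-root branch as (length, descendant leaf set), children first.

    A lone root-leaf tree has no branches and yields the empty list.
    """
    out: list[tuple[float, frozenset[str]]] = []
    leafsets: dict[int, frozenset[str]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            ls = frozenset([node.name])  # type: ignore[list-item]
        else:
            ls = frozenset().union(*(leafsets[id(c)] for c in node.children))
        leafsets[id(node)] = ls
        if node is not tree.root:
            out.append((node.length, ls))
    return out


# ---------------------------------------------------------------------------
# Newick parsing (recursive descent with explicit position tracking)
# ---------------------------------------------------------------------------


def _quote_label(label: str) -> str:
    if any(c in label for c in "()[]{}/\\,;:=*'\"`+<> \t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


class _Reader:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def advance(self) -> str:
        ch = self.peek()
        self.pos += 1
        return ch

    def skip_ws_and_comments(self) -> None:
        while self.pos < len(self.text):
            ch = self.text[self.pos]
            if ch.isspace():
                self.pos += 1
            elif ch == "[":
                end = self.text.find("]", self.pos)
                if end == -1:
                    raise NewickParseError("unterminated [comment]", self.pos)
                self.pos = end + 1
            else:
                return


_LABEL_TERMINATORS = set("(),;:[]")


def _parse_label(r: _Reader) -> str | None:
    r.skip_ws_and_comments()
    if r.peek() == "'":
        r.advance()
        chars: list[str] = []
        while True:
            ch = r.advance()
            if ch == "":
                raise NewickParseError("unterminated quoted label", r.pos)
            if ch == "'":
                if r.peek() == "'":  # escaped quote
                    chars.append("'")
                    r.advance()
                else:
                    break
            else:
                chars.append(ch)
        return "".join(chars)
    chars = []
    while r.peek() and r.peek() not in _LABEL_TERMINATORS and not r.peek().isspace():
        chars.append(r.advance())
    return "".join(chars) or None


def _parse_length(r: _Reader) -> float:
    r.skip_ws_and_comments()
    if r.peek() != ":":
        return 0.0
    r.advance()
    r.skip_ws_and_comments()
    start = r.pos
    while r.peek() and (r.peek() in "+-.eE" or r.peek().isdigit()):
        r.advance()
    token = r.text[start : r.pos]
    try:
        return float(token)
    except ValueError:
        raise NewickParseError(f"invalid branch length {token!r}", start) from None


def _parse_clade(r: _Reader) -> Node:
    r.skip_ws_and_comments()
    node = Node()
    if r.peek() == "(":
        open_pos = r.pos
        r.advance()
        while True:
            node.children.append(_parse_clade(r))
            r.skip_ws_and_comments()
            ch = r.peek()
            if ch == ",":
                r.advance()
                continue
            if ch == ")":
                r.advance()
                break
            raise NewickParseError(
                "unbalanced parentheses: '(' never closed", open_pos
            )
    node.name = _parse_label(r)
    node.length = _parse_length(r)
    return node


def parse_newick(text: str) -> PhyloTree:
    """Parse a single rooted Newick statement terminated by ';'.

    Quoted labels are supported and ``[...]`` comments are skipped.
    Missing branch lengths default to 0. Raises
    :class:`~microvar.exceptions.NewickParseError` with the offending
    position for syntax errors, and :class:`~microvar.exceptions.TreeError`
    for structural violations (negative lengths, duplicate leaf labels).
    """
    r = _Reader(text)
    r.skip_ws_and_comments()
    if not r.peek():
        raise NewickParseError("empty Newick input", 0)
    root = _parse_clade(r)
    r.skip_ws_and_comments()
    if r.peek() != ";":
        raise NewickParseError("expected ';' terminating the statement", r.pos)
    r.advance()
    r.skip_ws_and_comments()
    if r.peek():
        raise NewickParseError("trailing content after ';'", r.pos)
    return PhyloTree(root)
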