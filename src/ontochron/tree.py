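"""Rooted trees over labelled leaves, with Newick interchange.

Trees may be multifurcating. The root of an analysis tree is the
hypothetical all-absent ancestor (label :data:`ANCESTOR_LABEL`), whose
children include the 0%-of-development OTUs; see the parsimony module.
"""

from __future__ import annotations

import re
from typing import Iterable, Iterator, Optional

ANCESTOR_LABEL = "ancestor"


class NewickParseError(ValueError):
    """Malformed Newick input; message carries position information."""


class Node:
    """A tree node; ``label`` is a string for leaves, usually None internally."""

    __slots__ = ("label", "children", "parent")

    def __init__(self, label: Optional[str] = None,
                 children: Iterable["Node"] = ()) -> None:
        self.label = label
        self.parent: Optional[Node] = None
        self.children: list[Node] = []
        for c in children:
            self.add(c)

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def detach(self) -> "Node":
        if self.parent is not None:
            self.parent.children.remove(self)
            self.parent = None
        return self

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(reversed(n.children))

    def postorder(self) -> Iterator["Node"]:
        out = list(self.preorder())
        return reversed(out)

    def leaves(self) -> list["Node"]:
        return [n for n in self.preorder() if n.is_leaf]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.label!r}, {len(self.children)} children)"


class Tree:
    """A rooted, possibly multifurcating tree with uniquely labelled leaves."""

    def __init__(self, root: Node) -> None:
        self.root = root

    # -- traversal ------------------------------------------------------
    def preorder(self) -> Iterator[Node]:
        return self.root.preorder()

    def postorder(self) -> Iterator[Node]:
        return self.root.postorder()

    def leaves(self) -> list[Node]:
        return self.root.leaves()

    def leaf_labels(self) -> frozenset[str]:
        return frozenset(n.label for n in self.leaves() if n.label is not None)

    # -- clusters -------------------------------------------------------
    def clusters(self, include_trivial: bool = False) -> set[frozenset[str]]:
        """The set of leaf-label clusters (one per internal node).

        The root cluster (all leaves) is always included; singleton leaf
        clusters only when ``include_trivial`` is set.
        """
        out: set[frozenset[str]] = set()
        below: dict[int, frozenset[str]] = {}
        for n in self.root.postorder():
            if n.is_leaf:
                s = frozenset({n.label}) if n.label is not None else frozenset()
                below[id(n)] = s
                if include_trivial and n.label is not None:
                    out.add(s)
            else:
                s = frozenset().union(*(below[id(c)] for c in n.children))
                if n.label is not None:
                    # labelled internal node (e.g. the ancestor root) also
                    # carries its own label as a member of no cluster
                    pass
                below[id(n)] = s
                out.add(s)
        return out

    # -- structure ------------------------------------------------------
    def copy(self) -> "Tree":
        def dup(n: Node) -> Node:
            m = Node(n.label)
            for c in n.children:
                m.add(dup(c))
            return m

        return Tree(dup(self.root))

    def canonical(self):
        """A hashable canonical form: label-sorted nested tuples."""

        def canon(n: Node):
            if n.is_leaf:
                return ("L", n.label or "")
            return ("I", n.label or "", tuple(sorted(canon(c) for c in n.children)))

        return canon(self.root)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Tree):
            return NotImplemented
        return self.canonical() == other.canonical()

    def __hash__(self) -> int:
        return hash(self.canonical())

    def ascii_sketch(self) -> str:
        """A small indented sketch for terminal output."""
        lines: list[str] = []

        def walk(n: Node, depth: int) -> None:
            tag = n.label if n.label is not None else "*"
            lines.append("  " * depth + tag)
            for c in n.children:
                walk(c, depth + 1)

        walk(self.root, 0)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tree({to_newick(self)})"


# -- Newick interchange --------------------------------------------------

_SAFE = re.compile(r"^[A-Za-z0-9_.|-]+$")


def _quote(label: str) -> str:
    if _SAFE.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def to_newick(t: Tree) -> str:
    """Serialize; labels with spaces, ``%`` etc. are single-quoted."""

    def walk(n: Node) -> str:
        if n.is_leaf:
            return _quote(n.label or "")
        inner = ",".join(walk(c) for c in n.children)
        tag = _quote(n.label) if n.label else ""
        return f"({inner}){tag}"

    return walk(t.root) + ";"


def from_newick(text: str) -> Tree:
    """Parse one Newick tree (via dendropy); errors carry the position."""
    import dendropy

    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            suppress_leaf_node_taxa=False,
        )
    except Exception as exc:
        raise NewickParseError(f"Newick parse failed: {exc}") from exc

    def convert(dnode) -> Node:
        if dnode.taxon is not None:
            label = dnode.taxon.label
        else:
            label = dnode.label
        n = Node(label)
        for child in dnode.child_nodes():
            n.add(convert(child))
        return n

    return Tree(convert(dtree.seed_node))
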