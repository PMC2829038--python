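"""Rooted binary leaf-labeled trees with Newick I/O and canonical forms.

The central type is :class:`RootedTree`, a mutable rooted binary tree whose
leaves carry unique text labels.  Above the original root sits an auxiliary
*root handle* vertex ``p`` connected to the root by a pendant edge.  The
handle exists so that a subtree can be regrafted onto the edge above the
original root (producing a new root); it is never serialized and no operation
ever deletes it.

Isomorphism of rooted leaf-labeled trees (child order irrelevant) is decided
in O(1) per comparison through *canonical keys*: every distinct subtree shape
is interned to a small integer, computed bottom-up with the two child keys in
sorted order.  Two trees are isomorphic iff their root keys are equal.
Serialization uses a canonical Newick form in which children are ordered by
their canonical Newick text, so isomorphic trees serialize identically.

Newick parsing is delegated to :mod:`dendropy` (quoted labels, bracket
comments, branch lengths and internal-node labels are all accepted); only the
topology and the leaf labels are kept.
"""

from __future__ import annotations

from typing import Iterator

import dendropy

from .errors import (
    DuplicateLabelError,
    NewickError,
    NotBinaryError,
)

__all__ = [
    "Node",
    "RootedTree",
    "canonical_key",
    "are_isomorphic",
    "parse_newick",
    "write_newick",
]


class Node:
    """A vertex of a :class:`RootedTree`.

    Internal vertices have exactly two children and ``label is None``;
    leaves have no children and a non-empty label.  The root handle is an
    ordinary :class:`Node` with a single child (the original root).
    """

    __slots__ = ("parent", "children", "label")

    def __init__(self, label: str | None = None):
        self.parent: Node | None = None
        self.children: list[Node] = []
        self.label = label

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        if self.is_leaf:
            return f"Node({self.label!r})"
        return f"Node(<{len(self.children)} children>)"


# ---------------------------------------------------------------------------
# canonical keys
#
# A global intern table maps subtree shapes to integers:
#   leaf            ->  intern of ('L', label)
#   internal vertex ->  intern of ('I', min(k1, k2), max(k1, k2))
# Keys are comparable across trees for the lifetime of the process.
# ---------------------------------------------------------------------------

_INTERN: dict[tuple, int] = {}


def _intern(token: tuple) -> int:
    key = _INTERN.get(token)
    if key is None:
        key = len(_INTERN)
        _INTERN[token] = key
    return key


def subtree_key(node: Node) -> int:
    """Canonical key of the subtree rooted at ``node`` (iterative postorder)."""
    keys: dict[int, int] = {}
    stack = [(node, False)]
    while stack:
        v, done = stack.pop()
        if v.is_leaf:
            keys[id(v)] = _intern(("L", v.label))
        elif done:
            ks = sorted(keys[id(c)] for c in v.children)
            keys[id(v)] = _intern(("I", *ks))
        else:
            stack.append((v, True))
            stack.extend((c, False) for c in v.children)
    return keys[id(node)]


class RootedTree:
    """A rooted binary phylogenetic tree on uniquely labeled leaves.

    ``handle`` is the auxiliary vertex ``p``; its single child is the
    original root.  A one-leaf tree is the handle with a single leaf child.
    """

    __slots__ = ("handle",)

    def __init__(self, root: Node):
        self.handle = Node()
        self.handle.add_child(root)

    # -- basic accessors ----------------------------------------------------

    @property
    def root(self) -> Node:
        return self.handle.children[0]

    def nodes(self) -> Iterator[Node]:
        """All vertices below the handle, in deterministic preorder."""
        stack = [self.root]
        while stack:
            v = stack.pop()
            yield v
            stack.extend(reversed(v.children))

    def leaves(self) -> Iterator[Node]:
        return (v for v in self.nodes() if v.is_leaf)

    def leaf_labels(self) -> frozenset[str]:
        return frozenset(v.label for v in self.leaves())  # type: ignore[misc]

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self.leaves())

    # -- copying ------------------------------------------------------------

    def copy(self) -> "RootedTree":
        return self.copy_with_map()[0]

    def copy_with_map(self) -> tuple["RootedTree", dict[int, Node]]:
        """Deep copy; also return a map ``id(old node) -> new node``."""
        mapping: dict[int, Node] = {}
        new_root = copy_subtree(self.root, mapping)
        return RootedTree(new_root), mapping

    # -- canonical form -----------------------------------------------------

    def canonical_key(self) -> int:
        return subtree_key(self.root)

    def is_isomorphic_to(self, other: "RootedTree") -> bool:
        return self.canonical_key() == other.canonical_key()

    def to_newick(self) -> str:
        return write_newick(self)

    @classmethod
    def from_newick(cls, text: str) -> "RootedTree":
        return parse_newick(text)

    def validate(self) -> None:
        """Check structural invariants; raise on violation.  Test support."""
        if len(self.handle.children) != 1:
            raise NotBinaryError("root handle must have exactly one child")
        labels = []
        for v in self.nodes():
            if v.is_leaf:
                if not v.label:
                    raise NewickError("leaf without a label")
                labels.append(v.label)
            else:
                if len(v.children) != 2:
                    raise NotBinaryError(
                        f"internal vertex with {len(v.children)} children"
                    )
                if v.label is not None:
                    raise NewickError("internal vertex carrying a leaf label")
            for c in v.children:
                if c.parent is not v:
                    raise NewickError("broken parent link")
        if len(labels) != len(set(labels)):
            raise DuplicateLabelError("duplicate leaf labels")

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        n = self.n_leaves
        return f"RootedTree(n={n}, {self.to_newick()!r})" if n <= 12 else f"RootedTree(n={n})"


def copy_subtree(node: Node, mapping: dict[int, Node] | None = None) -> Node:
    """Deep-copy the subtree rooted at ``node`` (iterative)."""
    new = Node(node.label)
    if mapping is not None:
        mapping[id(node)] = new
    stack = [(node, new)]
    while stack:
        old, fresh = stack.pop()
        for c in old.children:
            nc = Node(c.label)
            fresh.add_child(nc)
            if mapping is not None:
                mapping[id(c)] = nc
            stack.append((c, nc))
    return new


def canonical_key(tree_or_node: "RootedTree | Node") -> int:
    """Canonical key of a tree or of a subtree rooted at a node.

    Equal keys ⟺ isomorphic as rooted leaf-labeled trees (child order is
    irrelevant).  Keys are process-lifetime interned integers.
    """
    if isinstance(tree_or_node, RootedTree):
        return tree_or_node.canonical_key()
    return subtree_key(tree_or_node)


def are_isomorphic(a: RootedTree, b: RootedTree) -> bool:
    """True iff ``a`` and ``b`` are isomorphic rooted leaf-labeled trees."""
    return a.canonical_key() == b.canonical_key()


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

_NEEDS_QUOTING = set("()[]{}/\\,;:=*'\"`<> \t\n")


def _format_label(label: str) -> str:
    if any(ch in _NEEDS_QUOTING for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def canonical_newick(node: Node) -> str:
    """Canonical Newick of the subtree at ``node``, without trailing ';'.

    Children are ordered by their own canonical Newick text, so isomorphic
    subtrees yield byte-identical strings.  Iterative to cope with very deep
    (caterpillar) trees.
    """
    out: dict[int, str] = {}
    stack = [(node, False)]
    while stack:
        v, done = stack.pop()
        if v.is_leaf:
            out[id(v)] = _format_label(v.label)  # type: ignore[arg-type]
        elif done:
            parts = sorted(out[id(c)] for c in v.children)
            out[id(v)] = "(" + ",".join(parts) + ")"
        else:
            stack.append((v, True))
            stack.extend((c, False) for c in v.children)
    return out[id(node)]


def write_newick(tree: RootedTree) -> str:
    """Serialize to canonical Newick (handle not serialized)."""
    return canonical_newick(tree.root) + ";"


def parse_newick(text: str) -> RootedTree:
    """Parse a single rooted Newick statement into a :class:`RootedTree`.

    Branch lengths, internal-node labels and bracket comments are accepted
    and discarded.  Multifurcations and unifurcations raise
    :class:`NotBinaryError`; duplicate leaf labels raise
    :class:`DuplicateLabelError`; anything unparseable raises
    :class:`NewickError`.
    """
    if not isinstance(text, str) or not text.strip():
        raise NewickError("empty Newick input")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        if type(exc).__name__ == "NewickReaderDuplicateTaxonError":
            raise DuplicateLabelError(str(exc)) from exc
        raise NewickError(f"malformed Newick: {exc}") from exc

    seen: set[str] = set()

    def convert(dnode) -> Node:
        stack = [(dnode, None)]
        root_new: Node | None = None
        while stack:
            dv, parent = stack.pop()
            kids = dv.child_nodes()
            if not kids:
                label = dv.taxon.label if dv.taxon is not None else None
                if not label:
                    raise NewickError("leaf without a label")
                if label in seen:
                    raise DuplicateLabelError(f"duplicate leaf label {label!r}")
                seen.add(label)
                nv = Node(label)
            else:
                if len(kids) != 2:
                    raise NotBinaryError(
                        f"vertex with {len(kids)} children (tree must be binary)"
                    )
                nv = Node()
            if parent is None:
                root_new = nv
            else:
                parent.add_child(nv)
            stack.extend((k, nv) for k in reversed(kids))
        assert root_new is not None
        return root_new

    root = convert(dtree.seed_node)
    tree = RootedTree(root)
    tree.validate()
    return tree
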