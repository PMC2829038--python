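"""The rooted SPR (subtree prune and regraft) operation and neighborhoods.

A single rooted SPR on a tree T with root handle p:

* choose an edge e = {u, v} not incident with p, with v the endpoint farther
  from p — v is the root of the pruned subtree;
* delete e; the component C_u containing u retains the handle;
* subdivide an edge of C_u with a new vertex u' and join u' to v;
* suppress the now degree-two vertex u.

Regrafting onto the pendant edge {p, original root} is allowed (it makes the
pruned subtree a child of a new root); regrafting onto either edge incident
to u is excluded because it recreates the original tree.

The *neighborhood* N(T) is the set of distinct trees exactly one rooted SPR
away from T.  It is deduplicated by canonical key and never contains T
itself; each member keeps one witnessing move so edit paths can be reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

from .errors import InvalidMoveError
from .tree import Node, RootedTree

__all__ = [
    "RSPRMove",
    "Neighborhood",
    "apply_move",
    "enumerate_moves",
    "neighborhood",
    "is_one_spr_apart",
]


@dataclass(frozen=True)
class RSPRMove:
    """One rooted SPR on a specific tree instance.

    ``prune`` is the root v of the pruned subtree (the child endpoint of the
    prune edge); ``regraft`` is the child endpoint of the edge of C_u to be
    subdivided.  Node references are only meaningful for the tree the move
    was enumerated on.
    """

    prune: Node
    regraft: Node

    def describe(self) -> dict:
        """Leaf-set description of the move (for logs and JSON reports)."""
        pruned = sorted(_subtree_labels(self.prune))
        target = sorted(_subtree_labels(self.regraft))
        return {"pruned_leaves": pruned, "regraft_above_leaves": target}


@dataclass
class Neighborhood:
    """Distinct trees one rooted SPR from a source tree.

    ``members`` maps canonical key -> (tree, witnessing move).  No member is
    isomorphic to the source or to another member.
    """

    source_key: int
    members: dict[int, tuple[RootedTree, RSPRMove]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, key: int) -> bool:
        return key in self.members

    def trees(self) -> Iterator[RootedTree]:
        return (t for t, _ in self.members.values())


def _subtree_labels(node: Node) -> set[str]:
    labels: set[str] = set()
    stack = [node]
    while stack:
        v = stack.pop()
        if v.is_leaf:
            labels.add(v.label)  # type: ignore[arg-type]
        else:
            stack.extend(v.children)
    return labels


def _subtree_ids(node: Node) -> set[int]:
    ids: set[int] = set()
    stack = [node]
    while stack:
        v = stack.pop()
        ids.add(id(v))
        stack.extend(v.children)
    return ids


def _validate(tree: RootedTree, move: RSPRMove) -> None:
    node_ids = {id(n) for n in tree.nodes()}
    v, f = move.prune, move.regraft
    if id(v) not in node_ids or id(f) not in node_ids:
        raise InvalidMoveError("move refers to nodes outside the tree")
    if v is tree.root:
        raise InvalidMoveError("prune edge is incident with the root handle")
    u = v.parent
    assert u is not None
    w = u.children[0] if u.children[1] is v else u.children[1]
    if id(f) in _subtree_ids(v):
        raise InvalidMoveError("regraft edge lies inside the pruned subtree")
    if f is u or f is w:
        raise InvalidMoveError("regraft onto an edge incident to u recreates the tree")


def apply_move(tree: RootedTree, move: RSPRMove) -> RootedTree:
    """Apply one rooted SPR, returning a new tree; the input is unmodified.

    The move's node references must belong to ``tree``.
    """
    _validate(tree, move)
    new_tree, mapping = tree.copy_with_map()
    v = mapping[id(move.prune)]
    f = mapping[id(move.regraft)]
    u = v.parent
    assert u is not None
    g = u.parent
    assert g is not None
    w = u.children[0] if u.children[1] is v else u.children[1]
    # detach the pruned subtree and suppress u
    g.children[g.children.index(u)] = w
    w.parent = g
    # reuse u as the subdividing vertex u' on the regraft edge
    fp = f.parent
    assert fp is not None
    fp.children[fp.children.index(f)] = u
    u.parent = fp
    u.children = [f, v]
    f.parent = u
    v.parent = u
    return new_tree


def enumerate_moves(tree: RootedTree) -> list[RSPRMove]:
    """All admissible (prune, regraft) pairs, each exactly once.

    Deterministic order: prune edges in preorder, then regraft edges in
    preorder.  Identity-recreating regrafts (edges incident to u) and the
    prune edge incident with the handle are excluded by construction; some
    listed moves may still produce a tree isomorphic to the input (the
    neighborhood dedups those).
    """
    order = list(tree.nodes())
    moves: list[RSPRMove] = []
    for v in order:
        if v is tree.root:
            continue
        u = v.parent
        assert u is not None
        w = u.children[0] if u.children[1] is v else u.children[1]
        forbidden = _subtree_ids(v)
        forbidden.add(id(u))
        forbidden.add(id(w))
        for f in order:
            if id(f) in forbidden:
                continue
            moves.append(RSPRMove(prune=v, regraft=f))
    return moves


def _key_without_leaf(tree: RootedTree, label: str) -> int:
    """Canonical key of the tree with one leaf deleted and its parent suppressed."""
    from .tree import subtree_key

    clone = tree.copy()
    leaf = next(v for v in clone.leaves() if v.label == label)
    parent = leaf.parent
    assert parent is not None and parent is not clone.handle
    sibling = parent.children[0] if parent.children[1] is leaf else parent.children[1]
    grand = parent.parent
    assert grand is not None
    grand.children[grand.children.index(parent)] = sibling
    sibling.parent = grand
    return subtree_key(clone.root)


def one_spr_apart_reduced(ra: RootedTree, rb: RootedTree) -> bool:
    """One-SPR test for a pair already at the collapse fixed point.

    A single SPR moves a pendant subtree common to both trees; at the fixed
    point any common pendant subtree is a single leaf, so the trees are one
    SPR apart iff deleting some one leaf (in both) makes them isomorphic.
    O(m^2) in the reduced leaf count m — far cheaper than enumerating the
    whole neighborhood.
    """
    if ra.canonical_key() == rb.canonical_key():
        return False  # distance 0, not 1
    labels = sorted(ra.leaf_labels())
    if len(labels) < 3:
        return False
    removed_b = {lab: _key_without_leaf(rb, lab) for lab in labels}
    return any(_key_without_leaf(ra, lab) == removed_b[lab] for lab in labels)


def is_one_spr_apart(a: RootedTree, b: RootedTree) -> bool:
    """True iff the trees (same taxon set) are exactly one rooted SPR apart.

    Equivalent to membership of ``b`` in ``neighborhood(a)`` but runs in
    O(n + m^2) where m is the size of the collapsed pair, so it scales to
    trees with thousands of leaves.
    """
    from .reduction import collapse_common_subtrees

    rp = collapse_common_subtrees(a, b)
    return one_spr_apart_reduced(rp.tree_a, rp.tree_b)


def neighborhood(tree: RootedTree) -> Neighborhood:
    """The deduplicated one-SPR neighborhood of ``tree``.

    Trees isomorphic to the source are excluded; when several moves yield the
    same tree, the first in enumeration order is kept as witness.
    """
    source_key = tree.canonical_key()
    nb = Neighborhood(source_key=source_key)
    for move in enumerate_moves(tree):
        candidate = apply_move(tree, move)
        key = candidate.canonical_key()
        if key == source_key or key in nb.members:
            continue
        nb.members[key] = (candidate, move)
    return nb
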