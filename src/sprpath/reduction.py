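"""Kernelization: common-subtree collapse and common-cluster decomposition.

Two reductions shrink an SPR-distance instance before (and during) search:

*Subtree collapse.*  Any pendant subtree occurring identically in both trees
is replaced, in both, by a single fresh-labeled leaf.  This is repeated until
no common pendant subtree with at least two leaves remains.  Collapse
preserves the rooted SPR distance, and replaying the collapse records in
reverse restores the original trees exactly — which is how cluster-level
edit paths are lifted back to full-size trees.

*Common clusters.*  After collapsing, a pendant subtree of one tree whose
leaf set equals that of a pendant subtree of the other, with different
topology, is a *common cluster*; the minimal ones (no returned cluster's
leaf set contains another's) are independent-looking subproblems.  A cluster
is flagged *solvable* (SCC) when the parent vertex's subtree spans the same
leaf set in both trees — the condition under which solving the cluster in
isolation is conjectured to preserve the overall distance.  When no proper
cluster qualifies the whole tree pair is returned, so callers always get at
least one subproblem.

Leaf sets are compared through 64-bit additive fingerprints (a stable hash
per label, summed over the subtree); candidate clusters that are actually
returned are verified by exact leaf-set comparison.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

from .errors import ExpansionError, LeafSetMismatchError, ReductionError
from .tree import Node, RootedTree, canonical_newick, copy_subtree, subtree_key

__all__ = [
    "DEFAULT_FRESH_PREFIX",
    "FreshLabeler",
    "CollapseRecord",
    "ReducedPair",
    "ClusterPair",
    "collapse_common_subtrees",
    "find_clusters",
    "expand",
]

DEFAULT_FRESH_PREFIX = "__c"

_MASK64 = (1 << 64) - 1


def _label_hash(label: str) -> int:
    digest = hashlib.blake2b(label.encode("utf-8"), digest_size=8).digest()
    return int.from_bytes(digest, "big")


class FreshLabeler:
    """Issues fresh leaf labels from a namespace disjoint from existing labels."""

    def __init__(self, existing_labels, prefix: str = DEFAULT_FRESH_PREFIX):
        existing = set(existing_labels)
        while any(lab.startswith(prefix) for lab in existing):
            prefix = "_" + prefix
        self.prefix = prefix
        self._counter = 0

    def next(self) -> str:
        self._counter += 1
        return f"{self.prefix}{self._counter}"


@dataclass
class CollapseRecord:
    """One collapsed common pendant subtree.

    ``subtree`` is the collapsed topology (owned by the record; identical in
    both trees at collapse time).  Replaying records in reverse order, each
    fresh leaf replaced by its subtree, restores the original trees.
    """

    fresh_label: str
    subtree: Node


@dataclass
class ReducedPair:
    """Two trees at the collapse fixed point plus the ordered collapse records."""

    tree_a: RootedTree
    tree_b: RootedTree
    records: list[CollapseRecord] = field(default_factory=list)


@dataclass
class ClusterPair:
    """A common-cluster subproblem.

    ``sub_a``/``sub_b`` are standalone copies of the cluster in each tree
    (same leaf set, different topology).  ``kind`` is ``"SCC"`` when the
    parent's subtree spans the same leaf set in both trees (for the
    whole-tree pair this holds trivially), else ``"MCC"``.  ``node_a`` and
    ``node_b`` reference the cluster roots inside the :class:`ReducedPair`
    the cluster was found in.
    """

    sub_a: RootedTree
    sub_b: RootedTree
    kind: str
    n_leaves: int
    node_a: Node | None = None
    node_b: Node | None = None


def _all_subtree_keys(tree: RootedTree) -> dict[int, int]:
    """Canonical key of every subtree, one postorder pass; id(node) -> key."""
    from .tree import _intern  # shared intern table

    keys: dict[int, int] = {}
    stack = [(tree.root, False)]
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
    return keys


def _replace_with_leaf(tree: RootedTree, node: Node, label: str) -> Node:
    """Detach ``node`` and put a fresh leaf in its place; returns the leaf."""
    leaf = Node(label)
    parent = node.parent
    assert parent is not None
    parent.children[parent.children.index(node)] = leaf
    leaf.parent = parent
    node.parent = None
    return leaf


def collapse_common_subtrees(
    a: RootedTree,
    b: RootedTree,
    labeler: FreshLabeler | None = None,
) -> ReducedPair:
    """Collapse maximal common pendant subtrees until a fixed point.

    Returns reduced *copies*; the inputs are unmodified.  The reduced trees
    share no common pendant subtree with >= 2 leaves, and the rooted SPR
    distance is unchanged by the reduction.  If the inputs are identical the
    result is a single shared fresh leaf (one record).
    """
    labels_a, labels_b = a.leaf_labels(), b.leaf_labels()
    if labels_a != labels_b:
        raise LeafSetMismatchError(
            f"trees are on different taxon sets ({len(labels_a)} vs {len(labels_b)} leaves)"
        )
    if labeler is None:
        labeler = FreshLabeler(labels_a)
    ra, rb = a.copy(), b.copy()
    records: list[CollapseRecord] = []
    changed = True
    while changed:
        changed = False
        keys_b = _all_subtree_keys(rb)
        by_key = {keys_b[id(v)]: v for v in rb.nodes() if not v.is_leaf}
        keys_a = _all_subtree_keys(ra)
        # preorder over ra, skipping below any collapsed node (maximality)
        stack = [ra.root]
        while stack:
            va = stack.pop()
            if va.is_leaf:
                continue
            vb = by_key.get(keys_a[id(va)])
            if vb is not None:
                fresh = labeler.next()
                _replace_with_leaf(rb, vb, fresh)
                _replace_with_leaf(ra, va, fresh)
                records.append(CollapseRecord(fresh_label=fresh, subtree=va))
                changed = True
            else:
                stack.extend(va.children)
    return ReducedPair(tree_a=ra, tree_b=rb, records=records)


def _leafset_stats(tree: RootedTree) -> dict[int, tuple[int, int]]:
    """id(node) -> (64-bit additive leaf-set fingerprint, leaf count)."""
    stats: dict[int, tuple[int, int]] = {}
    stack = [(tree.root, False)]
    while stack:
        v, done = stack.pop()
        if v.is_leaf:
            stats[id(v)] = (_label_hash(v.label), 1)  # type: ignore[arg-type]
        elif done:
            fp, n = 0, 0
            for c in v.children:
                cfp, cn = stats[id(c)]
                fp = (fp + cfp) & _MASK64
                n += cn
            stats[id(v)] = (fp, n)
        else:
            stack.append((v, True))
            stack.extend((c, False) for c in v.children)
    return stats


def _subtree_labelset(node: Node) -> frozenset[str]:
    labels = []
    stack = [node]
    while stack:
        v = stack.pop()
        if v.is_leaf:
            labels.append(v.label)
        else:
            stack.extend(v.children)
    return frozenset(labels)  # type: ignore[arg-type]


def find_clusters(pair: ReducedPair, require_scc: bool = True) -> list[ClusterPair]:
    """Minimal common clusters of a reduced pair, smallest leaf count first.

    With ``require_scc`` only solvable clusters (parent spans the same leaf
    set in both trees) are considered before minimality is applied; the
    whole-tree pair is the fallback when no proper cluster qualifies.  No
    returned cluster's leaf set strictly contains another's.
    """
    a, b = pair.tree_a, pair.tree_b
    if a.canonical_key() == b.canonical_key():
        raise ReductionError("cluster search on identical trees")
    stats_a, stats_b = _leafset_stats(a), _leafset_stats(b)
    by_fp: dict[tuple[int, int], Node] = {
        stats_b[id(v)]: v for v in b.nodes() if not v.is_leaf
    }
    keys_a, keys_b = _all_subtree_keys(a), _all_subtree_keys(b)

    candidates: dict[int, tuple[Node, Node]] = {}  # id(node_a) -> (node_a, node_b)
    for va in a.nodes():
        if va.is_leaf:
            continue
        vb = by_fp.get(stats_a[id(va)])
        if vb is None:
            continue
        if keys_a[id(va)] == keys_b[id(vb)]:
            continue  # identical topology: not discordant
        if require_scc:
            pa, pb = va.parent, vb.parent
            root_pair = pa is a.handle and pb is b.handle
            if not root_pair:
                if pa is a.handle or pb is b.handle:
                    continue
                if stats_a[id(pa)] != stats_b[id(pb)]:
                    continue
        candidates[id(va)] = (va, vb)

    # minimality: drop any candidate with a candidate strictly below it
    minimal: list[tuple[Node, Node]] = []
    for va, vb in candidates.values():
        stack = list(va.children)
        has_below = False
        while stack and not has_below:
            x = stack.pop()
            if id(x) in candidates:
                has_below = True
            else:
                stack.extend(x.children)
        if not has_below:
            minimal.append((va, vb))

    clusters: list[ClusterPair] = []
    for va, vb in minimal:
        if _subtree_labelset(va) != _subtree_labelset(vb):  # fingerprint guard
            continue
        pa, pb = va.parent, vb.parent
        if pa is a.handle and pb is b.handle:
            solvable = True
        elif pa is a.handle or pb is b.handle:
            solvable = False
        else:
            solvable = stats_a[id(pa)] == stats_b[id(pb)] and _subtree_labelset(
                pa
            ) == _subtree_labelset(pb)
        clusters.append(
            ClusterPair(
                sub_a=RootedTree(copy_subtree(va)),
                sub_b=RootedTree(copy_subtree(vb)),
                kind="SCC" if solvable else "MCC",
                n_leaves=stats_a[id(va)][1],
                node_a=va,
                node_b=vb,
            )
        )
    if not clusters:
        clusters.append(
            ClusterPair(
                sub_a=a.copy(),
                sub_b=b.copy(),
                kind="SCC",
                n_leaves=a.n_leaves,
                node_a=a.root,
                node_b=b.root,
            )
        )
    clusters.sort(key=lambda c: (c.n_leaves, canonical_newick(c.sub_a.root)))
    return clusters


def expand(
    records: list[CollapseRecord],
    tree: RootedTree,
    fresh_prefix: str | None = None,
    strict: bool = True,
) -> RootedTree:
    """Replace every collapsed (fresh-labeled) leaf by its recorded subtree.

    Records are replayed in reverse order, so nested collapses unfold
    correctly.  When ``strict``, a leaf whose label lies in the fresh
    namespace but has no record raises :class:`ExpansionError`; with
    ``strict=False`` such leaves are left alone (used when expanding one
    collapse level of a nested reduction at a time).  A tree without fresh
    labels is returned unchanged (as a copy).
    """
    out = tree.copy()
    if not records:
        return out
    by_label = {r.fresh_label: r for r in records}
    if fresh_prefix is None:
        prefixes = {r.fresh_label.rstrip("0123456789") for r in records}
        fresh_prefix = prefixes.pop() if len(prefixes) == 1 else DEFAULT_FRESH_PREFIX
    # index the fresh-labeled leaves present in the tree
    fresh_leaves: dict[str, Node] = {
        v.label: v for v in out.leaves() if v.label in by_label  # type: ignore[index]
    }
    if strict:
        for leaf in out.leaves():
            if (
                leaf.label
                and leaf.label.startswith(fresh_prefix)
                and leaf.label not in by_label
            ):
                raise ExpansionError(f"no collapse record for leaf {leaf.label!r}")
    for record in reversed(records):
        leaf = fresh_leaves.pop(record.fresh_label, None)
        if leaf is None:
            continue
        replacement = copy_subtree(record.subtree)
        parent = leaf.parent
        assert parent is not None
        parent.children[parent.children.index(leaf)] = replacement
        replacement.parent = parent
        # the spliced subtree may itself contain earlier fresh labels
        stack = [replacement]
        while stack:
            v = stack.pop()
            if v.is_leaf:
                if v.label in by_label:
                    fresh_leaves[v.label] = v
                elif strict and v.label and v.label.startswith(fresh_prefix):
                    raise ExpansionError(f"no collapse record for leaf {v.label!r}")
            else:
                stack.extend(v.children)
    return out
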