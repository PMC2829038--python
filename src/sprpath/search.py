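"""Greedy-first exhaustive depth-first search for the rooted SPR distance.

The recursion solves d(t, t') for one (sub)problem pair:

1. if t ≅ t' the current recursion depth is a solution;
2. otherwise collapse common subtrees of (t, t'), generate the SPR
   neighborhood of the reduced t, and test every neighbor against the
   reduced t' — a hit means a solution one deeper than the current level;
3. otherwise recurse over the neighborhood sorted by how far each neighbor
   collapses against the target (fewest uncollapsed leaves first), pruning
   any branch that cannot beat the incumbent.

Because the most-collapsed neighbor is explored first, the first descent is
greedy and establishes an upper limit quickly; the remaining bounded search
either verifies it or finds better, so a completed run is exact.  The
incumbent is seeded with a constructive (not necessarily minimal) edit path,
so a valid solution exists at any moment — a deadline or depth cap only
degrades the answer to an upper bound, never to nothing.

Every level's collapse keeps its records, and solutions are lifted back
through them level by level, so the reported path is a chain of full-size
trees on the input leaf set, consecutive trees exactly one SPR apart.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

from .errors import LeafSetMismatchError
from .moves import (
    Neighborhood,
    RSPRMove,
    apply_move,
    neighborhood,
    one_spr_apart_reduced,
)
from .reduction import CollapseRecord, collapse_common_subtrees, expand
from .tree import Node, RootedTree, canonical_newick

__all__ = [
    "SearchConfig",
    "SearchResult",
    "sort_neighborhood",
    "rspr_distance",
    "constructive_upper_bound",
]

EXACT = "exact"
HEURISTIC = "heuristic_upper_bound"


@dataclass
class SearchConfig:
    """Search-mode knobs.

    mode
        ``"exhaustive"`` runs to completion (exact answer); ``"heuristic"``
        returns the best solution found when ``time_limit`` expires.
    time_limit
        Deadline in seconds, used in heuristic mode (default 30).
    depth_cap
        Maximum recursion depth; ``None`` means n - 1 for an n-leaf
        subproblem, which the constructive fallback can always meet.
    use_memo
        Keep a visited (tree, target) -> depth table to skip re-expansions
        reached again no shallower.  Off by default: the depth-first search
        is chosen for its low memory footprint, and the table grows with the
        explored space.
    """

    mode: str = "exhaustive"
    time_limit: float = 30.0
    depth_cap: int | None = None
    use_memo: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("exhaustive", "heuristic"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "heuristic" and not self.time_limit > 0:
            raise ValueError("time_limit must be positive in heuristic mode")
        if self.depth_cap is not None and self.depth_cap < 1:
            raise ValueError("depth_cap must be >= 1")


@dataclass
class SearchResult:
    """Distance plus the witnessing edit path.

    ``path`` is t = x0, x1, ..., xd ≅ t' with consecutive trees one rooted
    SPR apart; ``status`` is ``"exact"`` when the search ran to completion,
    else ``"heuristic_upper_bound"``.  ``explored`` counts search-tree nodes
    and ``upper_limits`` the strictly improving incumbent distances, in
    order (diagnostics).
    """

    distance: int
    path: list[RootedTree]
    status: str
    explored: int = 0
    upper_limits: list[int] = field(default_factory=list)


class _Deadline(Exception):
    pass


def sort_neighborhood(nb: Neighborhood, target: RootedTree) -> list[RootedTree]:
    """Order neighbors by remaining uncollapsed leaves against ``target``.

    Each neighbor is scored by the leaf count left after collapsing it with
    the target (a neighbor isomorphic to the target scores 1); ascending,
    ties broken by canonical Newick text.
    """
    scored = []
    for tree, _move in nb.members.values():
        reduced = collapse_common_subtrees(tree, target)
        scored.append((reduced.tree_a.n_leaves, canonical_newick(tree.root), tree))
    scored.sort(key=lambda item: (item[0], item[1]))
    return [tree for _, _, tree in scored]


def _check_same_leaves(t: RootedTree, target: RootedTree) -> None:
    la, lb = t.leaf_labels(), target.leaf_labels()
    if la != lb:
        raise LeafSetMismatchError(
            f"trees are on different taxon sets "
            f"({sorted(la ^ lb)[:6]}... differ)" if len(la ^ lb) > 6 else
            f"trees are on different taxon sets (symmetric difference {sorted(la ^ lb)})"
        )


def constructive_upper_bound(t: RootedTree, target: RootedTree) -> SearchResult:
    """A valid (not necessarily minimal) edit path from t to target.

    Repeatedly: collapse common subtrees; pick a cherry (x, y) of the
    reduced target; prune leaf x in the reduced source and regraft it on
    y's pendant edge.  The new cherry is common, so the reduced problem
    shrinks by at least one leaf per move — at most n - 1 moves total.
    """
    _check_same_leaves(t, target)
    current = t.copy()
    path = [current]
    target_key = target.canonical_key()
    while current.canonical_key() != target_key:
        rp = collapse_common_subtrees(current, target)
        ra, rb = rp.tree_a, rp.tree_b
        # a cherry of the reduced target: internal vertex with two leaf children
        cherry = next(
            v for v in rb.nodes()
            if not v.is_leaf and all(c.is_leaf for c in v.children)
        )
        x_label, y_label = (c.label for c in cherry.children)
        leaves_a = {v.label: v for v in ra.leaves()}
        moved = apply_move(
            ra, RSPRMove(prune=leaves_a[x_label], regraft=leaves_a[y_label])
        )
        current = expand(rp.records, moved, strict=False)
        path.append(current)
    distance = len(path) - 1
    return SearchResult(
        distance=distance,
        path=path,
        status=EXACT if distance == 0 else HEURISTIC,
        explored=0,
        upper_limits=[distance] if distance else [],
    )


@dataclass
class _Frame:
    tree: RootedTree  # the tree visited at this level, in this level's coordinates
    records: list[CollapseRecord] = field(default_factory=list)


class _A2:
    """One invocation of the depth-first branch-and-bound."""

    def __init__(self, t: RootedTree, target: RootedTree, config: SearchConfig):
        self.config = config
        self.deadline = (
            time.monotonic() + config.time_limit
            if config.mode == "heuristic"
            else None
        )
        n = t.n_leaves
        self.depth_cap = config.depth_cap if config.depth_cap is not None else max(n - 1, 1)
        seed = constructive_upper_bound(t, target)
        self.best = seed.distance
        self.incumbent = seed.path
        self.upper_limits: list[int] = list(seed.upper_limits)
        self.explored = 0
        self.frames: list[_Frame] = []
        self.deadline_hit = False
        self.capped = False
        self.memo: dict[tuple[int, int], int] | None = {} if config.use_memo else None
        self.t0 = t
        self.target0 = target

    # -- path lifting -------------------------------------------------------

    def _lift(self, tree: RootedTree, level: int) -> RootedTree:
        """Expand ``tree`` (coordinates of ``level``) back to input coordinates."""
        for frame in reversed(self.frames[:level]):
            tree = expand(frame.records, tree, strict=False)
        return tree

    def _record_solution(
        self, distance: int, final: RootedTree | None, level: int
    ) -> None:
        path = [self._lift(f.tree, i) for i, f in enumerate(self.frames)]
        if final is not None:
            path.append(self._lift(final, level))
        self.best = distance
        self.incumbent = path
        self.upper_limits.append(distance)

    # -- the recursion ------------------------------------------------------

    def run(self) -> SearchResult:
        if self.t0.canonical_key() == self.target0.canonical_key():
            return SearchResult(distance=0, path=[self.t0.copy()], status=EXACT)
        if self.best > 0:
            try:
                self._dfs(self.t0, self.target0, 0)
            except _Deadline:
                self.deadline_hit = True
        complete = not self.deadline_hit and not self.capped
        return SearchResult(
            distance=self.best,
            path=self.incumbent,
            status=EXACT if complete else HEURISTIC,
            explored=self.explored,
            upper_limits=self.upper_limits,
        )

    def _dfs(self, t: RootedTree, target: RootedTree, depth: int) -> None:
        if self.deadline is not None and time.monotonic() > self.deadline:
            raise _Deadline
        self.explored += 1
        # depth > 0 identity is caught by the parent's neighborhood test;
        # depth == 0 identity is caught in run()
        if depth + 1 >= self.best:
            return
        rp = collapse_common_subtrees(t, target)
        tc, tgc = rp.tree_a, rp.tree_b
        if self.memo is not None:
            state = (tc.canonical_key(), tgc.canonical_key())
            seen = self.memo.get(state)
            if seen is not None and seen <= depth:
                return
            self.memo[state] = depth
        self.frames.append(_Frame(tree=t, records=rp.records))
        try:
            if tc.canonical_key() == tgc.canonical_key():
                # defensive: recursion never descends into the target itself
                self._record_solution(depth, None, depth)
                return
            if one_spr_apart_reduced(tc, tgc):
                # "a solution equal to the current level of recursion" + 1
                self._record_solution(depth + 1, target, depth)
                return
            # d(t, target) >= 2 here, so anything below costs >= depth + 2
            if depth + 2 >= self.best:
                return
            if depth + 1 > self.depth_cap:
                # pruned purely by the cap: the result is no longer certified
                self.capped = True
                return
            nb = neighborhood(tc)
            for n in sort_neighborhood(nb, tgc):
                if depth + 2 >= self.best:
                    break
                self._dfs(n, tgc, depth + 1)
        finally:
            self.frames.pop()


def rspr_distance(
    t: RootedTree,
    t_target: RootedTree,
    config: SearchConfig | None = None,
) -> SearchResult:
    """Rooted SPR distance between two trees on the same taxon set.

    In exhaustive mode the returned distance is the true minimum (status
    ``"exact"``); in heuristic mode the best solution found before the
    deadline is returned.  A valid edit path is always part of the result.
    """
    if config is None:
        config = SearchConfig()
    _check_same_leaves(t, t_target)
    return _A2(t, t_target, config).run()
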