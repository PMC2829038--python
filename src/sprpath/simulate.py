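"""Benchmark-pair generation and an independent brute-force oracle.

Two generators emulate the structure of the standard test settings for SPR
distance software:

* ``style="random"`` — a random tree plus k successive random SPR moves
  (each drawn uniformly from the admissible move list and guaranteed to
  change the topology).  Successive moves may overlap the same taxa, so the
  true distance is <= k, with equality not guaranteed.
* ``style="non_cumulative"`` — k mutually independent SPRs, each confined
  to its own disjoint pendant subtree (3-10 leaves).  Disjoint discordant
  clusters each force at least one move, so the true distance is exactly k.
  This mirrors curated large-tree benchmarks where a supertree with
  thousands of taxa carries many independent rearrangements.

The tree models are ``"yule"`` (leaves attached sequentially to a random
*pendant* edge, the speciation process) and ``"uniform"`` (leaves attached
to a random edge *including* the root-handle edge, which yields the uniform
distribution over labeled rooted binary topologies).

:func:`bfs_oracle` is a provably exact distance oracle for small instances,
independent of the branch-and-bound search: breadth-first expansion of SPR
neighborhoods with canonical-key deduplication (internally from both ends,
which does not change the reported depth).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .errors import SimulationError
from .moves import RSPRMove, apply_move, enumerate_moves
from .tree import Node, RootedTree, copy_subtree

__all__ = [
    "SimSpec",
    "random_tree",
    "random_pair",
    "non_cumulative_pair",
    "generate",
    "bfs_oracle",
]


@dataclass
class SimSpec:
    """Parameters of one simulated benchmark pair."""

    n_taxa: int
    k_moves: int
    seed: int
    model: str = "yule"  # "yule" | "uniform"
    style: str = "random"  # "random" | "non_cumulative"

    def __post_init__(self) -> None:
        if self.n_taxa < 1:
            raise ValueError("n_taxa must be >= 1")
        if self.k_moves < 0:
            raise ValueError("k_moves must be >= 0")
        if self.model not in ("yule", "uniform"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.style not in ("random", "non_cumulative"):
            raise ValueError(f"unknown style {self.style!r}")


def random_tree(n: int, seed: int, model: str = "yule") -> RootedTree:
    """Seeded random rooted binary tree with leaves labeled ``"1".."n"``.

    ``"yule"`` attaches each new leaf to a uniformly chosen pendant edge;
    ``"uniform"`` attaches to a uniformly chosen edge including the pendant
    edge above the root, which makes every labeled rooted binary topology
    equally likely.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = random.Random(seed)
    tree = RootedTree(Node("1"))
    for i in range(2, n + 1):
        if model == "yule":
            attach = rng.choice([v for v in tree.nodes() if v.is_leaf])
        elif model == "uniform":
            attach = rng.choice(list(tree.nodes()))
        else:
            raise ValueError(f"unknown model {model!r}")
        parent = attach.parent
        assert parent is not None
        fork = Node()
        parent.children[parent.children.index(attach)] = fork
        fork.parent = parent
        fork.add_child(attach)
        fork.add_child(Node(str(i)))
    return tree


def _random_topology_changing_move(
    tree: RootedTree, rng: random.Random
) -> tuple[RootedTree, RSPRMove]:
    """Uniform draw over admissible moves, rejecting isomorphic outcomes."""
    moves = enumerate_moves(tree)
    rng.shuffle(moves)
    source_key = tree.canonical_key()
    for move in moves:
        candidate = apply_move(tree, move)
        if candidate.canonical_key() != source_key:
            return candidate, move
    raise SimulationError("tree has no topology-changing SPR (empty neighborhood)")


def random_pair(
    tree: RootedTree, k: int, seed: int
) -> tuple[RootedTree, list[dict]]:
    """Apply k uniformly chosen topology-changing SPRs in succession.

    Returns the final tree and a move log (pruned and regraft-sibling leaf
    sets per move).  The walk witnesses distance <= k; moves may interact,
    so the exact distance can be smaller.
    """
    rng = random.Random(seed)
    current = tree.copy()
    log: list[dict] = []
    for _ in range(k):
        current, move = _random_topology_changing_move(current, rng)
        log.append(move.describe())
    return current, log


def _disjoint_subtrees(
    tree: RootedTree, min_leaves: int = 3, max_leaves: int = 10
) -> list[Node]:
    """Greedy bottom-up sweep for disjoint pendant subtrees of bounded size."""
    selected: list[Node] = []
    info: dict[int, tuple[int, bool]] = {}  # id -> (leaf count, selected below?)
    stack = [(tree.root, False)]
    while stack:
        v, done = stack.pop()
        if v.is_leaf:
            info[id(v)] = (1, False)
        elif done:
            count = sum(info[id(c)][0] for c in v.children)
            below = any(info[id(c)][1] for c in v.children)
            if not below and min_leaves <= count <= max_leaves:
                selected.append(v)
                below = True
            info[id(v)] = (count, below)
        else:
            stack.append((v, True))
            stack.extend((c, False) for c in v.children)
    return selected


def non_cumulative_pair(
    tree: RootedTree, k: int, seed: int
) -> tuple[RootedTree, list[dict]]:
    """Apply k independent SPRs, one inside each of k disjoint subtrees.

    Every move is confined to its own pendant subtree with 3-10 leaves, so
    the k rearranged clusters are pairwise disjoint and the SPR distance
    between input and output is exactly k.
    """
    rng = random.Random(seed)
    derived, mapping = tree.copy_with_map()
    sites = _disjoint_subtrees(tree)
    if len(sites) < k:
        raise SimulationError(
            f"only {len(sites)} disjoint pendant subtrees with 3-10 leaves "
            f"available, {k} requested"
        )
    rng.shuffle(sites)
    log: list[dict] = []
    for site in sites[:k]:
        node = mapping[id(site)]
        sub = RootedTree(copy_subtree(node))
        moved, move = _random_topology_changing_move(sub, rng)
        entry = move.describe()
        entry["cluster_leaves"] = sorted(sub.leaf_labels())
        log.append(entry)
        parent = node.parent
        assert parent is not None
        replacement = moved.root
        parent.children[parent.children.index(node)] = replacement
        replacement.parent = parent
    return derived, log


def generate(spec: SimSpec) -> tuple[RootedTree, RootedTree, list[dict]]:
    """Generate one benchmark pair: (source tree, derived tree, move log)."""
    source = random_tree(spec.n_taxa, spec.seed, spec.model)
    if spec.style == "random":
        derived, log = random_pair(source, spec.k_moves, spec.seed + 1)
    else:
        derived, log = non_cumulative_pair(source, spec.k_moves, spec.seed + 1)
    return source, derived, log


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------


def _expand_layer(layer: dict[int, RootedTree]) -> dict[int, RootedTree]:
    out: dict[int, RootedTree] = {}
    for tree in layer.values():
        source_key = tree.canonical_key()
        for move in enumerate_moves(tree):
            candidate = apply_move(tree, move)
            key = candidate.canonical_key()
            if key != source_key and key not in out:
                out[key] = candidate
    return out


def bfs_oracle(a: RootedTree, b: RootedTree, max_d: int = 4) -> int | None:
    """Exact SPR distance by breadth-first neighborhood expansion.

    Returns the first depth at which ``b`` appears among trees reachable
    from ``a``, or ``None`` if the distance exceeds ``max_d``.  Intended for
    small instances (n <= 9, max_d <= 4).  The frontier is grown from both
    endpoints (meeting in the middle), which is equivalent to one-sided BFS
    because the SPR adjacency relation is symmetric.
    """
    ka, kb = a.canonical_key(), b.canonical_key()
    if ka == kb:
        return 0
    visited_a: dict[int, int] = {ka: 0}
    visited_b: dict[int, int] = {kb: 0}
    frontier_a: dict[int, RootedTree] = {ka: a}
    frontier_b: dict[int, RootedTree] = {kb: b}
    depth_a = depth_b = 0
    while depth_a + depth_b < max_d:
        if len(frontier_a) <= len(frontier_b):
            frontier, visited, other = frontier_a, visited_a, visited_b
            depth_a += 1
            new_depth = depth_a
        else:
            frontier, visited, other = frontier_b, visited_b, visited_a
            depth_b += 1
            new_depth = depth_b
        fresh: dict[int, RootedTree] = {}
        best: int | None = None
        for key, tree in _expand_layer(frontier).items():
            if key in visited:
                continue
            visited[key] = new_depth
            fresh[key] = tree
            if key in other:
                d = new_depth + other[key]
                best = d if best is None else min(best, d)
        if best is not None:
            return best
        if not fresh:
            return None  # whole component exhausted: unreachable within max_d
        if frontier is frontier_a:
            frontier_a = fresh
        else:
            frontier_b = fresh
    return None
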