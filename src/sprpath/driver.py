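"""Outer loop: reduce, decompose into solvable clusters, solve, sum.

:func:`compute` is the top-level entry point for the SPR distance between
two rooted binary trees on the same taxon set.  It repeatedly

1. collapses common pendant subtrees (keeping the records),
2. identifies the solvable common cluster (SCC) with the fewest taxa,
3. solves that cluster with the depth-first search,
4. replaces the solved cluster so both trees agree on it,

until the trees are identical, and returns the sum of the cluster
distances.  Each cluster's edit path is lifted back to full-size trees by
expanding all collapse records, and the segments are concatenated into one
global chain from the first input to the second, one tree per inferred
transfer event.

Cluster decomposition rests on the solvable-common-cluster conjecture
(solving an SCC in isolation preserves the overall distance), so an
exhaustive run with decomposition reports status
``"exact_under_scc_conjecture"``; disable decomposition (``use_scc=False``)
for the unconditional guarantee at the price of searching the whole reduced
pair at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import LeafSetMismatchError
from .moves import apply_move, enumerate_moves
from .reduction import (
    ClusterPair,
    CollapseRecord,
    FreshLabeler,
    collapse_common_subtrees,
    expand,
    find_clusters,
)
from .search import EXACT, HEURISTIC, SearchConfig, SearchResult, rspr_distance
from .tree import Node, RootedTree, copy_subtree

__all__ = ["GlobalResult", "compute", "annotate_step"]

EXACT_UNDER_SCC = "exact_under_scc_conjecture"


@dataclass
class GlobalResult:
    """Total distance, the global edit path, and per-cluster diagnostics.

    ``total_distance == len(global_path) - 1``; consecutive path trees are
    one rooted SPR apart, the first ≅ the first input, the last ≅ the
    second.  ``cluster_log`` holds one dict per solved cluster (leaf count,
    distance, search status, cluster kind).  ``status`` is ``"exact"``
    (no decomposition, completed search), ``"exact_under_scc_conjecture"``
    (decomposition used, completed searches) or ``"heuristic_upper_bound"``.
    """

    total_distance: int
    global_path: list[RootedTree]
    cluster_log: list[dict] = field(default_factory=list)
    status: str = EXACT

    def move_annotations(self) -> list[dict]:
        """Which taxa each step displaces (prune and regraft-sibling leaf sets)."""
        return [
            annotate_step(x, y)
            for x, y in zip(self.global_path, self.global_path[1:])
        ]

    def to_report(self) -> dict:
        """JSON-serializable summary (deterministic for fixed inputs/config)."""
        return {
            "distance": self.total_distance,
            "status": self.status,
            "clusters": self.cluster_log,
            "moves": self.move_annotations(),
        }


def _replace_node(tree: RootedTree, old: Node, new_root: Node) -> None:
    parent = old.parent
    assert parent is not None
    parent.children[parent.children.index(old)] = new_root
    new_root.parent = parent
    old.parent = None


def _resolve_fresh(records: list[CollapseRecord]) -> dict[str, frozenset[str]]:
    """fresh label -> set of original taxa it stands for."""
    resolved: dict[str, frozenset[str]] = {}
    for record in records:  # records are ordered; nesting refers backwards
        labels: set[str] = set()
        stack = [record.subtree]
        while stack:
            v = stack.pop()
            if v.is_leaf:
                if v.label in resolved:
                    labels.update(resolved[v.label])
                else:
                    labels.add(v.label)  # type: ignore[arg-type]
            else:
                stack.extend(v.children)
        resolved[record.fresh_label] = frozenset(labels)
    return resolved


def annotate_step(x: RootedTree, y: RootedTree) -> dict:
    """Describe the single SPR separating two adjacent path trees.

    The pair is collapsed first, the witnessing move is recovered on the
    small reduced pair, and collapsed labels are translated back to the
    original taxa, so the annotation names exactly the taxa the transfer
    displaces and the subtree it lands next to.
    """
    rp = collapse_common_subtrees(x, y)
    resolved = _resolve_fresh(rp.records)

    def taxa(labels) -> list[str]:
        out: set[str] = set()
        for lab in labels:
            out.update(resolved.get(lab, frozenset([lab])))
        return sorted(out)

    target_key = rp.tree_b.canonical_key()
    for move in enumerate_moves(rp.tree_a):
        if apply_move(rp.tree_a, move).canonical_key() == target_key:
            described = move.describe()
            return {
                "pruned_taxa": taxa(described["pruned_leaves"]),
                "regraft_above_taxa": taxa(described["regraft_above_leaves"]),
            }
    raise ValueError("adjacent path trees are not one SPR apart")


def compute(
    T: RootedTree,
    T_target: RootedTree,
    config: SearchConfig | None = None,
    use_scc: bool = True,
) -> GlobalResult:
    """Rooted SPR distance with kernelization and cluster decomposition.

    With ``use_scc`` the reduced pair is solved one smallest solvable
    cluster at a time; without it the whole reduced pair goes to the search
    in one piece.  The result carries the full-size intermediate trees.
    """
    labels = T.leaf_labels()
    if labels != T_target.leaf_labels():
        raise LeafSetMismatchError("trees are on different taxon sets")
    if config is None:
        config = SearchConfig()

    labeler = FreshLabeler(labels)
    work_a, work_b = T.copy(), T_target.copy()
    records: list[CollapseRecord] = []
    path: list[RootedTree] = [T.copy()]
    cluster_log: list[dict] = []
    total = 0
    any_heuristic = False
    used_decomposition = False

    while True:
        rp = collapse_common_subtrees(work_a, work_b, labeler)
        records.extend(rp.records)
        work_a, work_b = rp.tree_a, rp.tree_b
        if work_a.canonical_key() == work_b.canonical_key():
            break
        if use_scc:
            cluster = find_clusters(rp, require_scc=True)[0]
            if cluster.node_a is not work_a.root:
                used_decomposition = True
        else:
            cluster = ClusterPair(
                sub_a=work_a.copy(),
                sub_b=work_b.copy(),
                kind="SCC",
                n_leaves=work_a.n_leaves,
                node_a=work_a.root,
                node_b=work_b.root,
            )
        result: SearchResult = rspr_distance(cluster.sub_a, cluster.sub_b, config)
        total += result.distance
        any_heuristic = any_heuristic or result.status != EXACT
        cluster_log.append(
            {
                "n_leaves": cluster.n_leaves,
                "distance": result.distance,
                "status": result.status,
                "kind": cluster.kind,
            }
        )
        # lift the cluster path to full-size intermediate trees
        for step in result.path[1:]:
            lifted, mapping = work_a.copy_with_map()
            _replace_node(
                lifted, mapping[id(cluster.node_a)], copy_subtree(step.root)
            )
            path.append(expand(records, lifted))
        # both trees now agree on the cluster; make that so in work_a
        _replace_node(work_a, cluster.node_a, copy_subtree(cluster.node_b))

    if any_heuristic:
        status = HEURISTIC
    elif total == 0:
        status = EXACT
    elif use_scc and used_decomposition:
        status = EXACT_UNDER_SCC
    else:
        status = EXACT
    assert total == len(path) - 1
    return GlobalResult(
        total_distance=total,
        global_path=path,
        cluster_log=cluster_log,
        status=status,
    )
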