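"""Common-subtree collapse, cluster identification, and expansion."""

import random

import pytest

from sprpath.errors import ExpansionError, LeafSetMismatchError, ReductionError
from sprpath.reduction import (
    ClusterPair,
    collapse_common_subtrees,
    expand,
    find_clusters,
)
from sprpath.simulate import bfs_oracle, random_pair, random_tree
from sprpath.tree import are_isomorphic, canonical_key, parse_newick, write_newick


class TestCollapse:
    def test_identical_trees_collapse_to_one_fresh_leaf(self):
        a = parse_newick("((1,2),3);")
        rp = collapse_common_subtrees(a, parse_newick("((1,2),3);"))
        assert rp.tree_a.n_leaves == 1
        assert rp.tree_b.n_leaves == 1
        assert len(rp.records) == 1
        assert are_isomorphic(rp.tree_a, rp.tree_b)

    def test_common_cherry_collapses_and_fixed_point_reached(self):
        a = parse_newick("((((1,2),3),4),5);")
        b = parse_newick("((((2,1),4),3),5);")
        rp = collapse_common_subtrees(a, b)
        fresh = rp.records[0].fresh_label
        assert len(rp.records) == 1
        assert are_isomorphic(rp.tree_a, parse_newick(f"((({fresh},3),4),5);"))
        assert are_isomorphic(rp.tree_b, parse_newick(f"((({fresh},4),3),5);"))
        # fixed point: collapsing again finds nothing new below the whole-tree level
        again = collapse_common_subtrees(rp.tree_a, rp.tree_b)
        assert not again.records

    def test_leaf_set_mismatch_rejected(self):
        with pytest.raises(LeafSetMismatchError):
            collapse_common_subtrees(
                parse_newick("((1,2),3);"), parse_newick("((1,2),4);")
            )

    def test_round_trip_restores_originals_exactly(self):
        for seed in range(20):
            a = random_tree(12, seed=seed)
            b, _ = random_pair(a, 2, seed=seed + 50)
            rp = collapse_common_subtrees(a, b)
            assert write_newick(expand(rp.records, rp.tree_a)) == write_newick(a)
            assert write_newick(expand(rp.records, rp.tree_b)) == write_newick(b)

    def test_collapse_preserves_oracle_distance(self):
        kept = 0
        for seed in range(100):
            a = random_tree(5 + seed % 3, seed=seed)
            b, _ = random_pair(a, 1 + seed % 2, seed=seed + 1000)
            before = bfs_oracle(a, b, max_d=3)
            rp = collapse_common_subtrees(a, b)
            after = bfs_oracle(rp.tree_a, rp.tree_b, max_d=3)
            assert before == after, f"distance changed by collapse (seed {seed})"
            kept += 1
        assert kept == 100

    def test_outcome_independent_of_sibling_order(self):
        # collapsing scrambled copies yields structurally identical reductions
        # (fresh label names may differ; compare after renaming each fresh
        # leaf by the smallest original taxon it stands for)
        def canonical_reduced(rp):
            names = {}
            for rec in rp.records:
                taxa = set()
                stack = [rec.subtree]
                while stack:
                    v = stack.pop()
                    if v.is_leaf:
                        taxa.update(names.get(v.label, {v.label}))
                    else:
                        stack.extend(v.children)
                names[rec.fresh_label] = taxa
            out = rp.tree_a.copy()
            for leaf in out.leaves():
                if leaf.label in names:
                    leaf.label = "collapsed_" + min(names[leaf.label])
            return canonical_key(out)

        rng = random.Random(7)
        for seed in range(15):
            a = random_tree(14, seed=seed)
            b, _ = random_pair(a, 2, seed=seed + 70)
            scrambled_a, scrambled_b = a.copy(), b.copy()
            for t in (scrambled_a, scrambled_b):
                for node in t.nodes():
                    if node.children:
                        rng.shuffle(node.children)
            assert canonical_reduced(
                collapse_common_subtrees(a, b)
            ) == canonical_reduced(collapse_common_subtrees(scrambled_a, scrambled_b))


class TestFindClusters:
    def test_single_scc_with_matching_parents(self):
        rp = collapse_common_subtrees(
            parse_newick("((((1,2),3),4),5);"), parse_newick("((((2,1),4),3),5);")
        )
        clusters = find_clusters(rp)
        assert len(clusters) == 1
        (c,) = clusters
        assert c.kind == "SCC"
        assert c.n_leaves == 3
        assert c.sub_a.leaf_labels() == c.sub_b.leaf_labels()
        assert not are_isomorphic(c.sub_a, c.sub_b)

    def test_two_disjoint_discordant_regions(self):
        rp = collapse_common_subtrees(
            parse_newick("(((1,2),3),((4,5),6));"),
            parse_newick("(((1,3),2),((4,6),5));"),
        )
        clusters = find_clusters(rp)
        assert len(clusters) == 2
        leafsets = [c.sub_a.leaf_labels() for c in clusters]
        assert leafsets[0].isdisjoint(leafsets[1])

    def test_entangled_pair_falls_back_to_whole_trees(self):
        a = parse_newick("((1,2),(3,4));")
        b = parse_newick("((1,3),(2,4));")
        rp = collapse_common_subtrees(a, b)
        clusters = find_clusters(rp)
        assert len(clusters) == 1
        assert clusters[0].n_leaves == 4
        assert are_isomorphic(clusters[0].sub_a, a)

    def test_identical_trees_rejected(self):
        rp = collapse_common_subtrees(
            parse_newick("((1,2),3);"), parse_newick("((1,2),3);")
        )
        with pytest.raises(ReductionError):
            find_clusters(rp)

    def test_minimality_no_cluster_contains_another(self):
        for seed in range(25):
            a = random_tree(12, seed=seed + 300)
            b, _ = random_pair(a, 2, seed=seed + 400)
            rp = collapse_common_subtrees(a, b)
            if are_isomorphic(rp.tree_a, rp.tree_b):
                continue
            for require_scc in (True, False):
                clusters = find_clusters(rp, require_scc=require_scc)
                sets = [c.sub_a.leaf_labels() for c in clusters]
                for i, s in enumerate(sets):
                    for j, t in enumerate(sets):
                        assert i == j or not s < t

    def test_scc_decomposition_preserves_oracle_distance(self):
        # empirical check of the solvable-cluster conjecture at small n:
        # run the outer loop (collapse, solve smallest SCC, replace, repeat)
        # but score every cluster with the brute-force oracle, and compare
        # the summed cluster distances with the whole-pair oracle distance
        from sprpath.tree import copy_subtree

        def oracle_guided_decomposition(a, b):
            work_a, work_b = a.copy(), b.copy()
            total = 0
            while True:
                rp = collapse_common_subtrees(work_a, work_b)
                work_a, work_b = rp.tree_a, rp.tree_b
                if are_isomorphic(work_a, work_b):
                    return total
                cluster = find_clusters(rp, require_scc=True)[0]
                d = bfs_oracle(cluster.sub_a, cluster.sub_b, max_d=4)
                assert d is not None
                total += d
                # make both trees agree on the solved cluster
                parent = cluster.node_a.parent
                replacement = copy_subtree(cluster.node_b)
                parent.children[parent.children.index(cluster.node_a)] = replacement
                replacement.parent = parent

        counterexamples = []
        checked = 0
        for seed in range(60):
            a = random_tree(6 + seed % 3, seed=seed + 800)
            b, _ = random_pair(a, 1 + seed % 2, seed=seed + 900)
            whole = bfs_oracle(a, b, max_d=4)
            if whole is None:
                continue
            total = oracle_guided_decomposition(a, b)
            if total != whole:
                counterexamples.append((seed, total, whole))
            checked += 1
        assert checked >= 40
        assert not counterexamples, (
            "solvable-cluster decomposition changed the distance: "
            f"{counterexamples}"
        )


class TestExpand:
    def test_expand_without_fresh_labels_is_identity(self):
        t = parse_newick("((1,2),3);")
        assert write_newick(expand([], t)) == write_newick(t)

    def test_unknown_fresh_label_raises(self):
        rp = None
        for seed in range(20):
            a = random_tree(14, seed=seed)
            b, _ = random_pair(a, 1, seed=seed + 2)
            candidate = collapse_common_subtrees(a, b)
            if len(candidate.records) >= 2:
                rp = candidate
                break
        assert rp is not None, "no seed produced two collapse records"
        missing = rp.records[:-1]
        with pytest.raises(ExpansionError):
            expand(missing, rp.tree_a, fresh_prefix=rp.records[0].fresh_label.rstrip("0123456789"))
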