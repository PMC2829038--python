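"""Branch-and-bound search: exactness, paths, bounds, deadlines."""

import pytest

from sprpath.errors import LeafSetMismatchError
from sprpath.moves import neighborhood
from sprpath.search import (
    SearchConfig,
    constructive_upper_bound,
    rspr_distance,
    sort_neighborhood,
)
from sprpath.simulate import bfs_oracle, random_pair, random_tree
from sprpath.tree import are_isomorphic, parse_newick



class TestExamples:
    def test_identical_trees(self):
        t = parse_newick("((1,2),3);")
        res = rspr_distance(t, t.copy())
        assert res.distance == 0
        assert res.status == "exact"
        assert len(res.path) == 1

    def test_distance_one(self, check_path):
        a, b = parse_newick("((1,2),3);"), parse_newick("((1,3),2);")
        res = rspr_distance(a, b)
        assert res.distance == 1
        assert res.status == "exact"
        check_path(res.path, a, b, res.distance)

    def test_two_disjoint_discordant_clusters(self, check_path):
        a = parse_newick("(((1,2),3),((4,5),6));")
        b = parse_newick("(((1,3),2),((4,6),5));")
        res = rspr_distance(a, b)
        assert res.distance == 2
        check_path(res.path, a, b, res.distance)

    def test_leaf_set_mismatch(self):
        with pytest.raises(LeafSetMismatchError):
            rspr_distance(parse_newick("((1,2),3);"), parse_newick("((1,2),4);"))


class TestSortNeighborhood:
    def test_target_itself_sorts_first(self):
        source = parse_newick("(((1,2),3),4);")
        target = parse_newick("(((1,3),2),4);")
        nb = neighborhood(source)
        assert target.canonical_key() in nb.members
        ordered = sort_neighborhood(nb, target)
        assert are_isomorphic(ordered[0], target)

    def test_scores_ascend(self):
        source = random_tree(8, seed=3)
        target, _ = random_pair(source, 2, seed=4)
        from sprpath.reduction import collapse_common_subtrees

        ordered = sort_neighborhood(neighborhood(source), target)
        scores = [
            collapse_common_subtrees(n, target).tree_a.n_leaves for n in ordered
        ]
        assert scores == sorted(scores)

    def test_order_deterministic_regardless_of_generation_order(self):
        source = random_tree(7, seed=5)
        target, _ = random_pair(source, 2, seed=6)
        nb1 = neighborhood(source)
        nb2 = neighborhood(source)
        # reverse the insertion order of the second neighborhood
        nb2.members = dict(reversed(list(nb2.members.items())))
        first = [t.to_newick() for t in sort_neighborhood(nb1, target)]
        second = [t.to_newick() for t in sort_neighborhood(nb2, target)]
        assert first == second


class TestExactness:
    def test_matches_bfs_oracle_on_random_pairs(self, check_path):
        for seed in range(60):
            n = 5 + seed % 4
            k = 1 + seed % 3
            a = random_tree(n, seed=seed + 40)
            b, _ = random_pair(a, k, seed=seed + 4000)
            res = rspr_distance(a, b)
            assert res.status == "exact"
            assert res.distance == bfs_oracle(a, b, max_d=4), f"seed {seed}"
            assert res.distance <= k
            check_path(res.path, a, b, res.distance)

    def test_metric_properties(self):
        def d(a, b):
            return rspr_distance(a, b).distance

        for seed in range(15):
            a = random_tree(6, seed=seed)
            b, _ = random_pair(a, 1 + seed % 2, seed=seed + 100)
            c, _ = random_pair(b, 1, seed=seed + 200)
            assert (d(a, b) == 0) == are_isomorphic(a, b)
            assert d(a, b) == d(b, a)
            assert d(a, c) <= d(a, b) + d(b, c)

    def test_upper_limits_strictly_decrease(self):
        for seed in range(10):
            a = random_tree(8, seed=seed + 60)
            b, _ = random_pair(a, 3, seed=seed + 600)
            res = rspr_distance(a, b)
            limits = res.upper_limits
            assert all(x > y for x, y in zip(limits, limits[1:]))
            if limits:
                assert limits[-1] == res.distance

    def test_memoization_does_not_change_the_answer(self):
        for seed in range(10):
            a = random_tree(7, seed=seed + 70)
            b, _ = random_pair(a, 2, seed=seed + 700)
            plain = rspr_distance(a, b)
            memo = rspr_distance(a, b, SearchConfig(use_memo=True))
            assert plain.distance == memo.distance


class TestConstructiveUpperBound:
    def test_identical_trees_need_no_moves(self):
        t = random_tree(9, seed=8)
        res = constructive_upper_bound(t, t.copy())
        assert res.distance == 0
        assert len(res.path) == 1

    def test_bounded_by_n_minus_one_and_valid(self, check_path):
        for seed in range(15):
            n = 5 + seed % 5
            a = random_tree(n, seed=seed + 20)
            b, _ = random_pair(a, 1 + seed % 4, seed=seed + 2000)
            res = constructive_upper_bound(a, b)
            assert res.distance <= n - 1
            check_path(res.path, a, b, res.distance)

    def test_never_below_true_distance(self):
        for seed in range(20):
            a = random_tree(6, seed=seed + 30)
            b, _ = random_pair(a, 1 + seed % 3, seed=seed + 3000)
            assert constructive_upper_bound(a, b).distance >= bfs_oracle(
                a, b, max_d=4
            )


class TestHeuristicMode:
    def test_equals_exhaustive_when_deadline_generous(self):
        for seed in range(20):
            a = random_tree(7, seed=seed + 90)
            b, _ = random_pair(a, 2, seed=seed + 9000)
            exact = rspr_distance(a, b)
            quick = rspr_distance(
                a, b, SearchConfig(mode="heuristic", time_limit=30.0)
            )
            assert quick.distance == exact.distance
            assert quick.status == "exact"  # completed before the deadline

    def test_tiny_deadline_still_returns_a_valid_solution(self, check_path):
        a = random_tree(40, seed=91)
        b, _ = random_pair(a, 6, seed=92)
        res = rspr_distance(a, b, SearchConfig(mode="heuristic", time_limit=0.1))
        assert res.distance >= 1
        check_path(res.path, a, b, res.distance)

    def test_heuristic_never_below_exhaustive(self):
        for seed in range(10):
            a = random_tree(6, seed=seed + 95)
            b, _ = random_pair(a, 2, seed=seed + 9500)
            exact = rspr_distance(a, b).distance
            quick = rspr_distance(
                a, b, SearchConfig(mode="heuristic", time_limit=0.05)
            ).distance
            assert quick >= exact

    def test_depth_cap_degrades_to_upper_bound(self, check_path):
        a = random_tree(10, seed=96)
        b, _ = random_pair(a, 4, seed=97)
        true_d = rspr_distance(a, b).distance
        capped = rspr_distance(a, b, SearchConfig(depth_cap=1))
        assert capped.distance >= true_d
        check_path(capped.path, a, b, capped.distance)
        if capped.distance > true_d:
            assert capped.status == "heuristic_upper_bound"

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SearchConfig(mode="fastest")
        with pytest.raises(ValueError):
            SearchConfig(mode="heuristic", time_limit=0.0)
        with pytest.raises(ValueError):
            SearchConfig(depth_cap=0)
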