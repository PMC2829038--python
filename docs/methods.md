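# Methods

## Model and problem

A rooted binary phylogenetic tree on taxon set *X* carries one label per
leaf.  Internally every tree holds an auxiliary *root handle* vertex *p*
above the original root, joined by a pendant edge; it exists so that a
subtree can be regrafted above the root (creating a new root) as an
ordinary move, and it is never serialized.

One **rooted SPR** move: choose an edge e = {u, v} not incident with *p*
(v the far endpoint), delete it, subdivide an edge of the component
containing *u* with a new vertex, attach *v* there, and suppress the
degree-two vertex *u*.  Regrafting onto either edge incident to *u* merely
recreates the tree and is excluded from the move set.  The **distance**
d(T, T′) is the minimum number of such moves transforming T into T′; it
lower-bounds the number of reticulation events (each transfer is one
move).  The package assumes both trees are strictly binary and on
identical taxon sets — polytomies are rejected rather than resolved,
because any resolution choice would change the distance.

## Pipeline

1. **Subtree collapse (kernelization).**  Maximal pendant subtrees
   identical in both trees are replaced, in both, by a single fresh-labeled
   leaf, repeatedly until no common pendant subtree with ≥ 2 leaves
   remains.  This preserves the distance and is recorded so that reduced
   trees — and every intermediate tree of a solution — can be expanded back
   to full size exactly.  Fresh labels come from a reserved prefix
   (`__c<counter>`), extended with underscores until it collides with no
   input label.

2. **Cluster decomposition.**  A *common cluster* is a pendant subtree of
   each tree on the same taxa with different topology; it is *solvable*
   (SCC) when the parent vertex's subtree also spans identical taxa in both
   trees ("the parent of the cluster has the same set of taxa" is read as:
   the leaf set of the parent's subtree is identical in both trees — the
   only reading that fixes the cluster boundary in both).  The driver
   filters candidate clusters to SCCs first and then keeps the minimal
   ones (no returned cluster's taxa strictly contain another's) — i.e. the
   smallest solvable clusters; when no proper cluster qualifies the whole
   reduced pair is the single subproblem.  The smallest cluster is solved,
   both trees are made to agree on it, and the loop re-collapses and
   repeats; the distance is the summed cluster solutions.  Solvable-cluster
   decomposition preserving the distance is a *conjecture*, so results
   obtained through it carry status `exact_under_scc_conjecture`;
   `use_scc=False` solves the whole reduced pair in one search and yields
   `exact`.  (When decomposition was available but never actually split
   anything, the status stays `exact`.)  The conjecture is probed
   empirically in the test suite by comparing decomposed against
   whole-pair distances, both against a brute-force oracle; a
   counterexample fails the suite loudly.

3. **Search (branch and bound).**  Recursive depth-first search.  At each
   node the pair is re-collapsed; if source ≅ target the recursion depth is
   a solution; if they are one move apart the depth plus one is; otherwise
   the SPR neighborhood of the reduced source is generated, ordered by the
   leaf count remaining after collapsing each neighbor against the target
   (ties by canonical Newick text), and explored in that order.  Branches
   that cannot beat the incumbent are pruned (a branch at depth d with
   d + 1 ≥ best cannot improve; d + 2 ≥ best suffices once the pair is
   known to be ≥ 2 apart).  The greedy-first ordering finds good solutions
   early, so the incumbent drops fast and the remaining sweep certifies
   optimality.  A completed sweep is exact in either mode; in heuristic
   mode an expired deadline returns the incumbent as an upper bound.

   The frontier test "is the target exactly one move away?" is implemented
   directly rather than by neighborhood enumeration: at the collapse fixed
   point the moved subtree is always a single (possibly fresh) leaf, so the
   pair is one move apart iff deleting some one leaf from both trees leaves
   isomorphic remainders — an O(m²) scan instead of O(|N|·m).  Soundness
   and completeness of this test are covered by dedicated tests against
   both neighborhood membership and the BFS oracle.

   The **constructive fallback** seeds the incumbent before any search:
   repeatedly collapse, pick a cherry (x, y) of the reduced target, and
   move leaf x next to leaf y.  Each move creates a new common cherry, so
   the reduced problem shrinks every step; at most n − 1 moves, always a
   valid edit path.  This is what guarantees an answer under arbitrarily
   tight deadlines or depth caps.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `SearchConfig.mode` | `exhaustive` | run to completion (exact) vs. stop at the deadline |
| `SearchConfig.time_limit` | 30 s | deadline in heuristic mode, checked at every node expansion; overshoot is bounded by one node expansion |
| `SearchConfig.depth_cap` | n − 1 | maximum recursion depth per subproblem; n − 1 is always reachable by the fallback, so the default never truncates an optimal search |
| `SearchConfig.use_memo` | off | visited-pair table keyed by canonical keys; trades the depth-first search's low memory footprint for fewer re-expansions on hard instances |
| `compute(use_scc=...)` | on | cluster decomposition (conjecture-conditional) vs. whole-pair search |

Distances and leaf counts are dimensionless; the only unit-bearing
parameter is the deadline (seconds of wall clock).

## Canonical forms and determinism

Isomorphism of rooted leaf-labeled trees (sibling order irrelevant) is
decided by canonical keys: every distinct subtree shape is interned once to
a small integer, built bottom-up from the two child keys in sorted order,
making comparisons O(1) and neighborhood deduplication cheap even at
thousands of leaves.  Serialization orders children by canonical Newick
text, so isomorphic trees print identically.  Leaf-set comparisons during
cluster search use 64-bit additive label-hash fingerprints, verified
exactly for any cluster actually returned.  All orderings (move
enumeration, neighbor sorting, cluster selection: fewest taxa first, ties
by canonical text) are deterministic, so identical inputs and
configuration reproduce identical outputs byte for byte; exhaustive mode
contains no randomness at all.

Degenerate inputs: one- and two-leaf trees have empty neighborhoods and
distance 0 (two-leaf rooted trees on the same taxa are unique); identical
inputs return distance 0 with a single-tree path; taxon-set mismatches and
non-binary vertices raise typed errors rather than being repaired.

## The simulator

`random_tree` grows trees by sequential leaf attachment: to a uniformly
chosen *pendant* edge (`yule`, the speciation null model) or to a uniformly
chosen edge including the root-handle edge (`uniform`, which yields the
uniform distribution over labeled rooted binary topologies — verified by a
chi-square test on the three 3-leaf topologies).

`random_pair` applies k successive moves drawn uniformly from the
admissible move list, re-enumerated after each move, rejecting any draw
that does not change the topology.  The walk witnesses distance ≤ k;
successive moves may overlap and partially cancel, so equality is not
guaranteed.  `non_cumulative_pair` instead plants k moves in k pairwise
disjoint pendant subtrees of 3–10 leaves (greedy bottom-up sweep for
disjoint sites, seeded shuffle among them), each move confined strictly
inside its subtree; disjoint discordant clusters each force at least one
move, so the distance is exactly k by construction.  The 3–10-leaf window
keeps each planted event local — mirroring curated many-taxon benchmarks
built from independent rearrangements — while leaving thousands of
candidate sites in large trees.

What the generator does *not* emulate: real gene trees disagree through
estimation error and incomplete lineage sorting as well as transfer, carry
polytomies and missing taxa, and real transfer events are not uniform over
edges.  Passing the simulated benchmarks therefore certifies the
*combinatorics* — that the solver returns minimum distances and valid edit
paths under known ground truth — not that every biological incongruence is
a transfer.

## Problem sizes used in tests and the acceptance script

Exhaustive-versus-oracle agreement uses 200 pairs at n = 5..8 with 1–3
random moves (the oracle expands neighborhoods from both endpoints, which
is exact and keeps 200 pairs to seconds).  Known-k recovery uses the full
n = 100 grid, k = 1..5 × 20 seeds, of independent-SPR pairs, plus the
5000-taxon / 50-event decomposition case.  Cumulative random walks at
n = 100 are checked for d ≤ k at k ∈ {1, 2}: uniform random SPRs usually
entangle into a single irreducible cluster of 25–45 reduced leaves, and
exhaustively certifying d ≥ 4 on such a cluster requires sweeping a
neighborhood of ~2m² trees two levels deep — beyond what this search (or
any depth-bounded SPR search without agreement-forest lower bounds) can
finish at that size; heuristic mode remains available there and, in the
suite's experience, matches the exhaustive answer whenever the latter is
obtainable.

## Known limitations

* Exact search scales with the entangled core, not the tree: huge trees
  with many *independent* events are easy; even mid-sized trees with ≥ 4
  mutually entangled events are not.  Agreement-forest or ILP lower bounds
  would push this boundary but are out of scope.
* Decomposed results are conditional on the solvable-cluster conjecture
  (flagged in the status); no counterexample has surfaced in the suite's
  randomized probes, but the conjecture is not proven.
* Multifurcating or unrooted inputs, branch-length arithmetic, alternative
  minimal solutions, and hybridization numbers are out of scope.
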