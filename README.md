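# sprpath

**Rooted SPR distance between binary phylogenetic trees, with the
intermediate trees connecting them.**

When a gene tree disagrees with the species tree (or with another gene
tree), each horizontal gene transfer or hybridization event can be modeled
as one *rooted subtree-prune-and-regraft* (rSPR) operation: detach a
pendant subtree and reattach it elsewhere.  The minimum number of rSPRs
transforming one rooted binary tree *T* into another *T′* on the same taxa,
d<sub>RSPR</sub>(T, T′), is a lower bound on the number of reticulation
events needed to reconcile them.  Computing it is NP-hard but
fixed-parameter tractable in the distance itself — and reticulation is rare
enough in practice that exact answers are often within reach.

sprpath is for molecular evolutionists who want to *count and localize*
transfer events between two rooted trees: it reports the exact distance (or
a guaranteed upper bound under a deadline), the chain of intermediate trees
— one per event — and the taxa each event displaces.

## Algorithm

Three pieces, composed:

1. **Kernelization.** Any pendant subtree identical in both trees is
   collapsed to a single fresh leaf, repeatedly, which preserves
   d<sub>RSPR</sub> and shrinks the problem to its discordant core.
2. **Cluster decomposition.** After collapsing, pendant subtrees of the two
   trees spanning the same taxa with different topology are *common
   clusters*; a cluster whose parent also spans identical taxa in both
   trees is a *solvable common cluster* (SCC).  The smallest SCC is solved
   in isolation, collapsed, and the loop repeats; the distance is the sum
   of cluster solutions.  (That SCC-wise solving preserves the distance is
   a conjecture; `use_scc=False` disables decomposition for an
   unconditional guarantee.)
3. **Greedy-first exhaustive search.** Each cluster is solved by
   depth-first branch and bound over the rSPR neighborhood *N* of the
   current tree, neighbors ordered by how far they collapse against the
   target (fewest remaining leaves first).  The first greedy descent yields
   an upper limit quickly; the bounded search then verifies or improves it,
   so a completed run is exact.  A constructive fallback (move one
   disagreeing leaf at a time, at most n−1 moves) seeds the incumbent, so
   a valid solution exists at every instant — a deadline only degrades the
   answer to an upper bound.

A brute-force breadth-first oracle (provably exact for small trees) ships
with the package and is used throughout the test suite to certify the
solver.

## Worked example

```python
from sprpath import compute, parse_newick

a = parse_newick("(((1,2),3),((4,5),6));")
b = parse_newick("(((1,3),2),((4,6),5));")
result = compute(a, b)
```

Running `python examples/01_distance_and_path.py` prints:

```
d_RSPR = 2  [exact_under_scc_conjecture]
edit path:
  (((1,2),3),((4,5),6));
  (((1,3),2),((4,5),6));
  (((1,3),2),((4,6),5));
events:
  1: transfer {1} next to {3}
  2: transfer {4} next to {6}
```

Two transfers fully explain the incongruence: the trees disagree in two
disjoint clusters, each fixed by one rSPR, and the path shows the
intermediate topology between the events.  The status records that cluster
decomposition (hence the SCC conjecture) was used; rerunning with
`compute(a, b, use_scc=False)` gives the same distance with status
`exact`.

The other scripts in `examples/` demonstrate recovering a planted number
of transfers in a 200-taxon tree, heuristic mode under a hard deadline,
and cross-checking against the brute-force oracle.

## Command line

```sh
sprpath distance TREE1.nwk TREE2.nwk [--mode exhaustive|heuristic]
        [--time-limit 30] [--scc/--no-scc] [--path OUT.nwk] [--json OUT.json]
sprpath simulate --n 100 --k 5 --seed 1 --style non-cumulative -o PREFIX
sprpath oracle TREE1.nwk TREE2.nwk --max-d 4
```

`distance` exits 0 on success (including heuristic answers at the
deadline), 2 on unparseable input, 3 on a taxon-set mismatch.

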