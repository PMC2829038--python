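"""Cross-checking the solver against brute-force breadth-first search.

For small trees the SPR distance can be computed by exhaustively expanding
neighborhoods — slow but provably exact.  This script verifies the
branch-and-bound solver against that oracle on a batch of random pairs.
"""

from sprpath import bfs_oracle, compute, random_pair, random_tree

agree = total = 0
for i in range(30):
    n = 5 + i % 4
    k = 1 + i % 3
    source = random_tree(n, seed=100 + i)
    derived, _ = random_pair(source, k, seed=200 + i)
    solver = compute(source, derived).total_distance
    oracle = bfs_oracle(source, derived, max_d=4)
    agree += solver == oracle
    total += 1
    print(f"n={n} k={k}: solver={solver} oracle={oracle}")

print(f"\nagreement: {agree}/{total}")
# Every line must agree; the oracle is independent of the solver's
# kernelization, decomposition and bounding machinery.
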