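"""Exact SPR distance between two small gene trees, with the edit path.

The two trees disagree in two independent places.  Each unit of distance is
one inferred transfer event; the intermediate trees show the order in which
the events reconcile the topologies, and the annotations name the taxa each
event displaces.
"""

from sprpath import compute, parse_newick

a = parse_newick("(((1,2),3),((4,5),6));")
b = parse_newick("(((1,3),2),((4,6),5));")

result = compute(a, b)

print(f"d_RSPR = {result.total_distance}  [{result.status}]")
print("edit path:")
for tree in result.global_path:
    print(" ", tree.to_newick())
print("events:")
for i, move in enumerate(result.move_annotations(), 1):
    pruned = ",".join(move["pruned_taxa"])
    beside = ",".join(move["regraft_above_taxa"])
    print(f"  {i}: transfer {{{pruned}}} next to {{{beside}}}")

# d_RSPR = 2 means two transfers fully explain the incongruence; each path
# step is one rooted SPR, so the chain is a minimal reconciliation scenario.
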