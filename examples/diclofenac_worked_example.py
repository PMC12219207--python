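"""Worked example: all 11 degree-based indices of Diclofenac.

Loads the packaged heavy-atom graph (19 atoms, 20 bonds), partitions its edges
by endpoint degrees, and evaluates each index as a weighted sum of per-edge
terms.  The printed values are the molecule's structural descriptors; e.g. the
first Zagreb index M1 sums d_u + d_v over all bonds.
"""
from tiqspr import fixtures
from tiqspr.indices import compute_all
from tiqspr.molgraph import edge_partition

graph = fixtures.diclofenac_graph()
partition = edge_partition(graph)
print(f"Diclofenac: {graph.n_vertices} heavy atoms, {graph.n_edges} bonds")
print("edge partition (degree pair -> bond count):")
for (a, b), n in partition.items():
    print(f"  ({a},{b}): {n}")
print("\ntopological indices:")
print(compute_all(partition).round(3).to_string())
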