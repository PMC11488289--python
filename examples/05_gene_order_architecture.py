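"""Conserved blocks and tRNA clusters across gene orders.

Compares the solenogaster ancestral arrangement with the published
arrangement of the most rearranged solenogaster genome: the conserved
blocks shared by both, the genes that rearrange, and the tRNA cluster
lengths (including the 14-tRNA cluster built by reversing six block-3
tRNAs onto the minus strand).
"""

from mitorder import (
    adjacency_breakpoints,
    find_conserved_blocks,
    largest_trna_cluster,
    reference_orders,
    three_block_partition,
)

refs = reference_orders()
sol = refs["solenogastres_ancestor"]
wir = refs["wirenia_argentea"]

part = three_block_partition(sol)
print("three-block architecture of the solenogaster ancestor:")
for strand, block in zip(part.strands, part.blocks):
    print(f"  ({strand}) {', '.join(block)}")

shared, bp = adjacency_breakpoints(sol, wir)
print(f"\nancestor vs derived order: {bp} breakpoints, "
      f"{len(shared)} shared adjacencies")

blocks, variable = find_conserved_blocks([sol, wir])
print(f"conserved blocks ({len(blocks)}):")
for b in blocks:
    print(f"  {','.join(b)}")
print(f"variable genes: {', '.join(variable)}")

print(f"\nlargest tRNA cluster: ancestor {largest_trna_cluster(sol)}, "
      f"derived {largest_trna_cluster(wir)}")
# the derived genome reverses I,K,R,N,A,S1 onto the minus strand, extending
# the MCYWQGL1E block into a 14-tRNA cluster
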