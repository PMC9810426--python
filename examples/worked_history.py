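"""Trace a transmission history by hand: the five-population worked example.

A 6x5 history matrix records, for each of the past six generations, the
population every population copied its cultural state from.  Tracing four
present-day state copies backward merges their lineages into a genealogy.
"""

import numpy as np

from netcoal import (
    TransmissionSpec,
    WORKED_EXAMPLE_G,
    log_history_prior,
    trace_lineages,
    transition_counts,
    transmission_matrix,
)

print("history matrix (1-based, row i = i-1 generations ago):")
print(WORKED_EXAMPLE_G + 1)

tree = trace_lineages(WORKED_EXAMPLE_G, [0, 1, 3, 4])
print(f"\nTMRCA of P1,P2,P4,P5: {tree.tmrca} generations")
print(f"MRCA population: P{tree.root.population + 1}")
print("genealogy:", tree.newick(comments=False))
# the four observed copies share one ancestor five generations back, in P3;
# branch lengths are in generations

c = transition_counts(WORKED_EXAMPLE_G)
A = transmission_matrix(TransmissionSpec.island(5, 0.5))
print(f"\nself-copy count sum(c_ii) = {np.trace(c)} of {c.sum()} events")
print(f"log P(G | island c=0.5) = {log_history_prior(c, A):.4f}")
# the history prior simply weights each of the 30 copying events by its
# transmission rate
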