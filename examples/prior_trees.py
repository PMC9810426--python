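"""Coalescent prior tree pool and its maximum clade credibility summary.

Backward in time, a lineage in population P_i moves to P_j with probability
a_ij, and co-located lineages coalesce.  Repeating (draw d from its prior,
simulate the coalescent) yields an i.i.d. sample from the genealogy prior,
which the heuristic sampler later reweights by the data likelihood.
"""

from netcoal import TransmissionSpec, Uniform, build_prior_pool, mcc_tree

leaves = [0, 3, 5, 10, 12, 15]  # six populations spread over a 4x4 grid
pool = build_prior_pool(
    TransmissionSpec.grid(4, 0.15), {"d": Uniform(0.1, 0.2)},
    leaves, pool_size=5000, tau_max=2000, seed=3,
)
print(f"pool: {len(pool)} trees from {pool.attempted} attempts "
      f"(rejection {pool.rejection_fraction:.3f})")
print(f"prior mean TMRCA: {pool.tmrcas.mean():.1f} generations "
      f"(max {pool.tmrcas.max()})")

mcc = mcc_tree(pool.trees[:2000])
print("prior MCC tree:", mcc.newick(comments=False))
supports = sorted(
    nd.support for nd in mcc.iter_nodes() if not nd.is_leaf() and nd.parent
)
print("non-root clade supports:", [f"{s:.2f}" for s in supports])
# prior clades reflect geography alone: nearby leaves coalesce first, and
# supports are modest because one trait carries little topological signal

pool.save("prior_pool.trees.nex", "prior_pool.theta.tsv")
print("wrote prior_pool.trees.nex / prior_pool.theta.tsv")
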