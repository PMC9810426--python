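"""Forward simulation on a square grid and dataset generation.

Each generation every population copies a random neighbour's state (rate d
per neighbour) and the copy mutates between the two states at rates q12 and
q21.  The long-run fraction of population-generations in state 1 approaches
the mutation chain's stationary probability pi1 = q21/(q12+q21).
"""

import numpy as np

from netcoal import (
    MutationSpec,
    TransmissionSpec,
    mask_dataset,
    mutation_matrix,
    simulate_forward,
    transmission_matrix,
)
from netcoal.io import write_dataset

L, d, q12, q21 = 4, 0.15, 0.01, 0.02
tspec = TransmissionSpec.grid(L, d)
A = transmission_matrix(tspec)
Qm = mutation_matrix(MutationSpec.two_state(q12, q21))

traj = simulate_forward(A, Qm, 60_000, seed=1, record=True)
frac = (traj[10_000:] == 0).mean()
print(f"fraction of population-generations in state 1: {frac:.3f}")
print(f"stationary pi1 = q21/(q12+q21) = {q21/(q12+q21):.3f}")
# the spatial model preserves the per-population stationary law of the
# mutation chain, so the two numbers agree up to Monte-Carlo error

states = traj[-1]
print("\nfinal grid states (1-based):")
print((states + 1).reshape(L, L))

rng = np.random.default_rng(2)
perm = rng.permutation(L * L)
obs = mask_dataset(states, sorted(perm[3:]), sorted(perm[:3]), coords=tspec.coords)
write_dataset("grid_dataset.tsv", L * L, 2, obs.observed, obs.infer_targets,
              coords=tspec.coords, true_states=states)
print(f"\nwrote grid_dataset.tsv: {obs.m} observed populations, "
      f"{obs.l} concealed inference targets")
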