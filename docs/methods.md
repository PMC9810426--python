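# Methods

## Model

A network of `n` populations each holds one of `k` discrete states of a
single cultural trait.  Time is discrete; one step is a human generation.
Each generation has two ordered events:

1. **Transmission.** Population `P_i` copies the previous generation's
   state of a source population drawn from row `i` of the transmission
   matrix `A` (`a_ii` is the probability of keeping its own state).
2. **Mutation.** The copied state `i` switches to `j` with probability
   `q_ij` from the mutation matrix `Q`.

Both matrices are row-stochastic and parameterized by small families:

| family | parameters | form |
|---|---|---|
| island | `c ∈ [0,1]` | `a_ii = 1−c`, `a_ij = c/(n−1)` |
| per_population | `c_1..c_n` | as island with one rate per row |
| gravity | `σ > 0`, sizes `π_j`, distances `d_ij` | `a_ij ∝ π_j exp(−d_ij²/2σ²)` |
| grid | `d ∈ [0, 0.25]`, side `L` | `a_ij = d` per side-sharing neighbour, `a_ii = 1 − d·deg(P_i)` |
| uniform mutation | `μ` | off-diagonal `μ/(k−1)` |
| two_state | `q12, q21` | `Q = [[1−q12, q12], [q21, 1−q21]]` |
| explicit | full matrix | validated, never renormalized silently |

Grid squares on edges and corners have degree 3 and 2 (no wraparound), so
the self-loop weight `1 − d·deg` varies over the lattice; validity requires
`d ≤ 1/max deg = 0.25`.  For the uniform mutation family the total mutation
probability `μ` is split evenly over the `k−1` *other states* — the
denominator indexes states, not populations.

The two-state `Q^t` has the spectral closed form with `λ = 1 − q12 − q21`,
`π1 = q21/(q12+q21)`, `π2 = q12/(q12+q21)`:

```
Q^t = [[π1 + π2 λ^t, π2 − π2 λ^t],
       [π1 − π1 λ^t, π2 + π1 λ^t]]
```

verified in the tests against iterated multiplication to 1e−10.  General
families use exact binary exponentiation; powers are memoized per `t`
(branch lengths are integers, so no fractional powers arise).

## Latent history and genealogy

`G` is a τ×n integer matrix: `G[i, j]` is the population `P_j` copied from
`i` generations ago (row 0 = the present generation's event).  τ is prior
knowledge — the maximum possible TMRCA of the traced copies.  Its prior
factorizes entrywise, `log P(G|θτ) = Σ c_ij log a_ij`, where `c_ij` counts
copies of `P_i` from `P_j`; rows older than the realized MRCA still carry
prior mass and are sampled as nuisance entries.

Tracing the `m + l` observed/target populations backward through `G` yields
the single-trait genealogy: a lineage in `p` at age `g` moves to `G[g, p]`,
and lineages landing in one population merge immediately (a population holds
one state, so three or more co-located lineages form a single multifurcating
node rather than stacked zero-length binary nodes).  If more than one lineage
survives all τ rows, the state has probability zero under the prior
constraint and is rejected by the samplers.

The leaf-state likelihood given the tree, `Q` and root state `S` is
Felsenstein pruning generalized to multifurcations (product over all
children), computed in log space; a linear-space route exists purely as a
numerical cross-check.  The root prior `P(S|θμ)` defaults to the stationary
distribution of `Q` (its dominant left eigenvector); reducible or absorbing
chains have no valid stationary prior and require an explicit uniform or
fixed root prior instead.  Populations whose states are inference targets
(`X`) enter the tree as ordinary leaves carrying their currently sampled
state.

## Samplers

The supplementary details of the original samplers are not part of this
package's sources; the kernels below are this package's own design, chosen
so every Hastings ratio is cheap.

**Exact sampler** (`run_mcmc_exact`) on (θτ, θμ, G, S, X):

* *G entries:* pick (row, column) uniformly, propose a new source from the
  transmission row `a_{col,·}`.  Prior and proposal cancel exactly, so
  entries off the traced lineages are accepted outright, and on-path entries
  are accepted on the likelihood ratio alone (zero if the new history fails
  to coalesce).  Occupancy of each generation is cached so off-path entries
  are recognized in O(1); only on-path changes trigger a retrace.
* *θτ, θμ:* uniform random walks reflected at the prior bounds (step =
  `step_frac` × prior width, default 0.2).  θτ changes only the history
  prior; θμ changes the likelihood and the stationary root prior.
* *S:* Gibbs from the root partial-likelihood vector (free, since pruning
  already produces all root states at once).
* *X:* Gibbs per target, evaluating the pruning likelihood at each of its
  `k` states.

By default moves are applied in a fixed sweep (all G updates, then θ, S,
X), which preserves the posterior but composes kernels irreversibly; a
`scan="random"` mode applies exactly one randomly chosen move per iteration,
giving a reversible chain used by the detailed-balance test.

Initialization draws whole histories from the prior until the traced
lineages coalesce (equivalently, backward simulation of the lineages with
the off-path entries filled from their row distributions); θ starts at the
prior means, `X` at the nearest observed population's state.

**Heuristic sampler** (`run_mcmc_heuristic`): the tree prior is replaced by
a pool of (θτ, genealogy) pairs simulated backward under θτ draws,
*conditioned on coalescing within `tau_max`* by discarding failed draws
together with their θτ — the same conditioning as the exact model's
TMRCA ≤ τ.  Pool entries are i.i.d., so proposing a uniformly random entry
makes the tree move a pure likelihood-ratio acceptance; θμ, S and X moves
are as above, and the θτ posterior is read off the accepted entries'
attached draws.  Pools store trees in a compact parent-array encoding
(tens of bytes per tree), and persist to NEXUS + TSV for reuse.

On instances small enough to enumerate every history matrix,
`exact_posterior_enumeration` sums the unnormalized posterior over all
`n^(τ·n)` histories × `k` root states × `k^l` target assignments; both
samplers are validated against it to total-variation 0.02 (exact) and 0.03
(heuristic, pool 10^5).

## Synthetic data

`simulate_forward` implements the generative process exactly (vectorized,
draw-order stable, bit-reproducible per seed).  Default study conditions
follow the grid setting: `d = 0.15` with `q12 = 0.04, q21 = 0.08`
(recovery study) or `q12 = 0.01, q21 = 0.02` (genealogy study).  What the
generator does *not* emulate about real data: within-population diversity
(one population, one state), state-dependent copying (neutral evolution
only), observation error, and non-stationary initial conditions — runs
start from uniform-random states and rely on a long burn-in, so passing
tests demonstrate correctness of the inference machinery under the model,
not robustness to model misspecification.

## Default problem sizes

Chosen as scaled-down versions of the full study conditions so that each
experiment completes in minutes on one CPU with identical semantics:

* *Recovery study:* 6×6 grid (full study: 10×10), all 36 populations
  observed, data from 2×10^4 generations, τ = 600 (≈ the 99.9th percentile
  of the simulated TMRCA of 36 lineages), 2 500 sweeps × 100 G-moves,
  20 replicates.  `d` is held at its true value: with single-entry updates
  the `d` chain mixes far too slowly on large grids to be worth sampling,
  so fixing it is the documented default there.
* *Genealogy study:* 4×4 grid, six taxa, pool 2×10^4 (full study: 5×10^6)
  with `tau_max = 2000`, 10^4 sweeps.  The contrast statistics are the mean
  TMRCA and the mean fraction of non-trivial clades whose leaves share one
  state.  The simulated dataset is redrawn (new seed) until the taxa carry
  both states, since a monochromatic dataset makes the contrast vacuous.
* *Enumeration benchmark:* n = 3 island model, τ = 3, m = 2, l = 1
  (19 683 histories).

## Numerical choices and conventions

* Row-stochasticity enforced to 1e−12; explicit matrices are rejected, not
  renormalized.
* Public API indices are 0-based; every file format and printed label is
  1-based (`P1..Pn`, states `1..k`).
* Stationary distributions come from the eigendecomposition of `Qᵀ` with a
  1e−8 residual check; `λ^t` underflow in the closed form is clamped at 0
  before logs.
* ESS uses Geyer's initial-monotone-sequence estimator (paired
  autocorrelations, truncated at the first negative pair, monotonized);
  constant series are flagged NaN.  arviz serves as an independent
  cross-check in the tests, not as the implementation.
* MCC trees maximize the *sum of log* clade supports over sampled trees
  (equivalent to the product, immune to underflow), ties broken by first
  occurrence; node heights are annotated with the mean age of the clade's
  MRCA across trees containing it.

## Limitations

* The exact sampler's single-entry G updates mix slowly in τ·n; transmission
  parameters on large grids effectively require fixing (or the heuristic
  sampler).  Conversely the heuristic sampler degrades when the observed
  leaf set is large, because a static pool rarely proposes trees with high
  likelihood.
* Posteriors under uninformative uniform priors are intrinsically broad: a
  single trait carries little information, so credible intervals are wide
  and MCC clade supports moderate.  Informative priors are recommended for
  empirical use.
* Continuous-time rate matrices, fractional generations, biased copying,
  rate heterogeneity across branches, partial/ambiguous observations and
  truncated-history likelihood approximations are out of scope.
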