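"""Self-contained replications of the package's two grid case studies.

These helpers bundle data generation and inference for the square-grid
setting so that tests, examples and the acceptance script all run the same
experiment: a mutation-rate recovery study on a 6x6 grid with the exact
history-matrix sampler, and a prior-versus-posterior genealogy contrast on
a 4x4 grid with the heuristic pool sampler.  Problem sizes default to
scaled-down versions of the full study conditions (smaller grid, shorter
runs) chosen so a complete replicate finishes in seconds on one CPU while
preserving every qualitative feature; the full-scale settings are plain
arguments away.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coalescent import PriorTreePool, build_prior_pool
from .forward_sim import ObservationSet, mask_dataset, simulate_forward
from .inference import McmcConfig, PriorConfig, Trace, run_mcmc_exact, run_mcmc_heuristic
from .models import MutationSpec, TransmissionSpec, mutation_matrix, transmission_matrix
from .priors import Fixed, Uniform
from .summaries import monochromatic_clade_score

__all__ = [
    "MutationRecoveryResult",
    "mutation_recovery_replicate",
    "TreeContrastResult",
    "grid_tree_contrast",
]


@dataclass
class MutationRecoveryResult:
    """One replicate of the grid mutation-rate recovery study."""

    trace: Trace
    true_q12: float
    true_q21: float
    ci_q12: tuple[float, float]
    ci_q21: tuple[float, float]

    @property
    def covered(self) -> bool:
        """True when both true rates fall inside their central 95% interval."""
        return (
            self.ci_q12[0] <= self.true_q12 <= self.ci_q12[1]
            and self.ci_q21[0] <= self.true_q21 <= self.ci_q21[1]
        )


def mutation_recovery_replicate(
    seed: int,
    L: int = 6,
    d: float = 0.15,
    q12: float = 0.04,
    q21: float = 0.08,
    rate_prior: Uniform = Uniform(0.0, 0.1),
    generations: int = 20_000,
    tau: int = 600,
    sweeps: int = 2500,
    g_moves_per_sweep: int = 100,
) -> MutationRecoveryResult:
    """Simulate grid data, run the exact sampler with d held fixed, and
    report 95% credible intervals for the two mutation rates.

    The grid rate ``d`` is fixed at its true value (it mixes far too slowly
    to be worth sampling on grids of this size); uniform priors on the
    mutation rates; all populations observed.
    """
    n = L * L
    tspec = TransmissionSpec.grid(L, d)
    A = transmission_matrix(tspec)
    Qm = mutation_matrix(MutationSpec.two_state(q12, q21))
    states = simulate_forward(A, Qm, generations, seed=seed)
    obs = mask_dataset(states, range(n), [], k=2, coords=tspec.coords)
    priors = PriorConfig(
        transmission={"d": Fixed(d)},
        mutation={"q12": rate_prior, "q21": rate_prior},
    )
    cfg = McmcConfig(
        sweeps=sweeps, thin=5, seed=seed + 1, g_moves_per_sweep=g_moves_per_sweep
    )
    trace = run_mcmc_exact(
        obs, tspec, MutationSpec.two_state(q12, q21), priors, cfg, tau=tau
    )
    s12, s21 = trace.series("q12"), trace.series("q21")
    return MutationRecoveryResult(
        trace=trace,
        true_q12=q12,
        true_q21=q21,
        ci_q12=tuple(np.quantile(s12, [0.025, 0.975])),
        ci_q21=tuple(np.quantile(s21, [0.025, 0.975])),
    )


@dataclass
class TreeContrastResult:
    """Prior-pool versus posterior tree contrast on the small grid."""

    pool: PriorTreePool
    trace: Trace
    leaf_states: dict[int, int]
    prior_mean_tmrca: float
    posterior_mean_tmrca: float
    prior_mono_score: float
    posterior_mono_score: float


def grid_tree_contrast(
    seed: int,
    L: int = 4,
    d: float = 0.15,
    q12: float = 0.01,
    q21: float = 0.02,
    leaves: tuple[int, ...] = (0, 3, 5, 10, 12, 15),
    d_prior: Uniform = Uniform(0.1, 0.2),
    rate_prior: Uniform = Uniform(0.0, 0.03),
    generations: int = 10_000,
    pool_size: int = 20_000,
    tau_max: int = 2000,
    sweeps: int = 10_000,
    require_both_states: bool = True,
) -> TreeContrastResult:
    """Simulate small-grid data, build a coalescent prior pool, run the
    heuristic sampler, and contrast prior and posterior genealogies.

    The six default leaves are spread over the 4x4 grid; the contrast
    statistics are the mean TMRCA (posterior trees should be older, since
    the low mutation-rate prior needs long branches to explain state
    differences) and the mean fraction of clades whose leaves share one
    state (posterior trees should group same-state populations).
    """
    n = L * L
    tspec = TransmissionSpec.grid(L, d)
    A = transmission_matrix(tspec)
    Qm = mutation_matrix(MutationSpec.two_state(q12, q21))
    # the contrast is only informative when the taxa carry both states
    # (as in the study dataset); redraw the simulation until they do
    states = simulate_forward(A, Qm, generations, seed=seed)
    tries = 0
    while require_both_states and len({int(states[p]) for p in leaves}) < 2:
        tries += 1
        if tries > 50:
            raise RuntimeError("no two-state dataset found in 50 simulations")
        states = simulate_forward(A, Qm, generations, seed=seed + 10_000 * tries)
    # taxa are only the selected leaves; other populations are left out
    obs = ObservationSet(
        n=n, k=2, observed={p: int(states[p]) for p in leaves},
        coords=tspec.coords, true_states=states,
    )
    pool = build_prior_pool(
        tspec, {"d": d_prior}, list(leaves), pool_size, tau_max, seed=seed + 1
    )
    priors = PriorConfig(mutation={"q12": rate_prior, "q21": rate_prior})
    cfg = McmcConfig(sweeps=sweeps, thin=5, seed=seed + 2)
    trace = run_mcmc_heuristic(
        obs, pool, MutationSpec.two_state(q12, q21), priors, cfg
    )
    leaf_states = {p: int(states[p]) for p in leaves}
    return TreeContrastResult(
        pool=pool,
        trace=trace,
        leaf_states=leaf_states,
        prior_mean_tmrca=float(pool.tmrcas.mean()),
        posterior_mean_tmrca=float(np.mean([s.tmrca for s in trace.samples])),
        prior_mono_score=monochromatic_clade_score(
            pool.trees[: min(len(pool), 5000)], leaf_states
        ),
        posterior_mono_score=monochromatic_clade_score(trace.trees(), leaf_states),
    )
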