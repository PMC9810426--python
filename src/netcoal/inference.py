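"""MCMC inference of transmission/mutation parameters, latent histories,
ancestral state and unobserved present states.

Two samplers target (up to constants) the joint posterior

    P(theta_tau, theta_mu, G, S, X | D)
        ∝ P(D, X | theta_mu, G, S) P(S | theta_mu) P(G | theta_tau)
          P(theta_tau) P(theta_mu)

where ``D`` is the observed states together with the prior constraint
TMRCA <= tau.  The exact sampler walks the full tau x n history matrix G;
the heuristic sampler replaces P(G | theta_tau) by an empirical prior pool
of (theta_tau, tree) pairs drawn by backward coalescent simulation, and
proposes trees by drawing pool entries uniformly.

Proposal kernels (own design; chosen so Hastings ratios are cheap):

* single G-entry updates with the prior-informed independence proposal
  ``g' ~ a_{p, .}`` — prior and proposal cancel exactly, so entries off the
  traced lineages are accepted outright and on-path entries are accepted on
  the likelihood ratio alone (rejecting non-coalescing histories);
* reflected uniform random walks for each free theta component;
* Gibbs draws for the root state S (from root partial likelihoods) and for
  each unobserved state in X.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .coalescent import PriorTreePool
from .forward_sim import ObservationSet
from .history import LinearTree, NoCoalescence, log_history_prior, trace_lineages
from .models import (
    MutationSpec,
    TransmissionSpec,
    ValidationError,
    mutation_matrix,
    transmission_matrix,
)
from .priors import param_means

__all__ = [
    "PriorConfig",
    "McmcConfig",
    "TraceSample",
    "Trace",
    "run_mcmc_exact",
    "run_mcmc_heuristic",
    "posterior_state_marginals",
    "tmrca_distribution",
    "effective_sample_size",
    "exact_posterior_enumeration",
    "EnumeratedPosterior",
    "total_variation",
]


@dataclass(frozen=True)
class PriorConfig:
    """Priors for the transmission parameters and the mutation parameters.

    Each entry maps a parameter name (as used by the model family, e.g.
    ``"d"``, ``"c"``, ``"q12"``) to a :class:`~netcoal.priors.Uniform` prior
    or a :class:`~netcoal.priors.Fixed` override; fixed parameters are held
    constant throughout the chain (e.g. holding the grid rate ``d`` at a
    known value, the documented default for large grids where ``d`` mixes
    too slowly to be worth sampling).
    """

    transmission: dict = field(default_factory=dict)
    mutation: dict = field(default_factory=dict)


@dataclass
class McmcConfig:
    """Chain-length, move-schedule and reproducibility settings.

    One "sweep" applies ``g_moves_per_sweep`` single-entry history updates
    (exact sampler) or ``tree_moves_per_sweep`` pool-index proposals
    (heuristic sampler), one reflected random-walk update per free theta
    component, a Gibbs draw of S, and a Gibbs draw of every X state.
    ``burn_in`` is a fraction of sweeps; every ``thin``-th sweep thereafter
    is recorded.
    """

    sweeps: int = 2000
    burn_in: float = 0.1
    thin: int = 10
    seed: int = 0
    g_moves_per_sweep: int | None = None   # default: ceil(tau*n/50)
    tree_moves_per_sweep: int = 3
    step_frac: float = 0.2                 # random-walk step as fraction of prior width
    init_retries: int = 200
    store_history: bool = False            # keep a copy of G in every sample
    scan: str = "sweep"                    # "sweep" or "random" (one move/iteration)

    def __post_init__(self) -> None:
        if not 0.0 <= self.burn_in < 1.0:
            raise ValueError("burn_in must be a fraction in [0, 1)")
        if self.sweeps < 1 or self.thin < 1:
            raise ValueError("sweeps and thin must be positive")


@dataclass
class TraceSample:
    """One retained draw of the full model state."""

    iteration: int
    theta_tau: dict[str, float]
    theta_mu: dict[str, float]
    S: int
    X: dict[int, int]
    tree: LinearTree
    tmrca: int
    log_likelihood: float
    log_tree_prior: float | None      # log P(G|theta_tau); None (pool index recorded) for heuristic
    log_root_prior: float             # log P(S|theta_mu)
    log_posterior: float
    pool_index: int | None = None
    history: np.ndarray | None = None


@dataclass
class Trace:
    """A list of :class:`TraceSample` plus per-move acceptance diagnostics."""

    samples: list[TraceSample]
    acceptance: dict[str, float]
    algorithm: str
    seed: int

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def series(self, name: str) -> np.ndarray:
        """Extract a scalar series: a theta name, "tmrca", "S",
        "log_likelihood", "log_posterior", or "X:<population>"."""
        if name.startswith("X:"):
            pop = int(name.split(":", 1)[1])
            return np.array([s.X[pop] for s in self.samples], dtype=float)
        if name in ("tmrca", "S", "log_likelihood", "log_posterior"):
            return np.array([getattr(s, name) for s in self.samples], dtype=float)
        out = []
        for s in self.samples:
            if name in s.theta_mu:
                out.append(s.theta_mu[name])
            elif name in s.theta_tau:
                out.append(s.theta_tau[name])
            else:
                raise KeyError(f"no parameter {name!r} in trace")
        return np.array(out, dtype=float)

    def trees(self) -> list[LinearTree]:
        return [s.tree for s in self.samples]


def total_variation(p, q) -> float:
    """Total-variation distance between two discrete distributions."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    return 0.5 * float(np.abs(p - q).sum())


# ---------------------------------------------------------------------------
# shared machinery
# ---------------------------------------------------------------------------


def _draw_cat(logw: np.ndarray, rng) -> int:
    w = np.exp(logw - logw.max())
    w /= w.sum()
    return int(rng.choice(len(w), p=w))


def _log_root_prior_vec(Qm) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(Qm.root_prior_vector())


class _MutationState:
    """Current theta_mu, realized Q, and cached root partials/likelihood."""

    def __init__(self, mspec: MutationSpec, theta_mu: dict[str, float]):
        self.mspec = mspec
        self.theta = dict(theta_mu)
        self.Qm = mutation_matrix(mspec.with_params(**self.theta))
        self.log_pi = _log_root_prior_vec(self.Qm)


def _init_x(obs: ObservationSet) -> dict[int, int]:
    """Initial X: nearest observed population's state (modal state fallback)."""
    states = list(obs.observed.values())
    modal = int(np.bincount(states).argmax())
    x0 = {}
    for x in obs.infer_targets:
        if obs.coords is not None:
            d = {y: np.sum((obs.coords[x] - obs.coords[y]) ** 2) for y in obs.observed}
            x0[x] = obs.observed[min(d, key=d.get)]
        else:
            x0[x] = modal
    return x0


# ---------------------------------------------------------------------------
# exact sampler (full history matrix G)
# ---------------------------------------------------------------------------


def run_mcmc_exact(
    obs: ObservationSet,
    tspec: TransmissionSpec,
    mspec: MutationSpec,
    priors: PriorConfig,
    cfg: McmcConfig,
    tau: int,
) -> Trace:
    """Metropolis-within-Gibbs over (theta_tau, theta_mu, G, S, X)."""
    from .likelihood import root_log_partials

    rng = np.random.default_rng(cfg.seed)
    n, k = obs.n, obs.k
    if tspec.n != n:
        raise ValueError(f"network size {tspec.n} does not match dataset n={n}")
    leaves = obs.leaves
    theta_tau = param_means(priors.transmission) or dict(tspec.params)
    theta_mu = param_means(priors.mutation) or dict(mspec.params)

    A = transmission_matrix(tspec.with_params(**theta_tau))
    cumA = np.cumsum(A, axis=1)
    mu = _MutationState(mspec, theta_mu)

    # G initialization: draw whole histories from the prior until the traced
    # lineages coalesce within tau (backward simulation in matrix form)
    tree = occ = G = None
    for _ in range(cfg.init_retries):
        u = rng.random((tau, n))
        Gcand = (u[:, :, None] > cumA[None, :, :]).sum(axis=2)
        res, occ_c = trace_lineages(Gcand, leaves, want_occupancy=True)
        if not isinstance(res, NoCoalescence):
            G, tree, occ = Gcand, res.to_linear(), occ_c
            break
    if G is None:
        raise RuntimeError(
            f"no coalescing initial history found in {cfg.init_retries} draws; "
            f"increase tau (= {tau}) or strengthen transmission"
        )
    counts = np.zeros((n, n), dtype=int)
    for col in range(n):
        counts[col] = np.bincount(G[:, col], minlength=n)
    log_g_prior = log_history_prior(counts, A)

    S = _draw_cat(mu.log_pi, rng)
    X = _init_x(obs)
    leaf_states = dict(obs.observed)
    leaf_states.update(X)
    rootvec = root_log_partials(tree, mu.Qm, leaf_states)
    loglik = float(rootvec[S])
    if not np.isfinite(loglik):
        # zero-likelihood start: resample S from its conditional instead
        S = _draw_cat(mu.log_pi + rootvec, rng)
        loglik = float(rootvec[S])
        if not np.isfinite(loglik):
            warnings.warn("initial state has zero likelihood", RuntimeWarning)

    g_moves = cfg.g_moves_per_sweep or max(1, (tau * n + 49) // 50)
    free_tau = [p for p, pr in priors.transmission.items() if not pr.fixed]
    free_mu = [p for p, pr in priors.mutation.items() if not pr.fixed]
    acc = {m: [0, 0] for m in ("G", "theta_tau", "theta_mu")}

    burn = int(cfg.burn_in * cfg.sweeps)
    samples: list[TraceSample] = []

    def g_move():
        nonlocal tree, occ, rootvec, loglik, log_g_prior
        r = int(rng.integers(tau))
        p = int(rng.integers(n))
        new = int((rng.random() > cumA[p]).sum())
        old = G[r, p]
        if new == old:
            return
        acc["G"][1] += 1
        if not occ[r, p]:
            # off-lineage entry: prior and proposal cancel, tree unchanged
            G[r, p] = new
            counts[p, old] -= 1
            counts[p, new] += 1
            log_g_prior += np.log(A[p, new]) - np.log(A[p, old])
            acc["G"][0] += 1
            return
        G[r, p] = new
        res, occ_new = trace_lineages(G, leaves, want_occupancy=True)
        if isinstance(res, NoCoalescence):
            G[r, p] = old
            return
        tree_new = res.to_linear()
        rootvec_new = root_log_partials(tree_new, mu.Qm, leaf_states)
        if np.log(rng.random()) < rootvec_new[S] - loglik:
            tree, occ, rootvec = tree_new, occ_new, rootvec_new
            loglik = float(rootvec[S])
            counts[p, old] -= 1
            counts[p, new] += 1
            log_g_prior += np.log(A[p, new]) - np.log(A[p, old])
            acc["G"][0] += 1
        else:
            G[r, p] = old

    def tau_move(name):
        # likelihood depends on G only, so the ratio is just the history prior
        nonlocal A, cumA, log_g_prior
        pr = priors.transmission[name]
        step = cfg.step_frac * (pr.hi - pr.lo)
        prop = pr.reflect(theta_tau[name] + rng.uniform(-step, step))
        acc["theta_tau"][1] += 1
        try:
            A_new = transmission_matrix(tspec.with_params(**{**theta_tau, name: prop}))
        except ValidationError:
            return
        lp_new = log_history_prior(counts, A_new)
        if np.log(rng.random()) < lp_new - log_g_prior:
            theta_tau[name] = prop
            A = A_new
            cumA = np.cumsum(A, axis=1)
            log_g_prior = lp_new
            acc["theta_tau"][0] += 1

    def mu_move(name):
        nonlocal mu, rootvec, loglik
        pr = priors.mutation[name]
        step = cfg.step_frac * (pr.hi - pr.lo)
        prop = pr.reflect(theta_mu[name] + rng.uniform(-step, step))
        acc["theta_mu"][1] += 1
        try:
            mu_new = _MutationState(mspec, {**theta_mu, name: prop})
            rootvec_new = root_log_partials(tree, mu_new.Qm, leaf_states)
        except ValidationError:
            return
        delta = (rootvec_new[S] + mu_new.log_pi[S]) - (loglik + mu.log_pi[S])
        if np.log(rng.random()) < delta:
            theta_mu[name] = prop
            mu = mu_new
            rootvec = rootvec_new
            loglik = float(rootvec[S])
            acc["theta_mu"][0] += 1

    def s_gibbs():
        nonlocal S, loglik
        S = _draw_cat(mu.log_pi + rootvec, rng)
        loglik = float(rootvec[S])

    def x_gibbs(x):
        nonlocal rootvec, loglik
        vecs = []
        logw = np.empty(k)
        for s in range(k):
            leaf_states[x] = s
            v = root_log_partials(tree, mu.Qm, leaf_states)
            vecs.append(v)
            logw[s] = v[S]
        s_new = _draw_cat(logw, rng)
        leaf_states[x] = s_new
        X[x] = s_new
        rootvec = vecs[s_new]
        loglik = float(rootvec[S])

    if cfg.scan == "random":
        # one randomly chosen move per iteration: a state-independent
        # mixture of reversible kernels, itself reversible (used for
        # detailed-balance checks); weights mirror the sweep composition
        kinds = (["G"] * g_moves + [("tau", nm) for nm in free_tau]
                 + [("mu", nm) for nm in free_mu]
                 + ["S"] + [("X", x) for x in obs.infer_targets])
    elif cfg.scan != "sweep":
        raise ValueError(f"unknown scan mode {cfg.scan!r}")

    for sweep in range(cfg.sweeps):
        if cfg.scan == "sweep":
            for _ in range(g_moves):
                g_move()
            for name in free_tau:
                tau_move(name)
            for name in free_mu:
                mu_move(name)
            s_gibbs()
            for x in obs.infer_targets:
                x_gibbs(x)
        else:
            kind = kinds[int(rng.integers(len(kinds)))]
            if kind == "G":
                g_move()
            elif kind == "S":
                s_gibbs()
            elif isinstance(kind, tuple) and kind[0] == "X":
                x_gibbs(kind[1])
            elif isinstance(kind, tuple) and kind[0] == "tau":
                tau_move(kind[1])
            else:
                mu_move(kind[1])

        if sweep >= burn and (sweep - burn) % cfg.thin == 0:
            log_prior_theta = sum(
                -np.log(pr.hi - pr.lo)
                for pr in (*priors.transmission.values(), *priors.mutation.values())
                if not pr.fixed
            )
            samples.append(
                TraceSample(
                    iteration=sweep,
                    theta_tau=dict(theta_tau),
                    theta_mu=dict(theta_mu),
                    S=S,
                    X=dict(X),
                    tree=tree,
                    tmrca=tree.tmrca,
                    log_likelihood=loglik,
                    log_tree_prior=log_g_prior,
                    log_root_prior=float(mu.log_pi[S]),
                    log_posterior=loglik + log_g_prior + float(mu.log_pi[S]) + log_prior_theta,
                    history=G.copy() if cfg.store_history else None,
                )
            )

    rates = {m: (a / p if p else np.nan) for m, (a, p) in acc.items()}
    return Trace(samples, rates, "exact_G", cfg.seed)


# ---------------------------------------------------------------------------
# heuristic sampler (prior tree pool instead of G)
# ---------------------------------------------------------------------------


def run_mcmc_heuristic(
    obs: ObservationSet,
    pool: PriorTreePool,
    mspec: MutationSpec,
    priors: PriorConfig,
    cfg: McmcConfig,
) -> Trace:
    """Metropolis-within-Gibbs over (pool entry, theta_mu, S, X).

    Pool entries are i.i.d. draws from the prior P(T', theta_tau | TMRCA <=
    tau), and tree proposals pick a uniformly random entry, so the prior and
    proposal cancel and the tree move is accepted on the likelihood ratio
    alone.  The transmission-parameter posterior is read off the theta_tau
    draws attached to the accepted entries.
    """
    from .likelihood import root_log_partials

    rng = np.random.default_rng(cfg.seed)
    k = obs.k
    if set(pool.leaves) != set(obs.leaves):
        raise ValueError(
            f"pool leaf set {sorted(pool.leaves)} does not match dataset "
            f"leaf set {obs.leaves}"
        )
    if len(pool) < 1000:
        warnings.warn(
            f"prior pool has only {len(pool)} trees; posterior tree support "
            "may be too coarse", RuntimeWarning,
        )
    theta_mu = param_means(priors.mutation) or dict(mspec.params)
    mu = _MutationState(mspec, theta_mu)
    X = _init_x(obs)
    leaf_states = dict(obs.observed)
    leaf_states.update(X)

    idx = int(rng.integers(len(pool)))
    tree = pool.trees[idx]
    rootvec = root_log_partials(tree, mu.Qm, leaf_states)
    S = _draw_cat(mu.log_pi + rootvec, rng)
    loglik = float(rootvec[S])

    free_mu = [p for p, pr in priors.mutation.items() if not pr.fixed]
    acc = {m: [0, 0] for m in ("tree", "theta_mu")}
    burn = int(cfg.burn_in * cfg.sweeps)
    samples: list[TraceSample] = []

    for sweep in range(cfg.sweeps):
        for _ in range(cfg.tree_moves_per_sweep):
            cand = int(rng.integers(len(pool)))
            acc["tree"][1] += 1
            if cand == idx:
                acc["tree"][0] += 1
                continue
            rootvec_new = root_log_partials(pool.trees[cand], mu.Qm, leaf_states)
            if np.log(rng.random()) < rootvec_new[S] - loglik:
                idx, tree, rootvec = cand, pool.trees[cand], rootvec_new
                loglik = float(rootvec[S])
                acc["tree"][0] += 1

        for name in free_mu:
            pr = priors.mutation[name]
            step = cfg.step_frac * (pr.hi - pr.lo)
            prop = pr.reflect(theta_mu[name] + rng.uniform(-step, step))
            acc["theta_mu"][1] += 1
            try:
                mu_new = _MutationState(mspec, {**theta_mu, name: prop})
                rootvec_new = root_log_partials(tree, mu_new.Qm, leaf_states)
            except ValidationError:
                continue
            delta = (rootvec_new[S] + mu_new.log_pi[S]) - (loglik + mu.log_pi[S])
            if np.log(rng.random()) < delta:
                theta_mu[name] = prop
                mu = mu_new
                rootvec = rootvec_new
                loglik = float(rootvec[S])
                acc["theta_mu"][0] += 1

        S = _draw_cat(mu.log_pi + rootvec, rng)
        loglik = float(rootvec[S])

        for x in obs.infer_targets:
            vecs = []
            logw = np.empty(k)
            for s in range(k):
                leaf_states[x] = s
                v = root_log_partials(tree, mu.Qm, leaf_states)
                vecs.append(v)
                logw[s] = v[S]
            s_new = _draw_cat(logw, rng)
            leaf_states[x] = s_new
            X[x] = s_new
            rootvec = vecs[s_new]
            loglik = float(rootvec[S])

        if sweep >= burn and (sweep - burn) % cfg.thin == 0:
            log_prior_theta = sum(
                -np.log(pr.hi - pr.lo)
                for pr in priors.mutation.values() if not pr.fixed
            )
            samples.append(
                TraceSample(
                    iteration=sweep,
                    theta_tau=dict(pool.thetas[idx]),
                    theta_mu=dict(theta_mu),
                    S=S,
                    X=dict(X),
                    tree=tree,
                    tmrca=tree.tmrca,
                    log_likelihood=loglik,
                    log_tree_prior=None,
                    log_root_prior=float(mu.log_pi[S]),
                    log_posterior=loglik + float(mu.log_pi[S]) + log_prior_theta,
                    pool_index=idx,
                )
            )

    rates = {m: (a / p if p else np.nan) for m, (a, p) in acc.items()}
    return Trace(samples, rates, "heuristic_pool", cfg.seed)


# ---------------------------------------------------------------------------
# posterior summaries over traces
# ---------------------------------------------------------------------------


def posterior_state_marginals(trace: Trace, populations=None) -> dict[int, np.ndarray]:
    """Per-population empirical state frequencies of the X draws."""
    samples = trace.samples if isinstance(trace, Trace) else list(trace)
    if not samples:
        raise ValueError("empty trace")
    targets = set(samples[0].X)
    if populations is None:
        populations = sorted(targets)
    out: dict[int, np.ndarray] = {}
    for p in populations:
        if p not in targets:
            raise ValueError(f"population {p} is not an inference target")
        ks = max(s.X[p] for s in samples) + 1
        counts = np.bincount([s.X[p] for s in samples], minlength=ks).astype(float)
        out[p] = counts / counts.sum()
    return out


def tmrca_distribution(trace: Trace) -> dict[int, float]:
    samples = trace.samples if isinstance(trace, Trace) else list(trace)
    vals, counts = np.unique([s.tmrca for s in samples], return_counts=True)
    return {int(v): c / counts.sum() for v, c in zip(vals, counts)}


def effective_sample_size(trace, parameter: str | None = None) -> float:
    """ESS by Geyer's initial-monotone-sequence estimator.

    Accepts a :class:`Trace` plus a parameter name, or a raw 1-D array.
    A constant series has no well-defined ESS and is flagged with NaN.
    """
    if isinstance(trace, Trace):
        x = trace.series(parameter)
    else:
        x = np.asarray(trace, dtype=float)
    N = len(x)
    if N < 100:
        raise ValueError(f"need >= 100 samples for an ESS estimate, got {N}")
    x = x - x.mean()
    var = float(np.mean(x * x))
    if var == 0.0:
        warnings.warn("constant trace: ESS undefined", RuntimeWarning)
        return float("nan")
    nfft = int(2 ** np.ceil(np.log2(2 * N)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:N].real / N
    rho = acov / acov[0]
    # pair consecutive autocorrelations; truncate at the first negative pair,
    # then enforce monotone non-increasing pairs
    tau_int = -1.0
    prev = np.inf
    for m in range(N // 2):
        gamma = rho[2 * m] + (rho[2 * m + 1] if 2 * m + 1 < N else 0.0)
        if gamma < 0.0:
            break
        gamma = min(gamma, prev)
        prev = gamma
        tau_int += 2.0 * gamma
    tau_int = max(tau_int, 1.0 / N)
    return float(min(N / tau_int, N * 1.5))


# ---------------------------------------------------------------------------
# exhaustive enumeration on tiny instances (exact reference posterior)
# ---------------------------------------------------------------------------


@dataclass
class EnumeratedPosterior:
    """Exact posterior marginals from summing over every history matrix."""

    p_x: dict[int, np.ndarray]       # population -> state distribution
    p_s: np.ndarray                  # root-state distribution
    p_tmrca: dict[int, float]        # TMRCA distribution
    coalescent_mass: float           # prior mass of histories that coalesce

    def tmrca_vector(self, tau: int) -> np.ndarray:
        return np.array([self.p_tmrca.get(t, 0.0) for t in range(tau + 1)])


def exact_posterior_enumeration(
    obs: ObservationSet,
    tspec: TransmissionSpec,
    mspec: MutationSpec,
    tau: int,
    max_histories: int = 2_000_000,
) -> EnumeratedPosterior:
    """Sum the unnormalized posterior over all n^(tau*n) history matrices,
    k root states and k^l unknown-state assignments (fixed parameters).

    Feasible only on tiny instances (the guard caps the enumeration size);
    serves as the exact reference that both MCMC samplers are checked
    against.
    """
    from .likelihood import root_log_partials

    n, k, l = obs.n, obs.k, obs.l
    n_hist = n ** (tau * n)
    if n_hist * (k**l) > max_histories:
        raise ValueError(
            f"enumeration would visit {n_hist * k**l} states (> {max_histories})"
        )
    A = transmission_matrix(tspec)
    with np.errstate(divide="ignore"):
        logA = np.log(A)
    Qm = mutation_matrix(mspec)
    log_pi = _log_root_prior_vec(Qm)
    leaves = obs.leaves
    targets = list(obs.infer_targets)
    cols = np.tile(np.arange(n), tau)

    p_x = {x: np.zeros(k) for x in targets}
    p_s = np.zeros(k)
    p_tmrca: dict[int, float] = {}
    total = 0.0
    prior_coalesced = 0.0

    for flat in itertools.product(range(n), repeat=tau * n):
        g = np.asarray(flat, dtype=int)
        log_prior = float(logA[cols, g].sum())
        res = trace_lineages(g.reshape(tau, n), leaves)
        if isinstance(res, NoCoalescence):
            continue
        prior_g = np.exp(log_prior)
        prior_coalesced += prior_g
        tree = res.to_linear()
        leaf_states = dict(obs.observed)
        for assign in itertools.product(range(k), repeat=l):
            for x, s in zip(targets, assign):
                leaf_states[x] = s
            rootvec = root_log_partials(tree, Qm, leaf_states)
            w_s = np.exp(log_prior + log_pi + rootvec)   # weight per root state
            w = float(w_s.sum())
            if w == 0.0:
                continue
            total += w
            p_s += w_s
            for x, s in zip(targets, assign):
                p_x[x][s] += w
            p_tmrca[tree.tmrca] = p_tmrca.get(tree.tmrca, 0.0) + w

    if total == 0.0:
        raise RuntimeError("data has zero probability under every history")
    return EnumeratedPosterior(
        p_x={x: v / total for x, v in p_x.items()},
        p_s=p_s / total,
        p_tmrca={t: v / total for t, v in p_tmrca.items()},
        coalescent_mass=prior_coalesced,
    )
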