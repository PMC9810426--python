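"""Felsenstein pruning over the single-trait genealogy.

Mutation acts independently on every branch of the genealogy, as a
discrete-time Markov chain with transition matrix Q per generation, so the
probability of the leaf states given the root (MRCA) state ``S`` is computed
by the pruning recursion: the partial likelihood ``L_i(j)`` of node ``v_i``
being in state ``j`` is the product over its children ``c`` of
``sum_{j'} (Q^{t_c})_{j j'} L_c(j')`` with ``t_c`` the child's integer branch
length.  Leaves carry indicator vectors of their assigned state; internal
nodes may have more than two children (co-located lineages merge at once),
in which case the product simply runs over all of them.

Computation is in log space, which keeps long branches and small rates
well-behaved; a linear-space route is kept for cross-checking.
"""

from __future__ import annotations

import numpy as np

from .history import Genealogy, LinearTree
from .models import MutationMatrix

__all__ = [
    "root_log_partials",
    "pruning_likelihood",
    "root_marginal_likelihood",
]


def _as_linear(tree: Genealogy | LinearTree) -> LinearTree:
    return tree.to_linear() if isinstance(tree, Genealogy) else tree


def _leaf_log_indicator(k: int, state: int) -> np.ndarray:
    if not 0 <= state < k:
        raise ValueError(f"leaf state {state} outside [0, {k})")
    v = np.full(k, -np.inf)
    v[state] = 0.0
    return v


def root_log_partials(
    tree: Genealogy | LinearTree,
    Q: MutationMatrix,
    leaf_states: dict[int, int],
) -> np.ndarray:
    """Log partial-likelihood vector at the root: ``log L_root(j)``, j = 0..k-1.

    ``leaf_states`` maps leaf population index -> assigned state; every leaf
    must be assigned (observed data and currently sampled X targets alike).
    """
    lt = _as_linear(tree)
    k = Q.k
    nn = lt.n_nodes
    partial = np.zeros((nn, k))
    for i in np.flatnonzero(lt.age == 0):
        p = int(lt.pop[i])
        if p not in leaf_states:
            raise ValueError(f"leaf population {p} has no assigned state")
        partial[i] = _leaf_log_indicator(k, leaf_states[p])
    for i in range(nn - 1):
        par = lt.parent[i]
        t = int(lt.age[par] - lt.age[i])
        logM = Q.log_power(t)
        partial[par] += np.logaddexp.reduce(logM + partial[i][None, :], axis=1)
    return partial[-1]


def _root_partials_linear(tree, Q: MutationMatrix, leaf_states) -> np.ndarray:
    """Linear-space pruning without scaling (cross-check route only)."""
    lt = _as_linear(tree)
    k = Q.k
    partial = np.ones((lt.n_nodes, k))
    for i in np.flatnonzero(lt.age == 0):
        v = np.zeros(k)
        v[leaf_states[int(lt.pop[i])]] = 1.0
        partial[i] = v
    for i in range(lt.n_nodes - 1):
        par = lt.parent[i]
        M = Q.power(int(lt.age[par] - lt.age[i]))
        partial[par] *= M @ partial[i]
    return partial[-1]


def pruning_likelihood(
    tree: Genealogy | LinearTree,
    Q: MutationMatrix,
    leaf_states: dict[int, int],
    root_state: int,
    log: bool = False,
    method: str = "log",
) -> float:
    """P(leaf states | Q, tree, root state) via Felsenstein pruning."""
    if not 0 <= root_state < Q.k:
        raise ValueError(f"root state {root_state} outside [0, {Q.k})")
    if method == "log":
        val = root_log_partials(tree, Q, leaf_states)[root_state]
        return float(val) if log else float(np.exp(val))
    if method == "linear":
        val = _root_partials_linear(tree, Q, leaf_states)[root_state]
        return float(np.log(val)) if log else float(val)
    raise ValueError(f"unknown method {method!r}")


def root_marginal_likelihood(
    tree: Genealogy | LinearTree,
    Q: MutationMatrix,
    leaf_states: dict[int, int],
    root_prior: np.ndarray,
    log: bool = False,
) -> float:
    """Likelihood with the root state marginalized over ``root_prior``."""
    root_prior = np.asarray(root_prior, dtype=float)
    if abs(root_prior.sum() - 1.0) > 1e-9:
        raise ValueError("root prior must sum to 1")
    lp = root_log_partials(tree, Q, leaf_states)
    with np.errstate(divide="ignore"):
        tot = np.logaddexp.reduce(np.log(root_prior) + lp)
    return float(tot) if log else float(np.exp(tot))
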