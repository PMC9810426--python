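"""Backward-in-time coalescent simulation on the population network.

Tracing a lineage backward, ``a_ij`` is the probability that a lineage
currently in ``P_i`` was in ``P_j`` one generation earlier (the population
``P_i`` copied from).  Two lineages coalesce the moment they occupy the
same population, because a population holds exactly one state copy.

The heuristic inference algorithm replaces the explicit history-matrix
prior with an empirical prior: draw transmission parameters from their
prior, simulate the coalescent to get a genealogy, and repeat, keeping
only draws whose lineages find a common ancestor within ``tau_max``
generations (the same conditioning as the exact model's TMRCA <= tau).
The retained (theta_tau, tree) pairs form an i.i.d. sample from
P(T', theta_tau | TMRCA <= tau) that the MCMC treats as the tree prior.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np

from .history import Genealogy, LinearTree, NoCoalescence, TreeNode
from .models import TransmissionSpec, transmission_matrix
from .priors import sample_params

__all__ = ["PriorTreePool", "sample_prior_tree", "build_prior_pool"]


def _cum_rows(A: np.ndarray) -> list[list[float]]:
    return [list(np.cumsum(row)) for row in np.asarray(A, dtype=float)]


def _simulate(cum: list[list[float]], leaves, tau_max: int, rng) -> Genealogy | NoCoalescence:
    lineages: dict[int, TreeNode] = {int(p): TreeNode(0, int(p)) for p in leaves}
    if len(lineages) == 1:
        return Genealogy(next(iter(lineages.values())))
    age = 0
    while age < tau_max:
        u = rng.random(len(lineages))
        moved: dict[int, list[TreeNode]] = {}
        for (p, node), up in zip(lineages.items(), u):
            dest = bisect_right(cum[p], up)
            moved.setdefault(dest, []).append(node)
        age += 1
        lineages = {}
        for dest, nodes in moved.items():
            if len(nodes) > 1:
                lineages[dest] = TreeNode(age, dest, children=nodes)
            else:
                lineages[dest] = nodes[0]
        if len(lineages) == 1:
            return Genealogy(next(iter(lineages.values())))
    return NoCoalescence(remaining=len(lineages))


def sample_prior_tree(
    A: np.ndarray,
    leaf_populations,
    tau_max: int,
    rng: np.random.Generator,
) -> Genealogy | NoCoalescence:
    """One backward coalescent draw for the given leaf populations.

    Conditional on returning a tree (rather than :class:`NoCoalescence`),
    this is an exact draw from P(T' | theta_tau, TMRCA <= tau_max): the
    lineage moves are precisely the distribution of the load-bearing
    history-matrix entries, with the off-lineage entries integrated out.
    """
    leaves = [int(p) for p in leaf_populations]
    if len(set(leaves)) != len(leaves):
        raise ValueError("leaf populations must be distinct")
    return _simulate(_cum_rows(A), leaves, tau_max, rng)


@dataclass
class PriorTreePool:
    """An i.i.d. sample of (theta_tau, genealogy) pairs from the tree prior."""

    trees: list[LinearTree]
    thetas: list[dict[str, float]]
    tau_max: int
    leaves: tuple[int, ...]
    attempted: int = 0

    def __len__(self) -> int:
        return len(self.trees)

    @property
    def rejection_fraction(self) -> float:
        return 1.0 - len(self.trees) / self.attempted if self.attempted else 0.0

    @property
    def tmrcas(self) -> np.ndarray:
        return np.array([t.tmrca for t in self.trees])

    def genealogy(self, i: int) -> Genealogy:
        return Genealogy.from_linear(self.trees[i])

    # -- persistence (NEXUS tree log + TSV of theta draws) ------------
    def save(self, tree_path, theta_path) -> None:
        from .io import write_nexus_trees, write_theta_table

        write_nexus_trees(tree_path, (self.genealogy(i) for i in range(len(self))),
                          self.leaves, tau_max=self.tau_max, attempted=self.attempted)
        write_theta_table(theta_path, self.thetas)


def build_prior_pool(
    spec: TransmissionSpec,
    theta_priors: dict,
    leaf_populations,
    pool_size: int,
    tau_max: int,
    seed: int | np.random.Generator = 0,
    max_rejection: float = 0.999,
    min_attempts: int = 2000,
) -> PriorTreePool:
    """Workflow steps A-C: repeatedly (draw theta_tau, simulate a tree).

    Failures to coalesce within ``tau_max`` are discarded together with
    their theta draw (joint conditioning on TMRCA <= tau_max).  Aborts with
    a diagnostic when the rejection fraction exceeds ``max_rejection`` after
    ``min_attempts`` attempts — the usual causes being tau_max too small or
    transmission too weak for lineages ever to meet.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    leaves = tuple(int(p) for p in leaf_populations)
    all_fixed = all(pr.fixed for pr in theta_priors.values())
    fixed_cum = None
    if all_fixed:
        theta0 = sample_params(theta_priors, rng)
        fixed_cum = _cum_rows(transmission_matrix(spec.with_params(**theta0)))
    trees: list[LinearTree] = []
    thetas: list[dict[str, float]] = []
    attempted = 0
    while len(trees) < pool_size:
        attempted += 1
        if all_fixed:
            theta, cum = theta0, fixed_cum
        else:
            theta = sample_params(theta_priors, rng)
            cum = _cum_rows(transmission_matrix(spec.with_params(**theta)))
        out = _simulate(cum, leaves, tau_max, rng)
        if isinstance(out, NoCoalescence):
            if attempted >= min_attempts and 1.0 - len(trees) / attempted > max_rejection:
                raise RuntimeError(
                    f"prior-tree rejection rate {1.0 - len(trees)/attempted:.4f} "
                    f"exceeds {max_rejection} after {attempted} attempts; "
                    "tau_max is likely too small or transmission too weak"
                )
            continue
        trees.append(out.to_linear())
        thetas.append(theta)
    return PriorTreePool(trees, thetas, tau_max, leaves, attempted)
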