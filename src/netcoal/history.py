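"""The latent transmission-history matrix G and the genealogies it induces.

``G`` is a ``tau x n`` integer matrix whose entry ``G[i, j]`` (0-based) names
the population from which ``P_j`` copied its state ``i`` generations ago
(row 0 is the present generation's copying event).  ``tau`` is prior
knowledge: the maximum possible age of the most recent common ancestor
(MRCA) of the traced state copies.

Tracing the observed populations' lineages backward through ``G`` — a
lineage sitting in population ``p`` at age ``g`` moves to ``G[g, p]`` at age
``g+1``, and lineages landing in the same population merge — yields the
single-trait genealogy ``T`` whose root is the MRCA.  Because a population
holds exactly one state, three or more co-located lineages merge into one
multifurcating node.

The prior of ``G`` given the transmission matrix ``A`` factorizes over its
entries: ``log P(G | theta_tau) = sum_ij c_ij log a_ij`` where ``c_ij``
counts how often ``P_i`` copied from ``P_j`` among the ``tau`` rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "HistoryMatrix",
    "Genealogy",
    "LinearTree",
    "TreeNode",
    "NoCoalescence",
    "transition_counts",
    "log_history_prior",
    "trace_lineages",
    "tmrca",
    "WORKED_EXAMPLE_G",
]

# Six-generation, five-population worked example used throughout the docs:
# tracing any four of the five present-day copies gives an MRCA in P_3
# (index 2) five generations ago.
WORKED_EXAMPLE_G = np.array(
    [
        [1, 2, 3, 4, 4],
        [2, 3, 2, 4, 5],
        [1, 3, 3, 5, 5],
        [1, 2, 3, 4, 4],
        [1, 3, 3, 3, 5],
        [2, 1, 3, 4, 5],
    ]
) - 1  # stored 0-based


@dataclass(frozen=True)
class HistoryMatrix:
    """Validated wrapper around the ``tau x n`` history matrix (0-based entries)."""

    g: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.g, dtype=int)
        if g.ndim != 2:
            raise ValueError("history matrix must be 2-D (tau x n)")
        if np.any((g < 0) | (g >= g.shape[1])):
            raise ValueError("history entries must be population indices in [0, n)")
        object.__setattr__(self, "g", g)

    @property
    def tau(self) -> int:
        return self.g.shape[0]

    @property
    def n(self) -> int:
        return self.g.shape[1]

    # CSV round trip uses 1-based entries, matching the printed convention
    def to_csv(self, path) -> None:
        np.savetxt(path, self.g + 1, fmt="%d", delimiter=",")

    @staticmethod
    def from_csv(path) -> "HistoryMatrix":
        return HistoryMatrix(np.loadtxt(path, delimiter=",", dtype=int, ndmin=2) - 1)


class TreeNode:
    """A genealogy node: integer age (generations before present) and population."""

    __slots__ = ("age", "population", "children", "parent", "support", "mean_age")

    def __init__(self, age: int, population: int, children=None):
        self.age = age
        self.population = population
        self.children: list[TreeNode] = children or []
        self.parent: TreeNode | None = None
        for ch in self.children:
            ch.parent = self
        self.support: float | None = None   # annotated by summaries.mcc_tree
        self.mean_age: float | None = None

    @property
    def branch_length(self) -> int | None:
        return None if self.parent is None else self.parent.age - self.age

    def is_leaf(self) -> bool:
        return not self.children


@dataclass(frozen=True)
class LinearTree:
    """Compact array encoding of a genealogy (child-before-parent order).

    ``parent[i]`` is the parent's index (-1 for the root, the last node);
    ``age[i]`` the node's age in generations; ``pop[i]`` its population.
    Leaves are the age-0 nodes.  Used for cheap pruning and for storing
    large prior-tree pools in tens of bytes per tree.
    """

    parent: np.ndarray
    age: np.ndarray
    pop: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def tmrca(self) -> int:
        return int(self.age[-1])

    @property
    def leaf_indices(self) -> np.ndarray:
        return np.flatnonzero(self.age == 0)

    @property
    def leaf_populations(self) -> np.ndarray:
        return self.pop[self.leaf_indices]

    def clades(self):
        """Yield (frozenset of leaf populations, node index) for every node."""
        sets = [frozenset() for _ in range(self.n_nodes)]
        for i in range(self.n_nodes):
            if self.age[i] == 0:
                sets[i] = frozenset([int(self.pop[i])])
        for i in range(self.n_nodes - 1):
            sets[self.parent[i]] = sets[self.parent[i]] | sets[i]
        return [(s, i) for i, s in enumerate(sets)]


class Genealogy:
    """Rooted, possibly multifurcating single-trait genealogy.

    Leaves are the traced populations (all at age 0); internal nodes are
    coalescences with strictly increasing ages root-ward; the root is the
    MRCA and its age is the TMRCA.  Branch lengths are integer generation
    counts, ``parent.age - child.age >= 1``.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        self.leaves = [nd for nd in self.iter_nodes() if nd.is_leaf()]

    def iter_nodes(self):
        stack = [self.root]
        while stack:
            nd = stack.pop()
            yield nd
            stack.extend(nd.children)

    @property
    def tmrca(self) -> int:
        return self.root.age

    @property
    def leaf_populations(self) -> list[int]:
        return sorted(nd.population for nd in self.leaves)

    def validate(self) -> None:
        for nd in self.iter_nodes():
            if nd.is_leaf():
                if nd.age != 0:
                    raise ValueError("leaf ages must all be 0")
            else:
                if len(nd.children) < 2:
                    raise ValueError("internal nodes need >= 2 children")
                for ch in nd.children:
                    if nd.age - ch.age < 1:
                        raise ValueError("branch lengths must be >= 1 generation")
        pops = [nd.population for nd in self.leaves]
        if len(set(pops)) != len(pops):
            raise ValueError("leaf populations must be distinct")

    # -- array encoding ----------------------------------------------
    def to_linear(self) -> LinearTree:
        nodes = sorted(self.iter_nodes(), key=lambda nd: nd.age)
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent = np.array(
            [-1 if nd.parent is None else index[id(nd.parent)] for nd in nodes],
            dtype=np.int32,
        )
        age = np.array([nd.age for nd in nodes], dtype=np.int32)
        pop = np.array([nd.population for nd in nodes], dtype=np.int32)
        return LinearTree(parent, age, pop)

    @staticmethod
    def from_linear(lt: LinearTree) -> "Genealogy":
        nodes = [TreeNode(int(a), int(p)) for a, p in zip(lt.age, lt.pop)]
        for i, par in enumerate(lt.parent):
            if par >= 0:
                nodes[par].children.append(nodes[i])
                nodes[i].parent = nodes[par]
        return Genealogy(nodes[-1])

    # -- Newick export -----------------------------------------------
    def newick(self, labels: dict[int, str] | None = None, comments: bool = True) -> str:
        """Newick string, branch lengths in generations, population comments.

        Leaf labels default to 1-based ``P<i>``; internal-node comments carry
        the population assignment (and clade support/mean age if annotated).
        """

        def lab(p: int) -> str:
            return labels[p] if labels else f"P{p + 1}"

        def meta(nd: TreeNode) -> str:
            if not comments:
                return ""
            parts = [f"population={nd.population + 1}"]
            if nd.support is not None:
                parts.append(f"posterior={nd.support:g}")
            if nd.mean_age is not None:
                parts.append(f"mean_age={nd.mean_age:g}")
            return "[&" + ",".join(parts) + "]"

        def rec(nd: TreeNode) -> str:
            if nd.is_leaf():
                core = lab(nd.population) + meta(nd)
            else:
                core = "(" + ",".join(rec(ch) for ch in nd.children) + ")" + meta(nd)
            if nd.parent is not None:
                core += f":{nd.parent.age - nd.age}"
            return core

        return rec(self.root) + ";"


@dataclass(frozen=True)
class NoCoalescence:
    """Tracing outcome when >1 lineage survives past tau (posterior weight 0)."""

    remaining: int


def _as_g(G) -> np.ndarray:
    return G.g if isinstance(G, HistoryMatrix) else np.asarray(G, dtype=int)


def transition_counts(G) -> np.ndarray:
    """c[i, j]: number of times P_i copied from P_j among the tau rows of G."""
    g = _as_g(G)
    tau, n = g.shape
    c = np.zeros((n, n), dtype=int)
    for col in range(n):
        c[col] = np.bincount(g[:, col], minlength=n)
    return c


def log_history_prior(c: np.ndarray, A: np.ndarray) -> float:
    """log P(G | theta_tau) = sum_ij c_ij log a_ij; -inf for unsupported G."""
    c = np.asarray(c)
    A = np.asarray(A, dtype=float)
    used = c > 0
    if np.any(A[used] <= 0.0):
        return -np.inf
    return float(np.sum(c[used] * np.log(A[used])))


def trace_lineages(G, leaf_populations, want_occupancy: bool = False):
    """Trace the leaf populations' lineages backward through G.

    Returns a :class:`Genealogy` (or :class:`NoCoalescence` if more than one
    lineage survives all ``tau`` rows).  With ``want_occupancy=True`` also
    returns a ``(tau, n)`` boolean array marking which populations host an
    active lineage at each age < TMRCA — exactly the entries of ``G`` that
    the realized tree depends on.
    """
    g = _as_g(G)
    tau, n = g.shape
    leaves = [int(p) for p in leaf_populations]
    if not leaves:
        raise ValueError("leaf population list must be non-empty")
    if len(set(leaves)) != len(leaves):
        raise ValueError("leaf populations must be distinct")
    if any(not 0 <= p < n for p in leaves):
        raise ValueError(f"leaf populations must lie in [0, {n})")

    occ = np.zeros((tau, n), dtype=bool) if want_occupancy else None
    lineages: dict[int, TreeNode] = {p: TreeNode(0, p) for p in leaves}
    result = None
    if len(lineages) == 1:
        result = Genealogy(next(iter(lineages.values())))
    age = 0
    while result is None and age < tau:
        if want_occupancy:
            occ[age, list(lineages)] = True
        moved: dict[int, list[TreeNode]] = {}
        row = g[age]
        for p, node in lineages.items():
            moved.setdefault(int(row[p]), []).append(node)
        age += 1
        lineages = {}
        for dest, nodes in moved.items():
            if len(nodes) > 1:
                lineages[dest] = TreeNode(age, dest, children=nodes)
            else:
                lineages[dest] = nodes[0]
        if len(lineages) == 1:
            node = next(iter(lineages.values()))
            if not node.is_leaf() or len(leaves) == 1:
                result = Genealogy(node)
    if result is None:
        result = NoCoalescence(remaining=len(lineages))
    return (result, occ) if want_occupancy else result


def tmrca(tree: Genealogy) -> int:
    """Root age of the genealogy: time to the most recent common ancestor."""
    return tree.tmrca
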