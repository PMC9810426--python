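"""Pruning-likelihood checks against an independent brute-force oracle.

The oracle enumerates every assignment of states to internal nodes and sums
the product of per-edge transition probabilities computed with plain
``numpy.linalg.matrix_power`` — sharing no code with the pruning recursion.
"""

import itertools

import numpy as np
import pytest

from conftest import random_genealogy
from netcoal import (
    Genealogy,
    MutationSpec,
    mutation_matrix,
    pruning_likelihood,
    root_marginal_likelihood,
)
from netcoal.history import TreeNode


def brute_force_likelihood(tree: Genealogy, Q: np.ndarray, leaf_states, root_state):
    nodes = list(tree.iter_nodes())
    internal = [nd for nd in nodes if not nd.is_leaf() and nd.parent is not None]
    k = Q.shape[0]

    def edge_prob(parent_state, child, child_state):
        M = np.linalg.matrix_power(Q, child.parent.age - child.age)
        return M[parent_state, child_state]

    def node_state(nd, assign):
        if nd.is_leaf():
            return leaf_states[nd.population]
        if nd.parent is None:
            return root_state
        return assign[id(nd)]

    total = 0.0
    for states in itertools.product(range(k), repeat=len(internal)):
        assign = {id(nd): s for nd, s in zip(internal, states)}
        prob = 1.0
        for nd in nodes:
            if nd.parent is None:
                continue
            prob *= edge_prob(node_state(nd.parent, assign), nd, node_state(nd, assign))
        total += prob
    return total


def all_binary_topologies(leaf_pops, ages):
    """All rooted binary tree shapes over the given leaf populations, with
    internal-node ages assigned root-down from the sorted ``ages`` list."""
    leaves = [TreeNode(0, p) for p in leaf_pops]

    def join(subtrees, remaining_ages):
        if len(subtrees) == 1:
            yield subtrees[0]
            return
        age = remaining_ages[0]
        for i, j in itertools.combinations(range(len(subtrees)), 2):
            rest = [s for t, s in enumerate(subtrees) if t not in (i, j)]
            node = TreeNode(age, subtrees[i].population,
                            children=[_clone(subtrees[i]), _clone(subtrees[j])])
            yield from join(rest + [node], remaining_ages[1:])

    # ages must decrease toward the leaves: join in decreasing-age order
    # reversed so the *last* join (the root) gets the largest age
    yield from join(leaves, sorted(ages, reverse=False))


def _clone(nd):
    c = TreeNode(nd.age, nd.population, children=[_clone(ch) for ch in nd.children])
    return c


def _fix_ages(root, base):
    """Reassign strictly increasing integer ages root-ward (post-fix pass)."""
    def depth(nd):
        return 0 if nd.is_leaf() else 1 + max(depth(c) for c in nd.children)

    def assign(nd):
        if nd.is_leaf():
            nd.age = 0
        else:
            for c in nd.children:
                assign(c)
            nd.age = max(c.age for c in nd.children) + base
    assign(root)
    return root


def enumerate_small_trees(max_leaves=4, k=2, rng=None):
    """All rooted binary topologies on 2..max_leaves leaves plus a star."""
    rng = rng or np.random.default_rng(0)
    out = []
    for m in range(2, max_leaves + 1):
        for shape in all_binary_topologies(list(range(m)), list(range(1, m))):
            root = _fix_ages(_clone(shape), base=int(rng.integers(1, 4)))
            out.append(Genealogy(root))
    star = Genealogy(TreeNode(3, 0, children=[TreeNode(0, p) for p in range(4)]))
    out.append(star)
    return out


class TestPruningAgainstBruteForce:
    def test_all_small_topologies_match_oracle(self, rng):
        for k in (2, 3):
            m = mutation_matrix(
                MutationSpec.explicit(rng.dirichlet(np.ones(k) * 2, size=k))
            )
            for tree in enumerate_small_trees(4, k, rng):
                leaf_states = {
                    p: int(rng.integers(k)) for p in tree.leaf_populations
                }
                for S in range(k):
                    got = pruning_likelihood(tree, m, leaf_states, S)
                    want = brute_force_likelihood(tree, m.Q, leaf_states, S)
                    assert got == pytest.approx(want, abs=1e-12)

    def test_total_probability_over_leaf_assignments(self, rng):
        # summing the likelihood over all k^m leaf-state assignments gives 1
        for k in (2, 3):
            m = mutation_matrix(
                MutationSpec.explicit(rng.dirichlet(np.ones(k) * 3, size=k))
            )
            tree = random_genealogy(4, rng)
            pops = tree.leaf_populations
            for S in range(k):
                tot = sum(
                    pruning_likelihood(tree, m, dict(zip(pops, assign)), S)
                    for assign in itertools.product(range(k), repeat=len(pops))
                )
                assert tot == pytest.approx(1.0, abs=1e-10)


class TestClosedFormCases:
    def test_identity_mutation_cherry(self):
        m = mutation_matrix(MutationSpec.uniform(2, 0.0))
        tree = Genealogy(TreeNode(2, 0, children=[TreeNode(0, 0), TreeNode(0, 1)]))
        assert pruning_likelihood(tree, m, {0: 1, 1: 1}, 1) == 1.0
        assert pruning_likelihood(tree, m, {0: 1, 1: 0}, 1) == 0.0

    def test_cherry_equals_product_of_transition_rows(self, two_state_q):
        # two leaves hanging off the root: the recursion's base case is the
        # product of one transition-matrix entry per branch
        j1, j2, S, t = 0, 1, 0, 7
        root = TreeNode(t, 0, children=[TreeNode(0, 0), TreeNode(0, 1)])
        tree = Genealogy(root)
        got = pruning_likelihood(tree, two_state_q, {0: j1, 1: j2}, S)
        want = two_state_q.power(t)[S, j1] * two_state_q.power(t)[S, j2]
        assert got == pytest.approx(want, rel=1e-12)

    def test_single_leaf_degenerate_tree(self, two_state_q):
        tree = Genealogy(TreeNode(0, 2))
        assert pruning_likelihood(tree, two_state_q, {2: 1}, 1) == 1.0
        assert pruning_likelihood(tree, two_state_q, {2: 1}, 0) == 0.0
        pi = two_state_q.stationary()
        assert root_marginal_likelihood(tree, two_state_q, {2: 1}, pi) == pytest.approx(pi[1])

    def test_identity_mutation_marginal_returns_prior_mass(self):
        m = mutation_matrix(MutationSpec.uniform(2, 0.0))
        tree = Genealogy(TreeNode(4, 0, children=[TreeNode(0, 0), TreeNode(0, 1)]))
        pi = np.array([0.7, 0.3])
        got = root_marginal_likelihood(tree, m, {0: 0, 1: 0}, pi)
        assert got == pytest.approx(0.7)


class TestNumericalRoutes:
    def test_marginal_equals_sum_over_root_states(self, rng, two_state_q):
        tree = random_genealogy(5, rng)
        ls = {p: int(rng.integers(2)) for p in tree.leaf_populations}
        pi = two_state_q.stationary()
        direct = sum(
            pi[S] * pruning_likelihood(tree, two_state_q, ls, S) for S in range(2)
        )
        assert root_marginal_likelihood(tree, two_state_q, ls, pi) == pytest.approx(
            direct, abs=1e-14
        )

    def test_log_and_linear_space_agree_on_long_branches(self, rng):
        m = mutation_matrix(MutationSpec.two_state(0.002, 0.004))
        root = TreeNode(10_000, 0, children=[TreeNode(0, 0), TreeNode(0, 1)])
        tree = Genealogy(root)
        for S in range(2):
            a = pruning_likelihood(tree, m, {0: 0, 1: 1}, S, log=True)
            b = pruning_likelihood(tree, m, {0: 0, 1: 1}, S, log=True, method="linear")
            assert a == pytest.approx(b, abs=1e-10)

    def test_child_order_invariance(self, rng, two_state_q):
        tree = random_genealogy(5, rng)
        ls = {p: int(rng.integers(2)) for p in tree.leaf_populations}
        base = pruning_likelihood(tree, two_state_q, ls, 0)
        for nd in tree.iter_nodes():
            nd.children.reverse()
        flipped = pruning_likelihood(tree, two_state_q, ls, 0)
        assert base == pytest.approx(flipped, rel=1e-14)

    def test_unassigned_leaf_rejected(self, two_state_q):
        tree = Genealogy(TreeNode(2, 0, children=[TreeNode(0, 0), TreeNode(0, 1)]))
        with pytest.raises(ValueError, match="no assigned state"):
            pruning_likelihood(tree, two_state_q, {0: 1}, 0)

    def test_state_outside_range_rejected(self, two_state_q):
        tree = Genealogy(TreeNode(2, 0, children=[TreeNode(0, 0), TreeNode(0, 1)]))
        with pytest.raises(ValueError):
            pruning_likelihood(tree, two_state_q, {0: 1, 1: 2}, 0)
        with pytest.raises(ValueError):
            pruning_likelihood(tree, two_state_q, {0: 1, 1: 1}, 5)
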