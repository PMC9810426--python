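import numpy as np
import pytest

from netcoal import (
    MutationSpec,
    ObservationSet,
    TransmissionSpec,
    WORKED_EXAMPLE_G,
    mutation_matrix,
    transmission_matrix,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def worked_g():
    """The six-generation, five-population worked history matrix."""
    return WORKED_EXAMPLE_G.copy()


@pytest.fixture
def two_state_q():
    return mutation_matrix(MutationSpec.two_state(0.04, 0.08))


@pytest.fixture
def tiny_obs():
    """Three-population island instance: two observed states, one target."""
    return ObservationSet(n=3, k=2, observed={0: 0, 1: 1}, infer_targets=[2])


@pytest.fixture
def tiny_tspec():
    return TransmissionSpec.island(3, 0.4)


@pytest.fixture
def tiny_mspec():
    return MutationSpec.two_state(0.1, 0.2)


def random_genealogy(n_leaves, rng, n_pops=None, c=0.7):
    """Random coalescent genealogy on distinct populations (tree generator)."""
    from netcoal import NoCoalescence, sample_prior_tree

    n_pops = n_pops or n_leaves + 2
    A = transmission_matrix(TransmissionSpec.island(n_pops, c))
    while True:
        out = sample_prior_tree(A, list(range(n_leaves)), 10_000, rng)
        if not isinstance(out, NoCoalescence):
            return out
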