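import numpy as np
import pytest

from netcoal import (
    Fixed,
    Genealogy,
    McmcConfig,
    MutationSpec,
    ObservationSet,
    PriorConfig,
    TransmissionSpec,
    Uniform,
    effective_sample_size,
    exact_posterior_enumeration,
    mutation_matrix,
    posterior_state_marginals,
    pruning_likelihood,
    run_mcmc_exact,
    run_mcmc_heuristic,
    tmrca_distribution,
    total_variation,
)
from netcoal.coalescent import PriorTreePool
from netcoal.history import TreeNode, transition_counts, log_history_prior
from netcoal.inference import TraceSample, Trace
from netcoal.likelihood import root_log_partials


@pytest.fixture(scope="module")
def tiny_posterior():
    obs = ObservationSet(n=3, k=2, observed={0: 0, 1: 1}, infer_targets=[2])
    tspec = TransmissionSpec.island(3, 0.4)
    mspec = MutationSpec.two_state(0.1, 0.2)
    enum = exact_posterior_enumeration(obs, tspec, mspec, tau=3)
    return obs, tspec, mspec, enum


class TestExactSampler:
    def test_matches_enumeration_on_tiny_instance(self, tiny_posterior):
        obs, tspec, mspec, enum = tiny_posterior
        priors = PriorConfig(
            transmission={"c": Fixed(0.4)},
            mutation={"q12": Fixed(0.1), "q21": Fixed(0.2)},
        )
        cfg = McmcConfig(sweeps=20_000, thin=2, seed=11, g_moves_per_sweep=5)
        tr = run_mcmc_exact(obs, tspec, mspec, priors, cfg, tau=3)
        px = posterior_state_marginals(tr)[2]
        ps = np.bincount([s.S for s in tr.samples], minlength=2) / len(tr)
        tm = tmrca_distribution(tr)
        tmv = np.array([tm.get(t, 0.0) for t in range(4)])
        assert total_variation(px, enum.p_x[2]) < 0.02
        assert total_variation(ps, enum.p_s) < 0.02
        assert total_variation(tmv, enum.tmrca_vector(3)) < 0.02

    def test_state_relabel_symmetry(self):
        # symmetric mutation + symmetric data: relabeling states 1<->2 and
        # swapping the two observed populations maps the posterior to
        # itself, so P(X = 1) must be exactly 1/2 in the enumeration and
        # within Monte-Carlo error for the sampler
        obs = ObservationSet(n=3, k=2, observed={0: 0, 1: 1}, infer_targets=[2])
        tspec = TransmissionSpec.island(3, 0.5)
        mspec = MutationSpec.two_state(0.15, 0.15)
        enum = exact_posterior_enumeration(obs, tspec, mspec, tau=3)
        assert enum.p_x[2][0] == pytest.approx(0.5, abs=1e-12)
        priors = PriorConfig(
            transmission={"c": Fixed(0.5)},
            mutation={"q12": Fixed(0.15), "q21": Fixed(0.15)},
        )
        cfg = McmcConfig(sweeps=8000, thin=2, seed=5, g_moves_per_sweep=5)
        tr = run_mcmc_exact(obs, tspec, mspec, priors, cfg, tau=3)
        assert posterior_state_marginals(tr)[2][0] == pytest.approx(0.5, abs=0.03)

    def test_prior_recovery_with_zero_information_data(self):
        # a single observed population and a uniform root prior make the
        # likelihood constant in the mutation rates, so their posterior
        # must reproduce the uniform prior's moments
        obs = ObservationSet(n=3, k=2, observed={1: 0})
        tspec = TransmissionSpec.island(3, 0.4)
        mspec = MutationSpec.two_state(0.05, 0.05, root_prior="uniform")
        priors = PriorConfig(
            transmission={"c": Fixed(0.4)},
            mutation={"q12": Uniform(0.0, 0.1), "q21": Uniform(0.0, 0.1)},
        )
        cfg = McmcConfig(sweeps=8000, thin=2, seed=6, g_moves_per_sweep=3)
        tr = run_mcmc_exact(obs, tspec, mspec, priors, cfg, tau=3)
        for name in ("q12", "q21"):
            x = tr.series(name)
            assert x.mean() == pytest.approx(0.05, abs=0.004)
            assert x.std() == pytest.approx(0.1 / np.sqrt(12), rel=0.15)

    def test_log_posterior_reproducible_from_recorded_state(self, tiny_posterior):
        obs, tspec, mspec, _ = tiny_posterior
        priors = PriorConfig(
            transmission={"c": Fixed(0.4)},
            mutation={"q12": Fixed(0.1), "q21": Fixed(0.2)},
        )
        cfg = McmcConfig(sweeps=500, thin=10, seed=7, store_history=True)
        tr = run_mcmc_exact(obs, tspec, mspec, priors, cfg, tau=3)
        from netcoal.models import transmission_matrix

        A = transmission_matrix(tspec)
        for s in tr.samples:
            Qm = mutation_matrix(mspec.with_params(**s.theta_mu))
            leaf_states = dict(obs.observed)
            leaf_states.update(s.X)
            ll = float(root_log_partials(s.tree, Qm, leaf_states)[s.S])
            assert ll == pytest.approx(s.log_likelihood, abs=1e-9)
            lp = log_history_prior(transition_counts(s.history), A)
            assert lp == pytest.approx(s.log_tree_prior, abs=1e-9)
            pi = Qm.root_prior_vector()
            assert np.log(pi[s.S]) == pytest.approx(s.log_root_prior, abs=1e-9)

    def test_detailed_balance_on_coarse_bins(self, tiny_posterior):
        # random-scan mode applies one reversible kernel per iteration, so
        # the stationary chain's empirical flows between (S, X) bins are
        # symmetric up to Monte-Carlo noise
        obs, tspec, mspec, _ = tiny_posterior
        priors = PriorConfig(
            transmission={"c": Fixed(0.4)},
            mutation={"q12": Fixed(0.1), "q21": Fixed(0.2)},
        )
        cfg = McmcConfig(sweeps=60_000, burn_in=0.1, thin=1, seed=8,
                         g_moves_per_sweep=5, scan="random")
        tr = run_mcmc_exact(obs, tspec, mspec, priors, cfg, tau=3)
        bins = [2 * s.S + s.X[2] for s in tr.samples]
        flows = np.zeros((4, 4))
        for a, b in zip(bins[:-1], bins[1:]):
            flows[a, b] += 1
        for i in range(4):
            for j in range(i + 1, 4):
                tot = flows[i, j] + flows[j, i]
                if tot > 50:
                    z = abs(flows[i, j] - flows[j, i]) / np.sqrt(tot)
                    assert z < 5.0

    def test_impossible_initialization_aborts(self):
        # identity transmission: lineages from distinct populations can
        # never coalesce, so no valid starting history exists
        obs = ObservationSet(n=3, k=2, observed={0: 0, 1: 1})
        tspec = TransmissionSpec.island(3, 0.0)
        mspec = MutationSpec.two_state(0.1, 0.1)
        priors = PriorConfig(transmission={"c": Fixed(0.0)},
                             mutation={"q12": Fixed(0.1), "q21": Fixed(0.1)})
        with pytest.raises(RuntimeError, match="no coalescing"):
            run_mcmc_exact(obs, tspec, mspec, priors,
                           McmcConfig(sweeps=10, seed=0, init_retries=20), tau=4)


class TestHeuristicSampler:
    def test_matches_enumeration_on_tiny_instance(self, tiny_posterior):
        obs, tspec, mspec, enum = tiny_posterior
        from netcoal import build_prior_pool

        pool = build_prior_pool(tspec, {"c": Fixed(0.4)}, obs.leaves, 100_000, 3, seed=21)
        priors = PriorConfig(mutation={"q12": Fixed(0.1), "q21": Fixed(0.2)})
        cfg = McmcConfig(sweeps=20_000, thin=2, seed=22)
        tr = run_mcmc_heuristic(obs, pool, mspec, priors, cfg)
        px = posterior_state_marginals(tr)[2]
        ps = np.bincount([s.S for s in tr.samples], minlength=2) / len(tr)
        tm = tmrca_distribution(tr)
        tmv = np.array([tm.get(t, 0.0) for t in range(4)])
        assert total_variation(px, enum.p_x[2]) < 0.03
        assert total_variation(ps, enum.p_s) < 0.03
        assert total_variation(tmv, enum.tmrca_vector(3)) < 0.03

    def test_single_tree_pool_reduces_to_fixed_tree_gibbs(self):
        # pool of identical trees: the tree marginal is that tree with
        # probability one, and the X marginal matches the direct conditional
        # computed by pruning on that tree
        root = TreeNode(4, 2, children=[TreeNode(0, 0),
                                        TreeNode(0, 1),
                                        TreeNode(0, 2)])
        lt = Genealogy(root).to_linear()
        pool = PriorTreePool([lt] * 2000, [{"c": 0.3}] * 2000, 10, (0, 1, 2))
        obs = ObservationSet(n=3, k=2, observed={0: 0, 1: 1}, infer_targets=[2])
        mspec = MutationSpec.two_state(0.1, 0.2)
        Qm = mutation_matrix(mspec)
        pi = Qm.root_prior_vector()
        w = np.zeros(2)
        for x in range(2):
            for S in range(2):
                w[x] += pi[S] * pruning_likelihood(lt, Qm, {0: 0, 1: 1, 2: x}, S)
        expected = w / w.sum()
        priors = PriorConfig(mutation={"q12": Fixed(0.1), "q21": Fixed(0.2)})
        cfg = McmcConfig(sweeps=12_000, thin=2, seed=30)
        tr = run_mcmc_heuristic(obs, pool, mspec, priors, cfg)
        assert all(s.tree is lt for s in tr.samples)
        px = posterior_state_marginals(tr)[2]
        assert total_variation(px, expected) < 0.02

    def test_leaf_set_mismatch_rejected(self, tiny_posterior):
        obs, tspec, mspec, _ = tiny_posterior
        from netcoal import build_prior_pool

        pool = build_prior_pool(tspec, {"c": Fixed(0.4)}, [0, 1], 1500, 5, seed=31)
        priors = PriorConfig(mutation={"q12": Fixed(0.1), "q21": Fixed(0.2)})
        with pytest.raises(ValueError, match="leaf set"):
            run_mcmc_heuristic(obs, pool, mspec, priors, McmcConfig(sweeps=10, seed=0))

    def test_tiny_pool_warns(self, tiny_posterior):
        obs, tspec, mspec, _ = tiny_posterior
        from netcoal import build_prior_pool

        pool = build_prior_pool(tspec, {"c": Fixed(0.4)}, obs.leaves, 200, 3, seed=32)
        priors = PriorConfig(mutation={"q12": Fixed(0.1), "q21": Fixed(0.2)})
        with pytest.warns(RuntimeWarning, match="pool"):
            run_mcmc_heuristic(obs, pool, mspec, priors, McmcConfig(sweeps=50, seed=1))


class TestPosteriorSummaries:
    def _toy_trace(self, xs, pop=7):
        samples = [
            TraceSample(iteration=i, theta_tau={}, theta_mu={}, S=0, X={pop: x},
                        tree=None, tmrca=1, log_likelihood=0.0, log_tree_prior=0.0,
                        log_root_prior=0.0, log_posterior=0.0)
            for i, x in enumerate(xs)
        ]
        return Trace(samples, {}, "exact_G", 0)

    def test_marginals_match_hand_count(self):
        tr = self._toy_trace([0, 1, 1, 0, 1, 1, 1, 0, 1, 1])
        marg = posterior_state_marginals(tr)[7]
        assert np.allclose(marg, [0.3, 0.7])
        assert marg.sum() == 1.0

    def test_unanimous_trace_gives_certainty(self):
        tr = self._toy_trace([1] * 10)
        assert posterior_state_marginals(tr)[7][1] == 1.0

    def test_non_target_population_rejected(self):
        tr = self._toy_trace([0, 1])
        with pytest.raises(ValueError, match="not an inference target"):
            posterior_state_marginals(tr, populations=[3])


class TestEffectiveSampleSize:
    def test_white_noise_ess_near_sample_count(self):
        x = np.random.default_rng(0).normal(size=10_000)
        ess = effective_sample_size(x)
        assert 8_000 <= ess <= 12_000

    def test_ar1_matches_closed_form(self):
        # AR(1) with autocorrelation rho has ESS = N (1-rho)/(1+rho)
        rho, N = 0.9, 100_000
        rng = np.random.default_rng(1)
        x = np.empty(N)
        x[0] = rng.normal()
        eps = rng.normal(size=N) * np.sqrt(1 - rho**2)
        for i in range(1, N):
            x[i] = rho * x[i - 1] + eps[i]
        ess = effective_sample_size(x)
        expected = N * (1 - rho) / (1 + rho)
        assert ess == pytest.approx(expected, rel=0.25)

    def test_agrees_with_arviz_on_correlated_series(self):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            import arviz

        rho, N = 0.8, 20_000
        rng = np.random.default_rng(2)
        x = np.empty(N)
        x[0] = rng.normal()
        eps = rng.normal(size=N) * np.sqrt(1 - rho**2)
        for i in range(1, N):
            x[i] = rho * x[i - 1] + eps[i]
        ours = effective_sample_size(x)
        theirs = float(arviz.ess(x))
        assert ours == pytest.approx(theirs, rel=0.25)

    def test_constant_trace_flagged(self):
        with pytest.warns(RuntimeWarning, match="constant"):
            assert np.isnan(effective_sample_size(np.ones(500)))

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="100"):
            effective_sample_size(np.arange(50))
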