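"""Correctness of the MCMC kernels: slice assignment moves, conjugate stick
updates, Metropolis-Hastings prevalence updates, and the chain driver."""

import numpy as np
import pytest
from scipy import stats

import clonaltree.likelihood as lik
from clonaltree.likelihood import BulkData, ScReadMatrix, ScRnaHyperparams
from clonaltree.sampler import (
    SamplerConfig,
    TreeSampler,
    assign_cells,
    map_estimate,
    run_mcmc,
)
from clonaltree.simulate import SimulationConfig, simulate_dataset
from clonaltree.tree import ClonalTree, StickState, TssbHyperparams


def _dummy_bulk(n_snvs=1, n_regions=1):
    """Bulk table with zero depth: flat likelihood everywhere."""
    shape = (n_snvs, n_regions)
    return BulkData(
        snv_ids=[f"s{i}" for i in range(n_snvs)],
        b=np.zeros(shape, dtype=int),
        d=np.zeros(shape, dtype=int),
        M=np.ones(n_snvs, dtype=int),
        m=np.ones(n_snvs, dtype=int),
        regions=[f"R{j}" for j in range(n_regions)],
    )


def _frozen_chain_sampler(pis, weights, seed=0):
    """Sampler on a frozen chain of len(pis) cancer nodes with injected
    per-node data log-likelihoods.  Sticks are set so node k has mass pis[k]
    and the partition is exhausted (no lazy growth possible)."""
    paths = [(0,) * (k + 1) for k in range(len(pis))]
    tree = ClonalTree([(), *paths])
    sticks = StickState()
    remaining = 1.0
    for k, p in enumerate(paths):
        nu = pis[k] / remaining if k < len(paths) - 1 else 1.0
        sticks.nu[p] = nu
        sticks.psi[p] = [1.0] if k < len(paths) - 1 else []
        remaining *= 1.0 - nu if nu < 1 else 0.0
    table = {p: np.log(w) for p, w in zip(paths, weights)}
    config = SamplerConfig(n_iterations=2, burn_in=1, seed=seed, prune_empty=False)
    sampler = TreeSampler(
        _dummy_bulk(), None, config,
        loglik_override=lambda n, path: table.get(tuple(path), -1e9),
    )
    phi = {(): np.ones(1)}
    val = 0.9
    for p in paths:
        phi[p] = np.array([val])
        val *= 0.5
    sampler.set_state(tree, sticks, [paths[0]], phi)
    return sampler, paths


class TestSliceKernel:
    def test_single_permissible_node_never_moves(self):
        sampler, paths = _frozen_chain_sampler([1.0], [1.0])
        for _ in range(50):
            sampler.slice_resample_assignment(0)
            assert sampler.z[0] == paths[0]

    def test_two_equal_weight_nodes_split_evenly(self):
        # target P(v) proportional to pi_v * w_v = (0.5, 0.5)
        sampler, paths = _frozen_chain_sampler([0.5, 0.5], [1.0, 1.0], seed=11)
        hits = 0
        n_draws = 10_000
        for _ in range(n_draws):
            sampler.slice_resample_assignment(0)
            hits += sampler.z[0] == paths[1]
        se = np.sqrt(0.25 / n_draws)
        assert abs(hits / n_draws - 0.5) < 3 * se

    def test_enumerated_conditional_1_2_7(self):
        # equal stick masses, likelihood ratios 1:2:7 -> frequencies .1/.2/.7
        sampler, paths = _frozen_chain_sampler(
            [1 / 3, 1 / 3, 1 / 3], [1.0, 2.0, 7.0], seed=13
        )
        n_draws = 10_000
        counts = {p: 0 for p in paths}
        for _ in range(n_draws):
            sampler.slice_resample_assignment(0)
            counts[sampler.z[0]] += 1
        for p, target in zip(paths, [0.1, 0.2, 0.7]):
            se = np.sqrt(target * (1 - target) / n_draws)
            assert abs(counts[p] / n_draws - target) < 3 * se


class TestGibbsSticks:
    def _sampler_with_counts(self, tree, z, tssb, seed=0):
        config = SamplerConfig(n_iterations=2, burn_in=1, seed=seed, tssb=tssb)
        sampler = TreeSampler(_dummy_bulk(len(z)), None, config)
        sticks = StickState()
        for p in tree.nodes:
            if p:
                sticks.nu[p] = 0.5
                sticks.psi[p] = [0.5] * len(tree.children(p))
        phi = {(): np.ones(1)}
        for p in tree.nodes:
            if p:
                phi[p] = np.array([0.9 ** len(p) * 0.5])
        sampler.set_state(tree, sticks, z, phi)
        return sampler

    def test_nu_posterior_is_conjugate_beta(self):
        # all N SNVs at the root child, lambda0 = lam = 1: nu ~ Beta(1 + N, 1)
        n = 12
        tree = ClonalTree()
        sampler = self._sampler_with_counts(
            tree, [(0,)] * n, TssbHyperparams(1.0, 1.0, 1.0), seed=3
        )
        draws = []
        for _ in range(4000):
            sampler.gibbs_resample_sticks()
            draws.append(sampler.sticks.nu[(0,)])
        ks = stats.kstest(draws, stats.beta(1 + n, 1).cdf)
        assert ks.pvalue > 1e-3
        assert np.mean(draws) == pytest.approx((1 + n) / (2 + n), abs=0.01)

    def test_psi_posterior_at_binary_split(self):
        # counts (3 left, 1 right), gamma = 1: psi_1 ~ Beta(4, 2)
        tree = ClonalTree([(), (0,), (0, 0), (0, 1)])
        z = [(0, 0)] * 3 + [(0, 1)]
        sampler = self._sampler_with_counts(tree, z, TssbHyperparams(1.0, 1.0, 1.0), seed=5)
        draws = []
        for _ in range(4000):
            sampler.gibbs_resample_sticks()
            draws.append(sampler.sticks.psi[(0,)][0])
        ks = stats.kstest(draws, stats.beta(4, 2).cdf)
        assert ks.pvalue > 1e-3

    def test_empty_nodes_draw_from_the_prior(self):
        # a childless, SNV-free node's nu comes from Beta(1, lambda0 lam^depth)
        tree = ClonalTree([(), (0,), (0, 0)])
        tssb = TssbHyperparams(2.0, 0.5, 1.0)
        sampler = self._sampler_with_counts(tree, [(0,)] * 4, tssb, seed=7)
        draws = []
        for _ in range(4000):
            sampler.gibbs_resample_sticks()
            draws.append(sampler.sticks.nu[(0, 0)])
        ks = stats.kstest(draws, stats.beta(1, 2.0 * 0.5).cdf)
        assert ks.pvalue > 1e-3


class TestMhPrevalences:
    def test_likelihood_free_chain_recovers_dirichlet_prior(self):
        # with zero-depth bulk data the eta posterior is the Dirichlet(1) prior
        config = SamplerConfig(
            n_iterations=2, burn_in=1, seed=21, mh_steps=5, mh_concentration=2.0
        )
        sampler = TreeSampler(_dummy_bulk(2), None, config)
        tree = ClonalTree([(), (0,), (0, 0)])
        sticks = StickState(nu={(0,): 0.5, (0, 0): 0.5}, psi={(0,): [0.5], (0, 0): []})
        sampler.set_state(
            tree, sticks, [(0,), (0, 0)],
            {(): np.ones(1), (0,): np.array([0.6]), (0, 0): np.array([0.2])},
        )
        etas = []
        for _ in range(20_000):
            sampler.mh_update_prevalences()
            etas.append(sampler._eta_mat()[:, 0].copy())
        etas = np.asarray(etas)
        # Dirichlet(1,1,1): mean 1/3, E[x^2] = 1/6 per component
        assert np.allclose(etas.mean(axis=0), 1 / 3, atol=0.02)
        assert np.allclose((etas**2).mean(axis=0), 1 / 6, atol=0.02)

    def test_prevalence_recovery_two_clone_chain(self):
        # deep bulk data (d = 10000) at known phi: posterior mean within 0.02
        rng = np.random.default_rng(17)
        true_phi = {(0,): 0.8, (0, 0): 0.3}
        n_per_clone = 5
        z = [(0,)] * n_per_clone + [(0, 0)] * n_per_clone
        d = np.full((2 * n_per_clone, 1), 10_000)
        # theta for the lone genotype (1, 2): phi/2 + (1 - phi) * eps
        th = np.array(
            [0.5 * true_phi[tuple(p)] + (1 - true_phi[tuple(p)]) * 0.001 for p in z]
        )[:, None]
        b = rng.binomial(d, th)
        bulk = BulkData(
            [f"s{i}" for i in range(2 * n_per_clone)], b, d,
            np.ones(2 * n_per_clone, int), np.ones(2 * n_per_clone, int), ["R0"],
        )
        config = SamplerConfig(n_iterations=2, burn_in=1, seed=23, mh_steps=2)
        sampler = TreeSampler(bulk, None, config)
        tree = ClonalTree([(), (0,), (0, 0)])
        sticks = StickState(nu={(0,): 0.5, (0, 0): 0.5}, psi={(0,): [0.5], (0, 0): []})
        sampler.set_state(
            tree, sticks, z,
            {(): np.ones(1), (0,): np.array([0.5]), (0, 0): np.array([0.25])},
        )
        phis = []
        for _ in range(3000):
            sampler.mh_update_prevalences()
            phis.append(sampler.phi_mat[:, 0].copy())
        mean_phi = np.asarray(phis)[500:].mean(axis=0)
        assert mean_phi[1] == pytest.approx(0.8, abs=0.02)
        assert mean_phi[2] == pytest.approx(0.3, abs=0.02)

    def test_acceptance_rate_is_tracked(self):
        config = SamplerConfig(n_iterations=2, burn_in=1, seed=1, mh_steps=5)
        sampler = TreeSampler(_dummy_bulk(), None, config)
        sampler.mh_update_prevalences()
        assert sampler.mh_proposals == 5
        assert 0 <= sampler.mh_accepts <= 5


class TestRunMcmc:
    def test_fixed_seed_gives_bit_identical_traces(self):
        cfg = SimulationConfig(n_snvs=20, n_cells=30, seed=5)
        truth, bulk, sc = simulate_dataset(cfg)
        sconf = SamplerConfig(n_iterations=40, burn_in=20, seed=9)
        t1 = run_mcmc(bulk, sc, sconf, sc_hyper=truth.sc_hyper)
        t2 = run_mcmc(bulk, sc, sconf, sc_hyper=truth.sc_hyper)
        np.testing.assert_array_equal(t1.log_joint, t2.log_joint)
        assert [s.z for s in t1.samples] == [s.z for s in t2.samples]

    def test_zero_cells_reduces_to_bulk_only_sampler(self):
        cfg = SimulationConfig(n_snvs=15, n_cells=10, seed=6)
        truth, bulk, sc = simulate_dataset(cfg)
        empty_sc = ScReadMatrix([], bulk.snv_ids, [], [], [], [])
        sconf = SamplerConfig(n_iterations=30, burn_in=10, seed=2)
        t_none = run_mcmc(bulk, None, sconf)
        t_empty = run_mcmc(bulk, empty_sc, sconf)
        np.testing.assert_array_equal(t_none.log_joint, t_empty.log_joint)

    def test_mismatched_snv_ids_rejected(self):
        cfg = SimulationConfig(n_snvs=5, n_cells=5, seed=1)
        truth, bulk, sc = simulate_dataset(cfg)
        sc.snv_ids = [f"other{i}" for i in range(5)]
        with pytest.raises(ValueError, match="align"):
            TreeSampler(bulk, sc, SamplerConfig(n_iterations=2, burn_in=1))

    def test_trace_bookkeeping(self):
        cfg = SimulationConfig(n_snvs=10, n_cells=0, seed=3)
        truth, bulk, _ = simulate_dataset(cfg)
        sconf = SamplerConfig(n_iterations=25, burn_in=10, thinning=3, seed=4)
        trace = run_mcmc(bulk, None, sconf)
        assert len(trace.log_joint) == 25
        assert len(trace.samples) == 5  # ceil((25 - 10) / 3)
        assert np.all(np.isfinite(trace.log_joint))

    def test_cached_state_matches_full_recomputation(self):
        # after 100 sweeps the incremental caches agree with a from-scratch
        # evaluation of every term
        cfg = SimulationConfig(n_snvs=15, n_cells=20, seed=8)
        truth, bulk, sc = simulate_dataset(cfg)
        sconf = SamplerConfig(n_iterations=2, burn_in=1, seed=12)
        sampler = TreeSampler(bulk, sc, sconf, sc_hyper=truth.sc_hyper)
        for _ in range(100):
            sampler.sweep()
        from clonaltree.tree import PrevalenceField

        field = PrevalenceField(
            phi={k: v.copy() for k, v in sampler.phi.items()}, regions=bulk.regions
        )
        fresh = lik.log_joint(
            sampler.tree, sampler.sticks, sampler.z, field, bulk, sc, truth.sc_hyper
        )
        assert sampler.log_joint() == pytest.approx(fresh, abs=1e-6)


class TestMapAndCells:
    def test_map_estimate_selects_maximum_and_breaks_ties_early(self):
        cfg = SimulationConfig(n_snvs=10, n_cells=0, seed=3)
        _, bulk, _ = simulate_dataset(cfg)
        trace = run_mcmc(bulk, None, SamplerConfig(n_iterations=20, burn_in=5, seed=1))
        best = map_estimate(trace)
        assert best.log_joint == max(s.log_joint for s in trace.samples)
        firsts = [s for s in trace.samples if s.log_joint == best.log_joint]
        assert best.iteration == firsts[0].iteration

    def test_map_estimate_requires_samples(self):
        from clonaltree.sampler import PosteriorTrace

        with pytest.raises(ValueError):
            map_estimate(PosteriorTrace(np.array([]), np.array([]), []))

    def test_uncovered_cell_gets_uniform_posterior(self):
        cfg = SimulationConfig(n_snvs=8, n_cells=6, seed=7, p_cov=0.5)
        truth, bulk, sc = simulate_dataset(cfg)
        # append a cell with no reads
        sc2 = ScReadMatrix(
            sc.cell_ids + ["empty"], sc.snv_ids, sc.cell_idx, sc.snv_idx, sc.b, sc.d
        )
        trace = run_mcmc(bulk, sc2, SamplerConfig(n_iterations=20, burn_in=10, seed=2), sc_hyper=truth.sc_hyper)
        best = map_estimate(trace)
        post = assign_cells(best, sc2, truth.sc_hyper)
        row = post.probabilities[-1]
        assert np.allclose(row, 1 / len(post.nodes), atol=1e-12)
        assert np.allclose(post.probabilities.sum(axis=1), 1.0)

    def test_assignment_matches_per_cell_enumeration(self):
        # posterior row equals softmax of per-node cell likelihoods computed
        # independently via the scalar site likelihood
        from clonaltree.likelihood import scrna_site_loglik
        from clonaltree.tree import is_ancestor_or_equal

        cfg = SimulationConfig(n_snvs=6, n_cells=5, seed=9, p_cov=0.6)
        truth, bulk, sc = simulate_dataset(cfg)
        trace = run_mcmc(bulk, sc, SamplerConfig(n_iterations=15, burn_in=5, seed=3), sc_hyper=truth.sc_hyper)
        best = map_estimate(trace)
        post = assign_cells(best, sc, truth.sc_hyper)
        alpha, beta, delta0 = truth.sc_hyper.per_snv(sc.n_snvs)
        for c in range(sc.n_cells):
            raw = []
            for node in post.nodes:
                total = 0.0
                for e in range(sc.n_entries):
                    if sc.cell_idx[e] != c:
                        continue
                    n = int(sc.snv_idx[e])
                    mu = 1 if is_ancestor_or_equal(tuple(best.z[n]), node) else 0
                    total += scrna_site_loglik(
                        int(sc.b[e]), int(sc.d[e]), mu, truth.sc_hyper,
                        alpha_n=float(alpha[n]), beta_n=float(beta[n]),
                        delta0_n=float(delta0[n]),
                    )
                raw.append(total)
            raw = np.asarray(raw)
            expected = np.exp(raw - raw.max())
            expected /= expected.sum()
            np.testing.assert_allclose(post.probabilities[c], expected, atol=1e-10)

    def test_mu_hat_matches_map_node_ancestry(self):
        cfg = SimulationConfig(n_snvs=6, n_cells=5, seed=10, p_cov=0.6)
        truth, bulk, sc = simulate_dataset(cfg)
        trace = run_mcmc(bulk, sc, SamplerConfig(n_iterations=15, burn_in=5, seed=3), sc_hyper=truth.sc_hyper)
        best = map_estimate(trace)
        post = assign_cells(best, sc, truth.sc_hyper)
        from clonaltree.tree import mutation_status

        tree = best.tree()
        for c, node in enumerate(post.map_nodes):
            np.testing.assert_array_equal(post.mu_hat[c], mutation_status(tree, best.z, node))
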