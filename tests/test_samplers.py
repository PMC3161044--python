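import math

import numpy as np
import pytest

import dpclust as dc
from dpclust import _kernels
from dpclust.mcmc import SamplerState

from helpers import exact_posterior


def _empirical_tv(a1, a2, J, alpha, lam, sams_per_cycle, iters, seed):
    parts, post = exact_posterior(a1, a2, J, alpha, lam)
    idx = {p: i for i, p in enumerate(parts)}
    trace = dc.run_mcmc((a1, a2, J), alpha=alpha, lam=lam, iterations=iters,
                        burn_in=min(2000, iters // 10), thin=1,
                        sams_per_cycle=sams_per_cycle, seed=seed)
    emp = np.zeros(len(parts))
    for row in trace.partitions:
        emp[idx[tuple(row)]] += 1
    emp /= emp.sum()
    return 0.5 * np.abs(emp - post).sum()


class TestGibbs:
    def test_single_individual_stays_singleton(self):
        a1 = np.array([[0]], dtype=np.int64)
        a2 = np.array([[1]], dtype=np.int64)
        st = SamplerState.from_arrays(a1, a2, np.array([2]), alpha=1.0)
        for _ in range(5):
            st.gibbs_scan()
            assert st.K == 1 and st.labels[0] == 0
        assert st.consistent()

    def test_visits_match_enumerated_posterior_small(self, tiny_snp):
        a1, a2, J = tiny_snp
        tv = _empirical_tv(a1[:4], a2[:4], J, 1.0, 1.0, 0, 40_000, seed=5)
        assert tv < 0.03

    def test_identical_individuals_coassigned_above_prior(self):
        # two copies of one strongly informative genotype: posterior
        # co-assignment must exceed the prior co-assignment 1/(1+alpha)
        rng = np.random.default_rng(2)
        g = rng.integers(0, 2, (1, 20))
        a1 = np.vstack([g, g]).astype(np.int64)
        a2 = a1.copy()
        J = np.full(20, 2)
        alpha = 1.0
        trace = dc.run_mcmc((a1, a2, J), alpha=alpha, lam=0.2, iterations=4000,
                            thin=1, sams_per_cycle=0, seed=3)
        co = np.mean(trace.partitions[:, 0] == trace.partitions[:, 1])
        assert co > 1 / (1 + alpha)


class TestSams:
    def test_counts_consistent_after_many_moves(self, two_pop_table):
        table, _ = two_pop_table
        st = SamplerState.from_table(table, alpha=0.5, lam=1.0, init="crp",
                                     rng=np.random.default_rng(0))
        _kernels.seed_kernels(123)
        for t in range(2000):
            if t % 5 == 4:
                st.gibbs_scan()
            else:
                st.sams_move()
            if t % 500 == 499:
                assert st.consistent()
        assert st.K >= 1 and np.all(st.sizes[:st.K] > 0)
        assert st.sizes[:st.K].sum() == table.n

    def test_merge_prior_ratio_two_singletons(self):
        # Gamma(2)/(alpha * Gamma(1) * Gamma(1)) = 1/alpha
        for alpha in (0.3, 1.0, 2.0):
            ratio = math.exp(dc.log_partition_prior([0, 0], alpha)
                             - dc.log_partition_prior([0, 1], alpha))
            assert math.isclose(ratio, 1 / alpha, rel_tol=1e-12)

    def test_forced_split_of_two_member_cluster(self):
        # n=2 sharing one cluster: the only split proposal makes two
        # singletons with no free allocations (q = 1); chain remains valid
        a1 = np.array([[0], [1]], dtype=np.int64)
        a2 = np.array([[0], [1]], dtype=np.int64)
        st = SamplerState.from_arrays(a1, a2, np.array([2]), alpha=1.0, lam=1.0)
        _kernels.seed_kernels(7)
        seen_k = set()
        for _ in range(200):
            st.sams_move()
            seen_k.add(st.K)
            assert st.consistent()
        assert seen_k == {1, 2}

    def test_mixed_schedule_matches_enumerated_posterior(self, tiny_snp):
        a1, a2, J = tiny_snp
        tv = _empirical_tv(a1[:4], a2[:4], J, 1.0, 1.0, 4, 40_000, seed=11)
        assert tv < 0.03


class TestLambdaUpdates:
    def test_lambda_stays_in_prior_support(self, two_pop_table):
        table, _ = two_pop_table
        for mode in ("single", "unique"):
            trace = dc.run_mcmc(table, alpha=0.5, lam=9.9, lambda_mode=mode,
                                iterations=500, thin=5, delta=0.5, seed=4)
            assert trace.lambdas is not None
            assert np.all(trace.lambdas > 0) and np.all(trace.lambdas <= 10.0)

    def test_single_mode_keeps_lambda_shared(self, two_pop_table):
        table, _ = two_pop_table
        trace = dc.run_mcmc(table, alpha=0.5, lam=1.0, lambda_mode="single",
                            iterations=400, thin=4, delta=0.3, seed=5)
        assert np.all(trace.lambdas == trace.lambdas[:, [0]])

    def test_posterior_lambda_orders_by_frequency_uniformity(self):
        # near-uniform ancestral frequencies favour larger lambda than
        # skewed ones (the single shared-lambda posterior mean shifts up)
        means = {}
        for kind, seed in (("uniform", 21), ("skewed", 22)):
            table, _ = dc.simulate_correlated(dc.microsat_scenario(kind, 30), seed=seed)
            trace = dc.run_mcmc(table, alpha=dc.alpha_for_expected_k(50, 2),
                                lam=1.0, lambda_mode="single", iterations=4000,
                                delta=0.3, seed=seed)
            means[kind] = trace.lambdas.mean()
        assert means["uniform"] > means["skewed"]

    def test_invalid_delta(self):
        a1 = np.array([[0], [1]], dtype=np.int64)
        with pytest.raises(ValueError):
            SamplerState.from_arrays(a1, a1, np.array([2]), alpha=1.0, delta=0.0)


class TestRunMcmc:
    def test_sample_count_arithmetic(self, two_pop_table):
        table, _ = two_pop_table
        trace = dc.run_mcmc(table, alpha=0.5, iterations=2000, burn_in=1000,
                            thin=10, seed=0)
        assert trace.n_samples == 100

    def test_deterministic_given_seed(self, two_pop_table):
        table, _ = two_pop_table
        kw = dict(alpha=0.5, lam=1.0, lambda_mode="single", iterations=1500,
                  thin=5, seed=42)
        t1 = dc.run_mcmc(table, **kw)
        t2 = dc.run_mcmc(table, **kw)
        assert np.array_equal(t1.partitions, t2.partitions)
        assert np.array_equal(t1.lambdas, t2.lambdas)

    def test_bad_schedule_rejected(self, two_pop_table):
        table, _ = two_pop_table
        with pytest.raises(ValueError):
            dc.run_mcmc(table, alpha=0.5, iterations=100, burn_in=100)

    def test_sams_accelerates_reaching_true_k(self, island_bases):
        # with several well-separated populations the split-merge moves
        # reach the true number of clusters far sooner than Gibbs alone
        cfg, model, bases = island_bases
        wins = 0
        seeds = range(5)
        for s in seeds:
            table, _ = model.draw_sample(bases[s % 2], [15] * 4, seed=300 + s)
            alpha = dc.alpha_for_expected_k(table.n, 4)
            first = {}
            for name, spc in (("gibbs", 0), ("mixed", 4)):
                tr = dc.run_mcmc(table, alpha=alpha, lam=1.0, iterations=500,
                                 burn_in=1, thin=1, sams_per_cycle=spc, seed=400 + s)
                hit = np.flatnonzero(tr.k >= 4)
                first[name] = hit[0] if hit.size else np.inf
            wins += first["mixed"] <= first["gibbs"]
        assert wins >= 0.8 * len(list(seeds))
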