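"""Unit tests of the DP clustering sampler's conditional updates."""

import numpy as np
import pytest

import profilegraph as pg
from profilegraph.dp import _Sampler, marginal_frequencies


def make_sampler(data, spec, rng=None, **kwargs):
    defaults = dict(iterations=10, burnin=0, truncation=5, max_truncation=5,
                    init_groups=5, seed=0)
    defaults.update(kwargs)
    cfg = pg.DPConfig(**defaults)
    return _Sampler(data, spec, cfg, rng or np.random.default_rng(cfg.seed))


class TestSubjectLikelihood:
    def test_all_switches_off_gives_marginal_product(self):
        rng = np.random.default_rng(0)
        pop = pg.worked_example_population()
        data, _ = pg.sample_cluster_population(pop, 50, rng)
        s = make_sampler(data, pop.spec)
        s.state.gamma[:] = 0
        x = data[0]
        expected = np.prod([s.pi[p, x[p]] for p in range(pop.spec.P)])
        for c in range(s.state.n_clusters):
            assert pg.subject_likelihood(x, c, s.state) == pytest.approx(expected)

    def test_single_covariate_all_selected(self):
        data = np.array([[0], [1]])
        s = make_sampler(data, pg.FactorSpec.binary(1))
        s.state.gamma[:] = 1
        assert pg.subject_likelihood([1], 2, s.state) == pytest.approx(
            s.state.phi[0, 2, 1])

    def test_worked_population_cluster_three(self):
        # all-zero profile under cluster 3 of the worked example,
        # all switches on: 0.29 * 0.29 * 0.8^4
        pop = pg.worked_example_population()
        data = np.zeros((4, 6), dtype=int)
        s = make_sampler(data, pop.spec)
        s.state.phi[:, :3, :] = np.transpose(pop.phi, (1, 0, 2))
        s.state.gamma[:] = 1
        got = pg.subject_likelihood(np.zeros(6, dtype=int), 2, s.state)
        assert got == pytest.approx(0.29 * 0.29 * 0.8 ** 4)

    def test_zero_marginal_frequency_rejected(self):
        data = np.array([[0], [0]])
        spec = pg.FactorSpec.binary(1)
        s = make_sampler(data, spec)
        s.state.gamma[:] = 0
        with pytest.raises(ValueError):
            pg.subject_likelihood([1], 0, s.state)  # level 1 never observed


class TestAllocations:
    def test_degenerate_sticks_put_everyone_in_first_cluster(self):
        rng = np.random.default_rng(1)
        data = rng.integers(0, 2, size=(100, 2))
        s = make_sampler(data, pg.FactorSpec.binary(2), rng)
        s.state.V[:] = 1e-12
        s.state.V[0] = 1 - 1e-12
        s.state.V[-1] = 1.0
        s.update_allocations()
        assert np.all(s.state.z == 0)

    def test_identical_clusters_follow_stick_weights(self):
        rng = np.random.default_rng(2)
        data = np.zeros((4000, 1), dtype=int)
        data[:2000] = 1
        s = make_sampler(data, pg.FactorSpec.binary(1), rng)
        s.state.phi[:] = 0.5  # identical across clusters
        s.state.gamma[:] = 1
        s.state.V[:] = [0.6, 0.5, 0.5, 0.5, 1.0]  # psi ~ (.6,.2,.1,.05,.05)
        s.update_allocations()
        psi = s.state.psi
        freqs = np.bincount(s.state.z, minlength=5) / 4000
        assert np.allclose(freqs, psi, atol=3 * np.sqrt(psi * (1 - psi) / 4000))

    def test_two_cluster_toy_matches_enumeration(self):
        # single binary covariate, fixed phi/gamma/psi: the allocation
        # conditional factorizes per subject; compare frequencies with the
        # exact per-subject posterior
        rng = np.random.default_rng(3)
        data = np.array([[0]] * 300 + [[1]] * 300)
        s = make_sampler(data, pg.FactorSpec.binary(1), rng,
                         truncation=2, max_truncation=2)
        s.state.phi[0, 0] = [0.8, 0.2]
        s.state.phi[0, 1] = [0.3, 0.7]
        s.state.gamma[:] = 1
        s.state.V[:] = [0.4, 1.0]
        hits = np.zeros((2, 2))  # level x cluster
        for _ in range(200):
            s.update_allocations()
            for lv in (0, 1):
                hits[lv, 0] += np.sum(s.state.z[data[:, 0] == lv] == 0)
                hits[lv, 1] += np.sum(s.state.z[data[:, 0] == lv] == 1)
        got = hits / hits.sum(axis=1, keepdims=True)
        for lv in (0, 1):
            num = 0.4 * s.state.phi[0, 0, lv]
            den = num + 0.6 * s.state.phi[0, 1, lv]
            assert got[lv, 0] == pytest.approx(num / den, abs=0.01)


class TestPhiUpdate:
    def test_empty_cluster_draws_from_prior(self):
        rng = np.random.default_rng(4)
        data = np.zeros((10, 1), dtype=int)
        s = make_sampler(data, pg.FactorSpec.binary(1), rng, lambda_dir=0.5)
        s.state.z[:] = 0
        draws = []
        for _ in range(3000):
            s.update_phi(s._level_counts())
            draws.append(s.state.phi[0, 3].copy())  # empty cluster
        draws = np.array(draws)
        # Dirichlet(0.5, 0.5) has mean 1/2 and var 1/8
        assert draws[:, 0].mean() == pytest.approx(0.5, abs=0.03)
        assert draws[:, 0].var() == pytest.approx(0.125, abs=0.01)

    def test_switched_off_covariate_ignores_data(self):
        rng = np.random.default_rng(5)
        data = np.zeros((50, 1), dtype=int)  # all level 0
        s = make_sampler(data, pg.FactorSpec.binary(1), rng)
        s.state.z[:] = 0
        s.state.gamma[:] = 0
        draws = [s.update_phi(s._level_counts()) or s.state.phi[0, 0, 0]
                 for _ in range(3000)]
        assert np.mean(draws) == pytest.approx(0.5, abs=0.03)

    def test_conditional_mean_matches_dirichlet_posterior(self):
        rng = np.random.default_rng(6)
        data = np.zeros((10, 1), dtype=int)  # counts (10, 0)
        s = make_sampler(data, pg.FactorSpec.binary(1), rng, lambda_dir=0.5)
        s.state.z[:] = 0
        s.state.gamma[:] = 1
        draws = [s.update_phi(s._level_counts()) or s.state.phi[0, 0, 0]
                 for _ in range(3000)]
        assert np.mean(draws) == pytest.approx(10.5 / 11, abs=0.01)


class TestGammaUpdate:
    def test_phi_equal_to_marginal_gives_probability_rho(self):
        rng = np.random.default_rng(7)
        data = np.array([[0]] * 30 + [[1]] * 30)
        s = make_sampler(data, pg.FactorSpec.binary(1), rng)
        s.state.phi[:] = 0.5  # equals the observed marginal
        s.state.rho[:] = 0.3
        hits = 0
        trials = 4000
        for _ in range(trials):
            s.update_gamma(s._level_counts())
            hits += s.state.gamma.sum()
        frac = hits / (trials * s.state.n_clusters)
        assert frac == pytest.approx(0.3, abs=0.02)

    def test_zero_rho_forces_all_switches_off(self):
        rng = np.random.default_rng(8)
        data = np.array([[0]] * 20 + [[1]] * 5)
        s = make_sampler(data, pg.FactorSpec.binary(1), rng)
        s.state.rho[:] = 0.0
        s.update_gamma(s._level_counts())
        assert np.all(s.state.gamma == 0)


class TestRhoUpdate:
    def test_conjugate_beta_counts(self):
        # all switches on over all 5 clusters, flat Beta(1,1) hyperprior
        rng = np.random.default_rng(9)
        data = np.zeros((5, 1), dtype=int)
        s = make_sampler(data, pg.FactorSpec.binary(1), rng)
        s.state.z[:] = np.arange(5)  # all clusters occupied
        draws = []
        for _ in range(4000):
            s.state.gamma[:] = 1
            s.update_rho()
            draws.append(s.state.rho[0])
        # Beta(6, 1): mean 6/7, var 6/(49*8)
        assert np.mean(draws) == pytest.approx(6 / 7, abs=0.01)
        assert np.var(draws) == pytest.approx(6 / (49 * 8), rel=0.2)

    def test_point_mass_keeps_rho_at_zero(self):
        rng = np.random.default_rng(10)
        data = np.zeros((4, 1), dtype=int)
        s = make_sampler(data, pg.FactorSpec.binary(1), rng)
        s.state.gamma[:] = 0
        s.update_rho()
        if s.state.w[0] == 0:
            assert s.state.rho[0] == 0.0

    def test_marginal_slab_probability_given_all_zero(self):
        # two-term Bayes factor: with C=3 clusters and Beta(1,1),
        # P(w=1 | gamma all zero) = B(1,4)/B(1,1) / (1 + B(1,4)/B(1,1)) = 0.2
        rng = np.random.default_rng(11)
        data = np.zeros((3, 1), dtype=int)
        s = make_sampler(data, pg.FactorSpec.binary(1), rng,
                         truncation=3, max_truncation=3, init_groups=3)
        hits = 0
        trials = 8000
        for _ in range(trials):
            s.state.gamma[:] = 0
            s.update_rho()
            hits += int(s.state.w[0])
        assert hits / trials == pytest.approx(0.2, abs=0.015)


class TestSticksAlpha:
    def test_single_occupied_cluster_stick_mean(self):
        rng = np.random.default_rng(12)
        n = 30
        data = np.zeros((n, 1), dtype=int)
        s = make_sampler(data, pg.FactorSpec.binary(1), rng, fix_alpha=True,
                         alpha=2.0)
        s.state.z[:] = 0
        draws = []
        for _ in range(4000):
            s.update_sticks_alpha()
            draws.append(s.state.V[0])
        assert np.mean(draws) == pytest.approx((1 + n) / (1 + n + 2.0), abs=0.005)

    def test_no_data_reverts_to_prior(self):
        rng = np.random.default_rng(13)
        data = np.zeros((1, 1), dtype=int)
        s = make_sampler(data, pg.FactorSpec.binary(1), rng, fix_alpha=True,
                         alpha=3.0)
        s.state.z[:] = 0
        draws = []
        for _ in range(6000):
            s.update_sticks_alpha()
            draws.append(s.state.V[2])  # empty cluster, no mass above either
        # Beta(1, 3) has mean 1/4
        assert np.mean(draws) == pytest.approx(0.25, abs=0.01)

    def test_alpha_conjugate_update(self):
        # for V_c ~ Beta(1, alpha) the conditional of alpha under a
        # Gamma(a0, b0) prior is Gamma(a0 + C_free, b0 - sum log(1 - V_c))
        rng = np.random.default_rng(14)
        data = np.zeros((10, 1), dtype=int)
        s = make_sampler(data, pg.FactorSpec.binary(1), rng,
                         alpha_shape=2.0, alpha_rate=1.0)
        V = np.array([0.3, 0.4, 0.2, 0.5, 1.0])
        shape, rate = s.alpha_conditional(V)
        assert shape == pytest.approx(2.0 + 4)
        assert rate == pytest.approx(1.0 - np.log1p(-V[:-1]).sum())

    def test_stick_weights_sum_to_one(self):
        rng = np.random.default_rng(15)
        pop = pg.worked_example_population()
        data, _ = pg.sample_cluster_population(pop, 100, rng)
        s = make_sampler(data, pop.spec, rng)
        for _ in range(20):
            s.sweep()
            psi = s.state.psi
            assert np.all(psi >= 0) and np.all(psi <= 1)
            assert psi.sum() == pytest.approx(1.0)


class TestRunChain:
    def test_seed_reproducibility(self):
        pop = pg.worked_example_population()
        data, _ = pg.sample_cluster_population(
            pop, 120, np.random.default_rng(16))
        cfg = dict(iterations=30, burnin=10, truncation=10, max_truncation=20,
                   seed=17)
        a = pg.run_chain(data, pop.spec, pg.DPConfig(**cfg))
        b = pg.run_chain(data, pop.spec, pg.DPConfig(**cfg))
        assert np.array_equal(a.z, b.z)
        assert np.array_equal(a.gamma, b.gamma)
        assert np.array_equal(a.rho, b.rho)

    def test_seed_required(self):
        data = np.zeros((5, 1), dtype=int)
        with pytest.raises(ValueError):
            pg.run_chain(data, pg.FactorSpec.binary(1),
                         pg.DPConfig(iterations=5, burnin=0))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            pg.DPConfig(iterations=0, seed=1).validate()
        with pytest.raises(ValueError):
            pg.DPConfig(truncation=60, max_truncation=50, seed=1).validate()

    def test_duplicated_covariate_gets_matching_selection(self):
        rng = np.random.default_rng(18)
        pop = pg.worked_example_population()
        base, _ = pg.sample_cluster_population(pop, 600, rng)
        data = np.column_stack([base, base[:, 0]])  # duplicate covariate 1
        spec = pg.FactorSpec.uniform(7, 3)
        cfg = pg.DPConfig(iterations=400, burnin=400, truncation=20,
                          max_truncation=30, seed=19)
        chain = pg.run_chain(data, spec, cfg)
        med = chain.median_rho()
        assert abs(med[0] - med[6]) < 0.25
        assert med[0] > 0.3 and med[6] > 0.3

    def test_marginals_match_observed_frequencies(self):
        rng = np.random.default_rng(20)
        data = rng.integers(0, 3, size=(200, 2))
        spec = pg.FactorSpec.uniform(2, 3)
        pi = marginal_frequencies(data, spec)
        for p in range(2):
            counts = np.bincount(data[:, p], minlength=3)
            assert np.allclose(pi[p], counts / 200)
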