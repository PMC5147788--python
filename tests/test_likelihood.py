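"""Covariances, the batch cache, and collapsed cluster marginals.

The headline correctness property lives here: the O(T) cached cluster
marginal must agree with a brute-force dense nT-dimensional Gaussian
evaluation on every cluster of small random instances.
"""

import itertools

import numpy as np
import pytest
from scipy.special import kv, gammaln
from scipy.stats import multivariate_normal, norm

from caesar.likelihood import (
    GPSpec,
    NodeTimecourses,
    NoiseState,
    build_batch_cache,
    cluster_log_marginal,
    covariance_matrix,
    posterior_timecourse,
    sample_cluster_timecourse,
    sample_noise,
    total_log_posterior,
)
from caesar.spatial import LinkState, SizePrior, build_grid_adjacency

from conftest import dense_cluster_log_marginal


class TestCovarianceMatrix:
    def test_zero_lag_equals_magnitude(self, default_spec):
        K = covariance_matrix(default_spec, np.arange(5) * 0.72)
        assert np.allclose(np.diag(K), 0.1)

    def test_independent_kind_is_scaled_identity(self):
        spec = GPSpec(kind="independent", magnitude=1.0)
        K = covariance_matrix(spec, np.arange(4) * 2.0)
        assert np.array_equal(K, np.eye(4))

    def test_matern_32_closed_form_matches_bessel_oracle(self):
        # generic Bessel-function evaluation of the Matérn family
        spec = GPSpec(order=1.5, magnitude=0.1, length_scale=3.6)
        times = np.array([0.0, 3.6, 7.2, 10.0])
        K = covariance_matrix(spec, times)
        nu, eta = 1.5, np.sqrt(3.0) / 3.6
        for i, j in itertools.product(range(4), repeat=2):
            r = abs(times[i] - times[j])
            if r == 0:
                expected = 0.1
            else:
                x = eta * r
                expected = 0.1 * 2 ** (1 - nu) / np.exp(gammaln(nu)) * x**nu * kv(nu, x)
            assert K[i, j] == pytest.approx(expected, abs=1e-10)

    def test_general_order_uses_bessel_branch(self):
        spec = GPSpec(order=2.5, magnitude=1.0, length_scale=2.0)
        K = covariance_matrix(spec, np.array([0.0, 1.0]))
        assert K[0, 0] == pytest.approx(1.0)
        assert 0 < K[0, 1] < 1.0

    def test_positive_semidefinite(self, default_spec):
        K = covariance_matrix(default_spec, np.arange(20) * 2.0)
        assert np.linalg.eigvalsh(K).min() > -1e-10

    def test_nonfinite_times_rejected(self, default_spec):
        with pytest.raises(ValueError):
            covariance_matrix(default_spec, np.array([0.0, np.inf]))


class TestBatchCache:
    def test_independent_unit_noise_eigenvalues(self):
        data = NodeTimecourses(np.zeros((3, 6)), np.arange(6.0) + 1.0)
        spec = GPSpec(kind="independent", magnitude=1.0)
        cache = build_batch_cache(data, spec, NoiseState(tau=1.0))
        assert np.allclose(cache.d, 1.0)

    def test_single_time_point(self):
        data = NodeTimecourses(np.ones((2, 1)), np.array([0.0]))
        noise = NoiseState(tau=2.0, phi=np.array([1.5]))
        cache = build_batch_cache(data, GPSpec(), noise)
        assert cache.d[0] == pytest.approx(0.1 * 2.0 * 1.5)

    def test_round_trip_reconstruction(self, small_data, default_spec, rough_noise):
        cache = build_batch_cache(small_data, default_spec, rough_noise)
        K = covariance_matrix(default_spec, small_data.times)
        scale = 1.0 / cache.sigma_inv_sqrt
        recon = scale[:, None] * (cache.V * cache.d) @ cache.V.T * scale[None, :]
        assert np.allclose(recon, K, atol=1e-8)

    def test_quadratics_are_row_norms(self, small_data, default_spec, rough_noise):
        cache = build_batch_cache(small_data, default_spec, rough_noise)
        assert np.allclose(cache.q, np.sum(cache.Z**2, axis=1))

    def test_nonpositive_precision_rejected(self, small_data, default_spec):
        with pytest.raises(ValueError):
            build_batch_cache(small_data, default_spec, NoiseState(tau=-1.0))


class TestClusterLogMarginal:
    def test_matches_dense_oracle_all_clusters(self, rng):
        """Every subset of a 6x9 instance agrees with the brute-force
        dense Gaussian to 1e-6 (tougher than needed: all 63 subsets)."""
        N, T = 6, 9
        data = NodeTimecourses(rng.normal(size=(N, T)), np.arange(T) * 2.0)
        spec = GPSpec()
        noise = NoiseState(tau=1.3, phi=rng.uniform(0.5, 2.0, size=T))
        cache = build_batch_cache(data, spec, noise)
        K = covariance_matrix(spec, data.times)
        sigma_diag = 1.0 / (noise.tau * noise.phi)
        for size in range(1, N + 1):
            for members in itertools.combinations(range(N), size):
                fast = cluster_log_marginal(cache, members)
                oracle = dense_cluster_log_marginal(
                    data.Y[list(members)], K, sigma_diag
                )
                assert fast == pytest.approx(oracle, abs=1e-6)

    def test_single_node_independent_closed_form(self, rng):
        T = 7
        y = rng.normal(size=(1, T))
        data = NodeTimecourses(y, np.arange(T) * 2.0)
        spec = GPSpec(kind="independent", magnitude=1.0)
        noise = NoiseState(tau=2.0, phi=np.full(T, 1.5))
        cache = build_batch_cache(data, spec, noise)
        got = cluster_log_marginal(cache, [0])
        var = 1.0 + 1.0 / (2.0 * 1.5)
        expected = norm.logpdf(y[0], scale=np.sqrt(var)).sum()
        assert got == pytest.approx(expected, abs=1e-8)

    def test_member_permutation_invariance(self, small_data, default_spec, rough_noise):
        cache = build_batch_cache(small_data, default_spec, rough_noise)
        assert cluster_log_marginal(cache, [0, 2, 4]) == cluster_log_marginal(
            cache, [4, 0, 2]
        )

    def test_statistic_additivity_on_merge(self, small_data, default_spec, rough_noise):
        """Joint evaluation equals evaluation from summed cached stats."""
        cache = build_batch_cache(small_data, default_spec, rough_noise)
        na, sa, Qa = cache.cluster_stats([0, 1])
        nb, sb, Qb = cache.cluster_stats([2, 3, 4])
        merged_from_sums = cache.log_marginal_from_stats(
            na + nb, sa + sb, Qa + Qb
        )
        joint = cluster_log_marginal(cache, [0, 1, 2, 3, 4])
        assert merged_from_sums == pytest.approx(joint, abs=1e-9)

    def test_empty_member_set_rejected(self, small_data, default_spec, rough_noise):
        cache = build_batch_cache(small_data, default_spec, rough_noise)
        with pytest.raises(ValueError):
            cluster_log_marginal(cache, [])

    def test_it_model_special_case(self, rng):
        """independent kind, sigma_m^2 = 1, phi = 1 reproduces a directly
        coded temporally-independent Gaussian marginal."""
        N, T = 4, 6
        Y = rng.normal(size=(N, T))
        data = NodeTimecourses(Y, np.arange(T) * 2.0)
        spec = GPSpec(kind="independent", magnitude=1.0)
        noise = NoiseState(tau=1.0, phi=np.ones(T))
        cache = build_batch_cache(data, spec, noise)
        members = [0, 1, 2]
        got = cluster_log_marginal(cache, members)
        # direct per-time evaluation: y_t ~ N(0, sigma_m^2 11^T + I/tau)
        cov_t = 1.0 * np.ones((3, 3)) + np.eye(3)
        expected = sum(
            multivariate_normal.logpdf(Y[members, t], cov=cov_t)
            for t in range(T)
        )
        assert got == pytest.approx(expected, abs=1e-8)


class TestTotalLogPosterior:
    @staticmethod
    def _setup(rng):
        g = build_grid_adjacency(2, 2)
        data = NodeTimecourses(rng.normal(size=(4, 5)), np.arange(5) * 2.0)
        noise = NoiseState(tau=1.2, phi=rng.uniform(0.8, 1.2, size=5))
        spec = GPSpec()
        cache = build_batch_cache(data, spec, noise)
        return g, data, noise, spec, cache

    def test_matches_term_by_term_oracle(self, rng):
        from caesar.spatial import link_log_prior, size_log_prior

        g, data, noise, spec, cache = self._setup(rng)
        links = np.array([1, 0, 3, 2])
        state = LinkState(links, g)
        sp = SizePrior(3, 1.0)
        got = total_log_posterior(state, cache, g, sp, noise)
        oracle = (
            cluster_log_marginal(cache, [0, 1])
            + cluster_log_marginal(cache, [2, 3])
            + sum(link_log_prior(g, n, int(links[n])) for n in range(4))
            + size_log_prior(np.array([2, 2]), sp)
            + noise.log_prior()
        )
        assert got == pytest.approx(oracle, abs=1e-10)

    def test_same_partition_differs_only_by_link_prior(self, rng):
        g, data, noise, spec, cache = self._setup(rng)
        # both give one 4-cycle cluster, via different link choices
        s1 = LinkState(np.array([1, 3, 0, 2]), g)
        s2 = LinkState(np.array([2, 0, 3, 1]), g)
        lp1 = total_log_posterior(s1, cache, g, None, noise)
        lp2 = total_log_posterior(s2, cache, g, None, noise)
        # uniform link priors on a symmetric grid -> identical here
        assert lp1 == pytest.approx(lp2, abs=1e-10)

    def test_disabling_size_prior_removes_exactly_its_term(self, rng):
        from caesar.spatial import size_log_prior

        g, data, noise, spec, cache = self._setup(rng)
        state = LinkState(np.array([0, 1, 2, 3]), g)
        sp = SizePrior(5, 2.0)
        with_prior = total_log_posterior(state, cache, g, sp, noise)
        without = total_log_posterior(state, cache, g, None, noise)
        assert with_prior - without == pytest.approx(
            size_log_prior(state.sizes(), sp), abs=1e-10
        )


class TestPosteriorTimecourse:
    def test_matches_dense_conjugate_oracle(self, rng):
        """2-node cluster, T=5: Gaussian conditional computed densely."""
        T = 5
        Y = rng.normal(size=(2, T))
        data = NodeTimecourses(Y, np.arange(T) * 2.0)
        spec = GPSpec()
        noise = NoiseState(tau=1.4, phi=rng.uniform(0.7, 1.4, size=T))
        cache = build_batch_cache(data, spec, noise)
        mean, var = posterior_timecourse(cache, [0, 1])
        K = covariance_matrix(spec, data.times)
        Sinv = np.diag(noise.tau * noise.phi)
        prec = np.linalg.inv(K) + 2 * Sinv
        cov = np.linalg.inv(prec)
        mean_oracle = cov @ (Sinv @ Y.sum(axis=0))
        assert np.allclose(mean, mean_oracle, atol=1e-8)
        assert np.allclose(var, np.diag(cov), atol=1e-8)

    def test_zero_data_gives_zero_mean_bounded_variance(self):
        data = NodeTimecourses(np.zeros((3, 6)), np.arange(6) * 2.0)
        cache = build_batch_cache(data, GPSpec(), NoiseState())
        mean, var = posterior_timecourse(cache, [0, 1, 2])
        assert np.allclose(mean, 0.0)
        assert np.all(var <= 0.1 + 1e-12)

    def test_large_cluster_mean_approaches_node_average(self, rng):
        T = 6
        signal = rng.normal(size=T)
        Y = np.tile(signal, (400, 1)) + rng.normal(scale=0.01, size=(400, T))
        data = NodeTimecourses(Y, np.arange(T) * 2.0)
        spec = GPSpec(kind="independent", magnitude=1.0)
        cache = build_batch_cache(data, spec, NoiseState())
        mean, _ = posterior_timecourse(cache, range(400))
        assert np.allclose(mean, Y.mean(axis=0), atol=0.02)


class TestSampleNoise:
    @staticmethod
    def _state_with_residuals(Y, graph_dims=(1, 2)):
        g = build_grid_adjacency(*graph_dims)
        return LinkState(np.arange(g.n_nodes), g)

    def test_zero_residuals_formula(self, rng):
        N, T = 2, 4
        x = rng.normal(size=T)
        Y = np.tile(x, (N, 1))
        data = NodeTimecourses(Y, np.arange(T) * 2.0)
        g = build_grid_adjacency(1, 2)
        state = LinkState(np.array([1, 0]), g)
        cid = int(state.cluster_of[0])
        noise = NoiseState()
        draws = []
        for seed in range(2000):
            new, _ = sample_noise(
                data, state, {cid: x}, noise, np.random.default_rng(seed)
            )
            draws.append(new.tau)
        # tau | zero residuals ~ Gamma(a0 + NT/2, b0): mean = (1 + 4)/0.01
        expected_mean = (1.0 + 0.5 * N * T) / 0.01
        se = expected_mean / np.sqrt(1.0 + 0.5 * N * T) / np.sqrt(len(draws))
        assert np.mean(draws) == pytest.approx(expected_mean, abs=4 * se)

    def test_tau_recovers_unit_precision_in_large_n_limit(self, rng):
        N, T = 400, 30
        g = build_grid_adjacency(1, N)
        state = LinkState(np.arange(N), g)
        x = np.zeros(T)
        Y = rng.normal(size=(N, T))  # iid N(0,1) residuals
        data = NodeTimecourses(Y, np.arange(T) * 2.0)
        tcs = {int(c): x for c in state.clusters}
        new, _ = sample_noise(data, state, tcs, NoiseState(), rng)
        assert new.tau == pytest.approx(1.0, rel=0.05)

    def test_phi_prior_mean_half_without_data(self, rng):
        # nu=4: phi ~ Gamma(2, rate 4), mean 1/2; checked via the update
        # formula at N=0 equivalent (zero residual contribution, zero count)
        from scipy.stats import gamma as gd

        assert gd.mean(a=2.0, scale=1.0 / 4.0) == pytest.approx(0.5)

    def test_transition_density_is_logpdf_of_draws(self, rng):
        from scipy.stats import gamma as gd

        N, T = 3, 5
        Y = rng.normal(size=(N, T))
        data = NodeTimecourses(Y, np.arange(T) * 2.0)
        g = build_grid_adjacency(1, 3)
        state = LinkState(np.arange(3), g)
        tcs = {int(c): np.zeros(T) for c in state.clusters}
        noise = NoiseState()
        new, logq = sample_noise(data, state, tcs, noise, np.random.default_rng(7))
        r2 = Y**2
        shape_tau = 1.0 + 0.5 * N * T
        rate_tau = 0.01 + 0.5 * r2.sum()
        expected = gd.logpdf(new.tau, a=shape_tau, scale=1.0 / rate_tau)
        rate_phi = 4.0 + 0.5 * new.tau * r2.sum(axis=0)
        expected += gd.logpdf(new.phi, a=2.0 + 1.5, scale=1.0 / rate_phi).sum()
        assert logq == pytest.approx(expected, abs=1e-10)


class TestSampleClusterTimecourse:
    def test_draws_centre_on_posterior_mean(self, small_data, default_spec, rough_noise):
        cache = build_batch_cache(small_data, default_spec, rough_noise)
        mean, var = posterior_timecourse(cache, [0, 1, 2])
        rng = np.random.default_rng(0)
        draws = np.array(
            [sample_cluster_timecourse(cache, [0, 1, 2], rng)[0] for _ in range(3000)]
        )
        assert np.allclose(draws.mean(axis=0), mean, atol=4 * np.sqrt(var / 3000))
        assert np.allclose(draws.var(axis=0), var, rtol=0.2)
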