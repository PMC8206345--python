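import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import multivariate_normal

from tracs import KernelParams, TimeGrid, fit_cluster_gp, kernel_matrix, log_marginal_likelihood
from tracs.gp import GPFit, _group_points, _lml_and_grad


class TestKernelMatrix:
    def test_equal_times_give_one_plus_noise_var(self):
        p = KernelParams(2.5, 0.3)
        k = kernel_matrix([1.0], [1.0], p)
        assert k[0, 0] == pytest.approx(1 + 0.3**2)

    def test_distant_times_decay_to_zero(self):
        p = KernelParams(1.0, 0.5)
        assert kernel_matrix([0.0], [100.0], p)[0, 0] == pytest.approx(0.0, abs=1e-300)

    def test_unit_length_scale_off_diagonal(self):
        k = kernel_matrix([0, 1, 2], [0, 1, 2], KernelParams(1.0, 0.0))
        assert k[0, 1] == pytest.approx(np.exp(-0.5), abs=1e-12)
        assert k[0, 2] == pytest.approx(np.exp(-2.0), abs=1e-12)

    def test_invalid_length_scale(self):
        with pytest.raises(ValueError):
            KernelParams(0.0, 0.1)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        times=st.lists(st.floats(-10, 10), min_size=1, max_size=6),
        l=st.floats(0.1, 20),
        s=st.floats(0, 2),
    )
    def test_matches_elementwise_brute_force(self, times, l, s):
        p = KernelParams(l, s)
        got = kernel_matrix(times, times, p)
        for i, ti in enumerate(times):
            for j, tj in enumerate(times):
                expect = np.exp(-((ti / l - tj / l) ** 2) / 2.0)
                if ti == tj:
                    expect += s**2
                assert got[i, j] == pytest.approx(expect, rel=1e-12, abs=1e-12)

    def test_symmetric_and_psd(self):
        rng = np.random.default_rng(0)
        t = rng.uniform(0, 10, 6)
        k = kernel_matrix(t, t, KernelParams(2.0, 0.4))
        np.testing.assert_allclose(k, k.T)
        assert np.linalg.eigvalsh(k).min() > -1e-10


class TestStructuredSolver:
    """The O(u^3) repeated-time solver must agree with a dense GP."""

    def _dense_lml(self, t, y, l, s2):
        k = np.exp(-((t[:, None] - t[None, :]) ** 2) / (2 * l**2))
        k[np.diag_indices_from(k)] += s2
        return multivariate_normal(mean=np.zeros(t.size), cov=k).logpdf(y)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_joint_lml_matches_dense_oracle(self, seed):
        rng = np.random.default_rng(seed)
        t = np.repeat(np.sort(rng.uniform(0, 10, 4)), 3)
        y = rng.normal(size=t.size)
        l, s2 = rng.uniform(0.5, 5), rng.uniform(0.05, 1)
        st_ = _group_points(t, y)
        lml, _ = _lml_and_grad(np.array([np.log(l), np.log(s2)]), st_)
        assert lml == pytest.approx(self._dense_lml(t, y, l, s2), abs=1e-7)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(3)
        t = np.tile(np.arange(5.0), 4)
        y = rng.normal(size=20)
        st_ = _group_points(t, y)
        theta = np.array([np.log(1.7), np.log(0.3)])
        lml, grad = _lml_and_grad(theta, st_)
        for i in range(2):
            th = theta.copy()
            th[i] += 1e-6
            l2, _ = _lml_and_grad(th, st_)
            assert grad[i] == pytest.approx((l2 - lml) / 1e-6, rel=1e-3, abs=1e-4)

    def test_posterior_matches_sklearn_gpr(self):
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import RBF, WhiteKernel

        rng = np.random.default_rng(4)
        t = np.tile(np.arange(5.0), 3)
        y = rng.normal(size=15)
        fit = fit_cluster_gp(t, y, TimeGrid([0, 1, 2, 3, 4]), restarts=2, seed=0)
        gpr = GaussianProcessRegressor(
            kernel=RBF(fit.params.length_scale, "fixed")
            + WhiteKernel(fit.params.noise_sd**2, "fixed"),
            optimizer=None,
            alpha=0.0,
        ).fit(t[:, None], y)
        mu, sd = gpr.predict(fit.grid_times[:, None], return_std=True)
        np.testing.assert_allclose(fit.mean, mu, atol=1e-8)
        np.testing.assert_allclose(fit.sd, sd, atol=1e-6)
        assert fit.log_marginal_likelihood >= gpr.log_marginal_likelihood_value_ - 1e-8


class TestFitClusterGP:
    def test_noiseless_line_recovered_on_dense_grid(self):
        t = np.linspace(0, 7, 15)
        v = 0.3 * t - 1.0
        fit = fit_cluster_gp(np.tile(t, 3), np.tile(v, 3), TimeGrid(np.arange(8.0)), seed=0)
        target = 0.3 * fit.grid_times - 1.0
        assert np.max(np.abs(fit.mean - target)) < 0.05

    def test_single_point_posterior_shrinks_toward_value(self):
        grid = TimeGrid([0, 1, 2])
        fit = fit_cluster_gp([1.0], [2.0], grid, seed=0)
        s2 = fit.params.noise_sd**2
        mu_at_train, _ = fit.posterior(np.array([1.0]))
        assert 2.0 / (1 + s2) - 1e-9 <= mu_at_train[0] <= 2.0 + 1e-9

    def test_variance_grows_between_distant_time_groups(self):
        rng = np.random.default_rng(5)
        t = np.concatenate([np.full(10, 0.0), np.full(10, 10.0)])
        y = rng.normal(0, 0.1, 20)
        fit = fit_cluster_gp(t, y, TimeGrid([0, 10], interpolation_step=1), seed=0)
        mid = np.argmin(np.abs(fit.grid_times - 5.0))
        assert fit.sd[mid] > fit.sd[0]
        assert fit.sd[mid] > fit.sd[-1]

    def test_constant_values_fit_flat_mean(self):
        t = np.tile(np.arange(4.0), 5)
        fit = fit_cluster_gp(t, np.full(20, 3.0), TimeGrid(np.arange(4.0)), seed=0)
        np.testing.assert_allclose(fit.mean, 3.0, atol=0.05)

    def test_positive_sd_everywhere_with_noise(self, small_matrix):
        t = np.tile(np.arange(8.0), 12)
        fit = fit_cluster_gp(t, small_matrix.values[:, :, 0].ravel(), small_matrix.grid, seed=0)
        assert fit.params.noise_sd > 0
        assert np.all(fit.sd > 0)

    def test_length_scale_respects_bounds(self):
        rng = np.random.default_rng(6)
        t = np.tile(np.arange(8.0), 4)
        fit = fit_cluster_gp(t, rng.normal(size=32), TimeGrid(np.arange(8.0)), seed=0)
        lo, hi = fit.params.length_scale_bounds
        assert lo <= fit.params.length_scale <= hi + 1e-9
        assert hi == pytest.approx(7.0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(7)
        t = np.tile(np.arange(6.0), 5)
        y = rng.normal(size=30)
        f1 = fit_cluster_gp(t, y, TimeGrid(np.arange(6.0)), seed=11)
        f2 = fit_cluster_gp(t, y, TimeGrid(np.arange(6.0)), seed=11)
        assert f1.params == f2.params
        np.testing.assert_array_equal(f1.mean, f2.mean)


class TestProfileLogLikelihood:
    def test_scalar_standard_normal_density(self):
        # single time, zero posterior mean, unit covariance: log N(0; 0, 1)
        fit = fit_cluster_gp([0.0], [0.0], TimeGrid([0.0, 1.0]), restarts=0, seed=0)
        fit.params = KernelParams(fit.params.length_scale, 0.0)
        ll = fit.profile_log_likelihood(np.array([0.0]), np.array([0.0]))
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-6)

    def test_zero_residual_leaves_only_determinant_terms(self):
        rng = np.random.default_rng(8)
        t = np.arange(5.0)
        fit = fit_cluster_gp(np.tile(t, 4), rng.normal(size=20), TimeGrid(t), seed=0)
        mu, _ = fit.posterior(t)
        l, s2 = fit.params.length_scale, fit.params.noise_sd**2
        cov = np.exp(-((t[:, None] - t[None, :]) ** 2) / (2 * l**2))
        cov[np.diag_indices_from(cov)] += s2
        expected = -0.5 * (np.linalg.slogdet(cov)[1] + 5 * np.log(2 * np.pi))
        assert fit.profile_log_likelihood(mu, t) == pytest.approx(expected, abs=1e-6)

    def test_quadratic_term_scales_with_squared_residual(self):
        rng = np.random.default_rng(9)
        t = np.arange(5.0)
        fit = fit_cluster_gp(np.tile(t, 4), rng.normal(size=20), TimeGrid(t), seed=0)
        mu, _ = fit.posterior(t)
        r = rng.normal(size=5)
        base = fit.profile_log_likelihood(mu, t)
        l1 = fit.profile_log_likelihood(mu + r, t)
        l2 = fit.profile_log_likelihood(mu + 2 * r, t)
        # (base - l2) = 4 * (base - l1): quadratic form scales by 4
        assert (base - l2) == pytest.approx(4 * (base - l1), rel=1e-8)

    def test_matches_multivariate_normal_oracle_5x5(self):
        rng = np.random.default_rng(10)
        t = np.arange(5.0)
        fit = fit_cluster_gp(np.tile(t, 4), rng.normal(size=20), TimeGrid(t), seed=0)
        mu, _ = fit.posterior(t)
        l, s2 = fit.params.length_scale, fit.params.noise_sd**2
        cov = np.exp(-((t[:, None] - t[None, :]) ** 2) / (2 * l**2))
        cov[np.diag_indices_from(cov)] += s2 + 1e-10
        for _ in range(5):
            x = rng.normal(size=5)
            oracle = multivariate_normal(mean=mu, cov=cov).logpdf(x)
            assert log_marginal_likelihood(x, fit, t) == pytest.approx(oracle, abs=1e-8)

    def test_nan_entries_marginalized(self):
        rng = np.random.default_rng(11)
        t = np.arange(4.0)
        fit = fit_cluster_gp(np.tile(t, 4), rng.normal(size=16), TimeGrid(t), seed=0)
        x = np.array([0.5, np.nan, -0.2, 0.1])
        full_on_subset = fit.profile_log_likelihood(
            np.array([0.5, -0.2, 0.1]), np.array([0.0, 2.0, 3.0])
        )
        assert fit.profile_log_likelihood(x, t) == pytest.approx(full_on_subset, abs=1e-10)
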