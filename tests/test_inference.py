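import numpy as np
import pytest
from scipy import stats

from smoketrends.inference import (
    McmcConfig,
    ess_multichain,
    find_map,
    metropolis_within_gibbs,
    overlap_statistic,
    profile_posterior,
    rhat,
    thin_to_sample,
)


class TestFindMap:
    def test_quadratic_recovers_mean_and_identity_hessian(self):
        m = np.array([1.0, -2.0, 0.5])
        res = find_map(lambda x: -0.5 * np.sum((x - m) ** 2), np.zeros(3))
        assert res.converged
        np.testing.assert_allclose(res.theta_hat, m, atol=1e-5)
        np.testing.assert_allclose(res.hessian, np.eye(3), atol=1e-3)
        assert res.hessian_pd
        np.testing.assert_allclose(res.asymptotic_sd(), 1.0, atol=1e-3)

    def test_beta_mode_one_parameter(self):
        a, b = 3.0, 5.0
        mode = (a - 1) / (a + b - 2)

        def log_post(x):
            p = 1 / (1 + np.exp(-x[0]))          # logit working scale
            return (a - 1) * np.log(p) + (b - 1) * np.log(1 - p)

        res = find_map(log_post, np.array([0.0]))
        p_hat = 1 / (1 + np.exp(-res.theta_hat[0]))
        assert p_hat == pytest.approx(mode, abs=1e-6)

    def test_grid_search_oracle_on_correlated_gaussian(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(2, 2))
        P = A @ A.T + np.eye(2)
        m = np.array([0.3, -0.7])

        def log_post(x):
            d = x - m
            return -0.5 * d @ P @ d

        res = find_map(log_post, np.zeros(2))
        # dense grid oracle
        g = np.linspace(-2, 2, 401)
        G1, G2 = np.meshgrid(g, g, indexing="ij")
        vals = np.array([log_post(np.array([a, b]))
                         for a, b in zip(G1.ravel(), G2.ravel())])
        best = np.unravel_index(np.argmax(vals), G1.shape)
        assert abs(res.theta_hat[0] - g[best[0]]) <= 1.5e-2
        assert abs(res.theta_hat[1] - g[best[1]]) <= 1.5e-2

    def test_fix_mask_holds_components(self):
        m = np.array([1.0, 2.0])
        res = find_map(lambda x: -0.5 * np.sum((x - m) ** 2),
                       np.array([0.0, 5.0]), fix=np.array([False, True]))
        assert res.theta_hat[1] == 5.0
        assert res.theta_hat[0] == pytest.approx(1.0, abs=1e-5)


class TestProfilePosterior:
    def _quadratic_map(self, sds=(1.0, 2.0), rho=0.6):
        cov = np.array([[sds[0] ** 2, rho * sds[0] * sds[1]],
                        [rho * sds[0] * sds[1], sds[1] ** 2]])
        P = np.linalg.inv(cov)
        m = np.array([0.5, -1.0])
        log_post = lambda x: -0.5 * (x - m) @ P @ (x - m)
        return find_map(log_post, np.zeros(2)), log_post, m, cov

    @pytest.mark.parametrize("level", [0.5, 0.9, 0.95])
    def test_profile_interval_equals_wald_on_quadratic(self, level):
        mr, log_post, m, cov = self._quadratic_map()
        for j in range(2):
            pr = profile_posterior(mr, j, log_post)
            lo, hi = pr.interval(level)
            z = stats.norm.ppf(0.5 + level / 2)
            sd = np.sqrt(cov[j, j])
            assert lo == pytest.approx(m[j] - z * sd, abs=1e-4)
            assert hi == pytest.approx(m[j] + z * sd, abs=1e-4)

    def test_gaussian_highest_level_near_one(self):
        mr, log_post, *_ = self._quadratic_map()
        pr = profile_posterior(mr, 0, log_post)
        assert pr.highest_contained_level > 0.999
        assert not pr.questionable
        # profile maximum equals the MAP value at the central grid point
        centre = pr.grid.size // 2
        assert pr.grid[centre] == pr.map_value
        assert pr.profile[centre] == pytest.approx(pr.map_log_post)
        assert np.all(pr.profile <= pr.map_log_post + 1e-9)

    def test_flat_direction_flagged_non_identifiable(self):
        # second parameter absent from the posterior
        log_post = lambda x: -0.5 * x[0] ** 2
        mr = find_map(log_post, np.zeros(2))
        pr = profile_posterior(mr, 1, log_post)
        assert pr.highest_contained_level == pytest.approx(0.0, abs=1e-6)
        assert pr.questionable
        lo, hi = pr.interval(0.95)
        assert lo == -np.inf and hi == np.inf

    def test_banana_profile_matches_dense_grid_oracle(self):
        # curved ridge: y ~ N(x^2, 0.3), x ~ N(0, 1)
        def log_post(v):
            x, y = v
            return -0.5 * x ** 2 - 0.5 * ((y - x ** 2) / 0.3) ** 2

        mr = find_map(log_post, np.array([0.5, 0.3]))
        pr = profile_posterior(mr, 1, log_post, sd_multiple=3.0, n_grid=11)
        ys = pr.grid
        xs = np.linspace(-4, 4, 4001)
        for yv, got in zip(ys, pr.profile):
            oracle = max(log_post(np.array([x, yv])) for x in xs)
            assert got == pytest.approx(oracle, abs=1e-3)


class TestOverlap:
    def test_identical_samples_near_one(self):
        rng = np.random.default_rng(42)
        a = rng.normal(0, 1, 5000)
        assert overlap_statistic(a, a.copy()) > 0.95

    def test_disjoint_near_zero(self):
        rng = np.random.default_rng(42)
        assert overlap_statistic(rng.normal(0, 1, 2000),
                                 rng.normal(100, 1, 2000)) < 0.01

    @pytest.mark.parametrize("delta", [0.0, 1.0, 2.0, 4.0])
    def test_equal_variance_gaussian_closed_form(self, delta):
        rng = np.random.default_rng(42)
        a = rng.normal(0, 1, 5000)
        b = rng.normal(delta, 1, 5000)
        expect = 2 * stats.norm.cdf(-delta / 2)
        assert overlap_statistic(a, b) == pytest.approx(expect, abs=0.03)

    def test_symmetry_and_degeneracy(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 3000), rng.normal(1, 2, 3000)
        assert overlap_statistic(a, b) == pytest.approx(
            overlap_statistic(b, a), abs=1e-12)
        with pytest.raises(ValueError):
            overlap_statistic(np.ones(100), a)


class TestEssRhat:
    def test_ess_matches_independent_implementation_on_ar1(self):
        # independent oracle: arviz's autocorrelation-based ESS estimator
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(8)
        for rho in (0.3, 0.7, 0.9):
            m, n = 4, 4000
            x = np.empty((m, n))
            for c in range(m):
                e = rng.normal(size=n)
                x[c, 0] = e[0]
                for t in range(1, n):
                    x[c, t] = rho * x[c, t - 1] + np.sqrt(1 - rho ** 2) * e[t]
            expect = float(az.ess(x))
            assert ess_multichain(x) == pytest.approx(expect, rel=0.15)

    def test_rhat_one_for_well_mixed(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(4, 2000))
        assert rhat(x) == pytest.approx(1.0, abs=0.01)
        # separated chains inflate R-hat
        y = x + np.arange(4)[:, None] * 3.0
        assert rhat(y) > 1.5


def _gaussian_target(dim=10, seed=0):
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(dim, dim))
    cov = A @ A.T / dim + np.eye(dim)
    prec = np.linalg.inv(cov)

    def log_post(x):
        return -0.5 * x @ prec @ x

    return log_post, cov


class TestMetropolisWithinGibbs:
    def test_same_seed_bit_identical(self):
        log_post, _ = _gaussian_target(4)
        blocks = [np.arange(2), np.arange(2, 4)]
        cfg = McmcConfig(burn_in=50, target_ess=20, check_every=100,
                         max_sweeps=200)
        starts = np.ones((3, 4))
        a = metropolis_within_gibbs(log_post, blocks, starts, cfg, seed=5)
        b = metropolis_within_gibbs(log_post, blocks, starts, cfg, seed=5)
        np.testing.assert_array_equal(a.draws, b.draws)
        c = metropolis_within_gibbs(log_post, blocks, starts, cfg, seed=6)
        assert not np.array_equal(a.draws, c.draws)

    def test_recovers_gaussian_moments(self):
        log_post, cov = _gaussian_target(10, seed=1)
        d = cov.shape[0]
        rng = np.random.default_rng(2)
        starts = rng.normal(0, 2, size=(5, d))
        cfg = McmcConfig(burn_in=400, target_ess=500, check_every=500,
                         max_sweeps=6000)
        chains = metropolis_within_gibbs(
            log_post, [np.arange(d)], starts, cfg, seed=11,
            proposal_chol=[np.linalg.cholesky(cov)])
        assert chains.converged and chains.min_ess >= 500
        pooled = chains.draws.reshape(-1, d)
        mc_se = np.sqrt(np.diag(cov) / chains.min_ess)
        assert np.all(np.abs(pooled.mean(0)) < 3 * mc_se)
        emp = np.cov(pooled.T)
        assert np.abs(emp - cov).max() / np.abs(cov).max() < 0.10
        assert chains.max_rhat < 1.11
        assert np.all((chains.acceptance > 0) & (chains.acceptance < 1))

    def test_blocks_must_partition(self):
        log_post, _ = _gaussian_target(3)
        with pytest.raises(ValueError):
            metropolis_within_gibbs(log_post, [np.arange(2)], np.zeros((1, 3)),
                                    McmcConfig(burn_in=10), seed=0)


class TestThinning:
    def _chains(self, n):
        rng = np.random.default_rng(0)
        from smoketrends.inference import ChainSet
        m, d = 5, 3
        return ChainSet(draws=rng.normal(size=(m, n, d)),
                        log_post=rng.normal(size=(m, n)),
                        log_lik=rng.normal(size=(m, n)), burn_in=0,
                        acceptance=np.full((m, 2), 0.3),
                        blocks=[np.arange(2), np.array([2])],
                        min_ess=100.0, max_rhat=1.0, converged=True)

    def test_five_by_forty_gives_two_hundred(self):
        s = thin_to_sample(self._chains(4000))
        assert s.draws.shape[0] == 200
        assert s.log_lik.shape == (200,)
        assert np.bincount(s.chain_id).tolist() == [40] * 5

    def test_exact_length_chain_fully_retained(self):
        ch = self._chains(40)
        s = thin_to_sample(ch)
        np.testing.assert_array_equal(s.draws[:40], ch.draws[0])

    def test_indices_even_and_strictly_increasing(self):
        ch = self._chains(301)
        idx = np.round(np.linspace(0, 300, 40)).astype(int)
        s = thin_to_sample(ch)
        np.testing.assert_array_equal(s.draws[:40], ch.draws[0, idx])
        assert np.all(np.diff(idx) > 0)
        assert idx[0] == 0 and idx[-1] == 300

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            thin_to_sample(self._chains(39))
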