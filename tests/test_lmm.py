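"""The Gaussian animal-model sampler: likelihood, conditional updates,
the Metropolis ratio step, and the full chain against a quadrature oracle."""

import numpy as np
import pytest

import microherit as mh
from microherit.lmm import LMMState, _reflect

RNG = np.random.default_rng


class TestLogLikelihood:
    def test_single_point_at_mean(self):
        ll = mh.lmm_log_likelihood(np.array([2.0]), np.array([2.0]),
                                   np.array([[1.0]]), np.eye(1))
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi))

    def test_two_points_identity_cov(self):
        y = np.array([1.0, 0.0])
        ll = mh.lmm_log_likelihood(y, np.zeros(2), np.eye(2), None)
        assert ll == pytest.approx(-np.log(2 * np.pi) - 0.5)

    def test_location_invariance(self):
        rng = RNG(0)
        X = np.ones((5, 1))
        y = rng.standard_normal(5)
        V = np.eye(5) * 1.3
        a = mh.lmm_log_likelihood(y, np.array([0.7]), V, X)
        b = mh.lmm_log_likelihood(y + 10.0, np.array([10.7]), V, X)
        assert a == pytest.approx(b)

    def test_matches_scipy_mvn(self):
        from scipy.stats import multivariate_normal

        rng = RNG(1)
        n = 6
        B = rng.standard_normal((n, n))
        V = B @ B.T + n * np.eye(n)
        y = rng.standard_normal(n)
        assert mh.lmm_log_likelihood(y, np.zeros(0), V, None) == pytest.approx(
            multivariate_normal(mean=np.zeros(n), cov=V).logpdf(y))


class TestGibbsUpdates:
    def test_beta_identity_design_centers_on_y(self):
        rng = RNG(2)
        y = np.array([1.0, -2.0, 3.0])
        draws = np.array([mh.gibbs_update_beta(y, np.eye(3), np.eye(3), rng)
                          for _ in range(4000)])
        assert np.allclose(draws.mean(axis=0), y, atol=3 * 1.0 / np.sqrt(4000))

    def test_beta_averages_to_gls(self):
        rng = RNG(3)
        n, p = 12, 2
        X = rng.standard_normal((n, p))
        B = rng.standard_normal((n, n))
        V = B @ B.T + n * np.eye(n)
        y = rng.standard_normal(n)
        Vi = np.linalg.inv(V)
        cov = np.linalg.inv(X.T @ Vi @ X)
        gls = cov @ X.T @ Vi @ y
        draws = np.array([mh.gibbs_update_beta(y, X, V, rng) for _ in range(10_000)])
        se = np.sqrt(np.diag(cov) / 10_000)
        assert np.all(np.abs(draws.mean(axis=0) - gls) < 3 * se)

    def test_beta_covariance_scales_with_sigma2(self):
        # paired seeds: scaling V by 4 doubles the draw's deviation exactly
        n = 40
        X = np.ones((n, 1))
        y = RNG(4).standard_normal(n)
        for seed in range(20):
            d1 = mh.gibbs_update_beta(y, X, np.eye(n), RNG(seed))
            d2 = mh.gibbs_update_beta(y, X, 4 * np.eye(n), RNG(seed))
            assert d2 - y.mean() == pytest.approx(2 * (d1 - y.mean()))

    def test_sigma2_posterior_mean(self, sib_pair_kernels):
        # with K = I the conditional is inverse-gamma(n/2-1, S/2), mean S/(n-4)
        rng = RNG(5)
        n = 20
        kern = mh.CovarianceKernels(np.eye(n), np.eye(n), np.eye(n))
        y = RNG(0).standard_normal(n)
        S = float(y @ y)
        draws = [mh.gibbs_update_sigma2(y, None, np.zeros(0),
                                        mh.VarianceRatios(0, 0, 0), kern, rng)
                 for _ in range(20_000)]
        assert np.mean(draws) == pytest.approx(S / (n - 4), rel=0.05)

    def test_sigma2_scales_quadratically_in_residual(self):
        n = 10
        kern = mh.CovarianceKernels(np.eye(n), np.eye(n), np.eye(n))
        y = RNG(1).standard_normal(n)
        d1 = mh.gibbs_update_sigma2(y, None, np.zeros(0),
                                    mh.VarianceRatios(0, 0, 0), kern, RNG(7))
        d2 = mh.gibbs_update_sigma2(2 * y, None, np.zeros(0),
                                    mh.VarianceRatios(0, 0, 0), kern, RNG(7))
        assert d2 == pytest.approx(4 * d1)

    def test_sigma2_needs_enough_data(self):
        kern = mh.CovarianceKernels(np.eye(2), np.eye(2), np.eye(2))
        with pytest.raises(ValueError, match="n > 2"):
            mh.gibbs_update_sigma2(np.ones(2), None, np.zeros(0),
                                   mh.VarianceRatios(0, 0, 0), kern, RNG(0))


class TestRatioMetropolis:
    def test_reflection_stays_inside(self):
        for x in np.linspace(-3, 3, 101):
            y = _reflect(x, 0.0, 0.7)
            assert 0.0 <= y <= 0.7
        assert _reflect(-0.1, 0.0, 1.0) == pytest.approx(0.1)
        assert _reflect(1.2, 0.0, 1.0) == pytest.approx(0.8)

    def test_flat_target_always_accepts(self):
        # identity kernels make V independent of every ratio
        n = 6
        kern = mh.CovarianceKernels(np.eye(n), np.eye(n), np.eye(n))
        state = LMMState(np.zeros(0), mh.VarianceRatios(0.2, 0.1, 0.1), 1.0)
        y = RNG(0).standard_normal(n)
        rng = RNG(1)
        accepted = 0
        for _ in range(200):
            new, acc = mh.mh_update_ratio("h2", state, y, None, kern, 0.1, rng)
            state.ratios = new
            accepted += acc
        assert accepted == 200

    def test_moving_upper_bound_respected(self):
        n = 4
        kern = mh.CovarianceKernels(np.eye(n), np.eye(n), np.eye(n))
        state = LMMState(np.zeros(0), mh.VarianceRatios(0.05, 0.55, 0.35), 1.0)
        y = RNG(2).standard_normal(n)
        rng = RNG(3)
        for _ in range(300):
            state.ratios, _ = mh.mh_update_ratio("h2", state, y, None, kern, 0.3, rng)
            assert 0 <= state.ratios.h2 <= 1 - 0.55 - 0.35 + 1e-12

    def test_step_must_be_positive(self):
        kern = mh.CovarianceKernels(np.eye(2), np.eye(2), np.eye(2))
        state = LMMState(np.zeros(0), mh.VarianceRatios(0, 0, 0), 1.0)
        with pytest.raises(ValueError):
            mh.mh_update_ratio("h2", state, np.zeros(2), None, kern, 0.0, RNG(0))


def _sib_pair_toy(n_pairs, h2, seed):
    """Full-sib-pair toy data under the one-ratio model (l2 = c2 = 0)."""
    n = 2 * n_pairs
    blocks = [np.array([[1.0, 0.5], [0.5, 1.0]])] * n_pairs
    K_A = np.zeros((n, n))
    for i, b in enumerate(blocks):
        K_A[2 * i:2 * i + 2, 2 * i:2 * i + 2] = b
    kern = mh.CovarianceKernels(K_A, np.eye(n), np.eye(n))
    rng = RNG(seed)
    K = h2 * K_A + (1 - h2) * np.eye(n)
    y = np.linalg.cholesky(K) @ rng.standard_normal(n)
    return y, kern, K_A


def _h2_marginal_oracle(y, K_A, grid):
    """log p(h2 | y) up to a constant, sigma2 integrated analytically
    under its flat positive prior: |K|^{-1/2} S^{-(n/2-1)}."""
    n = y.size
    out = np.empty(grid.size)
    for i, h2 in enumerate(grid):
        K = h2 * K_A + (1 - h2) * np.eye(n)
        sign, logdet = np.linalg.slogdet(K)
        S = y @ np.linalg.solve(K, y)
        out[i] = -0.5 * logdet - (n / 2 - 1) * np.log(S)
    return out


class TestFullChain:
    def test_same_seed_bitwise_identical(self, small_lmm_study):
        _, st = small_lmm_study
        y = st.traits.trait("trait_1")
        s = mh.MCMCSettings(n_iter=120, burnin=40, bf_stride=2, seed=11)
        c1 = mh.run_lmm_mcmc(y, st.design, st.kernels, s)
        c2 = mh.run_lmm_mcmc(y, st.design, st.kernels, s)
        assert np.array_equal(c1.ratios, c2.ratios)
        assert np.array_equal(c1.deviance, c2.deviance)
        for nm in c1.log_zero_density:
            assert np.array_equal(c1.log_zero_density[nm], c2.log_zero_density[nm])

    def test_kept_draws_respect_constraints(self, small_lmm_study):
        _, st = small_lmm_study
        y = st.traits.trait("trait_1")
        c = mh.run_lmm_mcmc(y, st.design, st.kernels,
                            mh.MCMCSettings(n_iter=300, burnin=50, bf_stride=0, seed=1))
        assert np.all(c.ratios >= 0)
        assert np.all(c.ratios.sum(axis=1) <= 1.0)
        assert np.all(c.sigma2 > 0)

    def test_h2_marginal_matches_quadrature_oracle(self):
        """The chain's h2 histogram agrees with the deterministic
        grid posterior of the one-ratio toy model (TV < 0.05)."""
        y, kern, K_A = _sib_pair_toy(n_pairs=15, h2=0.6, seed=42)
        s = mh.MCMCSettings(n_iter=50_000, burnin=2_000, bf_stride=0,
                            step_ratio=0.25, seed=5,
                            fix_ratios={"l2": 0.0, "c2": 0.0})
        chain = mh.run_lmm_mcmc(y, None, kern, s)
        edges = np.linspace(0, 1, 16)
        hist, _ = np.histogram(chain.ratio("h2"), bins=edges)
        p_chain = hist / hist.sum()
        fine = np.linspace(0, 1, 3001)[:-1] + 1.0 / 6002
        logp = _h2_marginal_oracle(y, K_A, fine)
        w = np.exp(logp - logp.max())
        w /= w.sum()
        p_oracle = np.array([w[(fine >= lo) & (fine < hi)].sum()
                             for lo, hi in zip(edges[:-1], edges[1:])])
        tv = 0.5 * np.abs(p_chain - p_oracle).sum()
        assert tv < 0.05
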