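"""Reduced-rank Gibbs sampler: initialization, posterior correctness,
PTVE, coefficient rank, latent embedding and convergence diagnostics."""

import numpy as np
import pytest
from scipy.linalg import subspace_angles
from scipy.stats import norm

from famspec import (
    BRRRConfig,
    FamilyDesign,
    coefficient_matrix,
    convergence_diagnostic,
    fit,
    init_reduced_rank,
    latent_embed,
    ptve,
    synthesize_cohort,
)
from famspec.brrr import BRRRPosterior


class TestInitReducedRank:
    def test_noise_free_exact_recovery(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((30, 5))
        psi = rng.standard_normal((5, 2))
        gamma = rng.standard_normal((2, 8))
        Y = X @ psi @ gamma
        p0, g0 = init_reduced_rank(Y, X, 2)
        assert np.allclose(X @ p0 @ g0, Y, atol=1e-6)

    def test_intercept_only_recovers_mean_direction(self):
        # X = ones column: the rank-1 fitted matrix is the outer product of
        # ones with the column means, so Gamma0 aligns with the mean profile
        rng = np.random.default_rng(1)
        Y = rng.standard_normal((20, 6)) + np.array([3, 1, -2, 0.5, 0, 1])
        X = np.ones((20, 1))
        _, g0 = init_reduced_rank(Y, X, 1)
        v = Y.mean(axis=0)
        cos = abs(g0[0] @ v) / (np.linalg.norm(g0[0]) * np.linalg.norm(v))
        assert cos > 1 - 1e-10

    def test_matches_brute_force_rank2_optimum(self):
        # variance explained by (Psi0, Gamma0) equals the Eckart-Young
        # optimum over rank-2 coefficient matrices (top-2 singular values
        # of the least-squares fitted values)
        rng = np.random.default_rng(2)
        X = rng.standard_normal((20, 5))
        Y = rng.standard_normal((20, 8))
        p0, g0 = init_reduced_rank(Y, X, 2)
        explained = np.sum((X @ p0 @ g0) ** 2)
        B_full, *_ = np.linalg.lstsq(X, Y, rcond=None)
        s = np.linalg.svd(X @ B_full, compute_uv=False)
        assert explained == pytest.approx(np.sum(s[:2] ** 2), rel=1e-6)

    def test_excessive_k_reduced_with_warning(self):
        rng = np.random.default_rng(3)
        X = np.ones((15, 1))
        Y = rng.standard_normal((15, 4)) + 7.0
        with pytest.warns(RuntimeWarning):
            p0, g0 = init_reduced_rank(Y, X, 3)
        assert g0.shape[0] == 1


class TestFitBasics:
    def test_single_retained_sample(self, tiny_cohort):
        Y, F, _, _ = tiny_cohort
        cfg = BRRRConfig(K=2, n_iter=6, burn_in=5, seed=0)
        post = fit(Y, F.indicator, cfg)
        assert post.n_samples == 1

    def test_same_seed_bitwise_identical(self, tiny_cohort):
        Y, F, _, _ = tiny_cohort
        cfg = BRRRConfig(K=3, n_iter=40, burn_in=20, seed=17)
        a = fit(Y, F.indicator, cfg)
        b = fit(Y, F.indicator, cfg)
        assert np.array_equal(a.psi_mean, b.psi_mean)
        assert np.array_equal(a.gamma_mean, b.gamma_mean)

    def test_nonfinite_rejected(self, tiny_cohort):
        Y, F, _, _ = tiny_cohort
        bad = Y.values.copy()
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            fit(bad, F.indicator, BRRRConfig(K=2, n_iter=4, burn_in=2))

    def test_k_larger_than_n_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            fit(rng.standard_normal((5, 8)), np.ones((5, 1)),
                BRRRConfig(K=6, n_iter=4, burn_in=2))

    def test_tau_is_exact_cumprod_of_delta(self, fitted_small):
        assert np.array_equal(
            fitted_small.tau_samples, np.cumprod(fitted_small.delta_samples, axis=1)
        )

    def test_gamma_subspace_recovery_low_noise(self):
        # principal angles between span(Gamma_hat^T) and span(gamma_true^T)
        # shrink at low noise
        Y, F, _, truth = synthesize_cohort(
            n_families=60, n_snps=5, p_features=40, k_true=3,
            familial_share=0.95, noise_sd=0.05, seed=21,
        )
        post = fit(Y, F.indicator, BRRRConfig(K=3, n_iter=200, burn_in=100, seed=2))
        ang = subspace_angles(post.gamma_mean.T, truth.gamma_true.T)
        assert np.degrees(np.max(ang)) < 5.0


class TestPtve:
    def test_zero_psi_gives_zero(self, tiny_cohort):
        Y, F, _, _ = tiny_cohort
        post = fit(Y, F.indicator, BRRRConfig(K=2, n_iter=10, burn_in=5, seed=0))
        post.psi_samples[:] = 0.0
        mean, sd, trace = ptve(post, Y, F.indicator)
        assert mean == 0.0 and np.all(trace == 0.0)

    def test_empty_subset_rejected(self, tiny_cohort, fitted_small, small_cohort):
        Y, F, _, _ = small_cohort
        with pytest.raises(ValueError):
            ptve(fitted_small, Y, F.indicator, [])

    def test_per_sample_matches_brute_force(self):
        # PTVE per retained sample equals a direct Frobenius-ratio
        # computation on a small instance
        rng = np.random.default_rng(4)
        Y = rng.standard_normal((10, 4))
        X = rng.standard_normal((10, 3))
        post = fit(Y, X, BRRRConfig(K=2, n_iter=12, burn_in=6, seed=2))
        sub = [0, 2]
        _, _, trace = ptve(post, Y, X, sub)
        Yc = Y - Y.mean(axis=0)
        for s in range(post.n_samples):
            A = X[:, sub] @ post.psi_samples[s][sub] @ post.gamma_samples[s]
            expected = np.sum(A**2) / np.sum(Yc**2)
            assert trace[s] == pytest.approx(expected, rel=1e-12)

    def test_single_column_shortcut_matches_general(self, small_cohort):
        Y, F, G, _ = small_cohort
        g = G.counts[:, 0] - G.counts[:, 0].mean()
        X = np.hstack([F.indicator, g[:, None]])
        post = fit(Y, X, BRRRConfig(K=3, n_iter=30, burn_in=15, seed=3))
        m1, _, t1 = ptve(post, Y, X, [F.m])
        Yc = Y.centered()
        A = X[:, [F.m]] @ post.psi_samples[0][[F.m]] @ post.gamma_samples[0]
        assert t1[0] == pytest.approx(np.sum(A**2) / np.sum(Yc**2), rel=1e-10)

    def test_near_noiseless_ptve_close_to_one(self):
        Y, F, _, truth = synthesize_cohort(
            n_families=30, n_snps=5, p_features=30, k_true=3,
            familial_share=0.999, noise_sd=0.01, seed=9,
        )
        post = fit(Y, F.indicator, BRRRConfig(K=3, n_iter=60, burn_in=30, seed=1))
        mean, _, _ = ptve(post, Y, F.indicator)
        assert mean > 0.95

    def test_monotone_in_k(self, small_cohort):
        Y, F, _, _ = small_cohort
        means = []
        for K in (2, 4, 6):
            post = fit(Y, F.indicator, BRRRConfig(K=K, n_iter=120, burn_in=60, seed=4))
            means.append(ptve(post, Y, F.indicator)[0])
        assert means[1] >= means[0] - 0.01
        assert means[2] >= means[1] - 0.01

    def test_family_ptve_recovers_generative_share(self):
        # family fixed effects absorb chance noise along the K latent
        # directions (upward bias ~ (M/N)(1-share)K/P), so recovery is
        # checked where that bias is small: 4 siblings per family
        Y, F, _, truth = synthesize_cohort(
            n_families=50, sibs_per_family=4, n_snps=5, p_features=60,
            k_true=6, familial_share=0.5, noise_sd=0.1, seed=13,
        )
        S = F.indicator @ truth.psi_true @ truth.gamma_true
        Sc = S - S.mean(axis=0)
        share = np.sum(Sc**2) / np.sum(Y.centered() ** 2)
        post = fit(Y, F.indicator, BRRRConfig(K=6, n_iter=200, burn_in=100, seed=8))
        mean, _, _ = ptve(post, Y, F.indicator)
        assert mean == pytest.approx(share, abs=0.02)


class TestCoefficientMatrix:
    def test_rank_equals_k(self, fitted_small):
        beta = coefficient_matrix(fitted_small)
        s = np.linalg.svd(beta, compute_uv=False)
        assert int(np.sum(s > s[0] * 1e-8)) == fitted_small.config.K

    def test_rank_one_for_k1(self, tiny_cohort):
        Y, F, _, _ = tiny_cohort
        post = fit(Y, F.indicator, BRRRConfig(K=1, n_iter=12, burn_in=6, seed=5))
        beta = coefficient_matrix(post)
        s = np.linalg.svd(beta, compute_uv=False)
        assert int(np.sum(s > s[0] * 1e-8)) == 1

    def test_two_sample_hand_average(self):
        psi = np.stack([np.array([[1.0], [0.0]]), np.array([[0.0], [2.0]])])
        gamma = np.stack([np.array([[1.0, 2.0]]), np.array([[3.0, 4.0]])])
        post = BRRRPosterior(
            psi_samples=psi, gamma_samples=gamma,
            omega_samples=np.zeros((2, 3, 1)), delta_samples=np.ones((2, 1)),
            col_means=np.zeros(2), config=BRRRConfig(K=1, n_iter=4, burn_in=2),
        )
        expected = (psi[0] @ gamma[0] + psi[1] @ gamma[1]) / 2
        assert np.allclose(coefficient_matrix(post, method="mean_of_products"), expected)


class TestLatentEmbed:
    def test_identity_block_gamma(self):
        rng = np.random.default_rng(6)
        Y = rng.standard_normal((8, 5))
        gamma = np.hstack([np.eye(2), np.zeros((2, 3))])
        emb = latent_embed(Y, gamma)
        Yc = Y - Y.mean(axis=0)
        assert np.allclose(emb, Yc[:, :2])

    def test_exact_inversion_on_row_space(self):
        rng = np.random.default_rng(7)
        Z = rng.standard_normal((10, 3))
        gamma = rng.standard_normal((3, 12))
        Y = Z @ gamma
        emb = latent_embed(Y, gamma, center=np.zeros(12))
        assert np.allclose(emb, Z, atol=1e-8)

    def test_matches_svd_pseudo_inverse(self):
        rng = np.random.default_rng(8)
        gamma = rng.standard_normal((5, 12))
        Y = rng.standard_normal((6, 12))
        emb = latent_embed(Y, gamma)
        Yc = Y - Y.mean(axis=0)
        assert np.allclose(emb, Yc @ np.linalg.pinv(gamma), atol=1e-10)

    def test_rank_deficient_warns(self):
        rng = np.random.default_rng(9)
        g1 = rng.standard_normal((1, 6))
        gamma = np.vstack([g1, g1])  # rank 1
        Y = rng.standard_normal((4, 6))
        with pytest.warns(RuntimeWarning):
            latent_embed(Y, gamma)


class TestConvergenceDiagnostic:
    def _const_posterior(self, tiny_cohort):
        from famspec import fit as _fit

        Y, F, _, _ = tiny_cohort
        post = _fit(Y, F.indicator, BRRRConfig(K=2, n_iter=12, burn_in=6, seed=0))
        for s in range(post.n_samples):
            post.psi_samples[s] = post.psi_samples[0]
            post.gamma_samples[s] = post.gamma_samples[0]
        return Y, F, post

    def test_constant_trace_zero_diff(self, tiny_cohort):
        Y, F, post = self._const_posterior(tiny_cohort)
        summ = convergence_diagnostic(post, Y, F.indicator)
        assert summ.split_half_diff == 0.0
        assert summ.converged

    def test_alternating_trace_flagged(self, tiny_cohort):
        Y, F, post = self._const_posterior(tiny_cohort)
        # scale alternate samples to create a 0/large oscillating PTVE trace
        for s in range(0, post.n_samples, 2):
            post.psi_samples[s] = 0.0
        summ = convergence_diagnostic(post, Y, F.indicator)
        assert not summ.converged

    def test_short_vs_long_chain_agree(self, small_cohort):
        Y, F, _, _ = small_cohort
        short = fit(Y, F.indicator, BRRRConfig(K=6, n_iter=500, burn_in=250, seed=6))
        long = fit(Y, F.indicator, BRRRConfig(K=6, n_iter=1500, burn_in=250, seed=7))
        m_s, _, _ = ptve(short, Y, F.indicator)
        m_l, _, _ = ptve(long, Y, F.indicator)
        assert abs(m_s - m_l) < 0.005


class TestGibbsCorrectness:
    def test_posterior_mean_beta_matches_importance_sampling(self):
        """On a tiny K=1 instance, the Gibbs posterior mean of beta agrees
        with an importance-sampling approximation that integrates Psi and
        Omega analytically and samples (delta, Gamma) from the prior."""
        rng = np.random.default_rng(12)
        N, P, M = 20, 4, 2
        X = rng.standard_normal((N, M))
        psi_t = np.array([[1.0], [-0.6]])
        gamma_t = np.array([[1.0, 0.5, -0.5, 0.25]])
        sigma = 1.0
        Y = X @ psi_t @ gamma_t + sigma * rng.standard_normal((N, P))
        cfg = BRRRConfig(K=1, n_iter=3000, burn_in=500, sigma_e=sigma, seed=3)
        post = fit(Y, X, cfg)
        beta_gibbs = np.mean(
            [post.psi_samples[s] @ post.gamma_samples[s] for s in range(post.n_samples)],
            axis=0,
        )

        # --- importance sampling oracle ---
        Yc = Y - Y.mean(axis=0)
        y2 = np.sum(Yc**2)
        XXt = X @ X.T
        d_eig, U = np.linalg.eigh(XXt)
        d_eig = np.clip(d_eig, 0, None)
        XtX = X.T @ X
        S = 200_000
        rng_is = np.random.default_rng(99)
        delta = rng_is.gamma(cfg.delta1_shape, 1.0 / cfg.delta1_rate, size=S)
        tau = delta
        gammas = rng_is.standard_normal((S, P)) / np.sqrt(tau)[:, None]
        gnorm = np.linalg.norm(gammas, axis=1)
        y1 = (Yc @ gammas.T) / gnorm  # (N, S) projections onto gamma direction
        u = U.T @ y1  # (N, S)
        s_om2 = (cfg.omega_scale / tau) ** 2
        var = (gnorm**2)[None, :] * (d_eig[:, None] / tau[None, :] + s_om2[None, :]) \
            + sigma**2
        loglik1 = -0.5 * np.sum(np.log(2 * np.pi * var) + u**2 / var, axis=0)
        orth = y2 - np.sum(y1**2, axis=0)
        loglik_orth = -orth / (2 * sigma**2)  # constant terms cancel in weights
        logw = loglik1 + loglik_orth
        logw -= logw.max()
        w = np.exp(logw)
        # E[psi | gamma, delta, Y] with omega and E noise combined
        m_noise = sigma**2 + gnorm**2 * s_om2
        beta_draws = np.empty((S, M, P))
        for i in range(S):
            A = (gnorm[i] ** 2 / m_noise[i]) * XtX + tau[i] * np.eye(M)
            psi_hat = np.linalg.solve(A, X.T @ y1[:, i]) * gnorm[i] / m_noise[i]
            beta_draws[i] = np.outer(psi_hat, gammas[i])
        wsum = w.sum()
        beta_is = np.tensordot(w, beta_draws, axes=1) / wsum
        # weighted-mean standard error per entry
        dev = beta_draws - beta_is
        se = np.sqrt(np.tensordot(w**2, dev**2, axes=1)) / wsum
        scale = np.abs(beta_is).max()
        assert np.all(np.abs(beta_gibbs - beta_is) < 5 * se + 0.05 * scale)
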