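"""Summary-level Gibbs sampler: single-step conditionals and full chains."""

import numpy as np
import pytest

import sbayesr as sb
from sbayesr.gibbs import GibbsState, _default_s2_beta
from sbayesr.sumstats import SufficientStats


def _toy_stats(p=5, djj=100.0, b=None):
    D = np.full(p, djj)
    b = np.zeros(p) if b is None else np.asarray(b, dtype=float)
    return SufficientStats(D_diag=D, Xty=D * b, yty=float(djj), n_bar=float(djj))


def _dense_identity_ld(p):
    import pandas as pd
    from sbayesr.ldref import SparseLDMatrix

    info = pd.DataFrame({
        "snp_id": [f"rs{i}" for i in range(p)], "chrom": "1",
        "bp": np.arange(1, p + 1) * 1000, "cm": np.zeros(p),
        "A1": "A", "A2": "G", "freq": np.full(p, 0.3),
    })
    indptr = np.arange(p + 1, dtype=np.int64)
    return SparseLDMatrix(info=info, window_start=np.arange(p, dtype=np.int64),
                          values_per_snp=(indptr, np.ones(p)))


class TestSweep:
    def test_conditional_mean_closed_form(self):
        # single scaled SNP: (X'X)_jj = n = 100, X'y = n*b = 20,
        # sigma_eps^2/sigma_beta^2 = 100, gamma = 1 -> l = 200, mean = 0.1
        mean, var = sb.conditional_beta_moments(
            r_j=20.0, djj=100.0, gamma_c=1.0, sigma2_beta=0.01, sigma2_eps=1.0)
        assert mean == pytest.approx(20.0 / 200.0)
        assert var == pytest.approx(1.0 / 200.0)

    def test_ridge_vanishes_in_large_variance_limit(self):
        mean, _ = sb.conditional_beta_moments(
            r_j=20.0, djj=100.0, gamma_c=1.0, sigma2_beta=1e12, sigma2_eps=1.0)
        assert mean == pytest.approx(20.0 / 100.0, rel=1e-9)

    def test_unchanged_beta_leaves_r_star_unchanged(self):
        stats = _toy_stats(p=3)  # all b = 0
        ld = _dense_identity_ld(3)
        mix = sb.MixtureSpec(gamma=(0.0, 1.0), pi_init=(1.0 - 1e-12, 1e-12))
        state = GibbsState.initial(stats, mix, sigma2_beta=0.01, sigma2_eps=1.0)
        before = state.r_star.copy()
        rng = np.random.default_rng(0)
        for j in range(3):
            sb.sweep_snp(j, state, stats, ld, mix, rng)
        # with pi_1 ~ 1 and r_j = 0 every SNP stays null: delta = 0
        np.testing.assert_array_equal(state.r_star, before)
        np.testing.assert_array_equal(state.beta, np.zeros(3))

    def test_rhs_update_is_windowed_subtraction(self, small_panel):
        sub = small_panel.subset(cols=np.arange(20))
        ld = sb.build_sparse_ld(sub, cfg=None)
        X = sub.standardized(scale=False)
        D = (X**2).sum(axis=0)
        rng0 = np.random.default_rng(1)
        y = rng0.standard_normal(sub.n)
        stats = SufficientStats(D_diag=D, Xty=X.T @ y, yty=float(y @ y),
                                n_bar=float(sub.n))
        mix = sb.MixtureSpec(gamma=(0.0, 1.0), pi_init=(1e-12, 1.0 - 1e-12))
        state = GibbsState.initial(stats, mix, sigma2_beta=0.1, sigma2_eps=1.0)
        rng = np.random.default_rng(2)
        for j in range(20):
            sb.sweep_snp(j, state, stats, ld, mix, rng)
        XtX = X.T @ X
        expected = stats.Xty - XtX @ state.beta
        np.testing.assert_allclose(state.r_star, expected, atol=1e-8)


class TestConditionals:
    def test_sigma2_beta_prior_when_empty(self):
        stats = _toy_stats()
        mix = sb.MixtureSpec()
        cfg = sb.ChainConfig(nu_beta=4.0, S2_beta_init=0.5, seed=0)
        state = GibbsState.initial(stats, mix, 0.5, 1.0)
        rng = np.random.default_rng(3)
        draws = [sb.sample_sigma2_beta(state, mix, cfg, rng) for _ in range(4000)]
        draws = np.array(draws)
        assert np.all(draws > 0)
        # scaled-inv-chi2(nu, S2) mean = nu S2/(nu-2) = 4*0.5/2 = 1
        assert draws.mean() == pytest.approx(1.0, abs=0.15)

    def test_sigma2_beta_concentrates_on_effect_scale(self):
        p = 400
        stats = _toy_stats(p=p)
        mix = sb.MixtureSpec(gamma=(0.0, 1.0), pi_init=(0.5, 0.5))
        cfg = sb.ChainConfig(nu_beta=4.0, S2_beta_init=1e-6, seed=0)
        v = 0.04
        state = GibbsState.initial(stats, mix, 1.0, 1.0)
        state.comp[:] = 1
        state.beta[:] = np.sqrt(v)  # beta^2/gamma = v for every SNP
        rng = np.random.default_rng(4)
        draws = np.array([sb.sample_sigma2_beta(state, mix, cfg, rng)
                          for _ in range(2000)])
        se = draws.std() / np.sqrt(len(draws))
        assert abs(draws.mean() - v) < 3 * se + v * 5.0 / p  # mean ~ q v/(q+nu-2)

    def test_sigma2_eps_null_model_sse(self):
        stats = _toy_stats(p=4, djj=100.0)
        mix = sb.MixtureSpec()
        cfg = sb.ChainConfig(nu_eps=4.0, S2_eps_init=1.0, seed=0)
        state = GibbsState.initial(stats, mix, 0.1, 1.0)
        # beta = 0 -> SSE = y'y = n_bar; draws around (n + nu S2)/(n + nu)
        rng = np.random.default_rng(5)
        draws = np.array([sb.sample_sigma2_eps(state, stats, cfg, rng)
                          for _ in range(2000)])
        expect = (stats.yty + 4.0) / (100.0 + 4.0 - 2.0)
        assert draws.mean() == pytest.approx(expect, rel=0.05)

    def test_sse_quadratic_form_identity(self, small_panel):
        """beta'(X'y - r*) equals the dense quadratic form beta'X'X beta."""
        sub = small_panel.subset(cols=np.arange(20))
        ld = sb.build_sparse_ld(sub, cfg=None)
        X = sub.standardized(scale=False)
        D = (X**2).sum(axis=0)
        rng = np.random.default_rng(6)
        y = rng.standard_normal(sub.n)
        stats = SufficientStats(D_diag=D, Xty=X.T @ y, yty=float(y @ y),
                                n_bar=float(sub.n))
        mix = sb.MixtureSpec()
        state = GibbsState.initial(stats, mix, 0.1, 1.0)
        beta = rng.normal(0, 0.05, 20)
        state.beta = beta
        XtX = X.T @ X
        state.r_star = stats.Xty - XtX @ beta
        lhs = float(beta @ (stats.Xty - state.r_star))
        rhs = float(beta @ XtX @ beta)
        assert lhs == pytest.approx(rhs, abs=1e-8)

    def test_sigma2_eps_simple_arithmetic(self):
        stats = _toy_stats(p=1, djj=100.0)
        mix = sb.MixtureSpec()
        state = GibbsState.initial(stats, mix, 0.1, 1.0)
        # y'y = 100, beta'(X'y + r*) = 40 -> SSE = 60
        state.beta = np.array([0.4])
        state.r_star = np.array([50.0])
        stats.Xty = np.array([50.0])
        sse = stats.yty - float(state.beta @ (stats.Xty + state.r_star))
        assert sse == pytest.approx(60.0)

    def test_pi_posterior_mean(self):
        stats = _toy_stats(p=1000)
        mix = sb.MixtureSpec()
        state = GibbsState.initial(stats, mix, 0.1, 1.0)
        comp = np.zeros(1000, dtype=np.int64)
        comp[:10] = [1] * 5 + [2] * 4 + [3] * 1
        # counts (990, 5, 4, 1), alpha = 1 -> mean (991, 6, 5, 2)/1004
        state.comp = comp
        rng = np.random.default_rng(7)
        draws = np.array([sb.sample_pi(state, mix, rng) for _ in range(4000)])
        np.testing.assert_allclose(draws.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(
            draws.mean(axis=0), np.array([991, 6, 5, 2]) / 1004.0, atol=0.01)

    def test_pi_uniform_prior_when_no_counts(self):
        stats = _toy_stats(p=4)
        mix = sb.MixtureSpec()
        state = GibbsState.initial(stats, mix, 0.1, 1.0)
        state.comp = np.arange(4) * 0  # all null -> counts (4,0,0,0)
        state.comp = np.zeros(0, dtype=np.int64)  # no SNPs at all
        rng = np.random.default_rng(8)
        draws = np.array([sb.sample_pi(state, mix, rng) for _ in range(4000)])
        np.testing.assert_allclose(draws.mean(axis=0), 0.25, atol=0.02)

    def test_h2_zero_for_null_beta(self):
        stats = _toy_stats(p=5)
        state = GibbsState.initial(stats, sb.MixtureSpec(), 0.1, 1.0)
        assert sb.compute_h2(state, stats) == 0.0

    def test_h2_half_when_variances_equal(self):
        stats = _toy_stats(p=1, djj=100.0)
        state = GibbsState.initial(stats, sb.MixtureSpec(), 0.1, 1.0)
        state.beta = np.array([1.0])
        stats.Xty = np.array([100.0])
        state.r_star = np.array([0.0])  # sigma_g^2 = 100/100 = 1
        state.sigma2_eps = 1.0
        assert sb.compute_h2(state, stats) == pytest.approx(0.5)

    def test_h2_matches_variance_of_fitted_values(self, small_panel):
        sub = small_panel.subset(cols=np.arange(20))
        X = sub.standardized(scale=False)
        D = (X**2).sum(axis=0)
        rng = np.random.default_rng(9)
        y = rng.standard_normal(sub.n)
        stats = SufficientStats(D_diag=D, Xty=X.T @ y, yty=float(y @ y),
                                n_bar=float(sub.n))
        state = GibbsState.initial(stats, sb.MixtureSpec(), 0.1, 1.0)
        beta = rng.normal(0, 0.05, 20)
        state.beta = beta
        state.r_star = stats.Xty - (X.T @ X) @ beta
        g = X @ beta
        sig2g = float(g @ g) / sub.n  # population variance (g is centred)
        expect = sig2g / (sig2g + state.sigma2_eps)
        assert sb.compute_h2(state, stats) == pytest.approx(expect, abs=1e-10)


class TestChain:
    def test_null_summary_data(self):
        p = 50
        stats = _toy_stats(p=p, djj=500.0)  # all b = 0
        ld = _dense_identity_ld(p)
        est = sb.SBayesR(n_iter=600, burn_in=200, thin=5, seed=1)
        est.fit(stats, ld)
        assert np.abs(est.beta_mean_).max() < 0.02
        assert est.h2_mean_ < 0.05

    def test_determinism_same_seed_bitwise(self, small_panel, small_trait):
        y = small_trait["y"]
        y = (y - y.mean()) / y.std()
        ds = sb.run_gwas(small_panel, y)
        stats = sb.reconstruct_sufficient(ds)
        ld = sb.build_genome_ld(small_panel)
        runs = []
        for _ in range(2):
            est = sb.SBayesR(n_iter=400, burn_in=100, seed=11,
                             record_beta_samples=True)
            est.fit(stats, ld)
            runs.append(est.summary_)
        a, b = runs
        np.testing.assert_array_equal(a.h2_samples, b.h2_samples)
        np.testing.assert_array_equal(a.beta_samples, b.beta_samples)
        np.testing.assert_array_equal(a.pi_samples, b.pi_samples)

    def test_different_seeds_differ(self, small_panel, small_trait):
        y = small_trait["y"]
        ds = sb.run_gwas(small_panel, (y - y.mean()) / y.std())
        stats = sb.reconstruct_sufficient(ds)
        ld = sb.build_genome_ld(small_panel)
        h2 = []
        for seed in (1, 2):
            est = sb.SBayesR(n_iter=300, burn_in=100, seed=seed).fit(stats, ld)
            h2.append(est.h2_samples_)
        assert not np.array_equal(h2[0], h2[1])

    def test_mismatched_snp_counts_rejected(self):
        stats = _toy_stats(p=5)
        ld = _dense_identity_ld(4)
        with pytest.raises(ValueError, match="disagree"):
            sb.SBayesR(n_iter=10, burn_in=1).fit(stats, ld)

    def test_default_prior_scale_positive(self):
        stats = _toy_stats(p=10)
        assert _default_s2_beta(stats, sb.MixtureSpec()) > 0


class TestMixtureSpecValidation:
    def test_nonzero_first_gamma_rejected(self):
        with pytest.raises(ValueError):
            sb.MixtureSpec(gamma=(0.1, 1.0), pi_init=(0.5, 0.5))

    def test_pi_must_sum_to_one(self):
        with pytest.raises(ValueError):
            sb.MixtureSpec(gamma=(0.0, 1.0), pi_init=(0.5, 0.6))

    def test_burn_in_bounds(self):
        with pytest.raises(ValueError):
            sb.ChainConfig(n_iter=100, burn_in=100)
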