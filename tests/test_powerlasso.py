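import math

import numpy as np
import pytest
from scipy import integrate

from cropgs import powerlasso as pl


def make_fixture(n=60, m=40, n_qtl=3, seed=0, h2_scale=1.0):
    rng = np.random.default_rng(seed)
    W = rng.integers(0, 3, size=(n, m)).astype(float)
    u = np.zeros(m)
    u[:n_qtl] = rng.normal(0, 1.0, n_qtl) * h2_scale
    y = 1.5 + W @ u + rng.normal(0, 1.0, n)
    X = np.ones((n, 1))
    return y, X, W, u


def bayes_lasso_oracle(y, X, W, chain, burnin, thin, seed):
    """Independent scale-mixture Bayesian Lasso with the same flat priors
    (numpy implementation, numpy.Generator.wald for the inverse Gaussian)."""
    rng = np.random.default_rng(seed)
    n, p = X.shape
    m = W.shape[1]
    xtx = (X**2).sum(axis=0)
    wtw = (W**2).sum(axis=0)
    b = np.zeros(p)
    u = rng.normal(0, 0.01, m)
    tau2 = np.ones(m)
    sig = float(np.var(y))
    lam = 1.0
    r = y - X @ b - W @ u
    draws = []
    for it in range(chain):
        for j in range(p):
            mean = b[j] + X[:, j] @ r / xtx[j]
            new = rng.normal(mean, math.sqrt(sig / xtx[j]))
            r -= X[:, j] * (new - b[j])
            b[j] = new
        for k in range(m):
            prec = wtw[k] / sig + 1.0 / tau2[k]
            mean = ((W[:, k] @ r + wtw[k] * u[k]) / sig) / prec
            new = rng.normal(mean, math.sqrt(1.0 / prec))
            r -= W[:, k] * (new - u[k])
            u[k] = new
            au = max(abs(u[k]), 1e-10)
            inv_t = rng.wald(lam / au, lam * lam)
            tau2[k] = 1.0 / max(inv_t, 1e-12)
        sig = (0.5 * float(r @ r)) / rng.gamma(0.5 * n - 1.0, 1.0)
        lam = rng.gamma(m + 1.0, 1.0 / max(np.abs(u).sum(), 1e-12))
        if it >= burnin and (it - burnin) % thin == 0:
            draws.append(u.copy())
    return np.array(draws)


class TestSampler:
    def test_determinism(self):
        y, X, W, _ = make_fixture()
        cfg = pl.PowerLassoConfig(beta=0.8, chain=800, burnin=200, thin=2, seed=9)
        p1 = pl.sample_posterior(y, X, W, cfg)
        p2 = pl.sample_posterior(y, X, W, cfg)
        np.testing.assert_array_equal(p1.u_mean, p2.u_mean)
        np.testing.assert_array_equal(p1.deviance_draws, p2.deviance_draws)

    def test_stored_draw_count(self):
        y, X, W, _ = make_fixture()
        cfg = pl.PowerLassoConfig(beta=1.0, chain=1000, burnin=400, thin=3, seed=1)
        post = pl.sample_posterior(y, X, W, cfg)
        assert post.n_stored == (1000 - 400) // 3

    def test_matches_independent_bayesian_lasso(self):
        y, X, W, _ = make_fixture(n=60, m=40, seed=2)
        cfg = pl.PowerLassoConfig(beta=1.0, chain=8000, burnin=2000, thin=2, seed=3)
        post = pl.sample_posterior(y, X, W, cfg)
        oracle = bayes_lasso_oracle(y, X, W, chain=8000, burnin=2000, thin=2, seed=4)
        for k in range(W.shape[1]):
            se = math.sqrt(
                np.var(post.u_draws[:, k]) / pl._ess(post.u_draws[:, k])
                + np.var(oracle[:, k]) / pl._ess(oracle[:, k])
            )
            diff = abs(post.u_mean[k] - oracle[:, k].mean())
            assert diff < 4.0 * se + 1e-4

    @pytest.mark.parametrize("beta", [1.0, 0.5])
    def test_single_snp_quadrature_oracle(self, beta):
        rng = np.random.default_rng(5)
        n = 80
        w = rng.integers(0, 3, n).astype(float)
        y = 2.0 + 0.5 * w + rng.normal(0, 1.0, n)
        X = np.ones((n, 1))
        sig, lam = 1.0, 2.0
        cfg = pl.PowerLassoConfig(
            beta=beta, chain=30_000, burnin=5_000, thin=5, seed=6,
            fix_sigma_e2=sig, fix_lambda=lam,
        )
        post = pl.sample_posterior(y, X, w[:, None], cfg)

        # flat prior on the intercept integrates out to the centered SSE
        yc = y - y.mean()
        wc = w - w.mean()

        def log_post(u):
            sse = np.sum((yc - wc * u) ** 2)
            return -sse / (2.0 * sig) - lam * abs(u) ** beta

        grid = np.linspace(-2.0, 3.0, 20_001)
        lp = np.array([log_post(u) for u in grid])
        lp -= lp.max()
        dens = np.exp(lp)
        mean_u = integrate.trapezoid(grid * dens, grid) / integrate.trapezoid(dens, grid)
        mc_se = math.sqrt(np.var(post.u_draws[:, 0]) / pl._ess(post.u_draws[:, 0]))
        assert abs(post.u_mean[0] - mean_u) < 2.0 * mc_se + 1e-3

    def test_shrinkage_monotone_in_lambda(self):
        y, X, W, _ = make_fixture(n=50, m=20, seed=7)
        norms = []
        for lam in (0.5, 5.0, 50.0):
            cfg = pl.PowerLassoConfig(
                beta=1.0, chain=3000, burnin=1000, thin=2, seed=8, fix_lambda=lam
            )
            post = pl.sample_posterior(y, X, W, cfg)
            norms.append(np.abs(post.u_mean).sum())
        assert norms[0] > norms[1] > norms[2]

    def test_rank_recovery_sparse_architecture(self):
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(100 + seed)
            n, m = 150, 300
            W = rng.integers(0, 3, size=(n, m)).astype(float)
            causal = rng.choice(m, 4, replace=False)
            u = np.zeros(m)
            u[causal] = rng.choice([-1.0, 1.0], 4) * rng.uniform(0.8, 1.2, 4)
            y = W @ u + rng.normal(0, 1.0, n)
            cfg = pl.PowerLassoConfig(beta=0.4, chain=3000, burnin=1000, thin=5, seed=seed)
            post = pl.sample_posterior(y, np.ones((n, 1)), W, cfg)
            top10 = set(np.argsort(-np.abs(post.u_mean))[:10])
            if set(causal) <= top10:
                hits += 1
        assert hits >= 16


class TestDic:
    def test_degenerate_posterior(self):
        entry = pl.dic_from_traces(np.full(100, 12.5), 12.5)
        assert entry["p_d"] == 0.0
        assert entry["dic"] == 12.5

    def test_normal_mean_pd_is_one(self):
        # y ~ N(mu, 1) known sigma, flat prior: mu | y ~ N(ybar, 1/n)
        rng = np.random.default_rng(10)
        n = 50
        y = rng.normal(1.0, 1.0, n)
        mus = rng.normal(y.mean(), math.sqrt(1.0 / n), 40_000)
        dev = np.array([np.sum((y - mu) ** 2) + n * math.log(2 * math.pi) for mu in mus])
        dev_at_mean = np.sum((y - mus.mean()) ** 2) + n * math.log(2 * math.pi)
        entry = pl.dic_from_traces(dev, dev_at_mean)
        assert entry["p_d"] == pytest.approx(1.0, abs=0.1)

    def test_noise_snps_increase_pd(self):
        ups, base = [], []
        for seed in range(5):
            y, X, W, _ = make_fixture(n=60, m=20, seed=20 + seed)
            rng = np.random.default_rng(seed)
            W_big = np.hstack([W, rng.integers(0, 3, size=(60, 50)).astype(float)])
            cfg = pl.PowerLassoConfig(beta=1.0, chain=4000, burnin=1000, thin=2, seed=seed)
            base.append(pl.dic(pl.sample_posterior(y, X, W, cfg))["p_d"])
            ups.append(pl.dic(pl.sample_posterior(y, X, W_big, cfg))["p_d"])
        assert np.mean(ups) > np.mean(base)

    def test_pd_nonnegative_on_mixed_chains(self):
        y, X, W, _ = make_fixture(seed=11)
        cfg = pl.PowerLassoConfig(beta=1.0, chain=6000, burnin=2000, thin=2, seed=12)
        entry = pl.dic(pl.sample_posterior(y, X, W, cfg))
        assert entry["p_d"] >= 0.0


class TestSelectBeta:
    def test_singleton_grid(self):
        y, X, W, _ = make_fixture()
        cfg = pl.PowerLassoConfig(beta=1.0, chain=1000, burnin=400, thin=2, seed=13)
        best, report, _ = pl.select_beta(y, X, W, [0.8], cfg)
        assert best == 0.8
        assert len(report.entries) == 1

    def test_sparse_prefers_small_beta(self):
        small = 0
        n_seeds = 12
        for seed in range(n_seeds):
            rng = np.random.default_rng(200 + seed)
            n, m = 100, 120
            W = rng.integers(0, 3, size=(n, m)).astype(float)
            u = np.zeros(m)
            u[rng.choice(m, 4, replace=False)] = rng.choice([-1.0, 1.0], 4) * 1.2
            y = W @ u + rng.normal(0, 1.0, n)
            cfg = pl.PowerLassoConfig(beta=1.0, chain=3000, burnin=1000, thin=5, seed=seed)
            best, _, _ = pl.select_beta(y, np.ones((n, 1)), W, [0.4, 1.0], cfg)
            if best < 1.0:
                small += 1
        assert small >= int(0.75 * n_seeds)

    def test_polygenic_prefers_large_beta_more_often(self):
        sparse_small, poly_small = 0, 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(300 + seed)
            n, m = 100, 120
            W = rng.integers(0, 3, size=(n, m)).astype(float)
            u_sparse = np.zeros(m)
            u_sparse[rng.choice(m, 4, replace=False)] = rng.choice([-1.0, 1.0], 4) * 1.2
            u_poly = rng.normal(0, 0.12, m)
            cfg = pl.PowerLassoConfig(beta=1.0, chain=2500, burnin=800, thin=5, seed=seed)
            for u, counter in ((u_sparse, "s"), (u_poly, "p")):
                y = W @ u + rng.normal(0, 1.0, n)
                best, _, _ = pl.select_beta(y, np.ones((n, 1)), W, [0.4, 1.0], cfg)
                if best < 1.0:
                    if counter == "s":
                        sparse_small += 1
                    else:
                        poly_small += 1
        assert sparse_small >= poly_small


class TestGebv:
    def test_in_sample_identity(self):
        y, X, W, _ = make_fixture(seed=14)
        cfg = pl.PowerLassoConfig(beta=1.0, chain=2000, burnin=500, thin=2, seed=15)
        post = pl.sample_posterior(y, X, W, cfg)
        gebv = pl.gebv_from_posterior(post, W)
        fitted = W @ post.u_mean
        assert np.corrcoef(gebv, fitted)[0, 1] > 0.99

    def test_zero_dosage_row(self):
        y, X, W, _ = make_fixture(seed=16)
        cfg = pl.PowerLassoConfig(beta=1.0, chain=1000, burnin=300, thin=2, seed=17)
        post = pl.sample_posterior(y, X, W, cfg)
        assert pl.gebv_from_posterior(post, np.zeros((1, W.shape[1])))[0] == 0.0

    def test_column_mismatch_rejected(self):
        y, X, W, _ = make_fixture(seed=18)
        cfg = pl.PowerLassoConfig(beta=1.0, chain=600, burnin=200, thin=2, seed=19)
        post = pl.sample_posterior(y, X, W, cfg)
        with pytest.raises(ValueError):
            pl.gebv_from_posterior(post, W[:, :-1])


class TestDiagnostics:
    def test_white_noise_passes_geweke(self):
        rng = np.random.default_rng(21)
        assert abs(pl._geweke_z(rng.normal(size=2000))) < 3.0

    def test_trending_trace_flagged(self):
        rng = np.random.default_rng(22)
        x = np.linspace(0, 5, 2000) + rng.normal(0, 0.5, 2000)
        assert abs(pl._geweke_z(x)) > 3.0

    def test_ess_of_iid_draws(self):
        rng = np.random.default_rng(23)
        x = rng.normal(size=5000)
        assert pl._ess(x) == pytest.approx(5000, rel=0.2)

    def test_convergence_report(self):
        y, X, W, _ = make_fixture(seed=24)
        cfg = pl.PowerLassoConfig(beta=1.0, chain=4000, burnin=1000, thin=2, seed=25)
        post = pl.sample_posterior(y, X, W, cfg)
        report = pl.convergence_check(post)
        assert "deviance" in report and "lambda_rp" in report
        assert report["deviance"]["ess"] > 0

    def test_too_few_draws_rejected(self):
        y, X, W, _ = make_fixture(seed=26)
        cfg = pl.PowerLassoConfig(beta=1.0, chain=500, burnin=300, thin=2, seed=27)
        post = pl.sample_posterior(y, X, W, cfg)
        with pytest.raises(ValueError):
            pl.convergence_check(post)


class TestPrior:
    @pytest.mark.parametrize("beta", [0.2, 0.4, 0.8, 1.0])
    def test_density_integrates_to_one(self, beta):
        lam = 1.7
        half, _ = integrate.quad(
            lambda u: float(pl.prior_density(np.array([u]), lam, beta)[0]),
            0.0, np.inf, limit=500,
        )
        assert 2.0 * half == pytest.approx(1.0, abs=1e-3)
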