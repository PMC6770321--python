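"""Bayesian Power Lasso whole-genome regression.

Model: y = X b + W u + e with dosages W coded 0/1/2, flat priors on the
fixed effects, the residual variance and the rate parameter, and an
exponential power prior on each SNP effect,

    p(u_i) = beta * lam^(1/beta) / (2 * Gamma(1/beta)) * exp(-lam * |u_i|^beta).

beta = 1 recovers the Bayesian Lasso (double-exponential prior) and is
sampled with the conjugate inverse-Gaussian scale-mixture update; beta < 1
uses adaptive Metropolis-within-Gibbs per SNP (proposal scales frozen at
the end of burn-in).  The rate parameter is conjugate Gamma under the
normalized prior.  Posterior means of the SNP effects are accumulated
online over every post-burn-in cycle; thinned draws of the monitored
scalars are stored for diagnostics and DIC.

The per-cycle coordinate updates are JIT-compiled with numba.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import special


class ChainError(RuntimeError):
    """MCMC chain diverged (non-finite deviance)."""


@dataclass
class PowerLassoConfig:
    beta: float = 1.0
    chain: int = 100_000
    burnin: int = 30_000
    thin: int = 10
    seed: int = 0
    adapt_target: float = 0.375  # mid 30-45% acceptance band
    adapt_interval: int = 50
    lambda_max: float = 1e6
    store_u_draws: bool | None = None  # auto: only for small problems
    fix_sigma_e2: float | None = None  # condition on a known residual variance
    fix_lambda: float | None = None  # condition on a known rate parameter

    def __post_init__(self) -> None:
        if not 0.0 < self.beta <= 1.0:
            raise ValueError("beta must be in (0, 1]")
        if self.burnin >= self.chain:
            raise ValueError("burn-in must be shorter than the chain")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_stored(self) -> int:
        return (self.chain - self.burnin) // self.thin


@dataclass
class PowerLassoPosterior:
    config: PowerLassoConfig
    snp_ids: np.ndarray
    u_mean: np.ndarray
    u_sd: np.ndarray
    b_mean: np.ndarray
    sigma_e2_mean: float
    lambda_mean: float
    sigma_e2_draws: np.ndarray
    lambda_draws: np.ndarray
    deviance_draws: np.ndarray
    u_draws: np.ndarray | None
    accept_rate: float
    deviance_at_mean: float

    @property
    def n_stored(self) -> int:
        return len(self.deviance_draws)

    def effects_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"snp_id": self.snp_ids, "u_mean": self.u_mean, "u_sd": self.u_sd}
        )


@dataclass
class DicReport:
    entries: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["beta", "d_bar", "d_at_mean", "p_d", "dic", "failed"]
        )
    )

    @property
    def selected_beta(self) -> float:
        ok = self.entries.loc[~self.entries["failed"]]
        if ok.empty:
            raise ChainError("every chain failed")
        return float(ok.loc[ok["dic"].idxmin(), "beta"])


@njit(cache=True)
def _inv_gauss(mu: float, lam: float) -> float:
    # Michael-Schucany-Haas
    v = np.random.standard_normal()
    w = v * v
    x = mu + mu * mu * w / (2.0 * lam) - mu / (2.0 * lam) * math.sqrt(
        4.0 * mu * lam * w + mu * mu * w * w
    )
    if np.random.random() <= mu / (mu + x):
        return x
    return mu * mu / x


@njit(cache=True)
def _chain_kernel(
    y, X, W, beta, chain, burnin, thin, seed,
    adapt_target, adapt_interval, lambda_max, store_u,
    fix_sigma_e2, fix_lambda,
):
    n = y.shape[0]
    p = X.shape[1]
    m = W.shape[1]
    np.random.seed(seed)

    xtx = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += X[i, j] * X[i, j]
        xtx[j] = s
    wtw = np.empty(m)
    for k in range(m):
        s = 0.0
        for i in range(n):
            s += W[i, k] * W[i, k]
        wtw[k] = s

    b = np.zeros(p)
    sigma_e2 = np.var(y) + 1e-12
    if fix_sigma_e2 > 0.0:
        sigma_e2 = fix_sigma_e2
    # small random start keeps sum |u|^beta away from 0, else the rate
    # parameter explodes and the chain is absorbed at u = 0
    u = np.empty(m)
    sd0 = 0.01 * math.sqrt(sigma_e2)
    for k in range(m):
        u[k] = sd0 * np.random.standard_normal()
    tau2 = np.ones(m)
    lam = 1.0
    if fix_lambda > 0.0:
        lam = fix_lambda
    prop = np.full(m, 0.1 * math.sqrt(sigma_e2))
    acc = np.zeros(m)
    n_acc_total = 0.0
    n_try_total = 0.0

    r = y.copy()
    for j in range(p):
        for i in range(n):
            r[i] -= X[i, j] * b[j]
    for k in range(m):
        for i in range(n):
            r[i] -= W[i, k] * u[k]

    n_stored = (chain - burnin) // thin
    sig_draws = np.empty(n_stored)
    lam_draws = np.empty(n_stored)
    dev_draws = np.empty(n_stored)
    u_draws = np.empty((n_stored if store_u else 1, m))
    u_sum = np.zeros(m)
    u_sumsq = np.zeros(m)
    b_sum = np.zeros(p)
    sig_sum = 0.0
    lam_sum = 0.0
    n_acc_cycles = 0
    stored = 0

    for it in range(chain):
        # fixed effects, flat prior
        for j in range(p):
            dot = 0.0
            for i in range(n):
                dot += X[i, j] * r[i]
            mean = b[j] + dot / xtx[j]
            new = mean + math.sqrt(sigma_e2 / xtx[j]) * np.random.standard_normal()
            d = new - b[j]
            for i in range(n):
                r[i] -= X[i, j] * d
            b[j] = new

        # SNP effects
        if beta == 1.0:
            for k in range(m):
                if wtw[k] <= 0.0:
                    u[k] = 0.0
                    continue
                dot = 0.0
                for i in range(n):
                    dot += W[i, k] * r[i]
                rhs = dot + wtw[k] * u[k]
                prec = wtw[k] / sigma_e2 + 1.0 / tau2[k]
                mean = (rhs / sigma_e2) / prec
                new = mean + math.sqrt(1.0 / prec) * np.random.standard_normal()
                d = new - u[k]
                for i in range(n):
                    r[i] -= W[i, k] * d
                u[k] = new
                au = abs(u[k])
                if au < 1e-10:
                    au = 1e-10
                inv_t = _inv_gauss(lam / au, lam * lam)
                if inv_t < 1e-12:
                    inv_t = 1e-12
                tau2[k] = 1.0 / inv_t
        else:
            for k in range(m):
                if wtw[k] <= 0.0:
                    u[k] = 0.0
                    continue
                cand = u[k] + prop[k] * np.random.standard_normal()
                d = cand - u[k]
                dot = 0.0
                for i in range(n):
                    dot += W[i, k] * r[i]
                dsse = -2.0 * d * dot + d * d * wtw[k]
                logr = -dsse / (2.0 * sigma_e2) - lam * (
                    abs(cand) ** beta - abs(u[k]) ** beta
                )
                n_try_total += 1.0
                if logr >= 0.0 or np.random.random() < math.exp(max(logr, -700.0)):
                    for i in range(n):
                        r[i] -= W[i, k] * d
                    u[k] = cand
                    acc[k] += 1.0
                    n_acc_total += 1.0
            n_acc_cycles += 1
            if it < burnin and n_acc_cycles % adapt_interval == 0:
                for k in range(m):
                    rate = acc[k] / adapt_interval
                    prop[k] *= math.exp(1.5 * (rate - adapt_target))
                    if prop[k] < 1e-8:
                        prop[k] = 1e-8
                    acc[k] = 0.0

        sse = 0.0
        for i in range(n):
            sse += r[i] * r[i]

        # residual variance, flat prior -> inverse gamma (n/2 - 1, SSE/2)
        if fix_sigma_e2 <= 0.0:
            shape = 0.5 * n - 1.0
            if shape < 0.5:
                shape = 0.5
            g = np.random.gamma(shape, 1.0)
            sigma_e2 = (0.5 * sse) / g
            if sigma_e2 < 1e-12:
                sigma_e2 = 1e-12

        # rate parameter, flat prior -> Gamma(m/beta + 1, sum |u|^beta)
        if fix_lambda <= 0.0:
            s_abs = 0.0
            for k in range(m):
                s_abs += abs(u[k]) ** beta
            if s_abs < 1e-12:
                s_abs = 1e-12
            lam = np.random.gamma(m / beta + 1.0, 1.0 / s_abs)
            if lam > lambda_max:
                lam = lambda_max

        if it >= burnin:
            u_sum += u
            u_sumsq += u * u
            b_sum += b
            sig_sum += sigma_e2
            lam_sum += lam
            if (it - burnin) % thin == 0 and stored < n_stored:
                sig_draws[stored] = sigma_e2
                lam_draws[stored] = lam
                dev_draws[stored] = n * math.log(2.0 * math.pi * sigma_e2) + sse / sigma_e2
                if store_u:
                    for k in range(m):
                        u_draws[stored, k] = u[k]
                stored += 1

    n_keep = chain - burnin
    u_mean = u_sum / n_keep
    u_var = u_sumsq / n_keep - u_mean * u_mean
    for k in range(m):
        if u_var[k] < 0.0:
            u_var[k] = 0.0
    acc_rate = n_acc_total / n_try_total if n_try_total > 0 else 1.0
    return (
        u_mean, np.sqrt(u_var), b_sum / n_keep, sig_sum / n_keep, lam_sum / n_keep,
        sig_draws, lam_draws, dev_draws, u_draws, acc_rate,
    )


def sample_posterior(
    y: np.ndarray,
    X: np.ndarray,
    W: np.ndarray,
    config: PowerLassoConfig,
    snp_ids: np.ndarray | None = None,
) -> PowerLassoPosterior:
    """Run the MCMC chain and return posterior summaries and thinned draws."""
    y = np.ascontiguousarray(y, dtype=np.float64)
    X = np.ascontiguousarray(np.atleast_2d(X), dtype=np.float64)
    W = np.ascontiguousarray(W, dtype=np.float64)
    n, m = W.shape
    if len(y) != n or X.shape[0] != n:
        raise ValueError("y, X and W row counts disagree")
    store_u = config.store_u_draws
    if store_u is None:
        store_u = config.n_stored * m <= 20_000_000
    (
        u_mean, u_sd, b_mean, sig_mean, lam_mean,
        sig_draws, lam_draws, dev_draws, u_draws, acc_rate,
    ) = _chain_kernel(
        y, X, W, float(config.beta), config.chain, config.burnin, config.thin,
        config.seed, config.adapt_target, config.adapt_interval,
        config.lambda_max, store_u,
        config.fix_sigma_e2 if config.fix_sigma_e2 is not None else 0.0,
        config.fix_lambda if config.fix_lambda is not None else 0.0,
    )
    if not np.all(np.isfinite(dev_draws)):
        raise ChainError("divergent chain: non-finite deviance recorded")
    resid = y - X @ b_mean - W @ u_mean
    dev_at_mean = n * math.log(2.0 * math.pi * sig_mean) + float(resid @ resid) / sig_mean
    return PowerLassoPosterior(
        config=config,
        snp_ids=np.asarray(snp_ids if snp_ids is not None else np.arange(m), dtype=object),
        u_mean=u_mean,
        u_sd=u_sd,
        b_mean=b_mean,
        sigma_e2_mean=float(sig_mean),
        lambda_mean=float(lam_mean),
        sigma_e2_draws=sig_draws,
        lambda_draws=lam_draws,
        deviance_draws=dev_draws,
        u_draws=u_draws if store_u else None,
        accept_rate=float(acc_rate),
        deviance_at_mean=float(dev_at_mean),
    )


def prior_density(u: np.ndarray, lam: float, beta: float) -> np.ndarray:
    """Normalized exponential power prior density (generalized normal)."""
    const = beta * lam ** (1.0 / beta) / (2.0 * special.gamma(1.0 / beta))
    return const * np.exp(-lam * np.abs(u) ** beta)


def dic_from_traces(deviance_draws: np.ndarray, deviance_at_mean: float) -> dict:
    """DIC = D_bar + pD with pD = D_bar - D(theta_bar)."""
    d_bar = float(np.mean(deviance_draws))
    p_d = d_bar - deviance_at_mean
    return {"d_bar": d_bar, "d_at_mean": deviance_at_mean, "p_d": p_d, "dic": d_bar + p_d}


def dic(posterior: PowerLassoPosterior) -> dict:
    """DIC of a fitted chain (deviance at the posterior means of all
    parameters)."""
    entry = dic_from_traces(posterior.deviance_draws, posterior.deviance_at_mean)
    entry["beta"] = posterior.config.beta
    return entry


def select_beta(
    y: np.ndarray,
    X: np.ndarray,
    W: np.ndarray,
    grid,
    config: PowerLassoConfig,
    snp_ids: np.ndarray | None = None,
) -> tuple[float, DicReport, dict[float, PowerLassoPosterior]]:
    """Fit the model for each shape in ``grid`` (same seed and chain
    settings) and select the DIC-minimizing shape."""
    grid = list(grid)
    if not grid:
        raise ValueError("empty beta grid")
    rows, posteriors = [], {}
    for beta in grid:
        cfg = PowerLassoConfig(
            beta=beta, chain=config.chain, burnin=config.burnin, thin=config.thin,
            seed=config.seed, adapt_target=config.adapt_target,
            adapt_interval=config.adapt_interval, lambda_max=config.lambda_max,
            store_u_draws=config.store_u_draws,
        )
        try:
            post = sample_posterior(y, X, W, cfg, snp_ids=snp_ids)
        except ChainError:
            rows.append(
                {"beta": beta, "d_bar": np.nan, "d_at_mean": np.nan,
                 "p_d": np.nan, "dic": np.nan, "failed": True}
            )
            continue
        posteriors[beta] = post
        entry = dic(post)
        rows.append({**{k: entry[k] for k in ("d_bar", "d_at_mean", "p_d", "dic")},
                     "beta": beta, "failed": False})
    report = DicReport(entries=pd.DataFrame(rows))
    return report.selected_beta, report, posteriors


def gebv_from_posterior(posterior: PowerLassoPosterior, w_target: np.ndarray) -> np.ndarray:
    """GEBVs as dosage matrix times posterior-mean SNP effects."""
    w_target = np.asarray(w_target, dtype=float)
    if w_target.shape[1] != len(posterior.u_mean):
        raise ValueError("target dosage columns do not match training SNPs")
    return w_target @ posterior.u_mean


def _ess(x: np.ndarray) -> float:
    """Effective sample size via Geyer's initial monotone sequence."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4 or np.std(x) == 0:
        return float(n)
    xc = x - x.mean()
    f = np.fft.rfft(xc, 2 * n)
    acov = np.fft.irfft(f * np.conj(f))[:n].real / n
    rho = acov / acov[0]
    # sums of adjacent pairs; stop at first negative, enforce monotone
    t = 1
    s = 0.0
    prev = np.inf
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        pair = min(pair, prev)
        s += pair
        prev = pair
        t += 2
    ess = n / (1.0 + 2.0 * s)
    return float(min(max(ess, 1.0), n))


def _geweke_z(x: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score comparing early and late chain means."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    a = x[: int(first * n)]
    b = x[int((1.0 - last) * n):]
    va = np.var(a, ddof=1) / _ess(a)
    vb = np.var(b, ddof=1) / _ess(b)
    denom = math.sqrt(va + vb)
    if denom == 0:
        return 0.0
    return float((a.mean() - b.mean()) / denom)


def convergence_check(posterior: PowerLassoPosterior, z_threshold: float = 3.0) -> dict:
    """Geweke z-scores and effective sample sizes for the monitored
    scalars plus (when draws are stored) the 10 largest SNP effects."""
    if posterior.n_stored < 200:
        raise ValueError("need >= 200 stored draws for diagnostics")
    monitored = {
        "deviance": posterior.deviance_draws,
        "sigma_e2": posterior.sigma_e2_draws,
        "lambda_rp": posterior.lambda_draws,
    }
    if posterior.u_draws is not None:
        top = np.argsort(-np.abs(posterior.u_mean))[:10]
        for k in top:
            monitored[f"u[{posterior.snp_ids[k]}]"] = posterior.u_draws[:, k]
    report = {}
    for name, trace in monitored.items():
        z = _geweke_z(trace)
        ess = _ess(trace)
        report[name] = {
            "geweke_z": z,
            "ess": ess,
            "pass": bool(abs(z) < z_threshold),
        }
    report["all_pass"] = bool(all(v["pass"] for v in report.values() if isinstance(v, dict)))
    return report
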