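"""REML variance components and (G)BLUP solving.

Models are of the form

    y = X b + sum_k Z u_k + e,   u_k ~ N(0, G_k * sigma_k^2),  e ~ N(0, I sigma_e^2)

with one or two genomic kernels G_k.  Variance components are estimated by
average-information REML with step-halving (EM-flavored damping) and
boundary reflection; solutions of the mixed-model equations are obtained
through the equivalent phenotype-covariance form, which also yields GEBVs
for unphenotyped lines via their kernel rows.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from cropgs.markers import G_RIDGE, GMatrix

logger = logging.getLogger(__name__)

MIN_VAR = 1e-10


class RemlError(RuntimeError):
    """REML failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace: list[dict] | None = None):
        super().__init__(message)
        self.trace = trace or []


class NonIdentifiableWarning(UserWarning):
    """Flat likelihood direction: variance components not separable."""


@dataclass
class ModelFrame:
    """Observations, fixed-effect design and genomic kernels.

    ``line_index`` maps each observation to a row of the kernels (all
    kernels must share line order).  Lines present in the kernels but not
    in ``line_index`` are unphenotyped and still receive GEBVs.
    """

    y: np.ndarray
    X: np.ndarray
    line_index: np.ndarray
    kernels: list[GMatrix]
    fixed_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.line_index = np.asarray(self.line_index, dtype=int)
        n = len(self.y)
        if self.X.shape[0] != n or len(self.line_index) != n:
            raise ValueError("y, X and line_index must agree in length")
        if not self.kernels:
            raise ValueError("at least one kernel required")
        base = self.kernels[0].lines
        for g in self.kernels[1:]:
            if not np.array_equal(g.lines, base):
                raise ValueError("kernels must share line order")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("fixed-effects design is rank deficient")
        if not self.fixed_names:
            self.fixed_names = [f"b{j}" for j in range(self.X.shape[1])]

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def lines(self) -> np.ndarray:
        return self.kernels[0].lines


def make_frame(
    phenotypes: pd.DataFrame,
    trait: str,
    kernels: list[GMatrix],
    set_column: str = "set",
    line_column: str = "line_id",
) -> ModelFrame:
    """Build a ModelFrame from a phenotype table.

    Fixed effects are an intercept plus a treatment-coded set/year factor
    (first level as reference).  Lines missing the trait value are dropped
    from the observations but keep their kernel rows (and hence receive
    GEBVs).
    """
    lines = kernels[0].lines
    pos = {l: i for i, l in enumerate(lines)}
    df = phenotypes.dropna(subset=[trait])
    unknown = set(df[line_column]) - set(lines)
    if unknown:
        raise KeyError(f"phenotyped lines absent from kernel: {sorted(unknown)[:5]}")
    y = df[trait].to_numpy(dtype=float)
    line_index = np.array([pos[l] for l in df[line_column]], dtype=int)
    cols = [np.ones(len(df))]
    names = ["intercept"]
    if set_column in df.columns:
        levels = sorted(pd.unique(df[set_column]))
        for lev in levels[1:]:
            cols.append((df[set_column] == lev).to_numpy(dtype=float))
            names.append(f"{set_column}[{lev}]")
    X = np.column_stack(cols)
    return ModelFrame(y=y, X=X, line_index=line_index, kernels=kernels, fixed_names=names)


@dataclass
class VarianceComponents:
    """REML estimates: one additive variance per kernel plus residual."""

    sigma_g2: np.ndarray  # per kernel
    sigma_e2: float
    se_g2: np.ndarray
    se_e2: float
    loglik: float
    d_g: np.ndarray  # average diagonal per kernel
    n_iter: int = 0
    converged: bool = True

    @property
    def single(self) -> tuple[float, float]:
        if len(self.sigma_g2) != 1:
            raise ValueError("not a single-kernel fit")
        return float(self.sigma_g2[0]), float(self.sigma_e2)


@dataclass
class BlupSolution:
    """Fixed-effect estimates and per-line GEBVs.

    ``u`` has one column per kernel; ``gebv`` is their row sum, defined for
    every line in the kernels whether phenotyped or not.
    """

    lines: np.ndarray
    b_hat: np.ndarray
    u: np.ndarray
    fixed_names: list[str]

    @property
    def gebv(self) -> np.ndarray:
        return self.u.sum(axis=1)

    def gebv_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"line_id": self.lines, "gebv": self.gebv})


def _obs_kernels(frame: ModelFrame) -> list[np.ndarray]:
    ix = frame.line_index
    return [g.ridged(G_RIDGE)[np.ix_(ix, ix)] for g in frame.kernels]


def _reml_loglik(
    V: np.ndarray, X: np.ndarray, y: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Restricted log-likelihood plus P*y and P (projection form)."""
    n, p = X.shape
    cho = linalg.cho_factor(V, lower=True)
    logdet_v = 2.0 * np.sum(np.log(np.diag(cho[0])))
    Vi_X = linalg.cho_solve(cho, X)
    Vi_y = linalg.cho_solve(cho, y)
    XtViX = X.T @ Vi_X
    cho_x = linalg.cho_factor(XtViX, lower=True)
    logdet_x = 2.0 * np.sum(np.log(np.diag(cho_x[0])))
    beta = linalg.cho_solve(cho_x, X.T @ Vi_y)
    Py = Vi_y - Vi_X @ beta
    # P = Vi - Vi_X (X'ViX)^-1 Vi_X'
    P = linalg.cho_solve(cho, np.eye(n)) - Vi_X @ linalg.cho_solve(cho_x, Vi_X.T)
    ll = -0.5 * (logdet_v + logdet_x + float(y @ Py))
    return ll, Py, P


def fit_reml(
    frame: ModelFrame,
    max_iter: int = 200,
    tol_loglik: float = 1e-8,
    tol_grad: float = 1e-6,
    start: np.ndarray | None = None,
) -> VarianceComponents:
    """Average-information REML with step-halving and boundary reflection.

    Convergence requires both a relative log-likelihood change below
    ``tol_loglik`` and a scaled gradient norm below ``tol_grad``.
    Variances are kept >= 1e-10 by reflection.  A flat likelihood
    direction (e.g. identity kernel with one record per line) triggers a
    :class:`NonIdentifiableWarning`.
    """
    if len(np.unique(frame.line_index)) < 2:
        raise ValueError("need >= 2 distinct phenotyped lines")
    y, X = frame.y, frame.X
    n = frame.n_obs
    Ks = _obs_kernels(frame) + [np.eye(n)]  # last component is residual
    q = len(Ks)
    vy = float(np.var(y, ddof=1))
    theta = np.full(q, vy / q) if start is None else np.asarray(start, dtype=float)

    trace: list[dict] = []
    ll_old = -np.inf
    warned_flat = False
    for it in range(max_iter):
        V = sum(t * K for t, K in zip(theta, Ks))
        try:
            ll, Py, P = _reml_loglik(V, X, y)
        except linalg.LinAlgError as exc:
            raise RemlError(f"covariance not PD at iteration {it}: {exc}", trace)
        # score and average information
        grad = np.empty(q)
        PK = [P @ K for K in Ks]
        KPy = [K @ Py for K in Ks]
        for k in range(q):
            grad[k] = -0.5 * (np.trace(PK[k]) - float(Py @ KPy[k]))
        AI = np.empty((q, q))
        for k in range(q):
            PKPy_k = P @ KPy[k]
            for l in range(k, q):
                AI[k, l] = AI[l, k] = 0.5 * float(KPy[l] @ PKPy_k)
        trace.append({"iter": it, "loglik": ll, "theta": theta.copy(), "grad": grad.copy()})

        cond = np.linalg.cond(AI)
        if cond > 1e10 and not warned_flat:
            warnings.warn(
                "average-information matrix is near-singular: variance "
                "components not separately identifiable",
                NonIdentifiableWarning,
            )
            warned_flat = True

        scale = np.maximum(theta, vy * 1e-3)
        # KKT: at the zero boundary a negative gradient is stationary
        kkt_grad = np.where((theta <= MIN_VAR * 1.01) & (grad < 0), 0.0, grad)
        gnorm = float(np.linalg.norm(kkt_grad * scale)) / max(vy, 1e-12)
        rel_dll = abs(ll - ll_old) / (abs(ll) + 1.0)
        if it > 0 and rel_dll < tol_loglik and gnorm < tol_grad:
            break
        ll_old = ll

        # active-set Newton step: parameters pinned at the zero boundary
        # with negative gradient are frozen, else the clamped step can
        # become a descent direction
        free = ~((theta <= MIN_VAR * 1.01) & (grad < 0))
        step = np.zeros(q)
        if free.any():
            sub = np.ix_(free, free)
            try:
                step[free] = np.linalg.solve(
                    AI[sub] + 1e-12 * np.eye(int(free.sum())), grad[free]
                )
            except np.linalg.LinAlgError:
                step[free] = grad[free] * (vy / n)
        # step-halving until likelihood does not decrease
        accepted = False
        for _ in range(30):
            cand = theta + step
            cand = np.where(cand < MIN_VAR, MIN_VAR, cand)  # reflect to boundary
            Vc = sum(t * K for t, K in zip(cand, Ks))
            try:
                ll_new, _, _ = _reml_loglik(Vc, X, y)
            except linalg.LinAlgError:
                step *= 0.5
                continue
            if ll_new >= ll - 1e-10:
                theta = cand
                accepted = True
                break
            step *= 0.5
        if not accepted:
            # gradient is ascent-direction fallback at tiny scale
            theta = np.where(theta + step * 1e-3 < MIN_VAR, MIN_VAR, theta + step * 1e-3)
    else:
        raise RemlError(f"REML did not converge in {max_iter} iterations", trace)

    if np.any(theta <= MIN_VAR * 1.01):
        warnings.warn("variance component reflected to boundary", UserWarning)

    # SEs from inverse AI at the optimum
    try:
        ai_inv = np.linalg.inv(AI + 1e-12 * np.eye(q))
        ses = np.sqrt(np.maximum(np.diag(ai_inv), 0.0))
    except np.linalg.LinAlgError:  # pragma: no cover
        ses = np.full(q, np.nan)

    d_g = np.array([g.average_diagonal() for g in frame.kernels])
    return VarianceComponents(
        sigma_g2=theta[:-1].copy(),
        sigma_e2=float(theta[-1]),
        se_g2=ses[:-1].copy(),
        se_e2=float(ses[-1]),
        loglik=float(ll),
        d_g=d_g,
        n_iter=it + 1,
        converged=True,
    )


def reml_loglik_at(frame: ModelFrame, sigma_g2, sigma_e2: float) -> float:
    """Restricted log-likelihood at fixed variance components (for
    perturbation / local-optimum checks)."""
    sigma_g2 = np.atleast_1d(np.asarray(sigma_g2, dtype=float))
    Ks = _obs_kernels(frame)
    V = sum(t * K for t, K in zip(sigma_g2, Ks)) + sigma_e2 * np.eye(frame.n_obs)
    ll, _, _ = _reml_loglik(V, frame.X, frame.y)
    return float(ll)


def solve_mme(frame: ModelFrame, vc: VarianceComponents) -> BlupSolution:
    """Solve the mixed-model equations at the given variance components.

    Uses the phenotype-covariance form: b_hat by GLS under
    V = sum_k sigma_k^2 G_k[obs,obs] + sigma_e^2 I, then
    u_k = sigma_k^2 G_k[:, obs] V^{-1} (y - X b_hat), which extends GEBVs
    to unphenotyped lines through their kernel rows.
    """
    if not np.all(np.isfinite(vc.sigma_g2)) or not np.isfinite(vc.sigma_e2):
        raise ValueError("non-finite variance components")
    y, X, ix = frame.y, frame.X, frame.line_index
    Ks_obs = _obs_kernels(frame)
    V = sum(t * K for t, K in zip(vc.sigma_g2, Ks_obs)) + vc.sigma_e2 * np.eye(frame.n_obs)
    try:
        cho = linalg.cho_factor(V, lower=True)
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"singular MME coefficient matrix: {exc}")
    Vi_X = linalg.cho_solve(cho, X)
    XtViX = X.T @ Vi_X
    b_hat = np.linalg.solve(XtViX, Vi_X.T @ y)
    r = y - X @ b_hat
    Vi_r = linalg.cho_solve(cho, r)
    u = np.empty((len(frame.lines), len(frame.kernels)))
    for k, g in enumerate(frame.kernels):
        u[:, k] = vc.sigma_g2[k] * (g.ridged(G_RIDGE)[:, ix] @ Vi_r)
    return BlupSolution(lines=frame.lines, b_hat=b_hat, u=u, fixed_names=frame.fixed_names)


def heritability(vc: VarianceComponents, g: GMatrix) -> float:
    """Narrow-sense genomic heritability h^2 = d(G) sg2 / (d(G) sg2 + se2)."""
    sg2, se2 = vc.single
    d = g.average_diagonal()
    denom = d * sg2 + se2
    if denom <= 0:
        raise ValueError("heritability undefined: both variances zero")
    return d * sg2 / denom


def predict_gebv(solution: BlupSolution, target_lines) -> np.ndarray:
    """GEBVs for the requested lines from a fitted BLUP solution."""
    pos = {l: i for i, l in enumerate(solution.lines)}
    missing = [l for l in target_lines if l not in pos]
    if missing:
        raise KeyError(f"lines absent from kernel: {missing[:5]}")
    idx = np.array([pos[l] for l in target_lines], dtype=int)
    return solution.gebv[idx]
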