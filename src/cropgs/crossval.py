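"""Cross-validation engine for genomic prediction.

Schemes: leave-one-out (LOO), leave-family-out (LFO, half-sib clusters),
leave-set-out (LSO), set-stratified k-fold, random training-fraction
curves, and the split-half genomic-feature protocol (GWAS SNP ranking on
one half, two-kernel LOO prediction on the other).

Predictive ability is the Pearson correlation between fixed-effect-
corrected phenotypes and GEBVs over validated lines; bias is the
deviation from 1.0 of the slope of corrected phenotypes regressed on
GEBVs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from cropgs.assoc import single_marker_scan
from cropgs.markers import G_RIDGE, GMatrix, MarkerMatrix, center, loco_g, partition_g, vanraden_g
from cropgs.mixedmodel import (
    ModelFrame,
    VarianceComponents,
    fit_reml,
    make_frame,
    solve_mme,
)
from cropgs import powerlasso as pl

logger = logging.getLogger(__name__)


@dataclass
class FoldPlan:
    """Partition of lines into validation folds.

    ``folds`` maps fold label -> array of line ids validated in that fold;
    training is the complement.  For the ``fraction`` scheme there is a
    single fold holding the validation lines.
    """

    scheme: str
    folds: dict[str, np.ndarray]
    lines: np.ndarray
    k: int | None = None
    fraction: float | None = None
    replicate: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        all_valid = np.concatenate([np.asarray(v) for v in self.folds.values()])
        if len(set(all_valid)) != len(all_valid):
            raise ValueError("folds overlap")
        unknown = set(all_valid) - set(self.lines)
        if unknown:
            raise ValueError(f"fold references unknown lines: {sorted(unknown)[:5]}")


def half_sib_clusters(pedigree: pd.DataFrame, max_size: int | None = None) -> dict[str, list]:
    """Group lines into clusters connected by shared parents (union-find).

    Lines sharing >= 1 parent (directly or transitively) land in the same
    cluster, so no parent is split across training and validation.  If
    ``max_size`` is given, oversized clusters are chopped (with a warning),
    which relaxes that guarantee.
    """
    parent_root: dict = {}
    line_root: dict = {}
    roots: dict = {}

    def find(x):
        while roots.get(x, x) != x:
            roots[x] = roots.get(roots[x], roots[x])
            x = roots[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            roots[ra] = rb

    for _, row in pedigree.iterrows():
        p1, p2 = ("p", row["parent1"]), ("p", row["parent2"])
        for p in (p1, p2):
            roots.setdefault(p, p)
        union(p1, p2)
    for _, row in pedigree.iterrows():
        line_root[row["line_id"]] = find(("p", row["parent1"]))

    clusters: dict[str, list] = {}
    for line, root in line_root.items():
        clusters.setdefault(str(root), []).append(line)
    out: dict[str, list] = {}
    for i, (_, members) in enumerate(sorted(clusters.items())):
        if max_size is not None and len(members) > max_size:
            warnings.warn("half-sib cluster larger than max_size was split")
            for j in range(0, len(members), max_size):
                out[f"hs{i + 1}_{j // max_size + 1}"] = members[j : j + max_size]
        else:
            out[f"hs{i + 1}"] = members
    return out


def make_folds(
    lines,
    scheme: str,
    pedigree: pd.DataFrame | None = None,
    sets: pd.Series | None = None,
    k: int | None = None,
    fraction: float | None = None,
    seed: int = 0,
    replicate: int = 0,
    max_family_size: int | None = None,
) -> FoldPlan:
    """Build a fold plan for the requested scheme.

    k-fold is stratified by set label so each training fold draws about
    half its lines from each set.
    """
    lines = np.asarray(lines, dtype=object)
    n = len(lines)
    rng = np.random.default_rng(seed + replicate)
    folds: dict[str, np.ndarray] = {}
    if scheme == "loo":
        folds = {f"f{i}": np.array([l], dtype=object) for i, l in enumerate(lines)}
    elif scheme == "lfo":
        if pedigree is None:
            raise ValueError("lfo requires a pedigree")
        clusters = half_sib_clusters(pedigree, max_size=max_family_size)
        folds = {
            name: np.array([l for l in members if l in set(lines)], dtype=object)
            for name, members in clusters.items()
        }
        folds = {name: v for name, v in folds.items() if len(v)}
    elif scheme == "lso":
        if sets is None:
            raise ValueError("lso requires set labels")
        sets = np.asarray(sets)
        for lev in pd.unique(sets):
            folds[str(lev)] = lines[sets == lev]
    elif scheme == "kfold":
        if k is None or k < 2:
            raise ValueError("kfold requires k >= 2")
        if k > n:
            raise ValueError("k exceeds number of lines")
        assign = np.empty(n, dtype=int)
        if sets is not None:
            sets = np.asarray(sets)
            for lev in pd.unique(sets):
                ix = np.nonzero(sets == lev)[0]
                rng.shuffle(ix)
                assign[ix] = np.arange(len(ix)) % k
        else:
            ix = rng.permutation(n)
            assign[ix] = np.arange(n) % k
        for f in range(k):
            folds[f"f{f}"] = lines[assign == f]
    elif scheme == "fraction":
        if fraction is None or not 0.0 < fraction < 1.0:
            raise ValueError("fraction scheme requires fraction in (0, 1)")
        n_train = int(round(fraction * n))
        ix = rng.permutation(n)
        folds["holdout"] = lines[ix[n_train:]]
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return FoldPlan(
        scheme=scheme, folds=folds, lines=lines, k=k, fraction=fraction,
        replicate=replicate, seed=seed,
    )


def predictive_ability(y_corrected: np.ndarray, gebv: np.ndarray) -> float:
    """Pearson correlation of corrected phenotypes with GEBVs."""
    y_corrected = np.asarray(y_corrected, dtype=float)
    gebv = np.asarray(gebv, dtype=float)
    if len(y_corrected) < 3:
        raise ValueError("need >= 3 pairs")
    if np.std(gebv) == 0 or np.std(y_corrected) == 0:
        raise ValueError("constant vector: correlation undefined")
    return float(np.corrcoef(y_corrected, gebv)[0, 1])


def bias(y_corrected: np.ndarray, gebv: np.ndarray) -> tuple[float, float, float]:
    """Regression of corrected phenotype on GEBV.

    Returns (slope, slope_se, slope - 1.0).  A slope of 1.0 means
    unbiased prediction.
    """
    y_corrected = np.asarray(y_corrected, dtype=float)
    gebv = np.asarray(gebv, dtype=float)
    if len(y_corrected) < 3:
        raise ValueError("need >= 3 pairs")
    sxx = float(np.sum((gebv - gebv.mean()) ** 2))
    if sxx == 0:
        raise ValueError("zero-variance GEBV: slope undefined")
    slope = float(np.sum((gebv - gebv.mean()) * (y_corrected - y_corrected.mean())) / sxx)
    resid = y_corrected - y_corrected.mean() - slope * (gebv - gebv.mean())
    dof = len(y_corrected) - 2
    se = float(np.sqrt(np.sum(resid**2) / dof / sxx)) if dof > 0 else np.nan
    return slope, se, slope - 1.0


@dataclass
class CvResult:
    scheme: str
    table: pd.DataFrame  # line_id, fold, gebv, y_corrected
    r: float
    slope: float
    slope_se: float
    bias: float
    training_sizes: dict[str, int] = field(default_factory=dict)
    replicate: int = 0


def _corrected_phenotypes(frame: ModelFrame, vc: VarianceComponents) -> np.ndarray:
    """y - X b_hat with b_hat from the full-data GLS fit."""
    sol = solve_mme(frame, vc)
    return frame.y - frame.X @ sol.b_hat


def _full_rank_columns(X: np.ndarray) -> np.ndarray:
    """Indices of a maximal linearly independent column subset (pivoted QR).

    Training folds can alias fixed-effect columns (e.g. leave-set-out makes
    the set factor constant); those columns are dropped for the fold fit.
    """
    if X.shape[1] == 1:
        return np.array([0])
    _, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    rank = int(np.sum(diag > diag[0] * 1e-10)) if diag.size else 0
    return np.sort(piv[:rank])


def _fast_loo_gebv(frame: ModelFrame, vc: VarianceComponents, y_corr: np.ndarray) -> np.ndarray:
    """Exact leave-one-out conditional-expectation GEBVs at fixed variance
    components and fixed fixed-effect correction.

    With A = sum_k sigma_k^2 G_k + sigma_e^2 I over observations and
    s = A^{-1} r, the LOO prediction of line i's genetic value is
    r_i - s_i / (A^{-1})_{ii} (off-diagonals of A equal the genetic
    covariance, so this is the standard kriging LOO identity).
    """
    ix = frame.line_index
    A = sum(
        t * g.ridged(G_RIDGE)[np.ix_(ix, ix)]
        for t, g in zip(vc.sigma_g2, frame.kernels)
    ) + vc.sigma_e2 * np.eye(frame.n_obs)
    Ainv = linalg.inv(A)
    s = Ainv @ y_corr
    return y_corr - s / np.diag(Ainv)


def run_cv(
    phenotypes: pd.DataFrame,
    trait: str,
    kernels: list[GMatrix],
    plan: FoldPlan,
    model: str = "gblup",
    vc: VarianceComponents | None = None,
    refit_per_fold: bool = False,
    loo_method: str = "fast",
    markers: MarkerMatrix | None = None,
    powerlasso_config: pl.PowerLassoConfig | None = None,
    min_training: int = 2,
) -> CvResult:
    """Run one cross-validation scheme and aggregate predictive ability.

    GBLUP / two-kernel models: variance components are REML-estimated once
    on the full data and reused across folds (``refit_per_fold`` refits
    within each training set).  ``loo_method='fast'`` uses the exact
    kriging LOO identity at fixed variance components and full-data fixed
    effects; ``'exact'`` refits the MME per fold.
    """
    frame = make_frame(phenotypes, trait, kernels)
    line_of_obs = frame.lines[frame.line_index]
    obs_pos = {l: i for i, l in enumerate(line_of_obs)}

    if model in ("gblup", "feature"):
        if vc is None:
            vc = fit_reml(frame)
        y_corr_all = _corrected_phenotypes(frame, vc)
    elif model == "powerlasso":
        if markers is None:
            raise ValueError("powerlasso model requires the marker matrix")
        if powerlasso_config is None:
            powerlasso_config = pl.PowerLassoConfig(chain=6000, burnin=2000, thin=4)
        # correction uses a GBLUP fit for comparability across models
        vc_corr = vc if vc is not None else fit_reml(frame)
        y_corr_all = _corrected_phenotypes(frame, vc_corr)
    else:
        raise ValueError(f"unknown model {model!r}")

    rows = []
    training_sizes: dict[str, int] = {}

    if model == "gblup" and plan.scheme == "loo" and loo_method == "fast" and not refit_per_fold:
        gebv = _fast_loo_gebv(frame, vc, y_corr_all)
        for name, valid in plan.folds.items():
            for l in valid:
                if l in obs_pos:
                    i = obs_pos[l]
                    rows.append(
                        {"line_id": l, "fold": name, "gebv": gebv[i], "y_corrected": y_corr_all[i]}
                    )
            training_sizes[name] = frame.n_obs - 1
    else:
        for name, valid in plan.folds.items():
            valid_set = set(valid)
            train_mask = np.array([l not in valid_set for l in line_of_obs])
            assert not any(l in valid_set for l in line_of_obs[train_mask])
            n_train = int(train_mask.sum())
            if n_train < min_training:
                warnings.warn(f"fold {name}: fewer than {min_training} training lines; skipped")
                continue
            training_sizes[name] = n_train
            valid_obs = [obs_pos[l] for l in valid if l in obs_pos]
            if not valid_obs:
                continue
            if model in ("gblup", "feature"):
                X_tr = frame.X[train_mask]
                keep_cols = _full_rank_columns(X_tr)
                sub = ModelFrame(
                    y=frame.y[train_mask], X=X_tr[:, keep_cols],
                    line_index=frame.line_index[train_mask], kernels=kernels,
                )
                vc_fold = fit_reml(sub) if refit_per_fold else vc
                sol = solve_mme(sub, vc_fold)
                gvec = sol.gebv
                for l in valid:
                    if l in obs_pos:
                        i = obs_pos[l]
                        rows.append(
                            {"line_id": l, "fold": name,
                             "gebv": gvec[frame.line_index[i]],
                             "y_corrected": y_corr_all[i]}
                        )
            else:  # powerlasso
                W = markers.codes.astype(float) + 1.0
                W[markers.missing] = 1.0  # mean-ish imputation at code 0
                W_obs = W[frame.line_index]
                post = pl.sample_posterior(
                    frame.y[train_mask], frame.X[train_mask], W_obs[train_mask],
                    powerlasso_config, snp_ids=markers.snps,
                )
                gvec = pl.gebv_from_posterior(post, W_obs)
                gvec = gvec - gvec.mean()
                for l in valid:
                    if l in obs_pos:
                        i = obs_pos[l]
                        rows.append(
                            {"line_id": l, "fold": name, "gebv": gvec[i],
                             "y_corrected": y_corr_all[i]}
                        )

    table = pd.DataFrame(rows, columns=["line_id", "fold", "gebv", "y_corrected"])
    if table.empty:
        warnings.warn("no validated lines: empty cross-validation result")
        return CvResult(
            scheme=plan.scheme, table=table, r=np.nan, slope=np.nan,
            slope_se=np.nan, bias=np.nan, training_sizes=training_sizes,
            replicate=plan.replicate,
        )
    r = predictive_ability(table["y_corrected"], table["gebv"])
    slope, slope_se, b = bias(table["y_corrected"], table["gebv"])
    return CvResult(
        scheme=plan.scheme, table=table, r=r, slope=slope, slope_se=slope_se,
        bias=b, training_sizes=training_sizes, replicate=plan.replicate,
    )


def training_fraction_curve(
    phenotypes: pd.DataFrame,
    trait: str,
    kernels: list[GMatrix],
    fractions=tuple(np.round(np.arange(0.1, 1.0, 0.1), 1)),
    reps: int = 100,
    base_seed: int = 0,
    min_training: int = 10,
    vc: VarianceComponents | None = None,
) -> pd.DataFrame:
    """Mean and SD of predictive ability per training fraction.

    Each replicate selects the given fraction of lines at random and runs
    leave-one-out cross-validation within that subset, so larger fractions
    mean larger LOO training sets and steadier replicate estimates.
    Replicate r uses seed = base_seed + r.  Fractions yielding fewer than
    ``min_training`` lines are skipped with a warning.
    """
    if reps < 2:
        raise ValueError("need reps >= 2")
    frame = make_frame(phenotypes, trait, kernels)
    if vc is None:
        vc = fit_reml(frame)
    lines = frame.lines[frame.line_index]
    out = []
    for frac in fractions:
        n_sel = int(round(frac * len(lines)))
        if n_sel < min_training:
            warnings.warn(f"fraction {frac}: fewer than {min_training} training lines; skipped")
            continue
        rs = []
        for rep in range(reps):
            rng = np.random.default_rng(base_seed + rep)
            chosen = rng.choice(lines, size=n_sel, replace=False)
            chosen_set = set(chosen)
            sub_ph = phenotypes[phenotypes["line_id"].isin(chosen_set)]
            plan = make_folds(chosen, "loo", seed=base_seed, replicate=rep)
            res = run_cv(sub_ph, trait, kernels, plan, vc=vc)
            rs.append(res.r)
        out.append(
            {"fraction": float(frac), "mean_r": float(np.mean(rs)),
             "sd_r": float(np.std(rs, ddof=1)), "reps": len(rs)}
        )
    return pd.DataFrame(out)


def genomic_feature_cv(
    markers: MarkerMatrix,
    phenotypes: pd.DataFrame,
    trait: str,
    thresholds,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Split-half genomic-feature protocol.

    Lines are split once into two halves: half A is used for a LOCO GWAS
    that ranks SNPs by raw p-value; on half B, for each threshold t the
    top-t SNPs form one kernel (G_s) and the rest another (G_n), and
    two-kernel LOO predictions are scored.  Threshold = all SNPs reduces
    to single-kernel GBLUP.
    """
    thresholds = sorted(set(int(t) for t in thresholds))
    if any(t <= 0 for t in thresholds):
        raise ValueError("thresholds must be positive")
    if thresholds[-1] > markers.n_snps:
        raise ValueError("threshold exceeds SNP count")
    rng = np.random.default_rng(seed)
    n = markers.n_lines
    perm = rng.permutation(n)
    a_ix, b_ix = perm[: n // 2], perm[n // 2 :]
    mask_a = np.zeros(n, dtype=bool)
    mask_a[a_ix] = True

    pheno = phenotypes.set_index("line_id")
    # --- half A: GWAS ranking ---
    mk_a = markers.subset_lines(mask_a)
    z_a = center(mk_a)
    loco = {c: loco_g(z_a, c) for c in pd.unique(mk_a.chromosomes)}
    ph_a = pheno.loc[mk_a.lines].reset_index()
    frame_a = make_frame(ph_a, trait, [vanraden_g(z_a)])
    scan = single_marker_scan(frame_a, mk_a, loco, alpha=alpha)
    order = np.argsort(
        np.where(np.isfinite(scan.table["p_raw"]), scan.table["p_raw"], np.inf)
    )

    # --- half B: two-kernel LOO per threshold ---
    mk_b = markers.subset_lines(~mask_a)
    z_b = center(mk_b)
    ph_b = pheno.loc[mk_b.lines].reset_index()
    out = []
    for t in thresholds:
        if t >= markers.n_snps:
            kernels = [vanraden_g(z_b)]
        else:
            top = np.zeros(markers.n_snps, dtype=bool)
            top[order[:t]] = True
            g_s, g_n = partition_g(z_b, top)
            kernels = [g_s, g_n]
        plan = make_folds(mk_b.lines, "loo")
        res = run_cv(ph_b, trait, kernels, plan, model="gblup")
        out.append({"threshold": t, "r": res.r, "slope": res.slope, "n_kernels": len(kernels)})
    return pd.DataFrame(out)
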