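"""Single-marker mixed-model association scans with LOCO kinship.

Each SNP is tested by generalized least squares of the phenotype on
[X | w_i] under the covariance sigma_g^2 * G_loco + sigma_e^2 * I, where
the variance components are REML estimates from the leave-one-chromosome-
out model of the SNP's own chromosome (held fixed across that
chromosome's SNPs).  Test statistics are Wald chi-squared with 1 df;
genomic control rescales them by the ratio of the observed to the
expected median.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from cropgs.markers import GMatrix, MarkerMatrix
from cropgs.mixedmodel import ModelFrame, VarianceComponents, fit_reml

logger = logging.getLogger(__name__)


@dataclass
class GwasResult:
    """Per-SNP scan results plus the trait-level inflation factor."""

    table: pd.DataFrame  # snp_id, chrom, maf, effect, se, chi2, p_raw, p_gc, significant
    lambda_if: float
    alpha: float
    threshold: float

    @property
    def significant_snps(self) -> np.ndarray:
        return self.table.loc[self.table["significant"], "snp_id"].to_numpy()


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test p-value threshold alpha / m."""
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    return alpha / m


def genomic_control(chi2: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Genomic-control correction of 1-df chi-squared statistics.

    lambda_IF = median(chi2) / median(chisq_1), the corrected statistics
    are chi2 / lambda_IF and p-values are recomputed from the 1-df upper
    tail.  No clamping at 1 is applied (see ``clamp`` in callers for the
    conventional lambda >= 1 behavior).
    """
    chi2 = np.asarray(chi2, dtype=float)
    finite = np.isfinite(chi2)
    if not finite.any():
        raise ValueError("no finite chi-squared values")
    expected_median = stats.chi2.ppf(0.5, df=1)
    lam = float(np.median(chi2[finite]) / expected_median)
    corrected = chi2 / lam
    p = stats.chi2.sf(corrected, df=1)
    return lam, corrected, p


def _gls_scan(
    y: np.ndarray, X: np.ndarray, W: np.ndarray, V: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Effects and SEs for each column of W added to the GLS regression of
    y on X under covariance V (V treated as known).

    Whitens by the Cholesky factor of V, projects out X, then performs the
    per-SNP univariate regressions in one vectorized pass.
    """
    L = linalg.cholesky(V, lower=True)
    yw = linalg.solve_triangular(L, y, lower=True)
    Xw = linalg.solve_triangular(L, X, lower=True)
    Ww = linalg.solve_triangular(L, W, lower=True)
    Q, _ = np.linalg.qr(Xw)
    y_r = yw - Q @ (Q.T @ yw)
    W_r = Ww - Q @ (Q.T @ Ww)
    wtw = np.einsum("ij,ij->j", W_r, W_r)
    with np.errstate(divide="ignore", invalid="ignore"):
        effect = (W_r.T @ y_r) / wtw
        se = np.where(wtw > 0, np.sqrt(1.0 / wtw), np.nan)
    effect = np.where(wtw > 1e-12, effect, np.nan)
    se = np.where(wtw > 1e-12, se, np.nan)
    return effect, se


def single_marker_scan(
    frame: ModelFrame,
    markers: MarkerMatrix,
    loco_gs: dict[str, GMatrix],
    alpha: float = 0.05,
    clamp_lambda: bool = False,
    vcs: dict[str, VarianceComponents] | None = None,
) -> GwasResult:
    """Mixed-linear-model scan of every SNP with LOCO structure correction.

    ``frame`` supplies y and the fixed-effect design; its kernel list is
    ignored — per-chromosome covariances come from ``loco_gs``.  Variance
    components are REML-estimated once per LOCO G (no per-SNP refitting)
    unless supplied in ``vcs``.  Heterozygous genotypes carry code 0 in
    w_i; SNPs monomorphic among phenotyped lines are flagged untestable.
    """
    y, X, ix = frame.y, frame.X, frame.line_index
    n = len(y)
    chroms = pd.unique(markers.chromosomes)
    missing_chrom = [c for c in chroms if c not in loco_gs]
    if missing_chrom:
        raise KeyError(f"no LOCO G for chromosome(s) {missing_chrom}")

    eff = np.full(markers.n_snps, np.nan)
    se = np.full(markers.n_snps, np.nan)
    vcs = dict(vcs) if vcs else {}
    for chrom in chroms:
        g = loco_gs[chrom]
        if chrom not in vcs:
            sub = ModelFrame(y=y, X=X, line_index=ix, kernels=[g])
            vcs[chrom] = fit_reml(sub)
        sg2, se2 = vcs[chrom].single
        V = sg2 * g.ridged()[np.ix_(ix, ix)] + se2 * np.eye(n)
        cols = np.nonzero(markers.chromosomes == chrom)[0]
        W = markers.codes[np.ix_(ix, cols)].astype(float)
        W[markers.missing[np.ix_(ix, cols)]] = 0.0
        # monomorphic among phenotyped lines -> untestable
        mono = W.std(axis=0) == 0.0
        e_c, s_c = _gls_scan(y, X, W, V)
        e_c[mono] = np.nan
        s_c[mono] = np.nan
        eff[cols] = e_c
        se[cols] = s_c
        n_mono = int(mono.sum())
        if n_mono:
            logger.info("%d SNPs on %s monomorphic among phenotyped lines", n_mono, chrom)

    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = (eff / se) ** 2
    p_raw = stats.chi2.sf(chi2, df=1)
    finite = np.isfinite(chi2)
    lam, chi2_corr, p_corr_finite = genomic_control(chi2[finite])
    if clamp_lambda and lam < 1.0:
        lam = 1.0
        chi2_corr = chi2[finite]
        p_corr_finite = stats.chi2.sf(chi2_corr, df=1)
    p_gc = np.full(markers.n_snps, np.nan)
    p_gc[finite] = p_corr_finite

    threshold = bonferroni_threshold(alpha, markers.n_snps)
    table = pd.DataFrame(
        {
            "snp_id": markers.snps,
            "chrom": markers.chromosomes,
            "maf": markers.maf(),
            "effect": eff,
            "se": se,
            "chi2": chi2,
            "p_raw": p_raw,
            "p_gc": p_gc,
            "significant": np.where(np.isfinite(p_gc), p_gc < threshold, False),
        }
    )
    return GwasResult(table=table, lambda_if=lam, alpha=alpha, threshold=threshold)


def explained_variance(p: float, a: float, sigma_g2: float) -> float:
    """Percent of additive genetic variance explained by one SNP:
    100 * 2 p (1-p) a^2 / sigma_g2."""
    if sigma_g2 <= 0:
        raise ValueError("sigma_g2 must be positive")
    if not 0.0 < p < 1.0:
        raise ValueError("allele frequency must be in (0, 1)")
    return 100.0 * 2.0 * p * (1.0 - p) * a * a / sigma_g2


def positive_allele_freq(result: GwasResult, markers: MarkerMatrix, snp_id: str) -> float:
    """Frequency of the allele with a positive estimated trait effect."""
    j = int(markers.snp_index([snp_id])[0])
    row = result.table.loc[result.table["snp_id"] == snp_id]
    if row.empty or not np.isfinite(row["effect"].iloc[0]):
        raise KeyError(f"no testable scan result for {snp_id!r}")
    p_plus = markers.allele_freq()[j]
    return float(p_plus if row["effect"].iloc[0] > 0 else 1.0 - p_plus)


@dataclass
class QtlSummary:
    """Allele-combination trait means for a small set of SNPs."""

    snp_ids: list[str]
    table: pd.DataFrame  # one row per homozygous allele combination
    n_classified: int
    n_excluded: int  # heterozygous or missing at any listed SNP


def allele_class_means(
    phenotypes: pd.DataFrame,
    markers: MarkerMatrix,
    snp_ids: list[str],
    trait: str,
    line_column: str = "line_id",
) -> QtlSummary:
    """Trait means per homozygous allele combination of the listed SNPs.

    Heterozygous or missing lines at any listed SNP are excluded and
    counted.  At most 6 SNPs (2^6 combinations) are allowed.
    """
    if len(snp_ids) > 6:
        raise ValueError("at most 6 SNPs supported for combination tables")
    idx = markers.snp_index(snp_ids)
    pos = {l: i for i, l in enumerate(markers.lines)}
    df = phenotypes.dropna(subset=[trait])
    rows, excluded = [], 0
    for _, rec in df.iterrows():
        i = pos.get(rec[line_column])
        if i is None:
            excluded += 1
            continue
        codes = markers.codes[i, idx]
        if np.any(markers.missing[i, idx]) or np.any(codes == 0):
            excluded += 1
            continue
        rows.append({"combo": tuple(int(c) for c in codes), "y": float(rec[trait])})
    classified = pd.DataFrame(rows, columns=["combo", "y"])
    if classified.empty:
        table = pd.DataFrame(columns=[*snp_ids, "mean", "n_lines"])
    else:
        grouped = classified.groupby("combo")["y"].agg(["mean", "count"]).reset_index()
        table = pd.DataFrame(
            [list(c) for c in grouped["combo"]], columns=list(snp_ids)
        )
        table["mean"] = grouped["mean"].to_numpy()
        table["n_lines"] = grouped["count"].to_numpy()
    return QtlSummary(
        snp_ids=list(snp_ids),
        table=table,
        n_classified=int(len(classified)),
        n_excluded=int(excluded),
    )
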