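"""File formats, configuration, summaries and the end-to-end pipeline.

Canonical on-disk formats are plain text: a tab-delimited genotype matrix
(rows = lines, columns = SNPs, codes 0/1/2 with "NA" for missing) plus a
3-column map file (snp_id, chromosome, cM), a phenotype CSV
(line_id, set, trait columns), TSV G-matrices and GWAS tables, and JSON
for nested reports.  VCF input is supported for diploid biallelic
records.

Internally genotypes are coded -1/0/+1; the 0/1/2 dosage coding used by
the whole-genome regression is derived as code + 1 at the model boundary.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from cropgs import __version__
from cropgs.markers import UNMAPPED, GMatrix, MarkerMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# genotype matrix + map


def write_genotypes(markers: MarkerMatrix, matrix_path, map_path) -> None:
    """Write the 0/1/2 ("NA" = missing) matrix and the 3-column map."""
    dosage = (markers.codes.astype(int) + 1).astype(object)
    dosage[markers.missing] = "NA"
    df = pd.DataFrame(dosage, index=markers.lines, columns=markers.snps)
    df.index.name = "line_id"
    df.to_csv(matrix_path, sep="\t")
    pd.DataFrame(
        {"snp_id": markers.snps, "chromosome": markers.chromosomes, "cM": markers.positions}
    ).to_csv(map_path, sep="\t", index=False)


def read_genotypes_tsv(matrix_path, map_path) -> MarkerMatrix:
    """Read the tab-delimited matrix + map written by :func:`write_genotypes`.

    SNPs present in the matrix but absent from the map are assigned the
    unmapped pseudo-chromosome.  Duplicated line ids are an error; rows of
    unequal length are rejected by the parser.
    """
    df = pd.read_csv(matrix_path, sep="\t", index_col=0, na_values=["NA"])
    if df.index.duplicated().any():
        raise ValueError("duplicated line id in genotype matrix")
    snp_map = pd.read_csv(map_path, sep="\t").set_index("snp_id")
    chroms, pos = [], []
    n_unmapped = 0
    for s in df.columns:
        if s in snp_map.index:
            chroms.append(str(snp_map.loc[s, "chromosome"]))
            pos.append(float(snp_map.loc[s, "cM"]))
        else:
            chroms.append(UNMAPPED)
            pos.append(np.nan)
            n_unmapped += 1
    if n_unmapped:
        logger.info("%d SNPs absent from map assigned to %s", n_unmapped, UNMAPPED)
    values = df.to_numpy(dtype=float)
    missing = np.isnan(values)
    codes = np.where(missing, 1.0, values) - 1.0
    if np.any((codes < -1) | (codes > 1)):
        raise ValueError("genotype codes outside 0/1/2")
    return MarkerMatrix(
        lines=df.index.to_numpy(dtype=object),
        snps=df.columns.to_numpy(dtype=object),
        codes=codes.astype(np.int8),
        chromosomes=np.array(chroms, dtype=object),
        positions=np.array(pos, dtype=float),
        missing=missing,
    )


def read_genotypes_vcf(path) -> MarkerMatrix:
    """Read diploid biallelic records from a VCF.

    GT mapping: 0/0 -> -1, 0/1 -> 0, 1/1 -> +1, ./. -> missing.
    Multi-allelic records are skipped with a logged count.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    lines = np.array(vcf.samples, dtype=object)
    snps, chroms, pos, cols, miss_cols = [], [], [], [], []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_skipped += 1
            continue
        gts = np.asarray(rec.genotype.array())[:, :2]
        missing = (gts < 0).any(axis=1)
        code = gts.clip(min=0).sum(axis=1) - 1
        snps.append(rec.ID or f"{rec.CHROM}_{rec.POS}")
        chroms.append(rec.CHROM)
        pos.append(float(rec.POS))
        cols.append(code.astype(np.int8))
        miss_cols.append(missing)
    if n_skipped:
        logger.info("skipped %d multi-allelic VCF records", n_skipped)
    if not snps:
        raise ValueError("no biallelic records in VCF")
    return MarkerMatrix(
        lines=lines,
        snps=np.array(snps, dtype=object),
        codes=np.column_stack(cols),
        chromosomes=np.array(chroms, dtype=object),
        positions=np.array(pos, dtype=float),
        missing=np.column_stack(miss_cols),
    )


def read_genotypes(path, fmt: str = "tsv", map_path=None) -> MarkerMatrix:
    if fmt == "tsv":
        if map_path is None:
            raise ValueError("tsv format requires a map file")
        return read_genotypes_tsv(path, map_path)
    if fmt == "vcf":
        return read_genotypes_vcf(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def write_vcf(markers: MarkerMatrix, path) -> None:
    """Minimal unphased diploid VCF export (REF=A, ALT=B placeholders)."""
    gt_of = {-1: "0/0", 0: "0/1", 1: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in pd.unique(markers.chromosomes):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, markers.lines))
            + "\n"
        )
        for j in range(markers.n_snps):
            pos = markers.positions[j]
            pos_i = int(round(pos * 1000)) + 1 if np.isfinite(pos) else j + 1
            gts = [
                "./." if markers.missing[i, j] else gt_of[int(markers.codes[i, j])]
                for i in range(markers.n_lines)
            ]
            fh.write(
                f"{markers.chromosomes[j]}\t{pos_i}\t{markers.snps[j]}\tA\tB\t.\t.\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def write_gmatrix(g: GMatrix, path) -> None:
    g.to_frame().to_csv(path, sep="\t", index_label="line_id")


def read_gmatrix(path, provenance: str = "full") -> GMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return GMatrix(
        lines=df.index.to_numpy(dtype=object),
        values=df.to_numpy(dtype=float),
        provenance=provenance,
        n_snps=0,
    )


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "line_id" not in df.columns:
        raise ValueError("phenotype file must have a line_id column")
    return df


# ---------------------------------------------------------------------------
# phenotype summaries


def summarize_phenotypes(phenotypes: pd.DataFrame, traits=None) -> pd.DataFrame:
    """Mean, range and coefficient of variation (100 * sample SD / mean)
    per trait.  A zero mean makes the CV undefined (NaN, flagged)."""
    skip = {"line_id", "set"}
    if traits is None:
        traits = [c for c in phenotypes.columns if c not in skip]
    rows = []
    for t in traits:
        vals = phenotypes[t].dropna().to_numpy(dtype=float)
        if len(vals) < 2:
            raise ValueError(f"trait {t!r}: need >= 2 observations")
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1))
        cv = np.nan if mean == 0 else 100.0 * sd / mean
        rows.append(
            {
                "trait": t, "n": len(vals), "mean": mean,
                "min": float(vals.min()), "max": float(vals.max()),
                "cv_percent": cv,
                "cv_flag": "undefined-mean-zero" if mean == 0
                else ("sign-degenerate" if mean < 0 else "ok"),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# run configuration and pipeline


@dataclass
class RunConfig:
    genotypes: str
    phenotypes: str
    out_dir: str
    genotype_map: str | None = None
    genotype_format: str = "tsv"
    traits: list[str] = field(default_factory=list)
    maf_min: float = 0.01
    max_missing: float = 0.10
    alpha: float = 0.05
    cv_schemes: list[str] = field(default_factory=lambda: ["loo"])
    kfold_k: int = 5
    seed: int = 1
    run_powerlasso: bool = False
    powerlasso_chain: int = 10_000
    powerlasso_burnin: int = 3_000
    powerlasso_beta: float = 1.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for p in filter(None, [self.genotypes, self.phenotypes, self.genotype_map]):
            if not Path(p).exists():
                raise FileNotFoundError(p)
        for thr in (self.maf_min, self.max_missing, self.alpha):
            if not 0.0 <= thr <= 1.0:
                raise ValueError("thresholds must lie in [0, 1]")
        if self.genotype_format == "tsv" and self.genotype_map is None:
            raise ValueError("tsv genotypes require genotype_map")


def run_pipeline(config: RunConfig) -> dict:
    """QC -> G-matrices -> GWAS -> GBLUP (-> Power Lasso) -> CV.

    Writes result tables under ``config.out_dir`` and returns the run
    manifest (also written as manifest.json).
    """
    from cropgs.assoc import single_marker_scan
    from cropgs.crossval import make_folds, run_cv
    from cropgs.markers import center, filter_markers, loco_g, vanraden_g
    from cropgs.mixedmodel import fit_reml, heritability, make_frame, solve_mme
    from cropgs import powerlasso as pl

    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest: dict = {
        "tool": "cropgs", "version": __version__, "seed": config.seed,
        "parameters": {k: v for k, v in vars(config).items()},
        "stages": [],
    }

    def stage(name, **info):
        entry = {"stage": name, "elapsed_s": round(time.time() - t0, 3), **info}
        manifest["stages"].append(entry)
        logger.info("stage=%s %s", name, info)

    raw = read_genotypes(config.genotypes, config.genotype_format, config.genotype_map)
    phenotypes = read_phenotypes(config.phenotypes)
    traits = config.traits or [
        c for c in phenotypes.columns if c not in ("line_id", "set")
    ]
    stage("load", n_lines=raw.n_lines, n_snps=raw.n_snps, traits=traits)

    markers, report = filter_markers(raw, config.maf_min, config.max_missing)
    report.removed.to_csv(out / "qc_removed.tsv", sep="\t", index=False)
    stage("qc", n_retained=report.n_retained, n_removed=len(report.removed))
    if markers.n_snps == 0:
        raise RuntimeError("qc: no SNPs retained")

    z = center(markers)
    g_full = vanraden_g(z)
    write_gmatrix(g_full, out / "gmatrix_full.tsv")
    loco = {c: loco_g(z, c) for c in pd.unique(markers.chromosomes)} if len(
        pd.unique(markers.chromosomes)
    ) > 1 else {}
    stage("gmatrix", d_g=g_full.average_diagonal(), n_loco=len(loco))

    summarize_phenotypes(phenotypes, traits).to_csv(
        out / "phenotype_summary.csv", index=False
    )

    vc_rows, cv_rows = [], []
    for trait in traits:
        frame = make_frame(phenotypes, trait, [g_full])
        vc = fit_reml(frame)
        h2 = heritability(vc, g_full)
        vc_rows.append(
            {"trait": trait, "var_g": vc.sigma_g2[0], "se_g": vc.se_g2[0],
             "var_e": vc.sigma_e2, "se_e": vc.se_e2, "d_g": g_full.average_diagonal(),
             "h2": h2}
        )
        sol = solve_mme(frame, vc)
        sol.gebv_frame().to_csv(out / f"gebv_{trait}.csv", index=False)
        stage("gblup", trait=trait, h2=round(h2, 4))

        if loco:
            scan = single_marker_scan(frame, markers, loco, alpha=config.alpha)
            scan.table.to_csv(out / f"gwas_{trait}.tsv", sep="\t", index=False)
            manh = scan.table[["chrom", "snp_id", "p_gc"]].copy()
            manh["neglog10p"] = -np.log10(manh["p_gc"])
            manh.to_csv(out / f"manhattan_{trait}.tsv", sep="\t", index=False)
            stage("gwas", trait=trait, lambda_if=round(scan.lambda_if, 4),
                  n_significant=int(scan.table["significant"].sum()))

        if config.run_powerlasso:
            W = markers.codes[frame.line_index].astype(float) + 1.0
            W[markers.missing[frame.line_index]] = 1.0
            cfg = pl.PowerLassoConfig(
                beta=config.powerlasso_beta, chain=config.powerlasso_chain,
                burnin=config.powerlasso_burnin, seed=config.seed,
            )
            post = pl.sample_posterior(frame.y, frame.X, W, cfg, snp_ids=markers.snps)
            post.effects_frame().to_csv(
                out / f"powerlasso_effects_{trait}.tsv", sep="\t", index=False
            )
            with open(out / f"powerlasso_dic_{trait}.json", "w") as fh:
                json.dump(pl.dic(post), fh, indent=2)
            stage("powerlasso", trait=trait, accept_rate=post.accept_rate)

        for scheme in config.cv_schemes:
            lines_t = phenotypes.dropna(subset=[trait])["line_id"].to_numpy(dtype=object)
            sets_t = phenotypes.dropna(subset=[trait])["set"] if "set" in phenotypes else None
            plan = make_folds(
                lines_t, scheme, sets=sets_t, k=config.kfold_k, seed=config.seed,
            )
            res = run_cv(phenotypes, trait, [g_full], plan, vc=vc)
            cv_rows.append(
                {"trait": trait, "scheme": scheme, "r": res.r, "slope": res.slope,
                 "bias": res.bias}
            )
            res.table.to_csv(out / f"cv_{scheme}_{trait}.csv", index=False)
            stage("cv", trait=trait, scheme=scheme, r=round(res.r, 4))

    pd.DataFrame(vc_rows).to_csv(out / "variance_components.csv", index=False)
    with open(out / "cv_results.json", "w") as fh:
        json.dump(cv_rows, fh, indent=2)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
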