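"""Marker QC, genotype coding and genomic relationship matrices.

Genotypes are coded additively as -1 / 0 / +1 for the two homozygotes and
the heterozygote; missing calls are flagged separately.  Relationship
matrices follow VanRaden's first method,

    G = Z2 Z2' / (2 * sum_i p_i (1 - p_i)),

where column i of Z2 is the coded genotype minus 2*(p_i - 0.5) and missing
cells are set to 0 after centering.  Variants are provided for
leave-one-chromosome-out (LOCO) kinship and for partitioning SNPs into a
"significant" and a "nonsignificant" kernel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: pseudo-chromosome label assigned to SNPs absent from the map
UNMAPPED = "UN"

#: diagonal ridge added before any factorization of a G-matrix
G_RIDGE = 1e-6


@dataclass
class MarkerMatrix:
    """Lines x SNPs genotype matrix with a chromosome map.

    Parameters
    ----------
    lines : array of str
        Line identifiers (rows).
    snps : array of str
        SNP identifiers (columns).
    codes : int8 array, shape (n_lines, n_snps)
        Additive genotype codes -1/0/+1.  Entries where ``missing`` is True
        are ignored.
    chromosomes : array of str
        Chromosome label per SNP (``"UN"`` for unmapped SNPs).
    positions : float array
        Genetic map position (cM) per SNP; NaN for unmapped.
    missing : bool array, same shape as ``codes``
        Mask of missing genotype calls.
    """

    lines: np.ndarray
    snps: np.ndarray
    codes: np.ndarray
    chromosomes: np.ndarray
    positions: np.ndarray
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.lines = np.asarray(self.lines, dtype=object)
        self.snps = np.asarray(self.snps, dtype=object)
        self.codes = np.asarray(self.codes, dtype=np.int8)
        self.chromosomes = np.asarray(self.chromosomes, dtype=object)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.missing is None:
            self.missing = np.zeros(self.codes.shape, dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool)
        n, m = self.codes.shape
        if len(self.lines) != n:
            raise ValueError("line ids do not match genotype rows")
        if len(self.snps) != m or len(self.chromosomes) != m:
            raise ValueError("snp ids / map do not match genotype columns")
        if self.missing.shape != self.codes.shape:
            raise ValueError("missing mask shape mismatch")
        if len(set(self.lines)) != n:
            raise ValueError("duplicated line id")

    @property
    def n_lines(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Frequency of the +1-coded allele per SNP, from non-missing calls.

        Returns NaN for SNPs with all calls missing.
        """
        called = ~self.missing
        n_called = called.sum(axis=0).astype(float)
        # dosage of the +1 allele is (code + 1) copies out of 2
        dosage = np.where(called, self.codes + 1, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_called > 0, dosage / (2.0 * n_called), np.nan)

    def maf(self) -> np.ndarray:
        """Minor allele frequency per SNP (in [0, 0.5])."""
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def missing_rate(self) -> np.ndarray:
        return self.missing.mean(axis=0)

    def subset_snps(self, mask: np.ndarray) -> "MarkerMatrix":
        mask = np.asarray(mask)
        if mask.dtype != bool:
            idx = np.zeros(self.n_snps, dtype=bool)
            idx[mask] = True
            mask = idx
        return MarkerMatrix(
            lines=self.lines,
            snps=self.snps[mask],
            codes=self.codes[:, mask],
            chromosomes=self.chromosomes[mask],
            positions=self.positions[mask],
            missing=self.missing[:, mask],
        )

    def subset_lines(self, mask: np.ndarray) -> "MarkerMatrix":
        mask = np.asarray(mask)
        if mask.dtype != bool:
            idx = np.zeros(self.n_lines, dtype=bool)
            idx[mask] = True
            mask = idx
        return MarkerMatrix(
            lines=self.lines[mask],
            snps=self.snps,
            codes=self.codes[mask],
            chromosomes=self.chromosomes,
            positions=self.positions,
            missing=self.missing[mask],
        )

    def snp_index(self, snp_ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.snps)}
        try:
            return np.array([lookup[s] for s in snp_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message path
            raise KeyError(f"unknown SNP id {exc.args[0]!r}") from exc


@dataclass
class FilterReport:
    """Per-SNP QC outcome produced by :func:`filter_markers`."""

    removed: pd.DataFrame  # columns: snp_id, reason, maf, missing_rate
    n_input: int
    n_retained: int


@dataclass
class CenteredMarkers:
    """Centered genotype matrix Z2 with its VanRaden scaling denominator.

    ``z`` holds M - P with missing cells set to exactly 0; ``freqs`` is the
    +1-allele frequency used for centering and ``denominator`` equals
    2 * sum_i p_i (1 - p_i).
    """

    lines: np.ndarray
    snps: np.ndarray
    z: np.ndarray
    freqs: np.ndarray
    chromosomes: np.ndarray
    denominator: float

    @property
    def n_lines(self) -> int:
        return self.z.shape[0]

    @property
    def n_snps(self) -> int:
        return self.z.shape[1]


@dataclass
class GMatrix:
    """Genomic relationship matrix with provenance.

    ``provenance`` is one of ``"full"``, ``"loco:<chrom>"`` or
    ``"subset"``; ``n_snps`` records how many SNPs entered the
    construction.
    """

    lines: np.ndarray
    values: np.ndarray
    provenance: str
    n_snps: int
    snp_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != self.values.shape[1]:
            raise ValueError("G must be square")
        if self.values.shape[0] != len(self.lines):
            raise ValueError("line ids do not match G dimension")

    @property
    def n_lines(self) -> int:
        return self.values.shape[0]

    def average_diagonal(self) -> float:
        """d(G): mean of the diagonal elements."""
        return float(np.mean(np.diag(self.values)))

    def ridged(self, ridge: float = G_RIDGE) -> np.ndarray:
        """Return G + ridge * I (guards against exact singularity)."""
        return self.values + ridge * np.eye(self.n_lines)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.lines, columns=self.lines)


def filter_markers(
    raw: MarkerMatrix,
    maf_min: float = 0.01,
    max_missing: float = 0.10,
) -> tuple[MarkerMatrix, FilterReport]:
    """Apply the marker-editing rules: MAF > ``maf_min`` and missing rate
    < ``max_missing`` (both strict).

    Returns the filtered matrix (SNP order preserved) and a report listing
    removed SNPs with reasons.  Removing every SNP is a warning, not an
    error.
    """
    if raw.n_snps == 0:
        raise ValueError("empty marker matrix")
    maf = raw.maf()
    miss = raw.missing_rate()
    # SNPs with all calls missing have NaN MAF; they fail the MAF rule
    maf_ok = np.nan_to_num(maf, nan=0.0) > maf_min
    miss_ok = miss < max_missing
    keep = maf_ok & miss_ok

    reasons = []
    for j in np.nonzero(~keep)[0]:
        why = []
        if not maf_ok[j]:
            why.append(f"maf<={maf_min}")
        if not miss_ok[j]:
            why.append(f"missing>={max_missing}")
        reasons.append(
            {
                "snp_id": raw.snps[j],
                "reason": ";".join(why),
                "maf": maf[j],
                "missing_rate": miss[j],
            }
        )
    report = FilterReport(
        removed=pd.DataFrame(
            reasons, columns=["snp_id", "reason", "maf", "missing_rate"]
        ),
        n_input=raw.n_snps,
        n_retained=int(keep.sum()),
    )
    if report.n_retained == 0:
        logger.warning("marker QC removed every SNP")
    return raw.subset_snps(keep), report


def center(markers: MarkerMatrix) -> CenteredMarkers:
    """Center genotype codes: Z2 = M - P with P column i = 2*(p_i - 0.5).

    ``p_i`` here is the frequency of the +1-coded allele, so the centering
    equals subtracting the column mean under complete data.  Missing cells
    are set to exactly 0 in Z2.  The VanRaden denominator
    2 * sum p_i (1 - p_i) is attached.
    """
    p = markers.allele_freq()
    if np.any(np.isnan(p)):
        bad = markers.snps[np.isnan(p)]
        raise ValueError(f"allele frequency undefined (all calls missing): {bad[:5]}")
    shift = 2.0 * (p - 0.5)
    z = markers.codes.astype(float) - shift[None, :]
    z[markers.missing] = 0.0
    denom = float(2.0 * np.sum(p * (1.0 - p)))
    return CenteredMarkers(
        lines=markers.lines,
        snps=markers.snps,
        z=z,
        freqs=p,
        chromosomes=markers.chromosomes,
        denominator=denom,
    )


def _recenter(z: CenteredMarkers, mask: np.ndarray) -> tuple[np.ndarray, float]:
    """Columns of Z2 restricted to ``mask`` with the matching denominator.

    Frequencies (and hence centering) are already per-SNP quantities, so a
    column subset of Z2 is itself correctly centered; only the denominator
    must be recomputed over the subset.
    """
    p = z.freqs[mask]
    denom = float(2.0 * np.sum(p * (1.0 - p)))
    return z.z[:, mask], denom


def vanraden_g(z: CenteredMarkers, subset=None) -> GMatrix:
    """VanRaden method-1 G-matrix over all SNPs or a named subset.

    ``subset`` may be a boolean mask, an integer index array, or a list of
    SNP ids.  The scaling denominator is recomputed over the subset.
    """
    if subset is None:
        mask = np.ones(z.n_snps, dtype=bool)
        provenance = "full"
        snp_ids = z.snps
    else:
        subset = np.asarray(subset)
        mask = np.zeros(z.n_snps, dtype=bool)
        if subset.dtype == bool:
            mask = subset.copy()
        elif np.issubdtype(subset.dtype, np.integer):
            mask[subset] = True
        else:
            lookup = {s: i for i, s in enumerate(z.snps)}
            for s in subset:
                if s not in lookup:
                    raise KeyError(f"unknown SNP id {s!r}")
                mask[lookup[s]] = True
        if not mask.any():
            raise ValueError("empty SNP subset")
        provenance = "subset"
        snp_ids = z.snps[mask]

    zz, denom = _recenter(z, mask)
    if denom <= 0.0:
        raise ValueError("subset has zero heterozygosity (2*sum p(1-p) = 0)")
    g = (zz @ zz.T) / denom
    return GMatrix(
        lines=z.lines,
        values=g,
        provenance=provenance,
        n_snps=int(mask.sum()),
        snp_ids=snp_ids,
    )


def loco_g(z: CenteredMarkers, chromosome: str) -> GMatrix:
    """Leave-one-chromosome-out G: all SNPs except those mapped to
    ``chromosome`` (unmapped SNPs are retained unless ``chromosome`` is the
    unmapped pseudo-chromosome itself).
    """
    on_chrom = z.chromosomes == chromosome
    if not on_chrom.any():
        raise KeyError(f"unknown chromosome {chromosome!r}")
    keep = ~on_chrom
    if not keep.any():
        raise ValueError("no SNPs remain outside the excluded chromosome")
    g = vanraden_g(z, subset=keep)
    g.provenance = f"loco:{chromosome}"
    return g


def partition_g(z: CenteredMarkers, significant_snps) -> tuple[GMatrix, GMatrix]:
    """Split SNPs into significant / nonsignificant sets and build one
    G-matrix from each.  The sets are disjoint and cover all SNPs.
    """
    idx = np.asarray(significant_snps)
    mask = np.zeros(z.n_snps, dtype=bool)
    if idx.dtype == bool:
        mask = idx.copy()
    elif np.issubdtype(idx.dtype, np.integer):
        mask[idx] = True
    else:
        lookup = {s: i for i, s in enumerate(z.snps)}
        for s in idx:
            if s not in lookup:
                raise KeyError(f"unknown SNP id {s!r}")
            mask[lookup[s]] = True
    if not mask.any():
        raise ValueError("significant SNP set is empty")
    if mask.all():
        raise ValueError("significant SNP set covers every SNP; nothing to partition")
    g_s = vanraden_g(z, subset=mask)
    g_n = vanraden_g(z, subset=~mask)
    g_s.provenance = "subset:significant"
    g_n.provenance = "subset:nonsignificant"
    return g_s, g_n
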