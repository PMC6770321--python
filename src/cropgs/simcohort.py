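"""Synthetic breeding-cohort generator.

Produces inbred-line cohorts with the structure the downstream analyses
assume: a founder pool whose haplotypes are mosaics of a small ancestral
haplotype set (so linkage disequilibrium decays with map distance),
full-sib families produced by biparental crosses, single-seed descent
selfing to a target generation, half-sib structure through parent reuse,
and a two-set (breeding-cycle) split.  Phenotypes are simulated from a
configurable architecture of major QTL plus a polygenic background, with
ground-truth records retained for parameter-recovery tests.

Recombination uses the Haldane map function (no interference): the
crossover process is Markov along the chromosome, so gametes are drawn by
switching parental phase between adjacent SNPs with probability
r = (1 - exp(-2 d / 100)) / 2 for map distance d cM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cropgs.markers import MarkerMatrix

#: ancestral haplotypes per chromosome in the founder mosaic model
N_ANCESTRAL = 8


class DesignError(ValueError):
    """Inconsistent breeding design or trait architecture."""


@dataclass
class ChromosomeSpec:
    name: str
    n_snps: int
    length_cm: float


@dataclass
class BreedingDesign:
    """Plan for a synthetic breeding cohort.

    ``selfing_generations = 5`` yields F6 lines.  ``set_sizes`` gives the
    number of lines per breeding set; full-sib families are distributed
    across sets proportionally and sized as evenly as possible unless an
    explicit ``family_sizes`` list is supplied.
    """

    n_parents: int = 96
    n_shared_parents: int = 6
    set_sizes: tuple[int, ...] = (321, 314)
    n_full_sib_families: int = 159
    selfing_generations: int = 5
    chromosomes: tuple[ChromosomeSpec, ...] = ()
    founder_maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_length: float = 10.0
    family_sizes: tuple[int, ...] | None = None
    missing_rate: float = 0.0
    #: crossing parents are partitioned into groups of this size and both
    #: parents of a cross come from one group, so half-sib clusters stay
    #: bounded instead of percolating into one component
    parent_group_size: int = 7

    def __post_init__(self) -> None:
        if not self.chromosomes:
            self.chromosomes = tuple(
                ChromosomeSpec(f"chr{i + 1}", 500, 150.0) for i in range(6)
            )
        self.chromosomes = tuple(
            c if isinstance(c, ChromosomeSpec) else ChromosomeSpec(*c)
            for c in self.chromosomes
        )
        if self.selfing_generations < 0:
            raise DesignError("selfing_generations must be >= 0")
        if self.n_shared_parents > self.n_parents:
            raise DesignError("shared parents exceed parent pool")
        lo, hi = self.founder_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise DesignError("founder_maf_range must lie in (0, 0.5]")
        if self.n_full_sib_families > self.n_lines:
            raise DesignError("more families than lines")
        if self.family_sizes is not None:
            if len(self.family_sizes) != self.n_full_sib_families:
                raise DesignError("family_sizes length != n_full_sib_families")
            if sum(self.family_sizes) != self.n_lines:
                raise DesignError("family_sizes do not sum to total lines")
        if not 0.0 <= self.missing_rate < 1.0:
            raise DesignError("missing_rate must be in [0, 1)")

    @property
    def n_snps(self) -> int:
        return sum(c.n_snps for c in self.chromosomes)

    @property
    def n_lines(self) -> int:
        return int(sum(self.set_sizes))

    def snp_map(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """SNP ids, chromosome labels and evenly spaced cM positions."""
        ids, chroms, pos = [], [], []
        for c in self.chromosomes:
            step = c.length_cm / max(c.n_snps, 1)
            for j in range(c.n_snps):
                ids.append(f"{c.name}_snp{j + 1}")
                chroms.append(c.name)
                pos.append((j + 0.5) * step)
        return (
            np.array(ids, dtype=object),
            np.array(chroms, dtype=object),
            np.array(pos, dtype=float),
        )


@dataclass
class Qtl:
    chromosome: str
    freq_target: float
    effect: float


@dataclass
class TraitArchitecture:
    """Major QTL plus polygenic background for one trait.

    ``genetic_var_target`` (when set) rescales the polygenic component so
    the realized genetic variance across lines equals it, which lets QTL
    effects be calibrated against an intended explained-variance share.
    When ``target_h2`` is set, the residual SD is derived from the realized
    genetic variance; otherwise ``residual_sd`` is used as given.
    """

    major_qtl: tuple[Qtl, ...] = ()
    polygenic_snp_fraction: float = 0.5
    target_h2: float | None = None
    set_effect_sd: float = 0.0
    residual_sd: float = 1.0
    trait_mean: float = 0.0
    genetic_var_target: float | None = None

    def __post_init__(self) -> None:
        self.major_qtl = tuple(
            q if isinstance(q, Qtl) else Qtl(*q) for q in self.major_qtl
        )
        if not 0.0 <= self.polygenic_snp_fraction <= 1.0:
            raise DesignError("polygenic_snp_fraction must be in [0, 1]")
        if self.target_h2 is not None and not 0.0 < self.target_h2 < 1.0:
            if self.target_h2 == 0.0 and (self.major_qtl or self.polygenic_snp_fraction):
                raise DesignError("target_h2 = 0 with nonzero genetic effects")
            raise DesignError("target_h2 must be in (0, 1)")
        for q in self.major_qtl:
            if not np.isfinite(q.effect):
                raise DesignError("QTL effect must be finite")


@dataclass
class TruthRecord:
    """Ground truth for parameter-recovery tests."""

    tbv: np.ndarray  # per-line true breeding value (centered)
    snp_effects: np.ndarray  # per-SNP effect on the +1-coded allele dosage
    qtl_snps: list[str]
    realized_h2: float
    realized_freqs: np.ndarray
    genetic_var: float
    residual_var: float


@dataclass
class FounderSet:
    """Phased founder haplotypes: two per parent."""

    haplotypes: np.ndarray  # (2 * n_parents, n_snps) uint8 alleles
    snp_ids: np.ndarray
    chromosomes: np.ndarray
    positions: np.ndarray

    @property
    def n_parents(self) -> int:
        return self.haplotypes.shape[0] // 2


def simulate_founders(design: BreedingDesign, seed: int) -> FounderSet:
    """Draw founder haplotypes from a block-mosaic ancestral model.

    Each founder haplotype is a mosaic of ``N_ANCESTRAL`` ancestral
    haplotypes with exponentially distributed segment lengths (mean
    ``ld_block_length`` cM), giving LD that decays with map distance.
    Per-SNP allele frequencies among the 2 * n_parents founder haplotypes
    are constrained to ``founder_maf_range`` by a greedy ancestral
    assignment plus a small per-haplotype repair step.
    """
    rng = np.random.default_rng(seed)
    ids, chroms, pos = design.snp_map()
    n_hap = 2 * design.n_parents
    m = design.n_snps
    lo, hi = design.founder_maf_range

    # mosaic of ancestor indices, per haplotype, chromosome by chromosome
    ancestry = np.empty((n_hap, m), dtype=np.int8)
    offset = 0
    for c in design.chromosomes:
        cpos = pos[offset : offset + c.n_snps]
        for h in range(n_hap):
            if design.ld_block_length <= 0:
                ancestry[h, offset : offset + c.n_snps] = rng.integers(
                    0, N_ANCESTRAL, c.n_snps
                )
                continue
            breaks = [0.0]
            while breaks[-1] < c.length_cm:
                breaks.append(breaks[-1] + rng.exponential(design.ld_block_length))
            seg = np.searchsorted(np.array(breaks[1:]), cpos, side="right")
            labels = rng.integers(0, N_ANCESTRAL, len(breaks))
            ancestry[h, offset : offset + c.n_snps] = labels[seg]
        offset += c.n_snps

    # per-SNP target minor-allele counts among founder haplotypes
    q = rng.uniform(lo, hi, m)
    t_lo = int(np.ceil(lo * n_hap))
    t_hi = int(np.floor(hi * n_hap))
    targets = np.clip(np.round(q * n_hap).astype(int), max(t_lo, 1), t_hi)

    haplotypes = np.zeros((n_hap, m), dtype=np.uint8)
    order = np.arange(N_ANCESTRAL)
    for j in range(m):
        counts = np.bincount(ancestry[:, j], minlength=N_ANCESTRAL)
        rng.shuffle(order)
        total, carrier = 0, np.zeros(N_ANCESTRAL, dtype=bool)
        for k in order:
            if total + counts[k] <= targets[j]:
                carrier[k] = True
                total += counts[k]
        col = carrier[ancestry[:, j]]
        deficit = targets[j] - int(col.sum())
        if deficit > 0:
            pool = np.nonzero(~col)[0]
            col[rng.choice(pool, deficit, replace=False)] = True
        elif deficit < 0:
            pool = np.nonzero(col)[0]
            col[rng.choice(pool, -deficit, replace=False)] = False
        haplotypes[:, j] = col
    return FounderSet(haplotypes=haplotypes, snp_ids=ids, chromosomes=chroms, positions=pos)


def _recomb_probs(chromosomes, positions, chrom_labels) -> np.ndarray:
    """Per-SNP phase-switch probabilities (Haldane); chromosome starts get
    probability 0.5 so phase is independent across chromosomes."""
    m = len(positions)
    r = np.empty(m)
    offset = 0
    for c in chromosomes:
        cpos = positions[offset : offset + c.n_snps]
        r[offset] = 0.5
        if c.n_snps > 1:
            d = np.diff(cpos)
            r[offset + 1 : offset + c.n_snps] = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
        offset += c.n_snps
    return r


def _gamete_batch(ha: np.ndarray, hb: np.ndarray, r: np.ndarray, rng) -> np.ndarray:
    """One meiosis per row: Markov phase switching along SNP order."""
    switches = rng.random(ha.shape) < r[None, :]
    phase = np.cumsum(switches, axis=1) & 1
    return np.where(phase == 0, ha, hb)


def _family_plan(design: BreedingDesign, rng) -> pd.DataFrame:
    """Assign families to sets, sizes to families, and parents to crosses."""
    n_fam = design.n_full_sib_families
    total = design.n_lines
    if design.family_sizes is not None:
        sizes = np.array(design.family_sizes, dtype=int)
    else:
        base = total // n_fam
        sizes = np.full(n_fam, base, dtype=int)
        sizes[: total - base * n_fam] += 1
        rng.shuffle(sizes)

    # families per set, proportional to set sizes; adjust so line totals match
    n_sets = len(design.set_sizes)
    fams_per_set = np.maximum(
        np.round(np.array(design.set_sizes) / total * n_fam).astype(int), 1
    )
    fams_per_set[-1] = n_fam - fams_per_set[:-1].sum()
    if fams_per_set[-1] < 1:
        raise DesignError("cannot allocate at least one family per set")
    set_of_family = np.repeat(np.arange(n_sets), fams_per_set)
    # rebalance family sizes so each set hits its target line count
    for s in range(n_sets):
        fam_ix = np.nonzero(set_of_family == s)[0]
        diff = design.set_sizes[s] - int(sizes[fam_ix].sum())
        k = 0
        while diff != 0:
            j = fam_ix[k % len(fam_ix)]
            if diff > 0:
                sizes[j] += 1
                diff -= 1
            elif sizes[j] > 1:
                sizes[j] -= 1
                diff += 1
            k += 1

    # parent pools: shared parents appear in both sets
    shared = np.arange(design.n_shared_parents)
    rest = np.arange(design.n_shared_parents, design.n_parents)
    rng.shuffle(rest)
    half = len(rest) // 2
    pools = [np.concatenate([shared, rest[:half]]), np.concatenate([shared, rest[half:]])]
    if n_sets != 2:
        pools = [np.arange(design.n_parents)] * n_sets

    # partition each pool into parent groups; crosses stay within a group
    groups_of_pool = []
    for pool in pools:
        pool = pool.copy()
        rng.shuffle(pool)
        size = max(design.parent_group_size, 2)
        groups = [pool[i : i + size] for i in range(0, len(pool), size)]
        if len(groups) > 1 and len(groups[-1]) < 2:
            groups[-2] = np.concatenate([groups[-2], groups[-1]])
            groups = groups[:-1]
        groups_of_pool.append(groups)

    rows = []
    for f in range(n_fam):
        s = int(set_of_family[f])
        groups = groups_of_pool[s]
        group = groups[f % len(groups)]
        p1, p2 = rng.choice(group, size=2, replace=False)
        rows.append(
            {
                "family_id": f"fam{f + 1}",
                "set": f"set{s + 1}",
                "size": int(sizes[f]),
                "parent1": int(p1),
                "parent2": int(p2),
            }
        )
    return pd.DataFrame(rows)


def simulate_cross_ssd(
    founders: FounderSet,
    design: BreedingDesign,
    seed: int,
    family_plan: pd.DataFrame | None = None,
) -> tuple[MarkerMatrix, pd.DataFrame]:
    """Biparental crosses followed by single-seed-descent selfing.

    Each line is an independent descent from an independent F1 of its
    family's cross.  Returns the genotype matrix (additive -1/0/+1 codes)
    and a pedigree table (line_id, family_id, set, parent1, parent2).
    """
    rng = np.random.default_rng(seed)
    plan = _family_plan(design, rng) if family_plan is None else family_plan
    if (plan[["parent1", "parent2"]].to_numpy() >= founders.n_parents).any():
        raise DesignError("family plan references unknown parent")

    line_rows = plan.loc[plan.index.repeat(plan["size"])].reset_index(drop=True)
    n_lines = len(line_rows)
    line_rows["line_id"] = [f"L{i + 1:04d}" for i in range(n_lines)]

    r = _recomb_probs(design.chromosomes, founders.positions, founders.chromosomes)
    p1 = line_rows["parent1"].to_numpy()
    p2 = line_rows["parent2"].to_numpy()
    # F1: one gamete from each parent's phased haplotype pair
    h1 = _gamete_batch(founders.haplotypes[2 * p1], founders.haplotypes[2 * p1 + 1], r, rng)
    h2 = _gamete_batch(founders.haplotypes[2 * p2], founders.haplotypes[2 * p2 + 1], r, rng)
    for _ in range(design.selfing_generations):
        new1 = _gamete_batch(h1, h2, r, rng)
        new2 = _gamete_batch(h1, h2, r, rng)
        h1, h2 = new1, new2

    codes = (h1.astype(np.int8) + h2.astype(np.int8)) - 1
    missing = np.zeros(codes.shape, dtype=bool)
    if design.missing_rate > 0:
        missing = rng.random(codes.shape) < design.missing_rate

    markers = MarkerMatrix(
        lines=line_rows["line_id"].to_numpy(),
        snps=founders.snp_ids,
        codes=codes,
        chromosomes=founders.chromosomes,
        positions=founders.positions,
        missing=missing,
    )
    pedigree = line_rows[["line_id", "family_id", "set", "parent1", "parent2"]].copy()
    return markers, pedigree


def heterozygosity(markers: MarkerMatrix) -> float:
    """Mean fraction of heterozygous calls per line (non-missing calls)."""
    called = ~markers.missing
    het = (markers.codes == 0) & called
    return float(het.sum() / max(called.sum(), 1))


def simulate_phenotypes(
    markers: MarkerMatrix,
    arch: TraitArchitecture,
    set_assignment: pd.Series | np.ndarray,
    seed: int,
    trait: str = "trait",
) -> tuple[pd.DataFrame, TruthRecord]:
    """Simulate phenotypes: mean + set effect + genetic value + residual.

    Major QTL are placed on the nearest-frequency SNP of their requested
    chromosome.  The polygenic background is rescaled so total genetic
    variance matches ``genetic_var_target`` (when set); the residual SD is
    derived from ``target_h2`` (when set) so the realized heritability
    tracks the target.
    """
    rng = np.random.default_rng(seed)
    n = markers.n_lines
    sets = np.asarray(set_assignment)
    if len(sets) != n:
        raise DesignError("set assignment length != number of lines")
    dosage = (markers.codes.astype(float) + 1.0)  # 0/1/2 copies of +1 allele
    freqs = markers.allele_freq()

    effects = np.zeros(markers.n_snps)
    qtl_snps: list[str] = []
    used: set[int] = set()
    for q in arch.major_qtl:
        on = np.nonzero(markers.chromosomes == q.chromosome)[0]
        if len(on) == 0:
            raise DesignError(f"QTL chromosome {q.chromosome!r} not in map")
        cand = [j for j in on if j not in used]
        # match the positive-allele frequency target on either allele
        dist = np.minimum(
            np.abs(freqs[cand] - q.freq_target), np.abs(1.0 - freqs[cand] - q.freq_target)
        )
        j = cand[int(np.argmin(dist))]
        used.add(j)
        sign = 1.0 if abs(freqs[j] - q.freq_target) <= abs(1.0 - freqs[j] - q.freq_target) else -1.0
        effects[j] = sign * q.effect
        qtl_snps.append(str(markers.snps[j]))

    g_major = dosage @ effects
    # polygenic background on a random fraction of the remaining SNPs
    g_poly = np.zeros(n)
    poly_ix = np.array([], dtype=int)
    if arch.polygenic_snp_fraction > 0:
        free = np.array([j for j in range(markers.n_snps) if j not in used])
        k = int(round(arch.polygenic_snp_fraction * len(free)))
        if k > 0:
            poly_ix = rng.choice(free, size=k, replace=False)
            poly_eff = rng.normal(0.0, 1.0, k)
            g_poly = dosage[:, poly_ix] @ poly_eff

    var_major = float(np.var(g_major, ddof=1))
    var_poly = float(np.var(g_poly, ddof=1))
    scale = 1.0
    if arch.genetic_var_target is not None and var_poly > 0:
        cov = float(np.cov(g_major, g_poly, ddof=1)[0, 1]) if var_major > 0 else 0.0
        a, b, c = var_poly, 2.0 * cov, var_major - arch.genetic_var_target
        disc = b * b - 4 * a * c
        if disc < 0:
            raise DesignError(
                "genetic_var_target below variance already contributed by major QTL"
            )
        scale = (-b + np.sqrt(disc)) / (2 * a)
    elif arch.genetic_var_target is not None and var_major > arch.genetic_var_target:
        raise DesignError("major-QTL variance alone exceeds genetic_var_target")
    g_poly = scale * g_poly
    if len(poly_ix):
        effects[poly_ix] = effects[poly_ix] + scale * poly_eff

    tbv = g_major + g_poly
    tbv = tbv - tbv.mean()
    var_g = float(np.var(tbv, ddof=1))

    if arch.target_h2 is not None:
        if var_g == 0:
            raise DesignError("target_h2 set but genetic variance is zero")
        resid_sd = np.sqrt(var_g * (1.0 - arch.target_h2) / arch.target_h2)
    else:
        resid_sd = arch.residual_sd
    e = rng.normal(0.0, resid_sd, n)

    set_levels = sorted(pd.unique(pd.Series(sets)))
    set_eff = {lev: rng.normal(0.0, arch.set_effect_sd) for lev in set_levels}
    set_term = np.array([set_eff[s] for s in sets])

    y = arch.trait_mean + set_term + tbv + e
    var_e = float(np.var(e, ddof=1)) if n > 1 else 0.0
    realized_h2 = var_g / (var_g + var_e) if (var_g + var_e) > 0 else 0.0

    phenotypes = pd.DataFrame(
        {"line_id": markers.lines, "set": sets, trait: y}
    )
    truth = TruthRecord(
        tbv=tbv,
        snp_effects=effects,
        qtl_snps=qtl_snps,
        realized_h2=realized_h2,
        realized_freqs=freqs,
        genetic_var=var_g,
        residual_var=var_e,
    )
    return phenotypes, truth


def simulate_from_kernel(
    g_values: np.ndarray,
    sigma_g2: float,
    sigma_e2: float,
    seed: int,
    X: np.ndarray | None = None,
    b: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (y, u) from the GBLUP generative model with a known kernel:
    u ~ N(0, G * sigma_g2), e ~ N(0, I * sigma_e2), y = X b + u + e.

    Used for variance-component recovery experiments where the true
    relationship matrix is taken as given.
    """
    rng = np.random.default_rng(seed)
    n = g_values.shape[0]
    w, v = np.linalg.eigh(g_values)
    w = np.clip(w, 0.0, None)
    u = v @ (np.sqrt(w * sigma_g2) * rng.standard_normal(n))
    e = rng.normal(0.0, np.sqrt(sigma_e2), n)
    y = u + e
    if X is not None:
        y = y + np.asarray(X, dtype=float) @ np.asarray(b, dtype=float)
    return y, u


def simulate_cohort(
    design: BreedingDesign,
    arch: TraitArchitecture,
    seed: int,
    trait: str = "trait",
) -> tuple[MarkerMatrix, pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Convenience wrapper: founders -> SSD cohort -> phenotypes.

    Returns (markers, phenotypes, pedigree, truth).  Sub-stages use
    decorrelated child seeds derived from ``seed``.
    """
    ss = np.random.SeedSequence(seed).spawn(3)
    founders = simulate_founders(design, ss[0].generate_state(1)[0])
    markers, pedigree = simulate_cross_ssd(
        founders, design, ss[1].generate_state(1)[0]
    )
    phenotypes, truth = simulate_phenotypes(
        markers, arch, pedigree["set"].to_numpy(), ss[2].generate_state(1)[0], trait=trait
    )
    return markers, phenotypes, pedigree, truth
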