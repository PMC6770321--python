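"""Shared fixtures: small simulated cohorts and hand-built marker sets."""

import numpy as np
import pandas as pd
import pytest

from cropgs.markers import MarkerMatrix, center, vanraden_g
from cropgs.simcohort import (
    BreedingDesign,
    ChromosomeSpec,
    Qtl,
    TraitArchitecture,
    simulate_cohort,
)


def small_design(**overrides) -> BreedingDesign:
    kwargs = dict(
        n_parents=40,
        n_shared_parents=2,
        set_sizes=(100, 100),
        n_full_sib_families=50,
        selfing_generations=5,
        chromosomes=(
            ChromosomeSpec("c1", 200, 100.0),
            ChromosomeSpec("c2", 200, 100.0),
            ChromosomeSpec("c3", 200, 100.0),
        ),
        parent_group_size=5,
    )
    kwargs.update(overrides)
    return BreedingDesign(**kwargs)


@pytest.fixture(scope="session")
def cohort():
    """200-line, 600-SNP cohort with one major QTL, h2 = 0.6."""
    design = small_design()
    arch = TraitArchitecture(
        major_qtl=(Qtl("c1", 0.3, 1.2),),
        polygenic_snp_fraction=0.3,
        target_h2=0.6,
        genetic_var_target=4.0,
        set_effect_sd=1.0,
        trait_mean=50.0,
    )
    markers, phenotypes, pedigree, truth = simulate_cohort(design, arch, seed=11)
    return {
        "design": design,
        "arch": arch,
        "markers": markers,
        "phenotypes": phenotypes,
        "pedigree": pedigree,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def cohort_g(cohort):
    z = center(cohort["markers"])
    return z, vanraden_g(z)


@pytest.fixture
def toy_markers():
    """3 lines x 2 SNPs with hand-computable G."""
    return MarkerMatrix(
        lines=["A", "B", "C"],
        snps=["s1", "s2"],
        codes=np.array([[1, -1], [-1, -1], [1, 1]], dtype=np.int8),
        chromosomes=["c1", "c2"],
        positions=[10.0, 20.0],
    )


def hwe_markers(n_lines, n_snps, seed, chroms=2):
    """Non-inbred markers with HWE genotype frequencies (for d(G) ~ 1)."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.1, 0.5, n_snps)
    u = rng.random((n_lines, n_snps))
    codes = np.where(u < (1 - p) ** 2, -1, np.where(u < (1 - p) ** 2 + 2 * p * (1 - p), 0, 1))
    per = n_snps // chroms
    labels = np.repeat([f"c{i+1}" for i in range(chroms)], per)
    labels = np.concatenate([labels, [f"c{chroms}"] * (n_snps - len(labels))])
    return MarkerMatrix(
        lines=[f"L{i}" for i in range(n_lines)],
        snps=[f"s{j}" for j in range(n_snps)],
        codes=codes.astype(np.int8),
        chromosomes=labels,
        positions=np.tile(np.arange(per, dtype=float), chroms + 1)[:n_snps],
    )


def pheno_frame(lines, y, sets=None):
    return pd.DataFrame(
        {
            "line_id": lines,
            "set": sets if sets is not None else ["set1"] * len(lines),
            "trait": y,
        }
    )
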