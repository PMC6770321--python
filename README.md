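# cropgs

Genomic prediction and mixed-model GWAS toolkit for inbred breeding
cohorts, with a synthetic-cohort generator for method validation.

The package implements an end-to-end quantitative-genetics workflow for
biallelic SNP data on (near-)inbred lines:

- **Marker QC and relationship matrices** (`cropgs.markers`): MAF /
  missingness filtering, additive -1/0/+1 coding, VanRaden method-1
  G-matrices, leave-one-chromosome-out (LOCO) kinship and
  significance-partitioned two-kernel constructions.
- **Mixed models** (`cropgs.mixedmodel`): average-information REML with
  EM-style damping for one or two genomic kernels, Henderson-equivalent
  BLUP solving with GEBVs for unphenotyped lines, genomic heritability
  `h2 = d(G) * sg2 / (d(G) * sg2 + se2)`.
- **Association scans** (`cropgs.assoc`): EMMAX-style single-marker GWAS
  under LOCO kinship, genomic-control inflation correction (median
  chi-squared ratio), Bonferroni thresholds, per-SNP explained genetic
  variance `100 * 2p(1-p)a^2 / sg2`, allele-combination summary tables.
- **Bayesian Power Lasso** (`cropgs.powerlasso`): whole-genome regression
  with an exponential power prior on SNP effects (shape beta in (0, 1];
  beta = 1 is the Bayesian Lasso), numba-accelerated Gibbs /
  Metropolis-within-Gibbs sampling, DIC-based shape selection, Geweke/ESS
  diagnostics.
- **Cross-validation** (`cropgs.crossval`): LOO (with an exact fast
  path), leave-family-out over half-sib clusters, leave-set-out,
  set-stratified k-fold, training-fraction curves (subset LOO), and the
  split-half genomic-feature protocol; predictive ability (correlation of
  fixed-effect-corrected phenotypes with GEBVs) and bias (regression
  slope vs 1.0).
- **Cohort simulator** (`cropgs.simcohort`): block-mosaic founder
  haplotypes with map-distance LD decay, biparental crosses, Haldane
  recombination, single-seed-descent selfing to F6, major-QTL +
  polygenic trait architectures with ground-truth records.
- **I/O and pipeline** (`cropgs.interface`, `cropgs.cli`): tab-delimited
  genotype matrix + map, phenotype CSV, VCF read/write, YAML-configured
  end-to-end pipeline with a machine-readable manifest.

## Command line

```bash
cropgs simulate --config design.yaml --seed 1 --out data/
cropgs qc --genotypes data/genotypes.tsv --map data/map.tsv --out qc/
cropgs gwas --genotypes data/genotypes.tsv --map data/map.tsv \
    --phenotypes data/phenotypes.csv --trait trait --out gwas.tsv
cropgs gblup --genotypes data/genotypes.tsv --map data/map.tsv \
    --phenotypes data/phenotypes.csv --trait trait --out gblup/
cropgs powerlasso --genotypes data/genotypes.tsv --map data/map.tsv \
    --phenotypes data/phenotypes.csv --trait trait \
    --beta-grid 0.2,0.4,0.8,1.0 --chain 100000 --burnin 30000 --out plasso/
cropgs cv --genotypes data/genotypes.tsv --map data/map.tsv \
    --phenotypes data/phenotypes.csv --pedigree data/pedigree.csv \
    --trait trait --scheme lfo --out cv/
cropgs feature --genotypes data/genotypes.tsv --map data/map.tsv \
    --phenotypes data/phenotypes.csv --trait trait \
    --thresholds 5,10,50,100,500,1000 --out feature.tsv
cropgs pipeline --config run.yaml
```

A pipeline YAML looks like:

```yaml
genotypes: data/genotypes.tsv
genotype_map: data/map.tsv
phenotypes: data/phenotypes.csv
out_dir: results/run1
traits: [trait]
cv_schemes: [loo, kfold]
kfold_k: 5
seed: 1
```

## Notes

- Genotypes are coded -1/0/+1 internally; the 0/1/2 dosage coding used by
  the whole-genome regression is derived as `code + 1` at the model
  boundary.
- G-matrix frequencies and scaling denominators are recomputed over the
  SNP subset actually used (full / LOCO / partition), and a `1e-6`
  diagonal ridge is applied before any factorization.
- For fully inbred lines the average G diagonal approaches 2; the
  heritability formula uses the realized `d(G)` explicitly and never
  assumes 1.
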