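# sirescan

Genome scans for sire conception rate (SCR), a phenotypic evaluation of
dairy-bull fertility, on pedigree + SNP panel data:

* **Additive scan** — single-step GBLUP: a reliability-weighted
  repeatability animal model solved with the combined pedigree–genomic
  relationship inverse `H⁻¹ = A⁻¹ + [0 0; 0 G⁻¹ − A₂₂⁻¹]`, SNP effects
  back-solved from GEBVs (`ŝ = DM′[MDM′]⁻¹û`), and the percentage of
  additive variance per 1.5-Mb window of adjacent SNPs.
* **Non-additive scan** — a two-step mixed-model screen: a genomic
  animal model fixes `V₀ = G σ̂u² + I σ̂e²` on one (most reliable) record
  per animal, then every SNP is tested under dominance (0,1,1),
  recessive (0,0,1) and overdominance (0,1,0) recodings with a score
  statistic, median-based genomic control and per-coding Bonferroni
  correction.
* **Gene-set enrichment** — SNPs are assigned to genes within ±15 kb,
  genes hit by the top 1% of |SNP effect| are flagged significant, and
  each GMT term is tested with the exact upper-tail hypergeometric
  probability.
* **Synthetic data** — seeded generators for pedigrees, gene-dropped
  genotypes, repeated phenotype records with reliabilities, additive and
  recessive QTL architectures, and BED/GMT annotation, so the whole
  pipeline is testable end to end without external data.

## Command line

```sh
sirescan show-config                       # effective defaults (QC thresholds, window span, ...)
sirescan run-all --out run1 --seed 7       # simulate -> qc -> both scans -> geneset
sirescan simulate --config sim.yaml --out data
sirescan qc --genotypes data/genotypes.tsv --map data/map.tsv --out data
sirescan scan-additive --pedigree data/pedigree.csv --genotypes data/genotypes_qc.tsv \
    --map data/map_qc.tsv --phenotypes data/phenotypes.tsv --out data
sirescan scan-nonadditive --pedigree data/pedigree.csv --genotypes data/genotypes_qc.tsv \
    --map data/map_qc.tsv --phenotypes data/phenotypes.tsv \
    --coding dominance,recessive,overdominance --out data
sirescan geneset --effects data/snp_effects.tsv --map data/map_qc.tsv \
    --genes data/genes.bed --sets data/sets.gmt --out data
```

A single YAML file (see `sirescan show-config` for every key) drives all
stages; results are reproducible byte-for-byte for a fixed config + seed.

File formats are plain text throughout: pedigree CSV (`animal,sire,dam`,
0 = unknown), PLINK-RAW-like genotype TSV (codes 0/1/2, `NA` missing)
with a `snp/chrom/pos` map TSV (1-based), phenotype TSV
(`animal, record_id, value, reliability[, covariates]`), BED (0-based
half-open) gene intervals and GMT gene sets.

## Layout

```
src/sirescan/
  synthetic.py    seeded pedigree / genotype / phenotype / annotation simulators
  pedigree.py     A (tabular), inbreeding (Meuwissen–Luo), sparse A⁻¹ (Henderson), A₂₂
  genotypes.py    QC filters, allele frequencies, VanRaden G with A₂₂ blending, H⁻¹
  ssgblup.py      REML (Woodbury-profiled), sparse MME solver, SNP back-solution, window scan
  nonadditive.py  record selection, null model, genotype recodings, score tests, GC, Bonferroni
  geneset.py      SNP→gene assignment, top-fraction flagging, hypergeometric enrichment
  cli.py, io.py, config.py   orchestration, plain-text readers/writers, validated config
tests/            unit + property tests per module, test_acceptance.py for the criteria
scripts/acceptance.py
```
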