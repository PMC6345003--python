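# bshprof

Profiling of the bile salt hydrolase (BSH) protein family across bacterial
strains and human gut metagenomes:

- **reference curation** — length filtering (300–400 aa), pairwise protein
  identity (BLOSUM45/62, BLAST-style identity with gap columns in the
  denominator), homology screening at an identity cutoff (default 45%), and
  within/between-genus identity density analysis with a derived threshold;
- **taxonomy & paralog census** — strain-name taxonomy parsing, per-strain
  family copy-number (NP) distribution, encoding-strain fractions, and
  genus/phylum rollups;
- **abundance profiling** — non-redundant gene catalog (95% identity / 90%
  overlap), read mapping, length-normalized relative abundance
  (`RA(g,i) = (c/L) / Σ(c/L)` per individual), per-individual family-member
  detection at 62% identity, and cumulative RA per population;
- **phylotyping** — neighbor-joining trees from alignment distances
  (p-distance or Poisson-corrected), average-linkage phylotype cutting with
  an unclassifiable outlier group (T0), nearest-reference assignment of new
  sequences, and a phylotype census with same- vs cross-phylotype paralog
  accounting;
- **association statistics** — healthy-cohort screening (strict
  18.5 < BMI < 29.9, 12 < age < 75 bounds), Mann-Whitney U with
  Benjamini-Hochberg FDR, Spearman phenotype correlations (exact permutation
  null for small n), chi-squared presence tests, and multivariable-adjusted
  OLS with per-factor partial-F p values and partial R² variance explained;
- **synthetic data** — a generator that plants a protein family with
  controllable within-genus (~82%) and between-genus (~35%/50% bimodal)
  identity, an exact largest-remainder paralog-count quota, error-free reads
  from codon back-translations, cohort covariates with plantable effects,
  and country-level phenotype tables with a plantable monotone link — so the
  whole pipeline is testable offline.

## CLI

```bash
bshprof simulate  --config sim.yaml --out data/ --seed 1
bshprof curate    --queries q.faa --proteomes data/proteomes --out hits.tsv
bshprof census    --hits hits.tsv --strains strains.tsv --out census/
bshprof phylotype --seqs family.faa --k 8 --out phylo/
bshprof assign    --query new.faa --scheme phylo/ --refs family.faa
bshprof run       --config run.yaml    # full pipeline with manifest + caching
```

`bshprof run` executes `simulate → curate → census → profile → phylotype →
associate` from a single YAML config, records SHA-256 checksums of every
stage's inputs and outputs in `manifest.json`, and skips stages whose
parameters and checksums are unchanged. Exit codes: 0 success, 2 validation
error, 3 stage failure.

Example `run.yaml`:

```yaml
seed: 13
out_dir: myrun
simulate:
  n_genera: 4
  strains_per_genus: 3
  populations: [US, CN, HZ]
  n_individuals_per_population: 5
phylotype:
  k: 4
```

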