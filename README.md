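# snpmdr

Case-control SNP association analysis with multifactor dimensionality
reduction (MDR), built around a seven-SNP 8q24 prostate-cancer panel:

- **cohort I/O** — a self-describing delimited cohort format (subject
  covariates + 0/1/2-coded or allele-pair genotypes) and read-only
  bi-allelic VCF input (`snpmdr.cohort`);
- **synthetic cohorts** — a generator calibrated to bundled per-SNP
  genotype counts, call rates, and covariate distributions, with
  a `plant_single_locus_effect` hook for parameter-recovery experiments
  (`snpmdr.simulate`);
- **QC** — per-SNP call rates, high-missingness subject removal
  (≥ 4 of 7 missing), ancestry-fraction inclusion (≥ 0.25), duplicate
  concordance (`snpmdr.qc`);
- **association statistics** — cross-product odds ratios with Woolf 95%
  CIs (Haldane-Anscombe correction on zero cells), Pearson chi-square
  homogeneity, the Cochran-Armitage trend test, and covariate-adjusted
  logistic regression fitted by IRLS (`snpmdr.stats`);
- **MDR** — exhaustive single- and multi-locus search, case:control-ratio
  risk binning, stratified 10-fold cross-validation scored by balanced
  accuracy (CVC + ATA), and label-permutation testing in which the whole
  search is re-run per permutation (`snpmdr.mdr`);
- **pipeline** — simulate/load → QC → association → MDR with
  deterministic TSV reports and a provenance block (`snpmdr.pipeline`).

## CLI

```sh
snpmdr simulate --seed 1 --out cohort.tsv          # calibrated synthetic cohort
snpmdr qc --in cohort.tsv --out qc.tsv
snpmdr assoc --in cohort.tsv --out assoc.tsv --covariates age,ancestry
snpmdr mdr --in cohort.tsv --out mdr.tsv -B 1000 --seed 1
snpmdr run --out outdir --seed 1 -B 1000           # full pipeline
```

`snpmdr run` writes `cohort.tsv`, `qc.tsv`, `summary.tsv`,
`association.tsv`, `mdr.tsv`, `mdr_null.tsv`, and `provenance.json` into
the output directory; identical config + seed reproduce the artifacts
byte-for-byte.

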