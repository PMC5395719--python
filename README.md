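# tmbkit

Panel-based tumor mutational burden (TMB) analysis toolkit with a synthetic
cohort generator, so the full pipeline runs end-to-end with no external data.

Components:

- **`tmbkit.tmb`** — the somatic filter cascade (non-coding, known somatic
  hotspot, tumor-suppressor truncation, zygosity-predicted germline,
  cohort-recurrent germline, dbSNP, population allele count ≥ 2) and TMB as
  counted mutations per megabase of coding territory (default panel:
  315 genes / 1.1 Mb; exome: 38 Mb). Includes a simplified allele-fraction
  zygosity proxy and a panel-vs-exome TMB comparison.
- **`tmbkit.downsample`** — binomial simulation of observed TMB when
  sequencing a given number of megabases; percent-deviation quantiles over a
  (TMB level × Mb) grid.
- **`tmbkit.msi`** — microsatellite-instability score: per-locus mean and
  variance of read repeat lengths over a 114-locus intronic homopolymer
  panel (228 features), projected onto the first principal component, with
  MSS / ambiguous / MSI-H thresholding (labeled or Gaussian-mixture based).
- **`tmbkit.association`** — per-gene and per-mutation OLS of
  `log10(TMB + pseudo-count) ~ carrier status + disease type` with
  Benjamini–Hochberg FDR; logistic co-occurrence testing with a TMB
  covariate; eligibility filters (≥ 6 carriers per gene, mutation frequency
  > 1/2000, homopolymer context < 6 bp, not in dbSNP).
- **`tmbkit.landscape`** — cohort eligibility (one specimen per patient,
  ≥ 300× coverage), per-disease TMB summaries with Wilson confidence
  intervals (high TMB = strictly > 20 mutations/Mb), age trend
  (fold-change between ages 10 and 90), MSI × TMB cross-tabulation, and
  driver-explained-fraction tallies.
- **`tmbkit.synthetic`** — cohort generator: per-disease log10-TMB
  baselines, a linear age effect, multiplicative driver effects
  (MMR / POLE / PMS2-promoter), Poisson somatic counts, germline
  polymorphisms with population allele counts and diploid allele fractions,
  and MSI read-length profiles for stable/unstable specimens. Ground truth
  (true TMB, variant origin, MSI status) is returned alongside the tables.
- **`tmbkit.io` / `tmbkit.pipeline` / `tmbkit.cli`** — MAF-like TSV,
  VCF v4.2, and BED (converted to 1-based inclusive on read) readers and
  writers, plus the end-to-end pipeline with a JSON run manifest.

## CLI

All stages hang off one `tmb` command:

```sh
tmb simulate --n 500 --seed 7 --out-dir sim/            # synthetic cohort
tmb compute --variants sim/variants.tsv --out tmb.tsv   # filter cascade + TMB
tmb downsample --levels 100,20,10 --mb 0.2:10:0.2 --reps 1000 --seed 7 --out grid.tsv
tmb msi --profiles sim/msi_profiles.tsv --out msi.tsv
tmb assoc --mode gene --specimens spec.tsv --carriers carriers.tsv --out assoc.tsv
tmb landscape --specimens spec.tsv --min-n 50 --out table1.tsv
tmb run --out-dir run/ --seed 7                         # full pipeline
```

Variant tables are tab-delimited UTF-8 with `#` comments and a header row;
required columns are `specimen_id, chrom, pos, ref, alt, gene, effect`, and
the annotation flags (`coding, known_somatic_hotspot, ts_truncation, dbsnp,
population_count, recurrent_germline, zygosity_call, allele_fraction,
homopolymer_len`) default to permissive values when absent. VCF input
carries the same annotations in INFO keys (`GENE, EFFECT, CODING, KSH, TST,
DBSNP, POPC, RECG, ZYG, VAF, HPL, SID`).

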