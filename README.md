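# mrkit

Two-sample Mendelian randomization (MR) from GWAS summary statistics:
fixed-effects meta-analysis across cohorts, instrument selection with LD
clumping and strength diagnostics, univariable MR (IVW, MR-Egger, weighted
median, contamination mixture) with heterogeneity, leave-one-out and Steiger
sensitivity analyses, multivariable MR, and product-method mediation
decomposition. A synthetic-data module generates two-sample summary
statistics under a known exposure → mediator → outcome structural model so
the whole pipeline is testable without external data.

## Layout

| module | contents |
| --- | --- |
| `mrkit.sumstats` | summary-statistics containers, TSV/CSV I/O, OR→log-odds conversion, allele harmonization incl. palindromic SNPs |
| `mrkit.simulate` | synthetic GWAS summary statistics + block LD under a configurable structural model |
| `mrkit.meta` | fixed-effects inverse-variance meta-analysis, Cochran's Q / I², heterogeneity filtering |
| `mrkit.instruments` | p-value instrument selection, greedy LD clumping, R²/F instrument strength |
| `mrkit.estimators` | Wald ratio, IVW, MR-Egger, weighted median, contamination mixture, leave-one-out, Steiger filtering, primary-estimate selection |
| `mrkit.mvmr` | multivariable MR direct effects, mediation (A×B, proportion mediated, delta-method uncertainty) |
| `mrkit.pipeline` | BH-FDR, univariable screen, full exposure→mediator→outcome workflow from a YAML config |

## CLI

```sh
mrkit simulate --config sim.yaml --seed 11 --out simdir/
mrkit clump simdir/exposure.tsv --ld simdir/ld.tsv --out instruments.tsv
mrkit harmonize --exposure instruments.tsv --outcome simdir/outcome.tsv --out harmonized.tsv
mrkit mr harmonized.tsv --seed 4 --out mr_results.tsv
mrkit meta cohort1.tsv cohort2.tsv --trait-type binary --out pooled.tsv
mrkit mvmr harmonized_multi.tsv --out mvmr.tsv
mrkit mediate --total 0.2 0.01 --a-path 0.5 0.01 --b-path 0.2 0.01
mrkit pipeline --config run.yaml --out results/
```

`mrkit pipeline` expects a YAML config naming per-trait summary-statistics
files (with a column-name mapping), the analysis graph (exposures, mediators,
outcomes), thresholds (instrument p-value, clump r², I² exclusion, FDR level,
Egger intercept alpha, palindrome EAF window) and a seed; it writes a
screen table, mediation JSON and a provenance log.

## Conventions

- All effects are additive internally: log-odds for binary traits, SD units
  for continuous ones. Odds-ratio inputs are converted at read time.
- Coordinates are 1-based; variants match by ID.
- Every stochastic routine (bootstrap, simulation) takes an explicit seed.
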