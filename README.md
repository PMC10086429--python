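# mrmediate

Two-sample Mendelian randomization (MR) and two-step MR mediation analysis
on GWAS summary statistics, with a synthetic-data generator for end-to-end
validation against known truth.

## What it does

- **sumstats** — read/write/validate tab-delimited GWAS summary tables
  (`snp, effect_allele, other_allele, beta, se, pval, eaf, n`; `NA` for
  missing), LD matrices, and proxy tables; reconstruct SEs from printed
  confidence intervals.
- **synthgen** — simulate cohorts under a linear structural model with a
  known exposure → mediator → outcome decomposition (per-SNP effects, LD
  blocks, palindromic alleles, allele-label flips, disjoint per-trait
  subsamples), and emit summary-statistics bundles plus truth files.
- **instruments** — p-value thresholding, exclusion lists, greedy LD
  clumping (r² < 0.001 within 10,000 kb by default), proxy lookup
  (r² > 0.8), per-SNP F statistics and explained variance.
- **harmonize** — effect-allele alignment, strand-complement resolution,
  and frequency-based handling of palindromic SNPs (ambiguous when the
  effect-allele frequency falls in the open interval (0.4, 0.6)).
- **uvmr** — IVW (fixed / multiplicative-random / auto), MR-Egger with
  intercept test, weighted and penalized weighted median, maximum
  likelihood, radial IVW, MR-PRESSO outlier detection, leave-one-out,
  and SIMEX correction of the Egger slope.
- **mvmr** — multivariable IVW, multivariable Egger, and a
  heterogeneity-minimizing (Q-based) estimator with bootstrap intervals.
- **mediation** — product-method indirect effects with delta-method SEs,
  proportion mediated, and parallel-mediator combined mediation.
- **pipeline** — config-driven orchestration with the
  pleiotropy/heterogeneity method decision rule, Benjamini–Hochberg FDR
  evidence labels, odds-ratio conversion, and a run manifest.

## CLI

```sh
mrmediate simulate --config truth.yaml --out data/ --seed 1
mrmediate instruments --exposure x.tsv --ld ld.tsv --loci loci.tsv --p 5e-5
mrmediate harmonize --exposure x.tsv --outcome y.tsv --out harmonized.tsv
mrmediate uvmr --harmonized harmonized.tsv --methods ivw,egger,wmedian --seed 1
mrmediate mediate --exposure x.tsv --mediators m1.tsv,m2.tsv --outcome y.tsv
mrmediate run --config analysis.yaml
```

`analysis.yaml` accepts the fields of `mrmediate.pipeline.AnalysisConfig`
(file paths, `p_threshold`, `clump_r2`, `clump_kb`, `proxy_r2_min`,
`af_ambiguous`, `presso_nb_sim`, `fdr_q`, `methods`, `seed`, `out_dir`).
A seed is mandatory whenever a stochastic method (PRESSO, medians, SIMEX)
is requested; reruns with the same config are byte-identical.

## Conventions

- Binary-trait effects are log-odds; `exp(estimate)` is the odds ratio.
  No internal scale conversion is performed.
- First-order inverse-variance weights (outcome SE only) are the default
  everywhere; second-order variants are available behind flags.
- Random-effects IVW uses multiplicative residual-variance scaling
  bounded below by 1.
- All stochastic procedures are reproducible bit-for-bit given a seed.
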