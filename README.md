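# vitdmr

Triangulation toolkit for the relationship between a seasonally varying serum
biomarker (25-hydroxyvitamin D, nmol/L) and blood pressure / hypertension:
conventional observational regression, split-sample one-sample Mendelian
randomization via an externally weighted genetic risk score, two-sample MR
sensitivity estimators implemented from first principles, and non-linear MR
by residual and doubly-ranked stratification. Because the motivating cohort
data are access-restricted, the package ships a first-class synthetic-cohort
generator that reproduces the statistical structure the analysis assumes
(Hardy–Weinberg genotypes, additive genetic effects, a one-harmonic seasonal
component, shared measured and unmeasured confounding, two survey waves,
antihypertensive-medication use).

## Layout

| module | purpose |
| --- | --- |
| `vitdmr.simdata` | SNP panels, synthetic cohorts, summary-statistic sets, outlier planting |
| `vitdmr.pheno` | BP summarization (+10/+5 medication amendment), hypertension coding, cosinor season standardization, biomarker bands, covariate encoding, prospective-sample selection |
| `vitdmr.grs` | weighted allele score, first-stage F/R² diagnostics, score–confounder balance |
| `vitdmr.obsmodels` | OLS / IRLS-logistic fits, cross-sectional and prospective tables, restricted-cubic-spline non-linearity test |
| `vitdmr.mr_onesample` | split-sample Wald ratio with delta-method SEs |
| `vitdmr.mr_twosample` | harmonization, IVW, Egger, weighted median, Cochran's Q, RSS-based outlier procedure (global / outlier / distortion tests) |
| `vitdmr.nlmr` | residual and doubly-ranked stratification, stratum Wald estimates, heterogeneity and trend non-linearity tests |
| `vitdmr.pipeline` | end-to-end orchestration with deterministic per-stage seed fan-out |

## CLI

```sh
# synthetic cohort (phenotypes.tsv, genotypes.tsv, panel.tsv [, minimal VCF])
vitdmr simulate --out sim/ --seed 1 [--vcf]

# individual stages
vitdmr obs  --phenotypes sim/phenotypes.tsv --genotypes sim/genotypes.tsv --panel sim/panel.tsv --out obs.tsv
vitdmr mr1  --phenotypes sim/phenotypes.tsv --genotypes sim/genotypes.tsv --panel sim/panel.tsv --out mr1.tsv
vitdmr mr2s --stats summary_stats.tsv --method all --seed 1 --out mr2s.tsv
vitdmr nlmr --phenotypes sim/phenotypes.tsv --genotypes sim/genotypes.tsv --panel sim/panel.tsv \
            --method doubly-ranked --strata 4 --out nlmr.tsv

# full pipeline from a YAML config (see below)
vitdmr all --config cfg.yaml
```

Example `cfg.yaml`:

```yaml
outdir: run1
seed: 7
sim:
  n_total: 20000
  n_subcohort: 2000
  theta_sbp: 0.0
scale: 25.0
ivw_model: random
strata_k: 4
```

The pipeline writes per-stage TSVs, a combined `summary.tsv` comparing the
cross-sectional, prospective, one-sample-MR and two-sample-MR estimates per
outcome, and `metadata.json` recording the seed, child seeds and every
setting; reruns with the same seed are byte-identical.

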