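# prsport — polygenic risk score portability across populations

A polygenic risk score (PRS) summarizes an individual's genetic liability
for a trait as a weighted sum of effect-allele counts,

```
PRS = Σᵢ wᵢ · Xᵢ ,      Xᵢ ∈ {0, 1, 2}
```

with weights taken from a published model — either directly the GWAS effect
sizes (`wᵢ = βᵢ`, as in large coronary-heart-disease scores) or shrunken
against the winner's curse (`wᵢ = βᵢ·πᵢ`, as in double-weighted type-2
diabetes scores). Risk is then stratified by quintiles of the score
distribution *within a reference cohort*: top quintile, highest assumed
genetic risk.

The catch, for anyone applying such thresholds in practice: effect-allele
frequencies differ between populations, so the *whole score distribution*
shifts between ancestries even when per-SNP effects are homogeneous. A
score that marks the top CHD-risk quintile among Europeans can sit below
the *bottom* quintile of an African-ancestry cohort — absolute cut-offs do
not transfer, and an individual assigned to the wrong population gets a
systematically wrong risk estimate.

`prsport` is a toolkit for quantifying exactly this failure mode:

* **weights** — read/validate single- and double-weighted PRS weight
  tables (TSV), orient all SNPs risk-increasing;
* **genotypes** — extract model-SNP dosage matrices from multi-sample VCF
  by ID or alias, with a sample→population map and a first-class exclusion
  log (`not_in_vcf`, `multiallelic`);
* **harmonize** — align VCF alleles to effect alleles: drop strand-ambiguous
  palindromic (A/T, C/G) SNPs, flip dosages where the effect allele is REF,
  exclude unresolvable records (`allele_mismatch`); no imputation, ever;
* **scoring** — vectorized `Σ wᵢXᵢ` with explicit missing-dosage policy,
  then z-scaling over **all samples pooled** (never per population — the
  between-population shift is the signal);
* **stratify** — per-population quantile tables (mean, 95% CI, min/max,
  quintile thresholds), quintile assignment against any reference
  population's thresholds, cross-population transfer matrices, and a
  single-covariate logistic fit giving the odds ratio per pooled-SD of PRS;
* **ancestry** — genotype PCA with the standard `2p̂(1−p̂)` dosage
  normalization, per-population PRS–PC1 correlation, and effect-allele
  frequency comparison of the top-|w| SNPs between two populations;
* **simulate** — a Balding–Nichols multi-population generator
  (per-population F, optional directional risk-allele frequency shift δ,
  Hardy–Weinberg genotypes, logistic phenotypes) with closed-form PRS
  moment oracles, plus a VCF/TSV fixture writer that exercises every
  harmonization path with exact counts;
* **pipeline / CLI** — `prsport simulate|score|stratify|pca|freqs|run-all|demo`
  over a flat YAML config, writing TSV tables and a JSON run manifest.

## Weight-table schema

Tab-separated with a header; columns are matched by name:

| column          | required       | meaning                                  |
|-----------------|----------------|------------------------------------------|
| `snp_id`        | yes            | rsID-style identifier, unique             |
| `effect_allele` | yes            | counted allele, one of A/C/G/T            |
| `other_allele`  | yes            | the alternative allele                    |
| `beta`          | yes            | effect size (log-odds per effect allele)  |
| `pi`            | double-weighted | shrinkage multiplier in [0, 1]           |

## Worked example

The built-in demo simulates six populations (1000 SNPs, 400 samples each):
two undifferentiated European-like cohorts (EST, EUR; F = 0.003) and four
populations with increasing differentiation and directional risk-allele
shifts (AMR, SAS, EAS, AFR; F up to 0.08, δ up to 0.12). It writes a VCF
fixture, runs the full pipeline, and reports on the pooled-scaled axis:

```sh
prsport demo --out-dir demo --seed 3
```

`demo/report/quantiles.tsv` (rounded):

```
population   n   mean    min    q20    q40    q60    q80    max
EST        400  -1.08  -1.95  -1.33  -1.14  -1.03  -0.86  -0.26
EUR        400  -1.07  -1.83  -1.32  -1.12  -0.99  -0.84  -0.10
AMR        400  -0.44  -1.25  -0.68  -0.51  -0.36  -0.18   0.46
SAS        400   0.24  -0.58   0.01   0.17   0.31   0.48   1.07
EAS        400   0.84   0.02   0.58   0.77   0.93   1.10   1.50
AFR        400   1.50   0.78   1.28   1.42   1.56   1.75   2.26
```

The two undifferentiated cohorts share thresholds (EST vs EUR quintiles
agree to ~0.02 pooled SD), while the shifted populations' distributions
march upward: AFR's *minimum* (0.78) already exceeds EUR's *maximum*
(−0.10). Applying EUR's quintile cut-offs across populations
(`demo/report/quintile_transfer.tsv`):

```
reference  target     q1     q2     q3     q4     q5
EUR        EST      0.212  0.212  0.207  0.188  0.180
EUR        AFR      0.000  0.000  0.000  0.000  1.000
```

EST transfers near-uniformly (fifths within sampling error); 100% of AFR
lands in EUR's top "risk" quintile — the score has become a population
label, not a risk ranking. The run manifest records the bookkeeping: 1000
model SNPs, 50 omitted from the VCF (`not_in_vcf`), 100 palindromic SNPs
dropped, 850 scored.

The same report contains the PCA scores (PC1 separates the differentiated
populations), the per-population PRS–PC1 correlations, and the
effect-allele frequency comparison of the top-20 SNPs between EUR and AFR,
where the risk-allele frequencies sit ≈ δ higher in AFR by construction.

For a real analysis, point `run-all` at your own inputs:

```sh
prsport run-all --config config.yaml
# config.yaml: vcf, weights, pop_map, out_dir, alias_map,
#              double_weighted, drop_palindromic, missing_policy,
#              n_components, top_k, reference_population, seed …
```

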