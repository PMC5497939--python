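# Methods

## The score and its scaling

The polygenic risk score of sample *j* is the weighted effect-allele count
PRS*ⱼ* = Σᵢ wᵢXᵢⱼ over the model's SNPs, Xᵢⱼ ∈ {0,1,2}. Two weighting
conventions are supported: single-weighted (wᵢ = βᵢ, the GWAS effect size)
and double-weighted (wᵢ = βᵢπᵢ with a per-SNP shrinkage multiplier
πᵢ ∈ [0,1] that damps winner's-curse inflation). Weights are parsed as
binary64 and never rounded; zero-weight records are retained so SNP counts
stay honest.

Scores are z-scaled over **all samples pooled**, with the n−1 standard
deviation. Pooled (never per-population) scaling is load-bearing: the
between-population location shift is the quantity under study, and
per-population scaling would erase it. The n−1 choice is distribution-
visible at small n and is therefore fixed and documented rather than left
to a library default.

## Missing dosages

Three explicit policies fill missing genotypes before the weighted sum:
`mean_dosage` (the pooled mean dosage of that SNP — the common default of
standard scoring tools), `zero`, and `drop_snp_for_sample` (omit the
term). For a plain sum the last two are numerically identical — omitting
a term equals adding zero — but both names are kept because the analyst's
intent differs; `n_snps_used` records the per-sample non-missing count
either way. Absent SNPs are never imputed: they are dropped and logged.

## Harmonization

VCF records are matched to the model by ID (or through a static alias
map); coordinates are ignored, so no liftover is needed or attempted.
Palindromic SNPs (allele pair A/T or C/G) are strand-ambiguous between
datasets and are dropped outright when the filter is enabled; the filter
is per-model configuration because some published pipelines pre-filter
them and others do not. For the remainder: effect allele = ALT keeps the
dosage, effect allele = REF flips it to 2 − d (missing stays missing), and
any other configuration is excluded as `allele_mismatch` — no strand
flipping is guessed for non-palindromic mismatches. Multiallelic records
are excluded with their own reason code, the conservative reading of
ID-based extraction. After harmonization the matrix's ref/alt fields are
rewritten so ALT is always the counted effect allele, which keeps
downstream frequency comparisons orientation-invariant. Retained plus
excluded always equals the model's SNP count; the exclusion log is a
first-class TSV output.

## Stratification

Per-population summaries use the linear-interpolation empirical quantile
estimator (`numpy.quantile`, `method="linear"` — the common default of
mainstream statistical environments); the estimator is fixed and named
because quintile thresholds are the headline output. The 95% CI is the
normal approximation mean ± 1.96·sd/√n. Quintile assignment against a
reference population's thresholds puts boundary scores in the **lower**
quintile (a score exactly at q80 is quintile 4); the convention is
arbitrary but must be fixed for determinism. Cross-population transfer
reports the fraction of a target population in each reference quintile;
with target = reference this is uniform fifths up to 1/n.

The odds-ratio check fits a maximum-likelihood logistic regression of a
binary phenotype on the scaled score (intercept + slope), reporting
OR = exp(slope) per scaled-PRS unit — i.e. per pooled SD, the natural
reading for a model on scaled scores — with a Wald 95% CI. Complete
separation and single-class phenotypes are hard errors.

## Genotype PCA

Dosage columns are mean-substituted for missing values (local to the PCA;
scoring keeps its own policy), centered by 2p̂ and scaled by √(2p̂(1−p̂)) —
the standard genotype-PCA normalization. Constant or monomorphic columns
are dropped; if none remain the decomposition is undefined and errors.
Eigenvectors come from a full SVD; each component's sign is fixed so its
loading sum is non-negative. Because any sign convention is arbitrary,
per-population PRS–PC1 correlations are reported signed but |r| is the
meaningful magnitude. The per-population correlation recomputes the PCA on
that population's samples only. Top-SNP selection ranks by |weight| with
lexicographic ID tie-break — a proxy for "largest GWAS z-score", which is
not recoverable from a weight file and should not be assumed identical.

## The synthetic generator

Per-population allele frequencies follow the Balding–Nichols model:
p_pop ~ Beta(p(1−F)/F, (1−p)(1−F)/F) around an ancestral p ~ U(0.1, 0.9),
with mean p and variance F·p(1−p); F plays the role of F_ST. A directional
shift δ then moves each SNP's **risk-allele** frequency (effect allele for
w > 0, other allele for w < 0) by δ, raising that population's expected
raw-PRS mean by exactly 2δΣ|wᵢ|. All frequencies are clipped to
[0.01, 0.99] to keep SNPs polymorphic for PCA scaling. Genotypes are
Binomial(2, p_pop) per SNP and sample (Hardy–Weinberg), SNPs in linkage
equilibrium. Weights are N(0, 0.1) by default — both signs, magnitudes in
the range typical of per-SNP log-odds — with π ~ U over a configurable
range for double-weighted models.

Linkage equilibrium is a deliberate simplification: the cross-population
shift mechanism studied here is frequency-driven, not LD-driven, and
independent SNPs keep the moment oracles exact —
E[PRS] = Σ2wᵢpᵢ, Var[PRS] = Σ2wᵢ²pᵢ(1−pᵢ). What the generator therefore
does **not** emulate: LD-induced effect-size transferability decay, real
site-frequency spectra, admixed individuals, genotyping error. Passing
tests demonstrate the pipeline's arithmetic, bookkeeping and statistical
contracts, not that any particular published score transfers or fails to
transfer in real cohorts.

The fixture writer assigns disjoint SNP categories by a seeded permutation
with exact rounded counts — palindromic alleles, effect-as-REF
orientation, omission from the VCF, aliased IDs, missing genotype calls —
so every harmonization path is exercised with deterministic expected
counts. Phenotypes are drawn from P(case) = expit(α + log(OR)·scaled PRS)
with α solved by Brent's method to hit a target prevalence. All
randomness derives from the model seed through independent per-operation
substreams, so call order does not affect determinism.

## Study sizes and tolerances in the checks

The end-to-end checks (`prsport.checks`, exercised by the test suite and
`scripts/acceptance.py`) use desk-scale study sizes chosen so every
contract is sharply testable: 100 random instances up to 50×200 for the
loop-oracle equivalence (tolerance 1e-12); n = 1000 for quintile occupancy
(exact 200 ± 1 by the interpolation estimator); five populations ×
2000 samples × 5000 SNPs for moment recovery (4 SEs; the variance SE uses
the normal approximation var·√(2/(n−1)), justified by the CLT for a sum of
thousands of independent terms); F = 0.2, 2000 SNPs, 100 + 100 samples for
PCA separation; 200 null replicates for the PRS–PC1 rejection rate; 100
replicates at n = 5000 for OR CI coverage, with OR = 1.76 per scaled unit
as the truth setting.

Two scenarios compare populations whose frequencies are **independent**
Balding–Nichols draws, which adds a realization variance
Σ4wᵢ²(F_a+F_b)pᵢ(1−pᵢ) to any between-population mean contrast on top of
binomial sampling noise. The shift-recovery and null-uniformity checks
therefore (a) use tiny F (5·10⁻⁴) so this term stays subdominant, and
(b) test against the **combined** SE — for quintile-transfer cells,
√(0.2·0.8/n + (φ(0.84)·s)²) with s the BN mean-offset SD on the scaled
axis, φ(0.84) ≈ 0.28 being the steepest standard-normal density at a
quintile boundary. Tolerances are 4 combined SEs throughout, matching the
convention used for the moment checks.

## Known limitations

* ID-only SNP matching: records absent under both primary ID and alias are
  lost even if present at the same position under another name.
* The quantile estimator, CI method and boundary convention are fixed
  choices among several defensible ones; thresholds from other
  environments may differ in the last interpolated digit.
* The logistic OR is per pooled-SD unit; per-quintile-contrast ORs are not
  computed.
* No absolute-risk calibration, no ancestry deconvolution for admixed
  samples — the package quantifies the portability problem; population-
  specific re-calibration of thresholds is the user's modelling decision.
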