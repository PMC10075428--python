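# Methods

This note documents the statistical model behind each stage, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical and design choices that were genuinely
open.

## Genotype model and QC cascade

Genotypes are biallelic SNP dosages in {0, 1, 2} (copies of a recorded
counted allele) with an explicit missing code. Readers are lossless: the
counted allele is whatever the file declares (PLINK A1, VCF ALT);
orientation to the minor allele happens once, at the end of QC, after
all sample removals (orienting earlier would make the cascade
non-idempotent, because removing samples can push a frequency across
0.5). Ties at frequency 0.5 keep the original orientation.

The cascade runs in a fixed order — SNP missingness, sample
missingness, sex mismatches, MAF, HWE, heterozygosity outliers,
relatedness, ancestry outliers — and recomputes MAF and HWE on the
sample set current at their step, so totals are order-dependent by
design and every step's removals are reported. Non-autosomal variants
are dropped right after the sex check: they are needed for it, but
hemizygous male X genotypes would corrupt every autosomal statistic
downstream; the drop is its own line in the report so that
`initial − Σ removed = final` always reconciles per axis.

Defaults (all configurable via `QCConfig`):

| parameter | default | rationale |
|---|---|---|
| max SNP / sample missingness | 0.20 | strictly-greater removal |
| min MAF | 0.05 | common-variant analysis |
| HWE alpha | 1e-6 | exact test, not mid-p |
| heterozygosity outlier | ±3 SD | two-sided on the autosomal het rate |
| PI_HAT threshold | 0.185 | halfway between 2nd/3rd-degree expectations |
| MDS components kept | 10 | covariate pool; 4 enter the logistic model |
| ancestry outlier | mean + 3 SD | see below |

**Sex check.** Per sample, over non-missing X SNPs:
`F = (obs_hom − exp_hom) / (n − exp_hom)` with `exp_hom = Σ (1 − 2p(1−p))`.
Recorded females with F > 0.8 and recorded males with F < 0.2 are
mismatches; all-missing X yields an "undetermined" flag. F separates
cleanly only with a few hundred X markers — at 60 X SNPs the female F
has an SD near 0.2 and the thresholds misclassify; the synthetic QC
fixture therefore carries 400 X SNPs.

**HWE exact test.** Two-sided exact test conditioning on allele counts,
summing the probabilities of all heterozygote counts no more probable
than the observed one; implemented with the numerically stable
mode-anchored recurrence. The test suite checks it against an
independent log-gamma enumeration for every genotype triple with
n ≤ 100 (|Δp| < 1e-12).

**Relatedness.** Method-of-moments IBD from per-pair IBS state counts
and pooled allele frequencies (the classic `--genome` estimator):
P(IBD=0) from the observed opposite-homozygote count, P(IBD=1) and
P(IBD=2) by successive subtraction, each clamped to [0, 1];
PI_HAT = P(IBD=1)/2 + P(IBD=2). The finite-sample bias-correction
factors of the original estimator are omitted; at the marker counts used
here the estimator is within ±0.05 of truth for unrelated pairs and
±0.1 for parent–offspring, which is what the tests assert. PI_HAT needs
on the order of a thousand markers: its sampling SD at a few hundred
LD-correlated SNPs is large enough to flag several percent of unrelated
pairs at 0.185. In each flagged pair the higher-missingness member is
removed.

**MDS and ancestry outliers.** Classical principal-coordinates
embedding of the distance 1 − mean-IBS-similarity, computed
pairwise-complete; components ordered by eigenvalue, zero-padded with a
warning past the positive spectrum. Outliers are samples whose distance
from the centroid of the first two components exceeds the mean distance
plus `sd_mult` SDs. The mean offset matters: centroid distances are
non-negative with a Rayleigh-like null shape, so a bare multiple of the
SD would flag roughly 15 % of a perfectly homogeneous cohort, while
mean + 3 SD flags well under 5 %.

## SNP association

The allelic chi-squared test is the 1-df Pearson statistic on the 2×2
allele-count table with no continuity correction; each sample
contributes two alleles, missing genotypes drop the sample for that SNP
only. Logistic regression is fit by damped Newton/IRLS (gradient
tolerance 1e-8, max 100 iterations); separation or non-convergence
flags the SNP and leaves its p missing rather than reporting an
untrustworthy Wald p. The suite cross-checks the IRLS fits against an
independent general-purpose GLM to |Δβ| < 1e-6.

## Gene-based test

The gene statistic sums the per-SNP 1-df chi-squared statistics of all
SNPs mapped to the gene (UTR-inclusive boundaries; mapping window
default 0 bp, configurable). The null draws `z ~ MVN(0, R)` — R the
Pearson correlation of dosages, estimated from the analyzed cohort
itself — and uses `Σ z²`. Indefinite R (possible under
pairwise-complete missingness) is repaired by eigenvalue clipping at
1e-8 followed by re-normalization to a unit diagonal; PSD matrices are
left untouched, so duplicated SNPs keep r = 1 exactly.

The empirical p-value is `(1 + #{null ≥ observed}) / (1 + n_sims)`:
never zero, slightly conservative at small simulation counts. Batches
escalate tenfold from 1,000 up to a configurable maximum (default
100,000 in the pipeline, 1,000,000 where small p-values matter) while
fewer than 10 exceedances support the estimate. Each gene draws from a
child seed keyed to the gene id (CRC32 spawn key), so results are
reproducible and independent of gene order or parallel scheduling.

Analytic limits anchor the tests: one SNP reduces to the SNP p;
identity LD matches the k-df chi-squared survival function; perfect LD
collapses to 1 df — each within 3 Monte-Carlo SEs at 1e5 draws. Under a
simulated global null the type-I error at α = 0.05 averages ≈ 0.047
across seeds (2,000 genes per study); note all genes in one study share
a single phenotype draw, so across-study variation exceeds the binomial
SD.

## Differential expression

The DE stage is intentionally minimal: median-of-ratios size factors
(linear-scale median of count / gene geometric mean over genes positive
everywhere), then per gene a negative-binomial log-linear model with
per-cell-line intercepts plus a post-treatment indicator, size factors
as a log offset, and a Wald test on the treatment coefficient.

Dispersion is a per-gene method-of-moments estimate on the Pearson
residuals of a first-pass Poisson fit of the same design — estimating
it conditional on the fitted means keeps the treatment and line
structure out of the dispersion, which a raw across-sample variance
would absorb (halving power at planted effects). Because that estimate
rests on very few residual degrees of freedom (5 at six pairs), the
Wald statistic carries a Pearson scale factor from the NB fit and is
referred to a t distribution with the residual df: with a plain normal
reference the null type-I error at six pairs is ≈ 0.16–0.19; with this
correction it is ≈ 0.057 at dispersion 0.1 (measured over 2,000 null
genes). There is no empirical-Bayes dispersion shrinkage, LFC
shrinkage, outlier or independent filtering — users with a full DESeq2
analysis can ingest its table via `ingest_de_table`, which recomputes
BH internally for consistency.

Power at the generator's default dispersion (0.05) and six pairs:
98 % of genes planted at |log2FC| = 2 are BH-significant with the
correct sign; at dispersion 0.1 the same design reaches 76 %.

## Evidence fusion

Raw (not BH-adjusted) p-values from both streams enter the combination;
combining adjusted p-values would double-correct. Expression p-values
are first rescaled to the range of the association p-values so that one
experiment's much larger dynamic range cannot dominate the fused
statistic. The default is a rank-preserving linear map on the p scale
onto [min, max] of the target; `log10` (the same map on the −log10
scale) and `quantile` strategies are available. The min–max map
compresses p-values far below the target minimum toward that minimum —
an intended flattening, since the association p floor is set by the
Monte-Carlo resolution.

Both p-values convert one-sided, `Z = Φ⁻¹(1 − p)`, and
`Z_s = (Z_exp + Z_assoc)/√2`, which is standard normal under the joint
null (dividing by 2 instead of √2 would not be). DE direction and risk
direction are deliberately not aligned — the fusion is evidence-based,
not sign-based. Only genes with finite p in both streams are combined;
the rest are flagged `in_both_datasets = False`, so a gene absent from
the expression data can never be combined-significant, by construction.
Bonferroni runs over the genes actually combined. Boundary p-values are
clamped to [1e-300, 1 − 1e-16] with a warning.

## ORA and PRS

ORA is the upper-tail hypergeometric test (equivalently one-sided
Fisher), per gene set, after intersecting each set with an explicit
universe (default: the genes entering the combined test); sets with
fewer than two members in the universe are skipped; BH across tested
sets. No pathway database ships with the package — content drifts by
release and the universe choice dominates the answer, so both are
explicit inputs.

PRS loci are SNPs with logistic p below 0.05 located inside
Bonferroni-significant combined genes. Weights are |ln OR|; protective
loci (OR < 1) are flipped so the counted allele is always the risk
allele. The score is the weighted risk-allele count divided by the
per-sample count of non-missing selected loci, keeping scores
comparable across missingness patterns. Cases and controls are compared
by two-sided Wilcoxon rank-sum (normal approximation with tie
correction), with Welch's t as a secondary check.

One caveat is structural and documented rather than hidden: weights are
estimated on the same cohort that is scored (no external cohort
exists in this workflow), so the case/control separation is
optimistically inflated — under a pure null the selected-locus PRS
still rejects more often than α, and the test suite asserts exactly
that. The PRS quantifies in-sample separation, not out-of-sample
prediction.

## Synthetic data

The generator emulates the study design end to end: LD-blocked
biallelic SNPs (thresholded AR(1) latent Gaussian haplotypes, adjacent
correlation 0.6), MAF drawn uniformly per SNP, gene regions tiling the
SNP coordinates with UTR-like margins, an X chromosome with hemizygous
males, a logistic disease model on planted causal SNPs with the
intercept solved numerically for the target prevalence, and paired
pre/post NB counts with per-line baselines, library-size factors and
planted log2 fold changes. Planted DE genes include the causal genes —
the assumption the fusion exploits. A violation planter injects exact,
disjoint QC failures (high-missingness SNPs, sex-label flips, low-MAF
SNPs, universal-heterozygote HWE violators, duplicated samples,
all-heterozygous samples, frequency-flipped ancestry outliers) and
records them, so QC reports can be checked count-for-count and
item-for-item. Everything is deterministic per seed, through
`numpy.random.Generator` streams spawned per stage.

Two stock configurations: the demo scale mirrors the rare-disease
setting (87 samples, prevalence 12/87, 1,500 autosomal SNPs in 100
genes, 6 cell lines); the powered scale (800 samples, prevalence 0.25,
15 causal genes × 2 causal SNPs at β = 0.8, 10 extra DE genes at
log2FC = 1.5) is sized so each evidence stream is individually
moderately powered and planted-truth recovery is a meaningful yardstick.
The initial powered design (25 causal genes × 3 SNPs at β = 0.7) was
revised during development: its latent logistic predictor had an SD
near 4.5, and the resulting non-collapsibility attenuated marginal
per-SNP odds ratios enough to destabilize gene-level power.

What the generator does **not** emulate: realistic human LD maps or
demographic structure (the ancestry outliers are frequency-flips, not
populations with drift histories), genotyping error, batch effects in
expression, gene-length or GC biases, or any correlation between a
gene's expression response and its variant content beyond the planted
overlap. Passing tests therefore demonstrate the statistical machinery
under its stated assumptions — not robustness to the full messiness of
real cohorts.

## Problem sizes used by the test suite

Simulation sizes were chosen as the smallest that make each assertion
statistically meaningful: 2,000 genes for null-calibration checks
(binomial 95 % band ±0.96 % around α = 0.05), 1e5 draws for Monte-Carlo
vs analytic comparisons (3 MC SEs), 300–400 samples for power-ordering
and PRS-replication studies, 100 seeded replicates for the PRS
separation rate, and the full powered configuration for end-to-end
recovery. The acceptance script runs the same computations from scratch
under a caller-supplied seed.

## Known limitations

- LD for the gene test comes from the analyzed cohort, not a reference
  panel; at very small n the correlation estimates are noisy and the
  gene test inherits that noise.
- The DE stage's t-referenced Wald test is calibrated but conservative
  relative to shrinkage-based pipelines at equal sample size; its p
  floor at six pairs is set by the fat t(5) tail.
- The min–max rescaling is scale-sensitive at the extremes: a single
  extreme association p-value stretches the target range for every
  gene. The quantile strategy is the robust alternative.
- Relatedness and ancestry steps assume a largely homogeneous cohort;
  strong structure inflates PI_HAT between subpopulation members and
  can cascade removals.
- PRS results are in-sample by construction (above).
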