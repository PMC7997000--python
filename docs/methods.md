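# Methods

This note documents the statistical models, the synthetic data they are
exercised on, and the numerical and design choices that were genuinely
open.

## Age-associated TF detection

Per-gene OLS of expression on age, sex, three genotype-derived principal
components and latent expression (PEER-style) factors.  Latent factors
whose Pearson correlation with age has p ≤ 0.05 are removed *before*
fitting: a latent factor aligned with age would otherwise absorb the age
coefficient.  Constant factors are retained (they carry no age signal)
with a warning.  The age test is the two-sided t-test on the age
coefficient; Benjamini–Hochberg control is applied across the TF panel
only, at FDR ≤ 0.1, because the hypothesis family of interest is the TF
panel, not the transcriptome.

**Adjusted TF expression** is the age component plus residual,
`β_age·AGE + ε`.  The intercept is deliberately excluded; every
downstream use (correlations, interaction products with a dosage that
also enters as a main effect) is invariant to constant offsets, and
dropping the intercept makes the decomposition exactly additive:
adjusted + (fitted non-age components) = observed expression.

Rank-deficient design columns (duplicated or constant covariates) are
dropped greedily keeping the first occurrence, with a warning, rather
than failing — degenerate covariate tables are common in practice.
Dropping the age column itself is an error.

## Allele-specific binding

Sequence windows are ±50 bp (101 bp total, SNP centered).  Scoring is
additive log₂-odds against a uniform 0.25 background, with a 0.01
pseudocount per matrix cell (renormalized) so zero-probability cells
stay finite.  Both strands are scanned; binding is strand-agnostic.
Positions overlapping `N` are unscoreable (−∞), a conservative choice.

The hit threshold is per-motif: the smallest score whose tail
probability under an i.i.d. uniform background is ≤ 1e-4, computed
*exactly* by dynamic-programming convolution of the per-position score
distribution discretized at 1e-3 bits.  This makes the cutoff
deterministic and motif-length aware.  An ASB call requires at least one
hit whose window covers the SNP position on exactly one allele;
both-or-neither yields no call.  Calls are then filtered to SNPs inside
open-chromatin intervals (0-based half-open; a SNP at 1-based position p
occupies [p−1, p)).

## Interaction detection

Candidates are (ASB call × gene) pairs with |SNP − TSS| ≤ 1 Mbp on the
same chromosome (closed bound; the TSS is the promoter proxy).  The
nested models share all covariates (age, sex, SNP PCs, retained latent
factors); the alternative adds the dosage × adjusted-TF product.  Dosage
counts the *binding* allele, so the interaction coefficient's sign is
mechanistically interpretable; the LLR is invariant to allele recoding.
The Gaussian profile log-likelihood at the OLS solution gives
LLR = n·log(RSS₀/RSS₁), referred to χ²(1).  Age appears both as a
covariate and inside the adjusted TF term; the resulting collinearity is
benign for the LLR (both models share it) and the rank-screening path
drops exactly collinear columns deterministically.

Per-triplet eligibility: ≥ 30 samples after dropping missing genotypes
(dropped per-triplet, not imputed), ≥ 2 distinct dosage values, full-rank
alternative design; ineligible triplets are recorded with a reason code.
BH is applied across all tested triplets of a run at FDR ≤ 0.05
(configurable).

The **consistency filter** stratifies samples into non-binding
homozygotes (0 binding alleles), heterozygotes (1) and binding
homozygotes (2), each requiring ≥ 10 samples, and computes Spearman
correlations of adjusted TF vs target expression.  Pass requires
p ≤ 0.05 in het and binding-homozygote groups, p > 0.05 in the
non-binding group, |r_homB| > |r_het| with matching sign.  Note this
filter has an intrinsic false-negative floor: even for a true
interaction the non-binding group's correlation is null, so ~5% of true
triplets fail its p > α requirement per run.  Recovery of planted truth
can therefore approach but not reach 100%.

**Controls.** The permutation background applies *one* permutation of
sample labels to the whole expression matrix: gene–gene covariance is
preserved exactly while all genotype and covariate relationships are
destroyed.  Replication re-runs age-TF detection and triplet testing on
sampled-without-replacement subsets (70/80/90%) and reports the fraction
of full-data detections re-detected; rates are undefined (NA) when the
full run detects nothing.

## Validation statistics

All comparisons are one-sided Wilcoxon rank-sum tests (exact for small
tie-free samples, normal approximation with tie/continuity corrections
otherwise — scipy's automatic policy).  Window scores are means of
per-base signal over 200-bp windows centered on the SNP, uncovered bases
contributing 0.  The allelic-imbalance score is
|log2((n₁+1e-6)/(n₂+1e-6))| over heterozygous sites with depth ≥ 10,
compared against per-site Binomial(depth, 0.5) draws; the score is
computed as a difference of logs so it is exactly symmetric in floating
point.  Chromatin-link support counts links with one anchor on the SNP
and the other on the gene's promoter window (TSS ± 2 kb — an explicit
choice; no window is standard).  Distance-matched backgrounds sample,
per foreground pair, one candidate within ±10% of its distance, without
replacement, in a seeded random order to avoid positional bias;
foreground pairs with no match are dropped from both sides, and > 50%
unmatched is an error.  Distances to the nearest phenotype SNP use
per-chromosome binary search; chromosomes without reference SNPs yield
+∞, excluded from rank tests.  Derived allele frequency is the alt
frequency when the ancestral allele equals ref, 1 − alt frequency when
it equals alt, excluded otherwise.

## Phenotype association

Detected interactions are aggregated into three standardized feature
blocks (adjusted TF expression, binding-allele dosage, their products
per detected pair), each reduced by PCA to ≤ k components (default 30,
truncated to rank, deterministic sign convention).  PCA is applied per
block so the null/alternative nesting is well-defined.  Nested logistic
models (null: confounders + TF + SNP components; alternative: +
interaction components) are compared by LLR with df = interaction
components actually used.  Non-convergent fits are ridge-stabilized
(penalty 1e-6) and flagged; the log-likelihood is always evaluated
directly at the fitted coefficients so both paths are comparable.

*Limitation:* the χ²(df) reference assumes total parameters ≪ n.  At
n = 400 we measured ~5% null rejection with ~25 parameters but ~12% with
~45; with k = 30 per block and small cohorts the test is
anticonservative.  Calibration simulations therefore use modest block
sizes; real analyses with many detected features should keep k well
below n/10 per block.

## Synthetic cohorts

The generator emulates the assumed mechanism end to end.  Ages are
uniform on 20–70 years (optionally decadal-bin midpoints), sex is
Bernoulli(0.5), genotypes are Hardy–Weinberg draws at MAF ∈ (0.25, 0.5)
with 1% missingness.  Age-associated TFs carry a slope of 0.05 log-units
per year (≈ 5% per decade, a realistic transcriptomic scale; with noise
sd 1 and n = 400 this is still a very strong signal, t ≈ 14) plus small
sex/PC/latent-factor loadings.  Planted target genes follow
`α + β_snp·d + β_int·d·TF~ + small covariate terms + noise` with
β_int = 1, noise sd 0.5 in the "strong" preset — crucially with **no TF
main effect**, so the TF–gene correlation appears only in carriers of
the binding allele, which is exactly what the consistency filter
requires.  The latent factors in the covariate table include two
age-correlated columns to exercise the factor filter, but expression
loads only on the uncorrelated ones; otherwise null TFs would be truly
age-associated through the factor and planted-truth bookkeeping would
break.

At the sequence level, each planted TF gets a random 9-mer consensus
matrix (0.94 on consensus bases); the consensus is written into the
genome around the SNP with the center base set to the *reference*
allele's mismatch, so the alternative allele reconstructs the consensus
exactly.  At the 1e-4 threshold only the perfect match scores high
enough (the ≥8-of-9 match tail already exceeds 1e-4 under the uniform
background), so binding is allele-specific by construction.  Decoy SNPs
carry either single-allele motifs with no expression effect (false-
positive probes) or degenerate-center motifs matching both alleles
(exactly-one-allele rule probes).  Open-chromatin peaks cover all
planted SNPs and 90% of decoys; the signal track is elevated near
planted SNPs; chromatin links bridge 60% of planted SNP–gene pairs plus
random noise links.  The binary phenotype is logistic in age, sex and
the standardized mean of the planted interaction features (effect 0.8).

Regenerating a bundle from the same configuration is byte-identical;
all floats are written with 17 significant digits and re-read with the
round-trip parser.

What the fixtures do **not** emulate: linkage disequilibrium, realistic
expression distributions (library-size effects, zero inflation),
population structure beyond i.i.d. PCs, trans effects, multi-SNP
architecture, or tissue sharing.  Passing tests demonstrate the
statistical machinery is correct and calibrated under the assumed
generative model, not that real-data detections at these rates are
expected.

## Problem sizes

Default test and reproduction runs use 400-sample cohorts, a 40-TF
panel, 55 SNPs and 60 genes (~3,000 candidate triplets), 1,000–2,000
replicate fits for calibration checks and 5–10 repetitions for
permutation/down-sampling summaries; these sizes make every property
measurable with comfortable statistical margins while keeping a full
run in the order of a minute.
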