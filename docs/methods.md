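# Methods

## DQ heterodimer model

A chromosome's DQ haplotype class is a total function of its two-field
(DQA1, DQB1) pair: exact match against DQ2.5 (05:01/02:01), DQ2.2
(02:01/02:02), DQ8.1 (03:01/03:02) or DQ7.5 (05:05/03:01), else OTHER
("X").  Alleles typed at higher resolution are truncated to two fields with
a warning; all downstream logic is two-field.  A genotype (unordered pair
of classes) is a *cis* DQ2.5 carrier iff either chromosome is DQ2.5 and a
*trans* carrier iff the pair is exactly {DQ2.2, DQ7.5} — the DQ7.5
chromosome supplies a DQA1\*05 α chain and the DQ2.2 chromosome a DQB1\*02
β chain, assembling the DQ2.5 heterodimer across chromosomes.

The four-level risk category is a lookup over the 15 unordered class
pairs.  Published sources fix the anchor points — DQ2.5/DQ2.5 and
DQ2.5/DQ2.2 highest, DQ7.5/X the low-risk reference, X/X no risk — but not
the full table, so the default map is a package decision:

- high: DQ2.5/DQ2.5, DQ2.5/DQ2.2
- moderate: DQ2.5/DQ7.5, DQ2.5/DQ8.1, DQ2.5/X, DQ2.2/DQ7.5 (the *trans*
  genotype), DQ2.2/DQ2.2, DQ8.1/DQ8.1
- low: DQ2.2/X, DQ2.2/DQ8.1, DQ8.1/DQ7.5, DQ8.1/X, DQ7.5/DQ7.5, DQ7.5/X
- none: X/X

The map is an argument everywhere it is consumed, so any published scheme
can be substituted; whether DQ2.2/DQ2.2 belongs in moderate or low is
genuinely open and the default keeps it moderate (β-chain dose).

rs2187668 is the only tagSNP modeled: carrier ⟺ dosage ≥ 1.  Other
tagSNPs are known to be unreliable for DQ2.2 and are out of scope.

## Haplotype-frequency estimation

`HaplotypeFrequencyEstimator` is the standard EM for multi-locus haplotype
frequencies under Hardy–Weinberg: the E-step distributes each
phase-ambiguous genotype over its compatible haplotype pairs in proportion
to current frequency products (2·f_i·f_j for heterozygous pairs, f_i² for
homozygous), the M-step renormalizes expected counts over 2N chromosomes.
The log-likelihood is non-decreasing and *asserted* at every iteration.

Numerical contract: convergence when the maximum absolute frequency change
drops below `tol` (default 1e-6), `max_iter` 1000; haplotypes below 1e-10
expected frequency are pruned between iterations to bound the state space;
at most 7 loci (explicit error beyond — no partition-ligation).
Initialization is the product of observed allele frequencies, not uniform:
a single double-heterozygote shows the uniform start is a symmetric fixed
point (¼,¼,¼,¼) that allele-frequency initialization cannot improve either,
but on real mixtures the uniform start can stall on saddle points;
`n_restarts` adds Dirichlet-perturbed seeded restarts and keeps the best
log-likelihood.  The EM conserves per-locus allele counts at every step, so
the fitted margins always equal observed allele frequencies — this is also
what the two-locus test oracle exploits (1-D search over D).

Phased input (the simulator's output, or imputed haplotypes treated as
phased) takes a direct-counting fast path; the result records which method
produced it.  Whether published linkage percentages were computed on phased
haplotypes or by frequency estimation is not stated, so both paths exist
and agree on synthetic data to sampling error.

Conditional linkage is Σf(h ∋ target ∧ given)/Σf(h ∋ given).  Interval
estimates are provided only as a seeded participant-level bootstrap; no
attempt is made to reproduce any specific published interval-estimation
method, which is undocumented.  LD metrics use the textbook definitions
D = f(AB) − p_A·p_B, D′ = D/D_max, r² = D²/(p_A(1−p_A)p_B(1−p_B)).

## Cohort assembly

Seropositive ⟺ reported positive, or max recorded tTG-IgA/DGP-IgA/DGP-IgG
≥ 20 IU/mL (the maximum, not the latest: antibody levels fall on a
gluten-free diet).  Cases must have an EHR or survey CeD record *and*
carry at least one of the four risk haplotypes; controls are non-CeD
participants free of CeD-associated comorbidities (autoimmune thyroid
disease, T1D, IgA deficiency, IBD, HIV, CVID, cancer, Down, DiGeorge).

Propensity matching fits an additive logistic case-vs-pool model and
matches greedily — cases in seeded random order, each taking its nearest
available controls by |Δlogit| without replacement, up to `ratio`
(default 5).  Caliper default 0.2 × SD of the logit (the common
convention; no published value exists for this analysis).  Cases with
fewer in-caliper controls keep what they find and are listed in a warning;
the matched set depends on the seed, which is documented behavior — the
original matched set is not reproducible.  Ancestry enters as an
exact-match stratum by default, mirroring an ancestry-matched design;
alternatively set `stratify=None` and put principal components in the
covariates.  Balance is reported as absolute standardized mean differences
before/after.

## Association statistics

Allele tests count chromosomes (2 per participant); genotype and carrier
tests count participants — the convention implied by published chromosome
denominators.  OR = ad/bc with Wald 95% CI on the log scale; the
Haldane–Anscombe +0.5 is applied to all four cells only when some cell is
zero (small African strata hit zeros) and is flagged in the result.
Display rounding follows the source convention: one decimal, two when the
leading digit is 1 and the OR < 10.  Chi-squared is Pearson with 1 df, no
continuity correction by default.  BH-FDR is the statsmodels step-up
implementation.  Serology-by-risk-group comparisons: one-way ANOVA, then
Tukey HSD for pairwise differences with family-wise 95% CIs; per-group
mean CIs use the pooled ANOVA error (mean ± t·√(MSE/n_g)), the standard
"group mean and 95% CI" display.  A covariate-adjusted logistic
association (age/sex) is provided as a supplement to, not a replacement
for, the table-based ORs.

## Risk scoring

PRS = HLA-genotype weight + Σ weight × effect-allele dosage.  The real
38-SNP panel's weights are not redistributable, so the weight table is an
input file; the test suite and acceptance script use synthetic panels.
Published score landmarks tied to the real weights (median score, the
90%-sensitivity threshold value 4.17, real-data AUCs) are therefore not
asserted anywhere — the scoring machinery is validated by construction
(additivity, oracle AUC equality, coefficient recovery) instead.  Missing
dosages impute as 0 with a warning and count.

The composite score is the linear predictor of a logistic regression on
PRS, family history, diarrhea, vitamin D deficiency, anemia,
hypothyroidism and a high/moderate-HLA indicator, fitted by Newton/IRLS
(convergence 1e-8 on coefficients, 100 iterations).  Separation or
collinearity raises an error that names the remedy; the fallback is ridge
(λ = 1e-4 on standardized features, mapped back to the raw scale).
Whether any inputs should be log-transformed before weighting is ambiguous
in the source description; the implementation scores on the linear
predictor scale with binary flags as 0/1.

Classification is score ≥ threshold.  `max_accuracy` ties break toward
higher specificity, and the returned threshold is the midpoint of the
indifference gap below the optimal cutpoint (so perfect separation yields
the gap midpoint); `sensitivity_90` returns the largest threshold keeping
sensitivity ≥ 0.90 (an observed score value).  AUC is the tie-corrected
midrank (Mann–Whitney) statistic; Platt calibration is a 1-D logistic fit
of labels on scores (constant scores calibrate to the prevalence); Brier
is the mean squared error of calibrated probabilities.

## Synthetic cohorts: what they emulate, and what they do not

Each ancestry stratum (EUR, AMR, AFR, OTHER) has an eight-haplotype pool
over A~B~C~DQA1~DQB1~DRB1 built analytically: the DQ2.5 mass is split
between the AH8.1 backbone (f_DQ2.5 × P(B8|DQ2.5)) and a non-B8 DQ2.5
backbone, so the configured marginal and conditional hold exactly, to
1e-9, before any sampling.  Defaults: f(DQ2.5) = 0.116 EUR / 0.081 AMR /
0.072 AFR; P(B8|DQ2.5) = 0.742 EUR / 0.421 AMR.  The AFR conditional
default 0.15 is a placeholder inside a published estimate range
(roughly 0.10–0.27), not a measured value.  DQ2.2/DQ8.1/DQ7.5 frequencies
(EUR 0.06/0.10/0.14, AMR 0.05/0.15/0.12, AFR 0.08/0.05/0.12) are typical
of published HLA surveys; residual mass collapses to three labeled
non-risk backbones whose internal composition affects no downstream
statistic.

Participants draw two haplotypes i.i.d. within their stratum
(Hardy–Weinberg; no admixture between strata, matching the stratified
analysis).  Disease status is logistic:
logit P(case) = logit(0.012) + log(3.6)·(DQB1\*02:01 copies) + category and
SNP increments (default 0) + clinical-covariate increments (family history
1.0, diarrhea 0.5, vitamin D deficiency 0.4, anemia 0.4, hypothyroidism
0.3 on the log-odds scale).  Under this rare-disease multiplicative model
the case/control allele OR equals the per-copy OR to first order, which is
what the recovery checks measure.  Serology is log-normal per risk
category and case status (case medians 60/35/8/4 IU/mL for
high/moderate/low/none, σ = 1.0; controls median 3 IU/mL, σ = 0.8; DGP
markers shifted down 0.3 log units); only the ordering
high > moderate > low is asserted — no distributional claim is made, since
none is published.  The tagSNP dosage equals the DQ2.5 count except for a
per-ancestry carrier-flip discordance rate (default 0; 0.373 emulates the
reported admixed-American concordance of 62.7%).

All randomness flows from one integer seed through
`numpy.random.SeedSequence` spawning; identical seed and configuration
give byte-identical cohort tables.

What passing tests on these cohorts do **not** show: real HLA imputation
error structure (only a flat tagSNP flip rate is modeled), EHR phenotype
noise, genotype-correlated ascertainment, admixture within individuals,
age/sex confounding of genotype (covariates are independent of genotype by
construction, which is precisely what makes the recovery checks sharp),
or real LD between the non-HLA PRS SNPs and HLA.  Quantities that depend
on the real cohort — real-data AUCs, the published median PRS and score
thresholds, exact matched sets and cohort counts — cannot be reproduced
here and are deliberately replaced by property-based checks.

## Problem sizes

Parameter-recovery checks run at n = 10,000–20,000 participants per
stratum; the OR-coverage check uses 50 replicates of n = 20,000; the
EM-vs-oracle equivalence uses ≤ 3 loci and ≤ 8 distinct genotypes, where
exhaustive likelihood maximization is dependable.  These sizes put
sampling error well inside the asserted tolerances (e.g. binomial SE on
f(DQ2.5) at 40,000 chromosomes ≈ 0.0016 against a ±0.01 band) while
keeping the full suite fast.
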