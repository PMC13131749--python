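# dqrisk

Ancestry-aware HLA-DQ risk analysis for celiac disease (CeD) cohorts.

Celiac disease is an autoimmune enteropathy triggered by gluten, and its
genetic risk is dominated by which HLA-DQ heterodimers a person can form.
The DQα and DQβ chains are encoded by the adjacent *DQA1* and *DQB1* genes;
the four CeD-compatible heterodimers and their *cis* haplotypes are
DQ2.5 (DQA1\*05:01–DQB1\*02:01), DQ2.2 (DQA1\*02:01–DQB1\*02:02),
DQ8.1 (DQA1\*03:01–DQB1\*03:02) and DQ7.5 (DQA1\*05:05–DQB1\*03:01).
DQ2.5 can also be assembled in *trans* by a DQ2.2/DQ7.5 genotype.  In
Europeans, DQ2.5 usually rides on the conserved ancestral haplotype 8.1
(A\*01:01–B\*08:01–C\*07:01–DRB1\*03:01, "AH8.1"), but the strength of the
B8–DQ2.5 linkage differs sharply between ancestries — a pattern that may
help explain ancestry-dependent differences in CeD risk and serology.

`dqrisk` implements the analysis stack this question requires, for tabular
(TSV) cohorts of HLA allele calls:

- **Heterodimer calling** — parse two-field HLA nomenclature, classify DQ
  haplotypes, call *cis*/*trans* DQ2.5 carriage, and assign a four-level
  (high/moderate/low/none) risk category (configurable map).
- **Haplotype inference** — EM estimation of multi-locus haplotype
  frequencies from unphased genotypes (direct counting for phased input),
  conditional linkage P(B | chromosome carries A) such as P(B8 | DQ2.5),
  and pairwise LD metrics (D, D′, r²).
- **Cohort assembly** — seropositivity (any of tTG-IgA / DGP-IgA / DGP-IgG
  ≥ 20 IU/mL or a reported positive), case/control inclusion rules, and
  5:1 greedy propensity matching on age, sex and ancestry with balance
  diagnostics.
- **Association statistics** — chromosome-level allele tables and
  participant-level genotype tables, odds ratios with Wald CIs
  (Haldane–Anscombe correction at zero cells), chi-squared tests,
  Benjamini–Hochberg FDR, and ANOVA + Tukey HSD for serology by risk group.
- **Risk scoring** — log-additive PRS (HLA-genotype weight + SNP dosages ×
  weights), a composite clinical score fitted by logistic regression
  (IRLS, ridge fallback), ROC/AUC, threshold selection (max-accuracy or
  90%-sensitivity), Platt calibration and Brier score.
- **Synthetic cohorts** — an analytic ancestry-pool builder and
  Hardy–Weinberg cohort simulator that reproduce configured DQ2.5
  frequencies, B8–DQ2.5 linkage, a logistic disease model, serology and
  clinical covariates, so the whole pipeline is testable without
  access-controlled biobank data.

## Worked example

```python
from dqrisk import (build_default_pools, sample_cohort, call_dq_frame,
                    em_haplotype_frequencies, conditional_linkage,
                    allele_table, odds_ratio)

pools = [p for p in build_default_pools() if p.ancestry_label == "EUR"]
cohort = sample_cohort(pools, n_per_ancestry=20_000, seed=1)
ann = call_dq_frame(cohort)
print(ann["risk_category"].value_counts().to_dict())

table = em_haplotype_frequencies(cohort, ("B", "DQA1", "DQB1"))
dq25 = ("DQA1*05:01", "DQB1*02:01")
f = sum(v for h, v in table.frequencies.items() if dq25[0] in h and dq25[1] in h)
print(f"f(DQ2.5) = {f:.3f}")
print(f"P(B8 | DQ2.5) = {conditional_linkage(table, 'B*08:01', dq25):.3f}")

res = odds_ratio(allele_table(cohort, "DQB1*02:01"))
print(f"DQB1*02:01 allele OR = {res.or_estimate:.2f} "
      f"(95% CI {res.ci_low:.2f}-{res.ci_high:.2f})")
```

prints

```
{'low': 8257, 'none': 6752, 'moderate': 4425, 'high': 566}
f(DQ2.5) = 0.116
P(B8 | DQ2.5) = 0.740
DQB1*02:01 allele OR = 3.60 (95% CI 3.16-4.10)
```

The simulated European stratum carries DQ2.5 at haplotype frequency 0.116
with B8 on 74% of DQ2.5 chromosomes; the EM estimator recovers both from
the unphased genotypes, and the per-allele disease effect built into the
generator (OR 3.6 for DQB1\*02:01) is recovered by the chromosome-level
case-control table with its 95% CI covering the generating value.

A command-line interface mirrors the library
(`dqrisk simulate | call-dq | estimate-haplotypes | assemble | associate |
score | roc | run-all`); `dqrisk run-all --seed 7 --out run/` executes the
whole pipeline and writes every stage table plus a JSON manifest.

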