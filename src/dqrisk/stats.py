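"""Case-control association statistics for HLA alleles and DQ genotypes.

Allele-level tests count chromosomes (two per participant); genotype- and
carrier-level tests count participants.  Odds ratios come with Wald 95%
confidence intervals on the log scale, applying the Haldane–Anscombe +0.5
correction to every cell only when some cell is zero.  Multiple testing is
controlled with Benjamini–Hochberg FDR, and serology differences across DQ
risk groups use one-way ANOVA followed by Tukey's HSD — the same toolkit the
stratified CeD analysis reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import call_dq_frame, max_serology
from .hla import RISK_CATEGORIES

__all__ = [
    "ContingencyTable2x2",
    "AssociationResult",
    "GroupComparison",
    "allele_table",
    "carrier_table",
    "odds_ratio",
    "odds_ratio_from_proportions",
    "chi_squared",
    "bh_fdr",
    "serology_by_risk",
    "genotype_frequency_table",
    "format_or",
    "logistic_association",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (case-exposed, case-unexposed, control-exposed, control-unexposed)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name, v in zip("abcd", (self.a, self.b, self.c, self.d)):
            if v < 0 or int(v) != v:
                raise ValueError(f"cell {name} must be a non-negative integer")

    @property
    def has_zero_cell(self) -> bool:
        return 0 in (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class AssociationResult:
    """An odds ratio with Wald CI and (optionally FDR-adjusted) p-value."""

    label: str
    or_estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    fdr_p: float = float("nan")
    corrected: bool = False

    def __post_init__(self) -> None:
        if not (
            math.isnan(self.ci_low)
            or self.ci_low <= self.or_estimate <= self.ci_high
        ):
            raise ValueError("CI does not contain the point estimate")


@dataclass(frozen=True)
class GroupComparison:
    """One risk group's mean with Tukey family-wise 95% CI bounds."""

    group: str
    n: int
    mean: float
    ci_low: float
    ci_high: float


def allele_table(cohort: pd.DataFrame, allele: str, locus: str | None = None) -> ContingencyTable2x2:
    """Chromosome-level 2×2 table for carrying ``allele`` by case status.

    Each participant contributes two chromosomes.  The locus is inferred
    from the allele string unless given.
    """
    if locus is None:
        locus = allele.split("*")[0]
    if len(cohort) == 0:
        return ContingencyTable2x2(0, 0, 0, 0)
    case = cohort["ced_ehr"].astype(bool) | cohort["ced_survey"].astype(bool)
    exp1 = cohort[f"{locus}_1"] == allele
    exp2 = cohort[f"{locus}_2"] == allele
    a = int((case & exp1).sum() + (case & exp2).sum())
    b = int((2 * case).sum() - a)
    c = int((~case & exp1).sum() + (~case & exp2).sum())
    d = int((2 * ~case).sum() - c)
    return ContingencyTable2x2(a, b, c, d)


def carrier_table(cohort: pd.DataFrame, carrier: pd.Series) -> ContingencyTable2x2:
    """Participant-level 2×2 table for a boolean carrier state by case status."""
    case = cohort["ced_ehr"].astype(bool) | cohort["ced_survey"].astype(bool)
    carrier = carrier.astype(bool)
    return ContingencyTable2x2(
        int((case & carrier).sum()),
        int((case & ~carrier).sum()),
        int((~case & carrier).sum()),
        int((~case & ~carrier).sum()),
    )


def odds_ratio(table: ContingencyTable2x2, label: str = "") -> AssociationResult:
    """OR = (a·d)/(b·c) with Wald 95% CI on the log scale.

    If any cell is zero the Haldane–Anscombe +0.5 correction is applied to
    all four cells (flagged in the result).  The p-value is the Wald z-test
    on log OR.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    corrected = table.has_zero_cell
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_est = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = 1.959963984540054  # Φ⁻¹(0.975)
    log_or = math.log(or_est)
    ci_low = math.exp(log_or - z * se)
    ci_high = math.exp(log_or + z * se)
    p = 2.0 * sps.norm.sf(abs(log_or) / se)
    return AssociationResult(label, or_est, ci_low, ci_high, float(p), corrected=corrected)


def odds_ratio_from_proportions(p1: float, p2: float, label: str = "") -> AssociationResult:
    """OR from two frequencies: (p1/(1−p1)) / (p2/(1−p2)); no CI available."""
    for name, p in (("p1", p1), ("p2", p2)):
        if not 0.0 < p < 1.0:
            raise ValueError(
                f"{name}={p}: use the count form for boundary proportions"
            )
    or_est = (p1 / (1 - p1)) / (p2 / (1 - p2))
    nan = float("nan")
    return AssociationResult(label, or_est, nan, nan, nan)


def chi_squared(table: ContingencyTable2x2, correction: bool = False) -> float:
    """Pearson chi-squared p-value (1 df); no continuity correction by default."""
    obs = np.array([[table.a, table.b], [table.c, table.d]], dtype=float)
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("chi-squared undefined: zero margin in the table")
    _, p, _, _ = sps.chi2_contingency(obs, correction=correction)
    return float(p)


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return [float(x) for x in adjusted]


def serology_by_risk(
    cohort: pd.DataFrame,
    marker: str,
    group_col: str = "risk_category",
) -> tuple[float, float, list[GroupComparison], pd.DataFrame]:
    """One-way ANOVA + Tukey HSD of max serology across DQ risk groups.

    Returns ``(F, p, group_means, pairwise)``: ``group_means`` carry 95% CIs
    around each group mean from the pooled ANOVA error, and ``pairwise`` is
    the Tukey HSD table (group pair, mean difference, adjusted p,
    family-wise CI).
    """
    ann = cohort if group_col in cohort.columns else call_dq_frame(cohort)
    values = ann.apply(lambda r: max_serology(r, marker), axis=1)
    frame = pd.DataFrame({"value": values, "group": ann[group_col]}).dropna()
    groups = [
        g for g in RISK_CATEGORIES if g in set(frame["group"])
    ] or sorted(frame["group"].unique())
    small = [g for g in groups if (frame["group"] == g).sum() < 2]
    if small:
        raise ValueError(f"groups with fewer than 2 observations: {small}")
    if len(groups) < 2:
        raise ValueError("need at least two groups for ANOVA")
    samples = [frame.loc[frame["group"] == g, "value"].to_numpy() for g in groups]
    if np.ptp(np.concatenate(samples)) == 0:
        f_stat, p_val = 0.0, 1.0
    else:
        f_stat, p_val = sps.f_oneway(*samples)

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    with np.errstate(invalid="ignore"):  # degenerate zero-variance groups
        tukey = pairwise_tukeyhsd(
            frame["value"].to_numpy(), frame["group"].to_numpy()
        )
    pairwise = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )

    # 95% CI on each group mean from the pooled error: mean ± t·√(MSE/n_g)
    n_total = len(frame)
    k = len(groups)
    mse = sum(
        ((s - s.mean()) ** 2).sum() for s in samples
    ) / (n_total - k)
    t_crit = sps.t.ppf(0.975, n_total - k)
    comparisons = []
    for g, s in zip(groups, samples):
        half = t_crit * math.sqrt(mse / len(s))
        comparisons.append(
            GroupComparison(g, len(s), float(s.mean()),
                            float(s.mean() - half), float(s.mean() + half))
        )
    return float(f_stat), float(p_val), comparisons, pairwise


def genotype_frequency_table(
    cohort: pd.DataFrame,
    reference: str = "DQ7.5/X",
    risk_map=None,
) -> pd.DataFrame:
    """Per-genotype case/control counts with OR vs a reference genotype.

    Participant-level counting.  Each genotype's OR contrasts its case:control
    split against the reference genotype's; p-values are BH-FDR adjusted over
    all non-reference genotypes present in both groups.
    """
    ann = cohort if "dq_genotype" in cohort.columns else call_dq_frame(
        cohort, risk_map
    )
    case = ann["ced_ehr"].astype(bool) | ann["ced_survey"].astype(bool)
    counts = (
        pd.DataFrame({"genotype": ann["dq_genotype"], "case": case})
        .groupby(["genotype", "case"]).size().unstack(fill_value=0)
        .reindex(columns=[True, False], fill_value=0)
    )
    counts.columns = ["n_case", "n_control"]
    if reference not in counts.index:
        raise ValueError(f"reference genotype {reference!r} absent from cohort")
    ref_case = int(counts.loc[reference, "n_case"])
    ref_ctrl = int(counts.loc[reference, "n_control"])
    rows = []
    for geno, row in counts.iterrows():
        n_case, n_ctrl = int(row["n_case"]), int(row["n_control"])
        if n_case == 0 and n_ctrl == 0:
            continue
        cat = ann.loc[ann["dq_genotype"] == geno, "risk_category"].iloc[0]
        if geno == reference:
            rows.append({
                "genotype": geno, "risk_category": cat,
                "n_case": n_case, "n_control": n_ctrl,
                "or": 1.0, "ci_low": np.nan, "ci_high": np.nan,
                "p": np.nan,
            })
            continue
        res = odds_ratio(
            ContingencyTable2x2(n_case, ref_case, n_ctrl, ref_ctrl), label=geno
        )
        rows.append({
            "genotype": geno, "risk_category": cat,
            "n_case": n_case, "n_control": n_ctrl,
            "or": res.or_estimate, "ci_low": res.ci_low,
            "ci_high": res.ci_high, "p": res.p_value,
        })
    out = pd.DataFrame(rows)
    mask = out["genotype"] != reference
    adjusted = pd.Series(np.nan, index=out.index)
    if mask.any():
        adjusted.loc[mask] = bh_fdr(out.loc[mask, "p"].tolist())
    out["fdr_p"] = adjusted
    return out.sort_values("or", ascending=False).reset_index(drop=True)


def format_or(or_value: float) -> str:
    """Display rounding for odds ratios: two decimals when the leading digit
    is 1 and the OR is below 10, one decimal otherwise."""
    if 1.0 <= or_value < 2.0:
        return f"{or_value:.2f}"
    return f"{or_value:.1f}"


def logistic_association(
    cohort: pd.DataFrame,
    exposure: pd.Series,
    covariates: Sequence[str] = ("age", "sex"),
) -> AssociationResult:
    """Covariate-adjusted logistic association (supplementary to table ORs).

    Fits case ~ exposure + covariates by Newton/IRLS and returns the
    exposure's OR with Wald CI.
    """
    import statsmodels.api as sm

    case = (
        cohort["ced_ehr"].astype(bool) | cohort["ced_survey"].astype(bool)
    ).astype(float)
    X = pd.get_dummies(cohort[list(covariates)], drop_first=True).astype(float)
    X.insert(0, "exposure", np.asarray(exposure, dtype=float))
    X = sm.add_constant(X)
    fit = sm.Logit(case.to_numpy(), X.to_numpy()).fit(disp=0)
    beta = fit.params[1]
    se = fit.bse[1]
    z = 1.959963984540054
    return AssociationResult(
        "exposure", math.exp(beta), math.exp(beta - z * se),
        math.exp(beta + z * se), float(fit.pvalues[1]),
    )
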