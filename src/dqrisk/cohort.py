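"""Cohort assembly: serostatus, case/control rules, propensity matching.

A cohort is a tidy participant table (one row per participant; see
``dqrisk.simulate`` for the column schema).  This module applies the study's
inclusion rules — cases must carry one of the four CeD-compatible DQ
haplotypes; controls must be free of CeD-associated comorbidities — defines
seropositivity (any antibody ≥ 20 IU/mL or a reported positive result), and
matches controls to cases 5:1 by propensity score on age, sex and ancestry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .hla import (
    DqHaplotypeClass,
    call_heterodimers_from_classes,
    classify_dq_haplotype,
    parse_allele,
)
from .simulate import SEROLOGY_MARKERS

__all__ = [
    "EXCLUSION_FLAGS",
    "MatchedCohort",
    "PropensityMatcher",
    "call_dq_frame",
    "max_serology",
    "is_seropositive",
    "select_cases",
    "eligible_controls",
    "propensity_match",
    "standardized_mean_differences",
]

#: Comorbidities that disqualify a participant from the control pool.
EXCLUSION_FLAGS = (
    "autoimmune_thyroid", "t1d", "iga_deficiency", "ibd", "hiv",
    "cvid", "cancer", "down", "digeorge",
)


def call_dq_frame(cohort: pd.DataFrame, risk_map=None) -> pd.DataFrame:
    """Annotate a cohort with per-participant DQ risk-genotype columns.

    Adds ``dq_class_1``, ``dq_class_2``, ``dq_genotype``, ``dq25_cis``,
    ``dq25_trans``, ``dq25_carrier`` and ``risk_category``.  Vectorized over
    the distinct (DQA1, DQB1) pairs actually present.
    """
    for col in ("DQA1_1", "DQB1_1", "DQA1_2", "DQB1_2"):
        if col not in cohort.columns:
            raise KeyError(f"cohort table lacks required column {col!r}")
    out = cohort.copy()

    def classify_series(dqa: pd.Series, dqb: pd.Series) -> pd.Series:
        pairs = pd.DataFrame({"a": dqa, "b": dqb})
        if len(pairs) == 0:
            return pd.Series(dtype=object)
        uniq = pairs.drop_duplicates()
        lut = {
            (row.a, row.b): classify_dq_haplotype(
                parse_allele(row.a), parse_allele(row.b)
            )
            for row in uniq.itertuples(index=False)
        }
        return pairs.apply(lambda r: lut[(r.a, r.b)], axis=1)

    cls1 = classify_series(out["DQA1_1"], out["DQB1_1"])
    cls2 = classify_series(out["DQA1_2"], out["DQB1_2"])
    geno_lut = {}
    for a in DqHaplotypeClass:
        for b in DqHaplotypeClass:
            geno_lut[(a, b)] = call_heterodimers_from_classes(a, b, risk_map)
    genos = [geno_lut[(a, b)] for a, b in zip(cls1, cls2)]
    out["dq_class_1"] = [str(c) for c in cls1]
    out["dq_class_2"] = [str(c) for c in cls2]
    out["dq_genotype"] = [str(g) for g in genos]
    out["dq25_cis"] = [g.dq25_cis for g in genos]
    out["dq25_trans"] = [g.dq25_trans for g in genos]
    out["dq25_carrier"] = [g.dq25_carrier for g in genos]
    out["risk_category"] = [g.risk_category for g in genos]
    return out


def _values_of(record, marker: str):
    """Serology values for a marker: scalar, list, or ';'-joined string."""
    if isinstance(record, pd.Series) or isinstance(record, Mapping):
        raw = record.get(marker)
    else:
        raw = getattr(record, marker, None)
    if raw is None:
        return []
    if isinstance(raw, str):
        parts = [p for p in raw.split(";") if p.strip()]
        return [float(p) for p in parts]
    if isinstance(raw, (list, tuple, np.ndarray)):
        return [float(v) for v in raw if not pd.isna(v)]
    if pd.isna(raw):
        return []
    return [float(raw)]


def max_serology(record, marker: str) -> float:
    """Highest recorded value for one antibody, NaN if none recorded.

    Antibody levels fall on a gluten-free diet, so the analysis keys on the
    maximum ever recorded rather than the latest.
    """
    values = _values_of(record, marker)
    if not values:
        return float("nan")
    if any(v < 0 for v in values):
        raise ValueError(f"negative serology value for {marker}: {values}")
    return max(values)


def is_seropositive(record, cutoff: float = 20.0) -> bool:
    """True iff a reported positive result or any antibody max ≥ cutoff IU/mL."""
    reported = record.get("reported_seropositive", False) if isinstance(
        record, (pd.Series, Mapping)
    ) else getattr(record, "reported_seropositive", False)
    if bool(reported):
        return True
    for marker in SEROLOGY_MARKERS:
        m = max_serology(record, marker)
        if not np.isnan(m) and m >= cutoff:
            return True
    return False


def seropositive_column(cohort: pd.DataFrame, cutoff: float = 20.0) -> pd.Series:
    """Vector form of :func:`is_seropositive` over a cohort table."""
    return cohort.apply(lambda row: is_seropositive(row, cutoff), axis=1)


def _is_case(cohort: pd.DataFrame) -> pd.Series:
    return cohort["ced_ehr"].astype(bool) | cohort["ced_survey"].astype(bool)


def select_cases(cohort: pd.DataFrame, risk_map=None) -> pd.DataFrame:
    """CeD cases carrying at least one of the four DQ risk haplotypes.

    A case has an EHR or survey CeD record; participants whose genotype is
    X/X (risk category ``none``) are dropped, mirroring the primary-cohort
    filter.
    """
    ann = cohort if "risk_category" in cohort.columns else call_dq_frame(
        cohort, risk_map
    )
    keep = _is_case(ann) & (ann["risk_category"] != "none")
    return ann.loc[keep].copy()


def eligible_controls(cohort: pd.DataFrame, risk_map=None) -> pd.DataFrame:
    """Non-CeD participants free of all CeD-associated exclusion comorbidities."""
    ann = cohort if "risk_category" in cohort.columns else call_dq_frame(
        cohort, risk_map
    )
    keep = ~_is_case(ann)
    for flag in EXCLUSION_FLAGS:
        if flag in ann.columns:
            # absent/NaN flags are treated as not present
            keep &= ~ann[flag].map(lambda v: bool(v) if pd.notna(v) else False)
    return ann.loc[keep].copy()


# ---------------------------------------------------------------------------
# propensity matching


@dataclass
class MatchedCohort:
    """A case set with its matched controls.

    ``match_map`` maps case id to the ids of its matched controls; every
    control is used at most once across the whole map.
    """

    cases: pd.DataFrame
    controls: pd.DataFrame
    match_map: dict
    ratio: int
    balance: pd.DataFrame = field(default_factory=pd.DataFrame)
    shortfalls: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        used = [c for ids in self.match_map.values() for c in ids]
        if len(used) != len(set(used)):
            raise ValueError("a control is matched to more than one case")
        over = {k: v for k, v in self.match_map.items() if len(v) > self.ratio}
        if over:
            raise ValueError(f"cases exceed the matching ratio: {sorted(over)}")

    def to_frame(self) -> pd.DataFrame:
        """Stacked cases + matched controls with a ``role`` column."""
        cases = self.cases.copy()
        cases["role"] = "case"
        controls = self.controls.copy()
        controls["role"] = "control"
        return pd.concat([cases, controls], ignore_index=True)


def standardized_mean_differences(
    cases: pd.DataFrame, controls: pd.DataFrame, covariates: Sequence[str]
) -> pd.Series:
    """Absolute standardized mean difference per covariate (pooled SD)."""
    out = {}
    for cov in covariates:
        x = _numeric_covariate(cases, cov)
        y = _numeric_covariate(controls, cov)
        sd = np.sqrt((x.var(ddof=1) + y.var(ddof=1)) / 2.0)
        diff = abs(x.mean() - y.mean())
        out[cov] = 0.0 if (sd == 0 or np.isnan(sd)) else diff / sd
    return pd.Series(out, name="smd")


def _numeric_covariate(frame: pd.DataFrame, cov: str) -> pd.Series:
    col = frame[cov]
    if col.dtype == object or str(col.dtype) == "category":
        levels = sorted(col.astype(str).unique())
        return (col.astype(str) == levels[-1]).astype(float)
    return col.astype(float)


class PropensityMatcher:
    """Greedy nearest-neighbor propensity matching (sklearn style).

    Fits an additive logistic case-vs-pool model on the covariates, then
    matches each case (in seeded random order) to its nearest available
    controls by absolute difference in the propensity logit, without
    replacement, within a caliper.

    Parameters
    ----------
    ratio : int
        Maximum controls per case (the study design uses 5).
    covariates : sequence of str
        Model covariates; non-numeric columns are dummy-encoded.
    stratify : str or None
        Column for exact-match strata (default ``"ancestry"``); ``None``
        matches across the whole pool (ancestry can then enter
        ``covariates`` as principal components).
    caliper : float
        Caliper width in units of the SD of the propensity logit.
    random_state : int
        Seed for the greedy case order.

    Attributes (after ``fit``)
    --------------------------
    result_ : MatchedCohort
    logit_model_ : fitted sklearn LogisticRegression
    """

    def __init__(
        self,
        ratio: int = 5,
        covariates: Sequence[str] = ("age", "sex"),
        stratify: str | None = "ancestry",
        caliper: float = 0.2,
        random_state: int = 0,
    ) -> None:
        self.ratio = ratio
        self.covariates = covariates
        self.stratify = stratify
        self.caliper = caliper
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "ratio": self.ratio, "covariates": self.covariates,
            "stratify": self.stratify, "caliper": self.caliper,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "PropensityMatcher":
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, cases: pd.DataFrame, pool: pd.DataFrame) -> "PropensityMatcher":
        from sklearn.linear_model import LogisticRegression

        if len(pool) == 0:
            raise ValueError("control pool is empty")
        for frame, name in ((cases, "cases"), (pool, "pool")):
            for cov in list(self.covariates) + (
                [self.stratify] if self.stratify else []
            ):
                if cov not in frame.columns:
                    raise ValueError(f"{name} table lacks covariate {cov!r}")
                bad = frame[frame[cov].isna()]
                if len(bad):
                    raise ValueError(
                        f"missing covariate {cov!r} for participant "
                        f"{bad['id'].iloc[0]!r}"
                    )
        if len(cases) == 0:
            self.result_ = MatchedCohort(
                cases.copy(), pool.iloc[0:0].copy(), {}, self.ratio
            )
            return self

        design = pd.concat([cases, pool], ignore_index=True)
        X = pd.get_dummies(
            design[list(self.covariates)], drop_first=True
        ).astype(float)
        y = np.r_[np.ones(len(cases)), np.zeros(len(pool))]
        model = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=500)
        model.fit(X.to_numpy(), y)
        logits = X.to_numpy() @ model.coef_.ravel() + model.intercept_[0]
        case_logit = logits[: len(cases)]
        pool_logit = logits[len(cases):]
        self.logit_model_ = model

        sd = np.std(logits, ddof=1)
        caliper_abs = self.caliper * sd if sd > 0 else np.inf

        rng = np.random.default_rng(self.random_state)
        order = rng.permutation(len(cases))

        pool_ids = pool["id"].to_numpy()
        case_ids = cases["id"].to_numpy()
        if self.stratify:
            pool_strata = pool[self.stratify].to_numpy()
            case_strata = cases[self.stratify].to_numpy()
        available = np.ones(len(pool), dtype=bool)

        match_map: dict = {}
        shortfalls: dict = {}
        for ci in order:
            eligible = available.copy()
            if self.stratify:
                eligible &= pool_strata == case_strata[ci]
            dist = np.abs(pool_logit - case_logit[ci])
            eligible &= dist <= caliper_abs
            idx = np.flatnonzero(eligible)
            if len(idx) == 0:
                match_map[case_ids[ci]] = []
                shortfalls[case_ids[ci]] = self.ratio
                continue
            take = idx[np.argsort(dist[idx], kind="stable")][: self.ratio]
            available[take] = False
            match_map[case_ids[ci]] = list(pool_ids[take])
            if len(take) < self.ratio:
                shortfalls[case_ids[ci]] = self.ratio - len(take)
        if shortfalls:
            warnings.warn(
                f"{len(shortfalls)} case(s) matched fewer than "
                f"{self.ratio} controls", stacklevel=2
            )
        matched_ids = {c for ids in match_map.values() for c in ids}
        controls = pool[pool["id"].isin(matched_ids)].copy()

        covs = list(self.covariates) + (
            [self.stratify] if self.stratify else []
        )
        balance = pd.DataFrame({
            "pre": standardized_mean_differences(cases, pool, covs),
            "post": standardized_mean_differences(cases, controls, covs)
            if len(controls) else np.nan,
        })
        self.result_ = MatchedCohort(
            cases.copy(), controls, match_map, self.ratio,
            balance=balance, shortfalls=shortfalls,
        )
        return self


def propensity_match(
    cases: pd.DataFrame,
    pool: pd.DataFrame,
    ratio: int = 5,
    covariates: Sequence[str] = ("age", "sex"),
    stratify: str | None = "ancestry",
    caliper: float = 0.2,
    seed: int = 0,
) -> MatchedCohort:
    """Functional wrapper over :class:`PropensityMatcher`."""
    matcher = PropensityMatcher(
        ratio=ratio, covariates=covariates, stratify=stratify,
        caliper=caliper, random_state=seed,
    )
    return matcher.fit(cases, pool).result_
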