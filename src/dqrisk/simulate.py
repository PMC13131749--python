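"""Synthetic ancestry-stratified cohorts with CeD-like haplotype structure.

The generator emulates the statistical structure the downstream analysis
assumes, so that every pipeline stage is testable without access-controlled
biobank data:

* per-ancestry extended-haplotype pools (A~B~C~DQA1~DQB1~DRB1) built
  analytically so that the marginal DQ2.5 frequency and the conditional
  B8-given-DQ2.5 linkage equal configured values exactly;
* Hardy–Weinberg random union of two haplotypes within each ancestry
  stratum (no admixture between strata — the analysis is stratified);
* a logistic disease model with additive per-allele, per-risk-category,
  per-SNP and per-covariate log-odds;
* right-skewed (log-normal) serology conditional on risk category and case
  status; clinical and exclusion flags at configured prevalences;
* an rs2187668 tagSNP whose dosage equals the DQ2.5 haplotype count up to a
  configurable per-ancestry discordance rate.

All randomness flows from one integer seed through ``numpy.random.SeedSequence``
spawning, so identical seed + config gives a byte-identical cohort table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .hla import (
    DqHaplotypeClass,
    Haplotype,
    HlaAllele,
    assign_risk_category,
    parse_allele,
)

__all__ = [
    "AncestryPoolSpec",
    "DiseaseModelSpec",
    "SerologyModelSpec",
    "SnpSpec",
    "PoolConfigError",
    "DEFAULT_POOL_PARAMS",
    "DEFAULT_FLAG_PREVALENCES",
    "HLA_LOCI",
    "build_default_pools",
    "build_pool",
    "sample_cohort",
    "attach_tagsnp",
    "default_snp_panel",
]

HLA_LOCI = ("A", "B", "C", "DQA1", "DQB1", "DRB1")

#: Extended haplotype backbones.  AH8.1 is the conserved European
#: A1-B8-C7-DR3-DQ2.5 ancestral haplotype; the non-B8 DQ2.5 backbone keeps the
#: DQ2.5 heterodimer but a different class-I arm; residual non-risk haplotypes
#: are collapsed to three labeled backbones whose internal composition does
#: not affect any downstream statistic.
_BACKBONES: dict[str, tuple[str, ...]] = {
    "AH8.1": ("A*01:01", "B*08:01", "C*07:01", "DQA1*05:01", "DQB1*02:01", "DRB1*03:01"),
    "DQ2.5-nonB8": ("A*02:01", "B*07:02", "C*07:02", "DQA1*05:01", "DQB1*02:01", "DRB1*03:01"),
    "DQ2.2": ("A*02:01", "B*44:03", "C*04:01", "DQA1*02:01", "DQB1*02:02", "DRB1*07:01"),
    "DQ8.1": ("A*02:01", "B*44:02", "C*05:01", "DQA1*03:01", "DQB1*03:02", "DRB1*04:01"),
    "DQ7.5": ("A*02:01", "B*35:01", "C*04:01", "DQA1*05:05", "DQB1*03:01", "DRB1*11:01"),
    "OTHER-1": ("A*03:01", "B*07:02", "C*07:02", "DQA1*01:02", "DQB1*06:02", "DRB1*15:01"),
    "OTHER-2": ("A*24:02", "B*51:01", "C*15:02", "DQA1*01:01", "DQB1*05:01", "DRB1*01:01"),
    "OTHER-3": ("A*68:01", "B*53:01", "C*04:01", "DQA1*01:03", "DQB1*06:03", "DRB1*13:01"),
}

#: Per-ancestry pool parameters.  f_dq25 and (EUR/AMR) b8_given_dq25 follow
#: the control-cohort values reported for a large US biobank; the AFR
#: conditional linkage is a placeholder within its published estimate range.
#: The DQ2.2/DQ8.1/DQ7.5 frequencies are typical of published HLA surveys for
#: each ancestry and are configurable.
DEFAULT_POOL_PARAMS: dict[str, dict[str, float]] = {
    "EUR": {"f_dq25": 0.116, "b8_given_dq25": 0.742, "f_dq22": 0.06, "f_dq81": 0.10, "f_dq75": 0.14},
    "AMR": {"f_dq25": 0.081, "b8_given_dq25": 0.421, "f_dq22": 0.05, "f_dq81": 0.15, "f_dq75": 0.12},
    "AFR": {"f_dq25": 0.072, "b8_given_dq25": 0.15, "f_dq22": 0.08, "f_dq81": 0.05, "f_dq75": 0.12},
    "OTHER": {"f_dq25": 0.10, "b8_given_dq25": 0.60, "f_dq22": 0.06, "f_dq81": 0.10, "f_dq75": 0.13},
}

#: Residual (non-risk) haplotype mass is split over the three OTHER backbones
#: in these fixed proportions.
_OTHER_SPLIT = (0.5, 0.3, 0.2)

DEFAULT_FLAG_PREVALENCES: dict[str, float] = {
    # clinical flags
    "family_history": 0.05,
    "diarrhea": 0.15,
    "vitamin_d_deficiency": 0.20,
    "anemia": 0.10,
    "hypothyroidism": 0.08,
    "ibs": 0.10,
    "migraine": 0.12,
    # control-exclusion comorbidities
    "t1d": 0.01,
    "autoimmune_thyroid": 0.05,
    "iga_deficiency": 0.002,
    "ibd": 0.01,
    "hiv": 0.003,
    "cvid": 0.0005,
    "cancer": 0.05,
    "down": 0.001,
    "digeorge": 0.0005,
}

SEROLOGY_MARKERS = ("ttg_iga", "dgp_iga", "dgp_igg")


class PoolConfigError(ValueError):
    """Raised for inconsistent or out-of-range pool frequencies."""


@dataclass(frozen=True)
class AncestryPoolSpec:
    """A haplotype pool for one ancestry stratum.

    ``haplotypes`` and ``frequencies`` are parallel; frequencies sum to 1.
    """

    ancestry_label: str
    haplotypes: tuple
    frequencies: tuple

    def __post_init__(self) -> None:
        if len(self.haplotypes) != len(self.frequencies):
            raise PoolConfigError("haplotypes and frequencies differ in length")
        if len(self.haplotypes) == 0:
            raise PoolConfigError("empty haplotype pool")
        freqs = np.asarray(self.frequencies, dtype=float)
        if np.any(freqs < 0) or np.any(freqs > 1):
            raise PoolConfigError(
                f"{self.ancestry_label}: haplotype frequencies outside [0, 1]"
            )
        if abs(freqs.sum() - 1.0) > 1e-9:
            raise PoolConfigError(
                f"{self.ancestry_label}: frequencies sum to {freqs.sum():.12f}, not 1"
            )
        loci = {tuple(sorted(h.alleles)) for h in self.haplotypes}
        if len(loci) != 1:
            raise PoolConfigError(
                f"{self.ancestry_label}: haplotypes do not share one locus set"
            )

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    def frequency_of(self, allele: HlaAllele) -> float:
        """Marginal frequency of ``allele`` over the pool."""
        return float(
            sum(f for h, f in zip(self.haplotypes, self.frequencies) if allele in h)
        )

    def dq25_frequency(self) -> float:
        dqa, dqb = HlaAllele("DQA1", 5, 1), HlaAllele("DQB1", 2, 1)
        return float(
            sum(
                f
                for h, f in zip(self.haplotypes, self.frequencies)
                if dqa in h and dqb in h
            )
        )


@dataclass(frozen=True)
class SnpSpec:
    """A biallelic non-HLA SNP: risk-allele frequency under HWE."""

    variant_id: str
    risk_allele_freq: float
    effect_allele: str = "A"

    def __post_init__(self) -> None:
        if not 0.0 <= self.risk_allele_freq <= 1.0:
            raise ValueError(f"{self.variant_id}: frequency outside [0, 1]")


@dataclass(frozen=True)
class DiseaseModelSpec:
    """Additive logistic disease model.

    log-odds(case) = logit(baseline_prevalence)
                     + Σ allele_log_odds[a] × (copies of a)
                     + category_log_odds[risk category]
                     + Σ snp_log_odds[v] × dosage(v)
                     + Σ covariate_log_odds[flag] × flag

    The default carries the DQB1*02:01 per-allele effect (OR 3.6) plus
    modest clinical-covariate effects; category increments default to zero so
    genotype risk flows through the allele term.
    """

    baseline_prevalence: float = 0.012
    allele_log_odds: Mapping[str, float] = field(
        default_factory=lambda: {"DQB1*02:01": math.log(3.6)}
    )
    category_log_odds: Mapping[str, float] = field(default_factory=dict)
    snp_log_odds: Mapping[str, float] = field(default_factory=dict)
    covariate_log_odds: Mapping[str, float] = field(
        default_factory=lambda: {
            "family_history": 1.0,
            "diarrhea": 0.5,
            "vitamin_d_deficiency": 0.4,
            "anemia": 0.4,
            "hypothyroidism": 0.3,
        }
    )

    def __post_init__(self) -> None:
        if not 0.0 < self.baseline_prevalence < 1.0:
            raise ValueError("baseline_prevalence must be in (0, 1)")
        for table in (
            self.allele_log_odds,
            self.category_log_odds,
            self.snp_log_odds,
            self.covariate_log_odds,
        ):
            for key, value in table.items():
                if not math.isfinite(value):
                    raise ValueError(f"non-finite log-odds for {key!r}")


@dataclass(frozen=True)
class SerologyModelSpec:
    """Log-normal serology (IU/mL) by risk category and case status.

    ``case_log_location`` maps risk category to the log-scale mean for cases;
    controls share ``control_log_location``.  DGP markers are shifted down by
    ``dgp_log_offset`` relative to tTG-IgA.  Values at or above
    ``seropositive_cutoff`` are read as seropositive downstream.
    """

    case_log_location: Mapping[str, float] = field(
        default_factory=lambda: {
            "high": math.log(60.0),
            "moderate": math.log(35.0),
            "low": math.log(8.0),
            "none": math.log(4.0),
        }
    )
    case_log_scale: float = 1.0
    control_log_location: float = math.log(3.0)
    control_log_scale: float = 0.8
    dgp_log_offset: float = -0.3
    seropositive_cutoff: float = 20.0
    case_measured_rate: float = 0.8
    control_measured_rate: float = 0.1

    def __post_init__(self) -> None:
        if self.case_log_scale <= 0 or self.control_log_scale <= 0:
            raise ValueError("serology log-scale must be positive")
        if self.seropositive_cutoff <= 0:
            raise ValueError("seropositive cutoff must be positive")
        locs = self.case_log_location
        if not (locs["high"] > locs["moderate"] > locs["low"]):
            raise ValueError(
                "case serology locations must be ordered high > moderate > low"
            )


def build_pool(
    ancestry_label: str,
    f_dq25: float,
    b8_given_dq25: float,
    f_dq22: float,
    f_dq81: float,
    f_dq75: float,
) -> AncestryPoolSpec:
    """Build one ancestry pool analytically (no sampling).

    The DQ2.5 mass is split between the AH8.1 backbone
    (``f_dq25 × b8_given_dq25``) and a non-B8 DQ2.5 backbone, so the
    configured marginal and conditional hold exactly; residual mass goes to
    the three OTHER backbones.
    """
    params = {
        "f_dq25": f_dq25,
        "b8_given_dq25": b8_given_dq25,
        "f_dq22": f_dq22,
        "f_dq81": f_dq81,
        "f_dq75": f_dq75,
    }
    for name, value in params.items():
        if not 0.0 <= value <= 1.0:
            raise PoolConfigError(f"{ancestry_label}: {name}={value} outside [0, 1]")
    f_ah81 = f_dq25 * b8_given_dq25
    if f_ah81 > f_dq25 + 1e-12:
        raise PoolConfigError(
            f"{ancestry_label}: joint B8–DQ2.5 frequency {f_ah81:.4f} exceeds "
            f"the DQ2.5 marginal {f_dq25:.4f}"
        )
    residual = 1.0 - (f_dq25 + f_dq22 + f_dq81 + f_dq75)
    if residual < -1e-12:
        raise PoolConfigError(
            f"{ancestry_label}: risk-haplotype frequencies sum to "
            f"{1 - residual:.4f} > 1"
        )
    residual = max(residual, 0.0)
    names = list(_BACKBONES)
    freqs = {
        "AH8.1": f_ah81,
        "DQ2.5-nonB8": f_dq25 - f_ah81,
        "DQ2.2": f_dq22,
        "DQ8.1": f_dq81,
        "DQ7.5": f_dq75,
        "OTHER-1": residual * _OTHER_SPLIT[0],
        "OTHER-2": residual * _OTHER_SPLIT[1],
        "OTHER-3": residual * _OTHER_SPLIT[2],
    }
    haplotypes, frequencies = [], []
    for name in names:
        if freqs[name] <= 0.0 and name not in ("AH8.1", "DQ2.5-nonB8"):
            if freqs[name] < 0.0:
                raise PoolConfigError(f"{ancestry_label}: negative mass for {name}")
        haplotypes.append(Haplotype.from_strings(_BACKBONES[name]))
        frequencies.append(freqs[name])
    total = sum(frequencies)
    frequencies = [f / total for f in frequencies]
    return AncestryPoolSpec(ancestry_label, tuple(haplotypes), tuple(frequencies))


def build_default_pools(
    config: Mapping[str, Mapping[str, float]] | None = None,
) -> list[AncestryPoolSpec]:
    """Build the per-ancestry default pools, optionally overriding parameters.

    ``config`` maps ancestry label to any subset of
    ``{f_dq25, b8_given_dq25, f_dq22, f_dq81, f_dq75}``; unspecified values
    fall back to :data:`DEFAULT_POOL_PARAMS`.
    """
    merged: dict[str, dict[str, float]] = {
        anc: dict(params) for anc, params in DEFAULT_POOL_PARAMS.items()
    }
    if config:
        for anc, overrides in config.items():
            base = merged.setdefault(anc, dict(DEFAULT_POOL_PARAMS["OTHER"]))
            unknown = set(overrides) - {
                "f_dq25", "b8_given_dq25", "f_dq22", "f_dq81", "f_dq75",
            }
            if unknown:
                raise PoolConfigError(
                    f"{anc}: unknown pool parameters {sorted(unknown)}"
                )
            base.update(overrides)
    return [build_pool(anc, **params) for anc, params in merged.items()]


def default_snp_panel(n_snps: int = 38, seed: int = 12345) -> list[SnpSpec]:
    """A reproducible panel of synthetic non-HLA risk SNPs.

    Risk-allele frequencies are drawn once from U(0.05, 0.5) under the given
    seed; the panel stands in for published PRS variants whose weights are
    not redistributable.
    """
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(0.05, 0.5, size=n_snps)
    return [
        SnpSpec(f"snp{i + 1:03d}", float(f)) for i, f in enumerate(freqs)
    ]


# ---------------------------------------------------------------------------
# cohort sampling


def _classify_pool(pool: AncestryPoolSpec) -> np.ndarray:
    """DQ class code (index into DqHaplotypeClass) per pool haplotype."""
    from .hla import classify_dq_haplotype

    order = list(DqHaplotypeClass)
    codes = [
        order.index(classify_dq_haplotype(h["DQA1"], h["DQB1"]))
        for h in pool.haplotypes
    ]
    return np.asarray(codes, dtype=np.int64)


def _category_matrix(risk_map=None) -> np.ndarray:
    """5×5 matrix of risk-category codes over ordered DQ-class pairs."""
    order = list(DqHaplotypeClass)
    cats = ("high", "moderate", "low", "none")
    mat = np.empty((5, 5), dtype=np.int64)
    for i, a in enumerate(order):
        for j, b in enumerate(order):
            mat[i, j] = cats.index(assign_risk_category((a, b), risk_map))
    return mat


def sample_cohort(
    pools: Sequence[AncestryPoolSpec],
    disease_model: DiseaseModelSpec | None = None,
    serology_model: SerologyModelSpec | None = None,
    n_per_ancestry: int | Mapping[str, int] = 1000,
    seed: int = 0,
    snp_panel: Sequence[SnpSpec] | None = None,
    flag_prevalences: Mapping[str, float] | None = None,
    tagsnp_discordance: Mapping[str, float] | None = None,
    risk_map=None,
) -> pd.DataFrame:
    """Sample a phased synthetic cohort as a tidy participant table.

    Each participant draws two haplotypes i.i.d. from their ancestry pool
    (Hardy–Weinberg), case status from the logistic disease model, serology
    from the log-normal model, and clinical/exclusion flags from configured
    prevalences.  Columns: ``id, ancestry, age, sex``, two allele columns per
    HLA locus (``A_1 … DRB1_2``, phased), ``ced_ehr, ced_survey``, flags,
    serology markers, ``reported_seropositive``, ``tagsnp_dosage`` and one
    ``dos_<variant>`` column per panel SNP.

    Reproducible: byte-identical output for identical seed + config.
    """
    if disease_model is None:
        disease_model = DiseaseModelSpec()
    if serology_model is None:
        serology_model = SerologyModelSpec()
    prevalences = dict(DEFAULT_FLAG_PREVALENCES)
    if flag_prevalences:
        prevalences.update(flag_prevalences)
    if not pools:
        raise PoolConfigError("no ancestry pools supplied")

    if isinstance(n_per_ancestry, Mapping):
        n_by_anc = {p.ancestry_label: int(n_per_ancestry.get(p.ancestry_label, 0)) for p in pools}
    else:
        n_by_anc = {p.ancestry_label: int(n_per_ancestry) for p in pools}
    if any(n < 0 for n in n_by_anc.values()):
        raise ValueError("n_per_ancestry must be non-negative")

    seeds = np.random.SeedSequence(seed).spawn(len(pools))
    frames = []
    offset = 0
    for pool, ss in zip(pools, seeds):
        n = n_by_anc[pool.ancestry_label]
        frames.append(
            _sample_stratum(
                pool, n, ss, disease_model, serology_model, prevalences,
                snp_panel or (), offset, risk_map,
            )
        )
        offset += n
    cohort = pd.concat(frames, ignore_index=True)
    discord = dict(tagsnp_discordance or {})
    return attach_tagsnp(
        cohort,
        discordance=discord,
        seed=int(np.random.SeedSequence(seed).generate_state(2)[1] % (2**31)),
    )


def _sample_stratum(
    pool, n, seedseq, disease_model, serology_model, prevalences,
    snp_panel, id_offset, risk_map,
) -> pd.DataFrame:
    rng = np.random.default_rng(seedseq)
    freqs = np.asarray(pool.frequencies, dtype=float)
    hap_idx = rng.choice(len(freqs), size=(n, 2), p=freqs)
    class_codes = _classify_pool(pool)
    c1, c2 = class_codes[hap_idx[:, 0]], class_codes[hap_idx[:, 1]]
    cat_mat = _category_matrix(risk_map)
    cat_code = cat_mat[c1, c2]
    categories = np.array(("high", "moderate", "low", "none"))[cat_code]

    data: dict = {
        "id": np.array([f"P{id_offset + i:07d}" for i in range(n)]),
        "ancestry": np.repeat(pool.ancestry_label, n),
        "age": np.clip(np.round(rng.normal(50, 17, size=n)), 18, 90).astype(int),
        "sex": np.where(rng.random(n) < 0.6, "F", "M"),
    }

    # phased allele columns
    for locus in HLA_LOCI:
        allele_strings = np.array([str(h[locus]) for h in pool.haplotypes])
        data[f"{locus}_1"] = allele_strings[hap_idx[:, 0]]
        data[f"{locus}_2"] = allele_strings[hap_idx[:, 1]]

    # clinical and exclusion flags (independent of genotype)
    for flag, prev in prevalences.items():
        data[flag] = rng.random(n) < prev

    # allele-dosage terms for the disease model
    logit = np.full(n, math.log(disease_model.baseline_prevalence / (1 - disease_model.baseline_prevalence)))
    for allele_str, beta in disease_model.allele_log_odds.items():
        allele = parse_allele(allele_str)
        carries = np.array([allele in h for h in pool.haplotypes])
        dosage = carries[hap_idx[:, 0]].astype(int) + carries[hap_idx[:, 1]].astype(int)
        logit = logit + beta * dosage
    if disease_model.category_log_odds:
        cat_beta = np.array([
            disease_model.category_log_odds.get(c, 0.0)
            for c in ("high", "moderate", "low", "none")
        ])
        logit = logit + cat_beta[cat_code]
    for flag, beta in disease_model.covariate_log_odds.items():
        if flag in data:
            logit = logit + beta * data[flag].astype(float)

    snp_dosages = {}
    for snp in snp_panel:
        d = rng.binomial(2, snp.risk_allele_freq, size=n)
        snp_dosages[snp.variant_id] = d
        beta = disease_model.snp_log_odds.get(snp.variant_id, 0.0)
        if beta:
            logit = logit + beta * d

    p_case = 1.0 / (1.0 + np.exp(-logit))
    case = rng.random(n) < p_case

    # diagnosis routes: every case is documented in EHR, survey, or both
    ehr_draw = rng.random(n) < 0.75
    survey_draw = rng.random(n) < 0.45
    data["ced_ehr"] = case & ehr_draw
    data["ced_survey"] = case & (survey_draw | ~ehr_draw)

    # serology: log-normal by (case status, risk category); mostly missing
    measured = np.where(
        case,
        rng.random(n) < serology_model.case_measured_rate,
        rng.random(n) < serology_model.control_measured_rate,
    )
    case_mu = np.array([
        serology_model.case_log_location[c]
        for c in ("high", "moderate", "low", "none")
    ])[cat_code]
    mu = np.where(case, case_mu, serology_model.control_log_location)
    sigma = np.where(case, serology_model.case_log_scale, serology_model.control_log_scale)
    for marker in SEROLOGY_MARKERS:
        shift = 0.0 if marker == "ttg_iga" else serology_model.dgp_log_offset
        values = np.exp(rng.normal(mu + shift, sigma))
        data[marker] = np.where(measured, np.round(values, 2), np.nan)
    data["reported_seropositive"] = case & (rng.random(n) < 0.1)

    for variant_id, d in snp_dosages.items():
        data[f"dos_{variant_id}"] = d

    return pd.DataFrame(data)


def attach_tagsnp(
    cohort: pd.DataFrame,
    discordance: Mapping[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Attach the rs2187668 tagSNP dosage column.

    The dosage equals the participant's count of DQ2.5 haplotypes
    (DQA1*05:01 with DQB1*02:01 in cis), except that with per-ancestry
    probability ``discordance[ancestry]`` the carrier state is flipped
    (carriers drop to dosage 0, non-carriers gain dosage 1), emulating
    ancestry-dependent tagSNP failure.
    """
    discordance = dict(discordance or {})
    for anc, rate in discordance.items():
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"discordance rate for {anc} outside [0, 1]")
    out = cohort.copy()
    is_dq25_1 = (out["DQA1_1"] == "DQA1*05:01") & (out["DQB1_1"] == "DQB1*02:01")
    is_dq25_2 = (out["DQA1_2"] == "DQA1*05:01") & (out["DQB1_2"] == "DQB1*02:01")
    dosage = is_dq25_1.astype(int) + is_dq25_2.astype(int)
    rng = np.random.default_rng(seed)
    flip_p = out["ancestry"].map(lambda a: discordance.get(a, 0.0)).to_numpy(dtype=float)
    flip = rng.random(len(out)) < flip_p
    dosage = dosage.to_numpy()
    flipped = np.where(dosage >= 1, 0, 1)
    out["tagsnp_dosage"] = np.where(flip, flipped, dosage)
    return out
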