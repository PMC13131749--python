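"""Tabular I/O, run configuration, and the end-to-end pipeline.

All exchange formats are TSV (participant tables, frequency tables, match
tables) plus JSON run summaries.  A pipeline run writes every stage output
under one output directory together with a machine-readable manifest
(config echo, seed, package version, per-stage row counts), and is
deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    call_dq_frame,
    eligible_controls,
    propensity_match,
    select_cases,
    seropositive_column,
)
from .haplotypes import conditional_linkage, count_phased_haplotypes, em_haplotype_frequencies
from .hla import HlaParseError, parse_allele
from .scoring import (
    PrsWeightTable,
    brier,
    build_feature_frame,
    compute_prs_frame,
    fit_composite,
    platt_calibrate,
    roc,
    score_frame,
    select_threshold,
)
from .simulate import (
    DiseaseModelSpec,
    SerologyModelSpec,
    build_default_pools,
    default_snp_panel,
    sample_cohort,
)
from .stats import allele_table, genotype_frequency_table, odds_ratio

__all__ = [
    "RunConfig",
    "ConfigError",
    "read_cohort",
    "write_cohort",
    "read_weight_table",
    "write_weight_table",
    "run_pipeline",
]

MANDATORY_COLUMNS = (
    "id", "ancestry", "age", "sex", "ced_ehr", "ced_survey",
    "DQA1_1", "DQA1_2", "DQB1_1", "DQB1_2",
)

#: Columns holding HLA allele strings, validated on read.
_ALLELE_COLUMNS = tuple(
    f"{locus}_{i}" for locus in ("A", "B", "C", "DPB1", "DQA1", "DQB1", "DRB1")
    for i in (1, 2)
)

SCHEMA_VERSION = "cohort-tsv-v1"


class ConfigError(ValueError):
    """Raised for invalid or incomplete run configuration."""


@dataclass
class RunConfig:
    """Validated pipeline configuration (unknown keys rejected)."""

    seed: int
    out_dir: str = "dqrisk-run"
    cohort_path: str | None = None  # None -> simulate
    n_per_ancestry: int = 5000
    pools: Mapping = field(default_factory=dict)  # per-ancestry overrides
    tagsnp_discordance: Mapping = field(default_factory=dict)
    n_snps: int = 38
    seropositive_cutoff: float = 20.0
    match_ratio: int = 5
    match_caliper: float = 0.2
    match_covariates: tuple = ("age", "sex")
    haplotype_loci: tuple = ("B", "DQA1", "DQB1")
    em_tol: float = 1e-6
    em_max_iter: int = 1000
    use_em: bool = False  # default: direct counting on phased input
    prs_weights_path: str | None = None
    verbosity: int = 1

    @classmethod
    def from_mapping(cls, raw: Mapping) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in raw:
            raise ConfigError("config must set 'seed' (stochastic stages)")
        cfg = cls(**{k: raw[k] for k in raw})
        cfg.match_covariates = tuple(cfg.match_covariates)
        cfg.haplotype_loci = tuple(cfg.haplotype_loci)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, Mapping):
            raise ConfigError(f"config file {path} is not a mapping")
        return cls.from_mapping(raw)


def read_cohort(
    path: str | Path,
    strict: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a participant table from TSV, validating HLA allele columns.

    Returns ``(cohort, errors)``: rows with unparseable alleles are dropped
    (or raise, with ``strict=True``) and reported in ``errors`` with the
    offending column and message.
    """
    frame = pd.read_csv(path, sep="\t", dtype={"id": str})
    missing = [c for c in MANDATORY_COLUMNS if c not in frame.columns]
    if missing:
        raise ConfigError(f"cohort file {path} lacks mandatory columns: {missing}")
    bad_rows = []
    allele_cols = [c for c in _ALLELE_COLUMNS if c in frame.columns]
    keep = np.ones(len(frame), dtype=bool)
    for col in allele_cols:
        # validate each distinct allele string once
        bad_values = {}
        for value in frame[col].unique():
            try:
                parse_allele(str(value))
            except HlaParseError as exc:
                bad_values[value] = str(exc)
        if not bad_values:
            continue
        for i in np.flatnonzero(frame[col].isin(bad_values) & keep):
            keep[i] = False
            bad_rows.append(
                {"row": int(i), "id": frame["id"].iloc[i], "column": col,
                 "error": bad_values[frame[col].iloc[i]]}
            )
    errors = pd.DataFrame(bad_rows, columns=["row", "id", "column", "error"])
    if strict and len(errors):
        raise HlaParseError(
            f"{len(errors)} row(s) with malformed alleles in {path}; "
            f"first: {errors.iloc[0].to_dict()}"
        )
    for col in ("ced_ehr", "ced_survey", "reported_seropositive"):
        if col in frame.columns:
            frame[col] = frame[col].astype(bool)
    return frame.loc[keep].reset_index(drop=True), errors


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write a participant table as TSV (the documented exchange schema)."""
    cohort.to_csv(path, sep="\t", index=False)


def read_weight_table(path: str | Path) -> PrsWeightTable:
    return PrsWeightTable.from_frame(pd.read_csv(path, sep="\t"))


def write_weight_table(weights: PrsWeightTable, path: str | Path) -> None:
    weights.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# pipeline


def _stage(result: dict, name: str, fn):
    try:
        return fn()
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc


def run_pipeline(config: RunConfig | Mapping) -> dict:
    """Run simulate/ingest → call-dq → assemble → haplotypes → associate → score.

    Writes all stage outputs and a manifest under ``config.out_dir`` and
    returns the manifest dict.
    """
    if not isinstance(config, RunConfig):
        config = RunConfig.from_mapping(dict(config))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "schema": SCHEMA_VERSION,
        "version": __version__,
        "seed": config.seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
        "stages": {},
    }

    # --- simulate / ingest
    if config.cohort_path is None:
        cohort = _stage(manifest, "simulate", lambda: sample_cohort(
            build_default_pools(config.pools or None),
            DiseaseModelSpec(),
            SerologyModelSpec(seropositive_cutoff=config.seropositive_cutoff),
            n_per_ancestry=config.n_per_ancestry,
            seed=config.seed,
            snp_panel=default_snp_panel(config.n_snps),
            tagsnp_discordance=config.tagsnp_discordance,
        ))
    else:
        cohort, errors = _stage(
            manifest, "ingest", lambda: read_cohort(config.cohort_path)
        )
        if len(errors):
            errors.to_csv(out / "ingest_errors.tsv", sep="\t", index=False)
    write_cohort(cohort, out / "cohort.tsv")
    manifest["stages"]["cohort"] = {"rows": int(len(cohort))}

    # --- call-dq
    ann = _stage(manifest, "call-dq", lambda: call_dq_frame(cohort))
    dq_cols = ["id", "dq_class_1", "dq_class_2", "dq_genotype",
               "dq25_cis", "dq25_trans", "dq25_carrier", "risk_category"]
    ann[dq_cols].to_csv(out / "dq_calls.tsv", sep="\t", index=False)
    manifest["stages"]["call-dq"] = {
        "rows": int(len(ann)),
        "carriers": int(ann["dq25_carrier"].sum()),
    }

    # --- assemble
    cases = _stage(manifest, "assemble", lambda: select_cases(ann))
    pool = eligible_controls(ann)
    matched = propensity_match(
        cases, pool, ratio=config.match_ratio,
        covariates=config.match_covariates, caliper=config.match_caliper,
        seed=config.seed,
    )
    matched.to_frame().to_csv(out / "matched_cohort.tsv", sep="\t", index=False)
    matched.balance.to_csv(out / "balance.tsv", sep="\t")
    manifest["stages"]["assemble"] = {
        "cases": int(len(matched.cases)),
        "controls": int(len(matched.controls)),
        "shortfall_cases": int(len(matched.shortfalls)),
    }

    # --- estimate-haplotypes (controls, per ancestry)
    loci = config.haplotype_loci
    hap_rows, linkage = [], {}
    for anc, sub in pool.groupby("ancestry"):
        if len(sub) < 10:
            continue
        if config.use_em:
            table = _stage(manifest, "estimate-haplotypes", lambda s=sub: (
                em_haplotype_frequencies(
                    s, loci, tol=config.em_tol, max_iter=config.em_max_iter,
                    stratum=str(anc),
                )
            ))
        else:
            table = count_phased_haplotypes(sub, loci, stratum=str(anc))
        hap_rows.append(table.to_frame())
        try:
            linkage[str(anc)] = conditional_linkage(
                table, "B*08:01", ("DQA1*05:01", "DQB1*02:01")
            )
        except ZeroDivisionError:
            linkage[str(anc)] = float("nan")
    pd.concat(hap_rows, ignore_index=True).to_csv(
        out / "haplotype_frequencies.tsv", sep="\t", index=False
    )
    manifest["stages"]["estimate-haplotypes"] = {
        "b8_given_dq25": linkage,
        "method": "em" if config.use_em else "counting",
    }

    # --- associate (matched cohort, per ancestry)
    stacked = matched.to_frame()
    assoc_rows = []
    for anc, sub in stacked.groupby("ancestry"):
        tab = allele_table(sub, "DQB1*02:01")
        if min(tab.a + tab.b, tab.c + tab.d) == 0:
            continue
        res = odds_ratio(tab, label=f"DQB1*02:01 [{anc}]")
        assoc_rows.append({
            "ancestry": anc, "label": "DQB1*02:01",
            "a": tab.a, "b": tab.b, "c": tab.c, "d": tab.d,
            "or": res.or_estimate, "ci_low": res.ci_low,
            "ci_high": res.ci_high, "p": res.p_value,
        })
    assoc = pd.DataFrame(assoc_rows)
    assoc.to_csv(out / "allele_association.tsv", sep="\t", index=False)
    geno = _stage(
        manifest, "associate", lambda: genotype_frequency_table(stacked)
    )
    geno.to_csv(out / "genotype_association.tsv", sep="\t", index=False)
    manifest["stages"]["associate"] = {"allele_rows": int(len(assoc)),
                                       "genotype_rows": int(len(geno))}

    # --- score + roc
    if config.prs_weights_path:
        weights = read_weight_table(config.prs_weights_path)
    else:
        # HLA-only default weights; SNP weights are an input in real use
        weights = PrsWeightTable(
            tuple(), {"high": 2.0, "moderate": 1.2, "low": 0.4, "none": 0.0}
        )
    scored = stacked.copy()
    scored["prs"] = compute_prs_frame(scored, weights)
    labels = (
        (scored["role"] == "case")
        & seropositive_column(scored, config.seropositive_cutoff)
    ).astype(int)
    summary: dict = {}
    if labels.sum() >= 5 and (1 - labels).sum() >= 5:
        features = _stage(
            manifest, "score",
            lambda: build_feature_frame(scored, weights),
        )
        model = fit_composite(features, labels, penalize=True)
        scores = score_frame(features, model)
        roc_res = roc(scores.to_numpy(), labels.to_numpy())
        (slope, intercept), probs = platt_calibrate(
            scores.to_numpy(), labels.to_numpy(), penalize=True
        )
        summary = {
            "auc": roc_res.auc,
            "threshold_max_accuracy": select_threshold(roc_res, "max_accuracy"),
            "threshold_sensitivity_90": select_threshold(roc_res, "sensitivity_90"),
            "platt": {"slope": slope, "intercept": intercept},
            "brier": brier(probs, labels.to_numpy()),
            "model": {"intercept": model.intercept,
                      "weights": dict(model.feature_weights)},
        }
        roc_res.to_frame().to_csv(out / "roc.tsv", sep="\t", index=False)
    manifest["stages"]["score"] = summary

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
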