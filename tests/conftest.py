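import numpy as np
import pandas as pd
import pytest

from dqrisk.simulate import (
    DiseaseModelSpec,
    SerologyModelSpec,
    build_default_pools,
    build_pool,
    default_snp_panel,
    sample_cohort,
)


@pytest.fixture(scope="session")
def default_pools():
    return build_default_pools()


@pytest.fixture(scope="session")
def eur_pool(default_pools):
    return next(p for p in default_pools if p.ancestry_label == "EUR")


@pytest.fixture(scope="session")
def eur_cohort(eur_pool):
    """A medium EUR-only cohort with the default disease/serology models."""
    return sample_cohort([eur_pool], n_per_ancestry=10_000, seed=42)


@pytest.fixture(scope="session")
def small_mixed_cohort(default_pools):
    """A small all-ancestry cohort with a 10-SNP panel attached."""
    return sample_cohort(
        default_pools,
        n_per_ancestry=1500,
        seed=7,
        snp_panel=default_snp_panel(10),
    )


def make_participant_frame(rows):
    """Build a minimal participant table from dicts, filling defaults."""
    defaults = {
        "ancestry": "EUR", "age": 40, "sex": "F",
        "ced_ehr": False, "ced_survey": False,
        "DQA1_1": "DQA1*01:01", "DQB1_1": "DQB1*05:01",
        "DQA1_2": "DQA1*01:01", "DQB1_2": "DQB1*05:01",
    }
    filled = []
    for i, row in enumerate(rows):
        r = dict(defaults)
        r.setdefault("id", f"X{i:04d}")
        r.update(row)
        filled.append(r)
    return pd.DataFrame(filled)
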