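"""Shared fixtures: synthetic cohorts at the sizes the checks need.

Session-scoped so the expensive cohorts are generated once per run.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd
import pytest

import mortgap as mg

RECOVERY_RR = (1.8, 1.75, 1.6, 1.35, 1.0)
RECOVERY_SEED = 11


@pytest.fixture(scope="session")
def recovery_cohort():
    """50 000 participants, direct-only education effects at the headline RRs."""
    cfg = mg.study_cohort_config(50_000, seed=RECOVERY_SEED, effects="direct_only",
                                 education_rr=RECOVERY_RR)
    return cfg, mg.generate_cohort(cfg)


@pytest.fixture(scope="session")
def recovery_records(recovery_cohort):
    _, cohort = recovery_cohort
    kept, _ = mg.apply_exclusions(cohort)
    return mg.lexis_split(mg.derive_categories(kept), 35, 75)


@pytest.fixture(scope="session")
def recovery_fit(recovery_records):
    return mg.fit_stratified_cox(recovery_records, "education")


@pytest.fixture(scope="session")
def small_cohort():
    """20 000 participants under the default (partially mediated) settings."""
    cfg = mg.study_cohort_config(20_000, seed=3)
    return cfg, mg.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_records(small_cohort):
    _, cohort = small_cohort
    kept, _ = mg.apply_exclusions(cohort)
    return mg.lexis_split(mg.derive_categories(kept), 35, 75)


def make_cohort_row(i=0, sex="male", entry_age=50.0, entry_date="2000-06-15",
                    education="secondary", death_date=None, death_cause=None,
                    **overrides):
    """One schema-complete participant row for hand-built cohort tables."""
    row = {
        "id": f"T{i:04d}", "sex": sex, "entry_age": entry_age,
        "entry_date": pd.Timestamp(entry_date), "education": education,
        "income_monthly": 2000.0, "sdi": 0.75, "smoking": "never",
        "alcohol": "never", "activity": "none", "height": 165.0, "weight": 70.0,
        "waist": 90.0, "hip": 100.0, "sbp": 125.0, "dbp": 82.0, "hba1c": 5.5,
        "diabetes_diagnosed": False,
        "death_date": pd.Timestamp(death_date) if death_date else pd.NaT,
        "death_cause": death_cause, "cause_uncertain": False,
    }
    row.update(overrides)
    return row


def make_cohort(rows):
    return pd.DataFrame(rows)


@pytest.fixture()
def toy_cohort_factory():
    return make_cohort_row
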