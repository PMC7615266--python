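"""Cohort eligibility rules and derived analysis categories.

Exclusions are applied sequentially, in a fixed order, so each participant is
counted against the first rule they violate:

1. aged 85 or older at recruitment;
2. missing education;
3. missing or implausibly extreme covariate data (height outside 120-200 cm,
   weight outside 35-250 kg, BMI outside 15-60 kg/m^2, waist outside
   60-180 cm, hip outside 70-180 cm, waist-to-hip ratio outside 0.5-1.5);
4. uncertain mortality linkage / cause of death.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._vocab import (
    DIABETES_UNKNOWN,
    EDUCATION_LEVELS,
    INCOME_LEVELS,
)

__all__ = ["ExclusionLedger", "apply_exclusions", "derive_categories"]

# Covariates that must be present (rule 3); income and area deprivation are
# analysed but their absence is an analysable category, not an exclusion.
REQUIRED_COVARIATES = ("smoking", "alcohol", "activity",
                       "height", "weight", "waist", "hip", "sbp")

EXTREME_LIMITS = {
    "height": (120.0, 200.0),
    "weight": (35.0, 250.0),
    "bmi": (15.0, 60.0),
    "waist": (60.0, 180.0),
    "hip": (70.0, 180.0),
    "whr": (0.5, 1.5),
}

RULE_NAMES = ("age_ge_cap", "missing_education", "missing_or_extreme_covariate",
              "uncertain_cause")


@dataclass
class ExclusionLedger:
    """Sequential record of how many participants each rule removed."""

    total_in: int
    steps: list[tuple[str, int, int]] = field(default_factory=list)  # (rule, n_excluded, n_remaining)

    @property
    def total_out(self) -> int:
        return self.steps[-1][2] if self.steps else self.total_in

    @property
    def counts(self) -> tuple[int, ...]:
        return tuple(n for _, n, _ in self.steps)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["rule", "n_excluded", "n_remaining"])

    def validate(self) -> None:
        remaining = self.total_in
        for rule, n_exc, n_rem in self.steps:
            if n_rem != remaining - n_exc:
                raise AssertionError(f"ledger inconsistent at rule {rule}")
            remaining = n_rem
        if self.total_in - sum(self.counts) != self.total_out:
            raise AssertionError("ledger does not conserve participants")


def _is_missing(col: pd.Series) -> np.ndarray:
    return col.isna().to_numpy() if col is not None else np.ones(0, dtype=bool)


def apply_exclusions(cohort: pd.DataFrame, age_cap: float = 85.0
                     ) -> tuple[pd.DataFrame, ExclusionLedger]:
    """Apply the eligibility rules in fixed order and return survivors + ledger."""
    df = cohort
    ledger = ExclusionLedger(total_in=len(df))

    height = pd.to_numeric(df.get("height"), errors="coerce")
    weight = pd.to_numeric(df.get("weight"), errors="coerce")
    waist = pd.to_numeric(df.get("waist"), errors="coerce")
    hip = pd.to_numeric(df.get("hip"), errors="coerce")
    bmi = weight / (height / 100.0) ** 2
    whr = waist / hip
    derived = {"height": height, "weight": weight, "waist": waist, "hip": hip,
               "bmi": bmi, "whr": whr}

    viol = {}
    viol["age_ge_cap"] = pd.to_numeric(df["entry_age"], errors="coerce") >= age_cap
    viol["missing_education"] = df["education"].isna()

    missing_cov = np.zeros(len(df), dtype=bool)
    for name in REQUIRED_COVARIATES:
        if name not in df.columns:
            raise ValueError(f"cohort lacks required covariate column {name!r}")
        missing_cov |= df[name].isna().to_numpy()
    extreme = np.zeros(len(df), dtype=bool)
    for name, (lo, hi) in EXTREME_LIMITS.items():
        x = derived[name]
        extreme |= ((x < lo) | (x > hi)).fillna(False).to_numpy()
    viol["missing_or_extreme_covariate"] = pd.Series(missing_cov | extreme, index=df.index)

    unc = df.get("cause_uncertain")
    if unc is None:
        unc = pd.Series(False, index=df.index)
    viol["uncertain_cause"] = unc.fillna(False).astype(bool)

    keep = pd.Series(True, index=df.index)
    for rule in RULE_NAMES:
        hits = viol[rule].fillna(False).astype(bool) & keep
        keep &= ~hits
        ledger.steps.append((rule, int(hits.sum()), int(keep.sum())))
    ledger.validate()
    return df.loc[keep].copy(), ledger


def _income_category(income: pd.Series) -> pd.Series:
    """Monthly income bands, left-closed on the lower bound of each band.

    Absent or zero income maps to the dedicated 'no income reported' category,
    which is kept as its own level (it may reflect high or low socioeconomic
    position) and never imputed.
    """
    x = pd.to_numeric(income, errors="coerce")
    out = pd.Series(INCOME_LEVELS[0], index=income.index, dtype=object)
    out[(x > 0) & (x < 1500)] = "lt_1500"
    out[(x >= 1500) & (x < 3000)] = "1500_to_3000"
    out[(x >= 3000) & (x < 4500)] = "3000_to_4500"
    out[x >= 4500] = "ge_4500"
    return out


def _sdi_quintile(sdi: pd.Series, reference: np.ndarray | None) -> pd.Series:
    """Quintile group 1-5 from the 20/40/60/80 empirical percentiles.

    Cut-points come from ``reference`` when given, else from the input column;
    values exactly on a cut-point fall in the lower quintile.
    """
    x = pd.to_numeric(sdi, errors="coerce")
    ref = np.asarray(reference, dtype=float) if reference is not None else x.dropna().to_numpy()
    out = pd.Series(pd.NA, index=sdi.index, dtype="object")
    if ref.size == 0:
        return out
    cuts = np.percentile(ref, [20, 40, 60, 80], method="linear")
    ok = x.notna()
    q = 1 + np.searchsorted(cuts, x[ok].to_numpy(), side="left")
    out[ok] = [str(v) for v in q]
    return out


def _diabetes_category(diagnosed: pd.Series, hba1c: pd.Series) -> pd.Series:
    """Five diabetes strata; undiagnosed diabetes requires HbA1c strictly >6.5%."""
    d = diagnosed.fillna(False).astype(bool)
    h = pd.to_numeric(hba1c, errors="coerce")
    out = pd.Series(DIABETES_UNKNOWN, index=diagnosed.index, dtype=object)
    out[~d & (h <= 6.5)] = "no_diabetes"
    out[~d & (h > 6.5)] = "undiagnosed"
    out[d & (h < 9.0)] = "diagnosed_hba1c_lt9"
    out[d & (h >= 9.0) & (h < 11.0)] = "diagnosed_hba1c_9_to_11"
    out[d & (h >= 11.0)] = "diagnosed_hba1c_ge11"
    return out


def derive_categories(cohort: pd.DataFrame,
                      sdi_reference: np.ndarray | None = None) -> pd.DataFrame:
    """Add derived quantities and analysis categories to a post-exclusion table.

    Adds ``bmi``, ``whr``, ``income_cat``, ``sdi_quintile`` and
    ``diabetes_cat``. The lifestyle variables (smoking, alcohol, activity) and
    education are already categorical tokens and are validated, not recoded.
    """
    df = cohort.copy()
    bad_edu = df["education"].dropna()[~df["education"].dropna().isin(EDUCATION_LEVELS)]
    if len(bad_edu):
        raise ValueError(f"unknown education levels: {sorted(set(bad_edu))}")
    height = pd.to_numeric(df["height"], errors="coerce")
    df["bmi"] = pd.to_numeric(df["weight"], errors="coerce") / (height / 100.0) ** 2
    df["whr"] = pd.to_numeric(df["waist"], errors="coerce") / pd.to_numeric(df["hip"],
                                                                            errors="coerce")
    df["income_cat"] = _income_category(df["income_monthly"]) if "income_monthly" in df \
        else INCOME_LEVELS[0]
    df["sdi_quintile"] = _sdi_quintile(df["sdi"], sdi_reference) if "sdi" in df else pd.NA
    df["diabetes_cat"] = _diabetes_category(
        df.get("diabetes_diagnosed", pd.Series(False, index=df.index)),
        df.get("hba1c", pd.Series(np.nan, index=df.index)))
    return df
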