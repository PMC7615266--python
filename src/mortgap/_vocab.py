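"""Controlled vocabularies for categorical study variables and cause-of-death groups."""

from __future__ import annotations

EDUCATION_LEVELS = (
    "none",
    "primary_incomplete",
    "primary_complete",
    "secondary",
    "tertiary",
)
EDUCATION_REFERENCE = "tertiary"

SMOKING_LEVELS = ("never", "former", "occasional", "lt10_per_day", "ge10_per_day")
ALCOHOL_LEVELS = ("never", "former", "lt_weekly", "le2_days_per_week", "gt2_days_per_week")
ACTIVITY_LEVELS = ("none", "le2_per_week", "ge3_per_week")

DIABETES_LEVELS = (
    "no_diabetes",
    "undiagnosed",
    "diagnosed_hba1c_lt9",
    "diagnosed_hba1c_9_to_11",
    "diagnosed_hba1c_ge11",
)
DIABETES_UNKNOWN = "unknown"

INCOME_LEVELS = (
    "no_income",
    "lt_1500",
    "1500_to_3000",
    "3000_to_4500",
    "ge_4500",
)

SEXES = ("male", "female")

# Atomic cause-of-death tokens assigned to individual deaths.
CAUSE_TOKENS = (
    "cardiac",
    "stroke",
    "hepatobiliary",
    "renal_and_acute_diabetic",
    "cancer",
    "respiratory",
    "infectious",
    "other",
)

# Analysable cause groups: each maps to the set of atomic tokens it covers.
CAUSE_GROUPS: dict[str, frozenset[str]] = {
    "all": frozenset(CAUSE_TOKENS),
    "vascular": frozenset({"cardiac", "stroke"}),
    "cardiac": frozenset({"cardiac"}),
    "stroke": frozenset({"stroke"}),
    "hepatobiliary": frozenset({"hepatobiliary"}),
    "renal_and_acute_diabetic": frozenset({"renal_and_acute_diabetic"}),
    "cancer": frozenset({"cancer"}),
    "respiratory": frozenset({"respiratory"}),
    "infectious": frozenset({"infectious"}),
    "other": frozenset({"other"}),
}

CATEGORY_LEVELS: dict[str, tuple[str, ...]] = {
    "education": EDUCATION_LEVELS,
    "smoking": SMOKING_LEVELS,
    "alcohol": ALCOHOL_LEVELS,
    "activity": ACTIVITY_LEVELS,
    "diabetes_cat": DIABETES_LEVELS + (DIABETES_UNKNOWN,),
    "income_cat": INCOME_LEVELS,
    "sex": SEXES,
    "sdi_quintile": ("1", "2", "3", "4", "5"),
}


def resolve_cause_group(name: str) -> frozenset[str]:
    """Return the atomic cause tokens covered by a cause-group name."""
    try:
        return CAUSE_GROUPS[name]
    except KeyError:
        known = ", ".join(sorted(CAUSE_GROUPS))
        raise ValueError(f"unknown cause group {name!r}; known groups: {known}") from None
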