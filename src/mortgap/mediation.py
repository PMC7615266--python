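"""Mediation by proportional attenuation.

Quantifies how much of the education-mortality association is accounted for by
lifestyle and physiological covariates, using two complementary summaries:

* the proportional change in the likelihood-ratio chi-square for the exposure
  when it is added to a model with versus without the candidate mediators; and
* the proportional change in a contrast's log rate ratio between the
  unadjusted and mediator-adjusted fits.

These are attenuation measures, not counterfactual (natural direct/indirect)
effects: mediators may or may not lie on the causal pathway, and single
baseline measurements understate long-run exposure to a mediator. Percentages
can fall outside [0, 100] (suppression) and are reported as computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from ._vocab import EDUCATION_REFERENCE
from .cox import StratifiedCoxModel, StratifiedCoxResults

__all__ = [
    "DEFAULT_MEDIATORS",
    "MediationResult",
    "lr_chi2",
    "proportion_explained",
    "logrr_attenuation",
    "mediation_analysis",
]

# Lifestyle factors, adiposity (as its continuous components), diabetes status
# and systolic blood pressure.
DEFAULT_MEDIATORS = ("smoking", "alcohol", "activity",
                     "weight", "height", "waist", "hip", "diabetes_cat", "sbp")


def _complete_rows(records: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Rows complete on every model column, so nested likelihoods are comparable."""
    mask = pd.Series(True, index=records.index)
    for c in columns:
        mask &= records[c].notna()
        if c == "diabetes_cat":
            mask &= records[c] != "unknown"
    return records.loc[mask]


def lr_chi2(records: pd.DataFrame, base_covariates: tuple[str, ...],
            exposure: str = "education", reference: str | None = None,
            **fit_kwargs) -> tuple[float, int]:
    """Likelihood-ratio chi-square for adding ``exposure`` to a base model.

    Both nested fits run on the identical record set (rows missing any model
    column are dropped from both). Returns (chi2, df) with df = observed
    exposure levels - 1.
    """
    base = tuple(base_covariates)
    sub = _complete_rows(records, list(base) + [exposure])
    full_model = StratifiedCoxModel(sub, exposure=exposure, reference=reference,
                                    adjust=base)
    full = full_model.fit(**fit_kwargs)
    if base:
        base_fit = StratifiedCoxModel(sub, exposure=None, adjust=base).fit(**fit_kwargs)
        ll_base = base_fit.loglik
        if not base_fit.converged:
            warnings.warn("base model did not converge; chi2 may be unreliable")
    else:
        ll_base = full.loglik_null
    if not full.converged:
        warnings.warn("full model did not converge; chi2 may be unreliable")
    chi2 = 2.0 * (full.loglik - ll_base)
    if chi2 < -1e-6:
        raise AssertionError(
            f"nested likelihoods out of order (chi2 = {chi2:.3g}); "
            "record sets are probably not identical")
    df = len(full_model.exposure_levels) - 1
    return max(chi2, 0.0), df


def proportion_explained(chi2_unadjusted: float, chi2_adjusted: float) -> float:
    """Percent of the exposure chi-square removed by adjusting for mediators."""
    if chi2_unadjusted <= 0:
        raise ValueError("proportion explained is undefined when the unadjusted "
                         "chi-square is zero")
    return 100.0 * (1.0 - chi2_adjusted / chi2_unadjusted)


def logrr_attenuation(fit_unadjusted: StratifiedCoxResults,
                      fit_adjusted: StratifiedCoxResults,
                      contrast: tuple) -> float:
    """Percent attenuation of a contrast's log rate ratio after adjustment."""
    unadj = fit_unadjusted.contrast_log_rr(contrast)
    adj = fit_adjusted.contrast_log_rr(contrast)
    if unadj == 0:
        raise ValueError("attenuation is undefined when the unadjusted log RR is zero")
    return 100.0 * (1.0 - adj / unadj)


@dataclass
class MediationResult:
    exposure: str
    mediators: tuple[str, ...]
    contrast: tuple
    df: int
    chi2_unadjusted: float
    chi2_adjusted: float
    prop_chi2_explained: float
    logrr_unadjusted: pd.Series
    logrr_adjusted: pd.Series
    prop_logrr_explained: float
    prop_logrr_by_level: pd.Series = field(default_factory=pd.Series)
    n_records: int = 0
    n_events: int = 0

    def summary(self) -> str:
        lines = [
            f"Mediation of the {self.exposure}-mortality association "
            f"({len(self.mediators)} mediators)",
            f"LR chi2 for {self.exposure} (df={self.df}): "
            f"{self.chi2_unadjusted:.2f} unadjusted -> {self.chi2_adjusted:.2f} adjusted",
            f"proportion of chi2 explained: {self.prop_chi2_explained:.1f}%",
            f"log RR attenuation for {self.contrast[0]} vs {self.contrast[1]}: "
            f"{self.prop_logrr_explained:.1f}%",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "exposure": self.exposure,
            "mediators": list(self.mediators),
            "contrast": list(self.contrast),
            "df": self.df,
            "chi2_unadjusted": self.chi2_unadjusted,
            "chi2_adjusted": self.chi2_adjusted,
            "prop_chi2_explained_pct": self.prop_chi2_explained,
            "logrr_unadjusted": self.logrr_unadjusted.to_dict(),
            "logrr_adjusted": self.logrr_adjusted.to_dict(),
            "prop_logrr_explained_pct": self.prop_logrr_explained,
            "prop_logrr_by_level_pct": self.prop_logrr_by_level.to_dict(),
            "n_records": self.n_records,
            "n_events": self.n_events,
        }


def mediation_analysis(records: pd.DataFrame, exposure: str = "education",
                       mediators: tuple[str, ...] = DEFAULT_MEDIATORS,
                       contrast: tuple | None = None,
                       reference: str | None = None,
                       **fit_kwargs) -> MediationResult:
    """Full attenuation analysis on one cause-specific record set.

    Continuous mediators enter linearly; categorical mediators by their study
    groupings. Rows missing any mediator (or with unknown diabetes status) are
    excluded from every nested model so the likelihoods are comparable.
    """
    mediators = tuple(mediators)
    sub = _complete_rows(records, list(mediators) + [exposure])
    if contrast is None:
        ref = reference or (EDUCATION_REFERENCE if exposure == "education" else None)
        fit_probe = StratifiedCoxModel(sub, exposure=exposure, reference=reference)
        ref = fit_probe.reference
        first = fit_probe.exposure_levels[0]
        contrast = (first if first != ref else fit_probe.exposure_levels[1], ref)

    unadj = StratifiedCoxModel(sub, exposure=exposure, reference=reference).fit(**fit_kwargs)
    adj = StratifiedCoxModel(sub, exposure=exposure, reference=reference,
                             adjust=mediators).fit(**fit_kwargs)
    base = StratifiedCoxModel(sub, exposure=None, adjust=mediators).fit(**fit_kwargs)
    df = len(unadj.model.exposure_levels) - 1
    chi2_u = max(unadj.lr_chi2, 0.0)
    chi2_a = max(2.0 * (adj.loglik - base.loglik), 0.0)

    lr_u = unadj.exposure_log_rr()
    lr_a = adj.exposure_log_rr()
    by_level = {}
    for level in lr_u.index:
        if level == unadj.model.reference or lr_u[level] == 0:
            continue
        by_level[level] = 100.0 * (1.0 - lr_a[level] / lr_u[level])

    return MediationResult(
        exposure=exposure, mediators=mediators, contrast=contrast, df=df,
        chi2_unadjusted=chi2_u, chi2_adjusted=chi2_a,
        prop_chi2_explained=proportion_explained(chi2_u, chi2_a),
        logrr_unadjusted=lr_u, logrr_adjusted=lr_a,
        prop_logrr_explained=logrr_attenuation(unadj, adj, contrast),
        prop_logrr_by_level=pd.Series(by_level),
        n_records=len(sub), n_events=int(sub["event"].sum()),
    )
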