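"""Configuration objects for the synthetic-cohort generator and pipeline runs.

The generator is parameterised by three blocks:

* demographic structure (sex split, education distribution per sex, entry ages,
  recruitment window, administrative censoring date);
* a mediator model giving the distribution of each lifestyle / physiological
  covariate conditional on education;
* a hazard model: piecewise-constant cause-specific baseline mortality rates on
  5-year age bands by sex, direct log rate ratios per education level, and log
  hazard-ratio coefficients through which mediators transmit part of the
  education effect.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

from ._vocab import (
    ACTIVITY_LEVELS,
    ALCOHOL_LEVELS,
    CAUSE_TOKENS,
    EDUCATION_LEVELS,
    SEXES,
    SMOKING_LEVELS,
)


class ConfigurationError(ValueError):
    """Raised when a generator or run configuration violates its invariants."""


def _check_probs(name: str, probs: Sequence[float], length: int) -> tuple[float, ...]:
    p = tuple(float(x) for x in probs)
    if len(p) != length:
        raise ConfigurationError(f"{name} must have length {length}, got {len(p)}")
    if any(x < 0 for x in p):
        raise ConfigurationError(f"{name} has negative entries: {p}")
    if abs(sum(p) - 1.0) > 1e-12:
        raise ConfigurationError(f"{name} must sum to 1 (got {sum(p)!r})")
    return p


@dataclass(frozen=True)
class ContinuousMediator:
    """Gaussian covariate with education-specific means.

    ``means`` run from no education to tertiary; ``female_shift`` is added to
    the mean for women; values are truncated below at ``lower`` when given.
    """

    means: tuple[float, float, float, float, float]
    sd: float
    female_shift: float = 0.0
    lower: float | None = None

    def mean_for(self, education_idx: np.ndarray, is_female: np.ndarray) -> np.ndarray:
        m = np.asarray(self.means, dtype=float)[education_idx]
        return m + self.female_shift * is_female


@dataclass(frozen=True)
class CategoricalMediator:
    """Multinomial covariate with education-specific level probabilities."""

    levels: tuple[str, ...]
    # probs[k] is the probability vector over levels for education level k.
    probs: tuple[tuple[float, ...], ...]

    def __post_init__(self) -> None:
        if len(self.probs) != len(EDUCATION_LEVELS):
            raise ConfigurationError(
                f"categorical mediator needs one probability row per education level"
            )
        for k, row in enumerate(self.probs):
            _check_probs(f"probs[{k}]", row, len(self.levels))


@dataclass(frozen=True)
class MediatorModel:
    continuous: Mapping[str, ContinuousMediator]
    categorical: Mapping[str, CategoricalMediator]
    # Probability of having previously diagnosed diabetes, per education level.
    diabetes_prevalence: tuple[float, float, float, float, float] = (
        0.21, 0.19, 0.145, 0.085, 0.06,
    )
    # HbA1c (%) among the undiagnosed: Gaussian with education-specific means;
    # among the diagnosed the mean is shifted upwards and the spread widens.
    hba1c_means: tuple[float, float, float, float, float] = (5.85, 5.80, 5.70, 5.55, 5.45)
    hba1c_sd: float = 0.9
    hba1c_diagnosed_shift: float = 2.3
    hba1c_diagnosed_sd: float = 1.8


@dataclass(frozen=True)
class HazardModel:
    """Piecewise-constant cause-specific mortality model.

    ``band_edges`` define half-open 5-year age bands [e_i, e_{i+1}); the hazard
    for cause c, sex s in band b for a participant with education k and
    mediator vector m is

        baseline_rates[c][s][b] * exp(education_log_rr[c][k] + sum_j effect_j(m_j))

    where continuous mediator effects are ``coef * (x - center)`` and
    categorical effects are per-level log hazard ratios.
    """

    baseline_rates: Mapping[str, Mapping[str, tuple[float, ...]]]
    education_log_rr: Mapping[str, tuple[float, float, float, float, float]]
    mediator_log_hr: Mapping[str, Mapping[str, object]] = field(default_factory=dict)
    continuous_centers: Mapping[str, float] = field(default_factory=dict)
    band_edges: tuple[float, ...] = tuple(float(a) for a in range(35, 90, 5))

    @property
    def causes(self) -> tuple[str, ...]:
        return tuple(self.baseline_rates)

    @property
    def n_bands(self) -> int:
        return len(self.band_edges) - 1

    def validate(self) -> None:
        edges = np.asarray(self.band_edges, dtype=float)
        if len(edges) < 2 or np.any(np.diff(edges) <= 0):
            raise ConfigurationError("band_edges must be strictly increasing")
        for cause, by_sex in self.baseline_rates.items():
            for sex in SEXES:
                if sex not in by_sex:
                    raise ConfigurationError(f"baseline_rates[{cause!r}] missing sex {sex!r}")
                rates = np.asarray(by_sex[sex], dtype=float)
                if rates.shape != (self.n_bands,):
                    raise ConfigurationError(
                        f"baseline_rates[{cause!r}][{sex!r}] must have {self.n_bands} entries"
                    )
                if np.any(rates < 0) or not np.all(np.isfinite(rates)):
                    raise ConfigurationError(
                        f"baseline_rates[{cause!r}][{sex!r}] must be finite and >= 0"
                    )
            if cause not in self.education_log_rr:
                raise ConfigurationError(f"education_log_rr missing cause {cause!r}")
            if len(self.education_log_rr[cause]) != len(EDUCATION_LEVELS):
                raise ConfigurationError(
                    f"education_log_rr[{cause!r}] must have {len(EDUCATION_LEVELS)} entries"
                )


@dataclass(frozen=True)
class EntryAgeDistribution:
    """Truncated-normal (or uniform) entry-age distribution on [low, high)."""

    kind: str = "truncated_normal"  # or "uniform"
    mean: float = 50.7
    sd: float = 10.8
    low: float = 35.0
    high: float = 85.0

    def __post_init__(self) -> None:
        if not (35.0 <= self.low < self.high <= 85.0):
            raise ConfigurationError("entry ages must lie within [35, 85)")
        if self.kind not in ("truncated_normal", "uniform"):
            raise ConfigurationError(f"unknown entry-age distribution kind {self.kind!r}")


@dataclass(frozen=True)
class CohortConfig:
    n_participants: int
    seed: int = 0
    fraction_male: float = 0.33
    education_probs_by_sex: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_EDUCATION_PROBS)
    )
    entry_age_distribution: EntryAgeDistribution = field(default_factory=EntryAgeDistribution)
    recruitment_start: dt.date = dt.date(1998, 1, 1)
    recruitment_end: dt.date = dt.date(2004, 12, 31)
    admin_censor_date: dt.date = dt.date(2020, 12, 31)
    mediator_model: MediatorModel = field(default_factory=lambda: default_mediator_model())
    hazard_model: HazardModel = field(default_factory=lambda: default_hazard_model())

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ConfigurationError("n_participants must be positive")
        if not 0.0 <= self.fraction_male <= 1.0:
            raise ConfigurationError("fraction_male must lie in [0, 1]")
        for sex in SEXES:
            if sex not in self.education_probs_by_sex:
                raise ConfigurationError(f"education_probs_by_sex missing {sex!r}")
            _check_probs(
                f"education_probs_by_sex[{sex!r}]",
                self.education_probs_by_sex[sex],
                len(EDUCATION_LEVELS),
            )
        if self.recruitment_end < self.recruitment_start:
            raise ConfigurationError("recruitment window is empty")
        self.hazard_model.validate()


def _normalised(probs: Sequence[float]) -> tuple[float, ...]:
    total = float(sum(probs))
    return tuple(float(p) / total for p in probs)


# Education distributions by sex: the male percentages printed for the study
# (7/16/24/27/25) sum to 99% from rounding and are renormalised here.
DEFAULT_EDUCATION_PROBS: dict[str, tuple[float, ...]] = {
    "male": _normalised((0.07, 0.16, 0.24, 0.27, 0.25)),
    "female": _normalised((0.13, 0.21, 0.29, 0.25, 0.12)),
}


def default_mediator_model() -> MediatorModel:
    """Education-graded mediator distributions.

    Continuous means decline (blood pressure, adiposity measures, HbA1c) or are
    flat-to-rising (height) with increasing education, mirroring the observed
    cross-tabulated gradients; categorical probabilities follow the same
    qualitative pattern. Mediators are conditionally independent given
    education and sex.
    """
    continuous = {
        "height": ContinuousMediator((163.5, 164.0, 164.5, 165.0, 166.0), 7.0, -11.0, lower=130.0),
        "weight": ContinuousMediator((74.0, 75.0, 75.0, 75.0, 75.0), 12.0, -4.0, lower=38.0),
        "waist": ContinuousMediator((97.0, 96.5, 95.0, 93.5, 92.5), 11.0, -1.0, lower=62.0),
        "hip": ContinuousMediator((103.0, 104.0, 104.0, 103.5, 103.0), 9.0, 4.0, lower=72.0),
        "sbp": ContinuousMediator((133.5, 131.0, 127.5, 124.0, 123.0), 16.0, 0.0, lower=70.0),
        "dbp": ContinuousMediator((85.0, 84.5, 84.0, 82.5, 82.0), 10.0, -1.0, lower=40.0),
        "sdi": ContinuousMediator((0.72, 0.73, 0.745, 0.765, 0.815), 0.10, 0.0, lower=0.0),
    }
    categorical = {
        "smoking": CategoricalMediator(
            SMOKING_LEVELS,
            (
                (0.60, 0.18, 0.09, 0.09, 0.04),
                (0.55, 0.19, 0.10, 0.11, 0.05),
                (0.50, 0.19, 0.12, 0.12, 0.07),
                (0.45, 0.19, 0.14, 0.14, 0.08),
                (0.43, 0.21, 0.14, 0.14, 0.08),
            ),
        ),
        "alcohol": CategoricalMediator(
            ALCOHOL_LEVELS,
            (
                (0.30, 0.18, 0.30, 0.16, 0.06),
                (0.25, 0.16, 0.33, 0.19, 0.07),
                (0.21, 0.13, 0.36, 0.21, 0.09),
                (0.18, 0.11, 0.38, 0.23, 0.10),
                (0.16, 0.08, 0.40, 0.25, 0.11),
            ),
        ),
        "activity": CategoricalMediator(
            ACTIVITY_LEVELS,
            (
                (0.89, 0.04, 0.07),
                (0.85, 0.06, 0.09),
                (0.80, 0.08, 0.12),
                (0.74, 0.11, 0.15),
                (0.64, 0.13, 0.23),
            ),
        ),
    }
    return MediatorModel(continuous=continuous, categorical=categorical)


# Gompertz-like all-cause baseline: doubling roughly every 8 years of age,
# anchored so that with study-like entry ages and ~19 years of follow-up about
# 9-10% of participants die before age 75 (the anchor applies at the reference
# education level with mediators at their centres; population-average rates
# sit above it through the education and mediator effects).
_BAND_STARTS = np.arange(35.0, 85.0, 5.0)
_ALL_CAUSE_BASE = 0.00035 * np.exp(np.log(2.0) / 8.0 * (_BAND_STARTS - 35.0))
_SEX_FACTOR = {"male": 1.3, "female": 0.85}

# Share of deaths by cause, loosely matching the premature-mortality cause mix
# (vascular ~27% split cardiac/stroke, renal & acute diabetic ~20%, ...).
_CAUSE_SHARE = {
    "cardiac": 0.19,
    "stroke": 0.06,
    "hepatobiliary": 0.085,
    "renal_and_acute_diabetic": 0.20,
    "cancer": 0.165,
    "respiratory": 0.13,
    "infectious": 0.065,
    "other": 0.105,
}

# Headline all-cause education rate ratios (none, incomplete primary, complete
# primary, secondary, tertiary) used as the default total effect.
DEFAULT_EDUCATION_RR = (1.8, 1.75, 1.6, 1.35, 1.0)


def flat_mediator_model() -> MediatorModel:
    """Mediators with NO education gradient (every level shares one distribution).

    Used for null-calibration studies: the covariates exist and vary between
    people but carry no part of any education-mortality association, neither
    through their distribution nor (when hazard coefficients are off) through
    the hazard.
    """
    base = default_mediator_model()
    continuous = {
        name: ContinuousMediator((spec.means[2],) * 5, spec.sd, spec.female_shift,
                                 lower=spec.lower)
        for name, spec in base.continuous.items()
    }
    categorical = {
        name: CategoricalMediator(spec.levels, (spec.probs[2],) * 5)
        for name, spec in base.categorical.items()
    }
    return MediatorModel(
        continuous=continuous, categorical=categorical,
        diabetes_prevalence=(0.145,) * 5,
        hba1c_means=(5.7,) * 5,
    )


def default_hazard_model(
    education_rr: Sequence[float] = DEFAULT_EDUCATION_RR,
    mediation: str = "partial",
) -> HazardModel:
    """Build the default cause-specific hazard model.

    Parameters
    ----------
    education_rr
        Total (direct, when ``mediation != 'partial'``) education rate ratios,
        reference tertiary.
    mediation
        ``"partial"``: a direct education effect plus mediator coefficients
        (blood pressure, diabetes, smoking, activity) that add an indirect,
        education-graded component. ``"none"``: the whole ``education_rr`` is
        direct and no mediator enters the hazard. ``"full"``: no direct
        education term; mediators carry the entire association.
    """
    if mediation not in ("partial", "none", "full"):
        raise ConfigurationError(f"unknown mediation mode {mediation!r}")

    baseline = {
        cause: {
            sex: tuple(_ALL_CAUSE_BASE * _SEX_FACTOR[sex] * share)
            for sex in SEXES
        }
        for cause, share in _CAUSE_SHARE.items()
    }
    log_rr = tuple(float(np.log(r)) for r in education_rr)

    if mediation == "none":
        edu = {cause: log_rr for cause in CAUSE_TOKENS}
        med: dict[str, dict[str, object]] = {}
        centers: dict[str, float] = {}
    else:
        med_common: dict[str, object] = {
            "sbp": 0.022,
            "diabetes_diagnosed": (0.0, 0.9),  # (no, yes) log hazard ratios
            "smoking": (0.0, 0.15, 0.15, 0.35, 0.55),
            "activity": (0.30, 0.12, 0.0),
        }
        med = {cause: dict(med_common) for cause in CAUSE_TOKENS}
        centers = {"sbp": 126.0}
        if mediation == "full":
            edu = {cause: (0.0,) * 5 for cause in CAUSE_TOKENS}
        else:
            # Direct share of the log rate ratio; the rest flows via mediators.
            edu = {cause: tuple(0.6 * b for b in log_rr) for cause in CAUSE_TOKENS}

    return HazardModel(
        baseline_rates=baseline,
        education_log_rr=edu,
        mediator_log_hr=med,
        continuous_centers=centers,
    )


def study_cohort_config(
    n_participants: int,
    seed: int = 0,
    effects: str = "default",
    education_rr: Sequence[float] = DEFAULT_EDUCATION_RR,
) -> CohortConfig:
    """Convenience constructor for the standard study-like generator settings.

    ``effects`` selects the education-effect architecture:

    * ``"default"`` — direct education effect plus mediated component;
    * ``"direct_only"`` — the full ``education_rr`` acts directly, mediators
      carry nothing (mediation analyses should attenuate ~0%);
    * ``"mediated_only"`` — no direct term, mediators carry everything
      (mediation analyses should explain ~100%);
    * ``"mediator_free"`` — the full ``education_rr`` acts directly AND the
      mediators carry no education gradient at all, so adjusting for them is
      asymptotically inert (attenuation analyses should report ~0%);
    * ``"null"`` — education unrelated to mortality (direct and mediated
      components both switched off).
    """
    mediator_model = None
    if effects == "default":
        hm = default_hazard_model(education_rr, mediation="partial")
    elif effects == "direct_only":
        hm = default_hazard_model(education_rr, mediation="none")
    elif effects == "mediated_only":
        hm = default_hazard_model(education_rr, mediation="full")
    elif effects == "mediator_free":
        hm = default_hazard_model(education_rr, mediation="none")
        mediator_model = flat_mediator_model()
    elif effects == "null":
        hm = default_hazard_model((1.0,) * 5, mediation="none")
    else:
        raise ConfigurationError(f"unknown effects mode {effects!r}")
    kwargs = {"mediator_model": mediator_model} if mediator_model is not None else {}
    return CohortConfig(n_participants=n_participants, seed=seed, hazard_model=hm,
                        **kwargs)


def config_digest(obj) -> str:
    """Stable short hash of a (nested dataclass) configuration object."""
    import hashlib
    import json

    def encode(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return {f.name: encode(getattr(o, f.name)) for f in dataclasses.fields(o)}
        if isinstance(o, Mapping):
            return {str(k): encode(v) for k, v in o.items()}
        if isinstance(o, (list, tuple)):
            return [encode(v) for v in o]
        if isinstance(o, (dt.date, dt.datetime)):
            return o.isoformat()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        return o

    payload = json.dumps(encode(obj), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
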