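"""Synthetic cohort generator.

Emulates the statistical structure the downstream analysis assumes: a
recruitment wave of adults aged 35-84, education distributions differing by
sex, education-graded lifestyle and physiological covariates, cause-specific
mortality with piecewise-constant baseline hazards on 5-year age bands and
proportional education/mediator effects, and administrative censoring at a
fixed calendar date.

Event times are drawn exactly by inversion of the piecewise-constant
cumulative hazard (no discrete-time approximation), and the cause of death is
drawn proportional to the cause-specific hazards at the event age.
"""

from __future__ import annotations

import datetime as dt
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._vocab import EDUCATION_LEVELS, SEXES
from .config import CohortConfig, ConfigurationError, HazardModel

__all__ = ["generate_cohort", "simulate_event_time", "inject_defects"]

DAYS_PER_YEAR = 365.25

# Personal monthly income (pesos): log-normal location by education for men;
# women's incomes scale down sharply and 'no income reported' is much more
# common among women, as observed at recruitment.
_INCOME_LOG_MEDIAN = np.log(np.array([1300.0, 1700.0, 2350.0, 3200.0, 6700.0]))
_INCOME_LOG_SD = 0.9
_INCOME_FEMALE_LOG_SHIFT = np.log(0.25)
_P_NO_INCOME = {"male": 0.08, "female": 0.64}


def _mediator_effect_columns(hazard_model: HazardModel, cause: str,
                             cols: Mapping[str, np.ndarray],
                             edu_idx: np.ndarray) -> np.ndarray:
    """Sum of mediator log hazard-ratio terms for one cause."""
    effects = hazard_model.mediator_log_hr.get(cause, {})
    total = np.zeros(len(edu_idx))
    for name, spec in effects.items():
        if name == "education":
            continue
        col = cols[name]
        if np.isscalar(spec):
            center = hazard_model.continuous_centers.get(name, 0.0)
            total += float(spec) * (np.asarray(col, dtype=float) - center)
        else:
            per_level = np.asarray(spec, dtype=float)
            total += per_level[np.asarray(col, dtype=int)]
    return total


def _linear_predictors(hazard_model: HazardModel, edu_idx: np.ndarray,
                       cols: Mapping[str, np.ndarray]) -> np.ndarray:
    """(n, n_causes) matrix of log relative hazards, causes in model order."""
    lp = np.empty((len(edu_idx), len(hazard_model.causes)))
    for c, cause in enumerate(hazard_model.causes):
        log_rr = np.asarray(hazard_model.education_log_rr[cause], dtype=float)
        lp[:, c] = log_rr[edu_idx] + _mediator_effect_columns(hazard_model, cause, cols, edu_idx)
    return lp


def _simulate_events(entry_ages: np.ndarray, sexes: np.ndarray, lp: np.ndarray,
                     hazard_model: HazardModel, u_time: np.ndarray,
                     u_cause: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised piecewise-exponential competing-cause sampler.

    Returns (event_age, cause_index); event_age is NaN and cause_index -1
    where no event occurs before the end of the hazard grid.
    """
    edges = np.asarray(hazard_model.band_edges, dtype=float)
    n_bands = len(edges) - 1
    causes = hazard_model.causes
    n = len(entry_ages)
    if np.any(entry_ages < edges[0]) or np.any(entry_ages >= edges[-1]):
        raise ValueError("entry ages must lie within the hazard age grid")
    if not np.all(np.isfinite(lp)):
        raise ValueError("linear predictors must be finite")

    event_age = np.full(n, np.nan)
    cause_idx = np.full(n, -1, dtype=int)
    w = np.exp(lp)  # (n, C)

    for sex in SEXES:
        m = sexes == sex
        if not m.any():
            continue
        base = np.array([hazard_model.baseline_rates[c][sex] for c in causes], dtype=float)
        rates = w[m] @ base                      # (n_s, n_bands) total hazard
        a = entry_ages[m]
        # Time at risk inside each band given entry age a.
        width = np.clip(edges[1:][None, :] - np.maximum(edges[:-1][None, :], a[:, None]),
                        0.0, None)
        cum = np.cumsum(rates * width, axis=1)
        target = -np.log(u_time[m])
        band = np.sum(cum < target[:, None], axis=1)
        hit = band < n_bands
        bi = band[hit]
        rows = np.flatnonzero(m)[hit]
        prev = np.where(bi > 0, np.take_along_axis(cum[hit], np.maximum(bi - 1, 0)[:, None],
                                                   axis=1).ravel(), 0.0)
        rate_b = np.take_along_axis(rates[hit], bi[:, None], axis=1).ravel()
        start_b = np.maximum(edges[bi], a[hit])
        event_age[rows] = start_b + (target[hit] - prev) / rate_b
        # Cause drawn proportional to cause-specific hazard at the event age.
        cause_rates = w[rows] * base[:, bi].T    # (n_hit, C)
        cdf = np.cumsum(cause_rates, axis=1)
        u = u_cause[rows] * cdf[:, -1]
        cause_idx[rows] = np.sum(cdf < u[:, None], axis=1)
    return event_age, np.minimum(cause_idx, len(causes) - 1)


def simulate_event_time(entry_age: float, sex: str,
                        linear_predictors_by_cause: Mapping[str, float] | Sequence[float],
                        hazard_model: HazardModel,
                        u_time: float | None = None, u_cause: float | None = None,
                        rng: np.random.Generator | None = None):
    """Draw one (event_age, cause) pair for a single participant.

    ``u_time`` and ``u_cause`` are the underlying uniforms; pass them
    explicitly for reproducible single draws, otherwise supply ``rng``.
    Returns ``(None, None)`` when no event occurs before the end of the grid.
    """
    hazard_model.validate()
    if u_time is None or u_cause is None:
        if rng is None:
            raise ValueError("provide (u_time, u_cause) or rng")
        u_time = rng.random() if u_time is None else u_time
        u_cause = rng.random() if u_cause is None else u_cause
    causes = hazard_model.causes
    if isinstance(linear_predictors_by_cause, Mapping):
        lp = np.array([[linear_predictors_by_cause[c] for c in causes]], dtype=float)
    else:
        lp = np.asarray(linear_predictors_by_cause, dtype=float).reshape(1, -1)
        if lp.shape[1] != len(causes):
            raise ValueError("one linear predictor per cause required")
    age, cidx = _simulate_events(
        np.array([float(entry_age)]), np.array([sex], dtype=object), lp,
        hazard_model, np.array([float(u_time)]), np.array([float(u_cause)]),
    )
    if np.isnan(age[0]):
        return None, None
    return float(age[0]), causes[int(cidx[0])]


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate one row per participant under ``config``.

    Deterministic given (config, seed): all draws are vectorised against a
    fixed family of substreams derived from the root seed, and a participant's
    draws depend only on their row index, never on other rows.
    """
    n = config.n_participants
    root = np.random.SeedSequence(config.seed)
    children = iter(root.spawn(16))

    def stream() -> np.random.Generator:
        return np.random.default_rng(next(children))

    rng_sex, rng_age, rng_date, rng_edu = stream(), stream(), stream(), stream()
    rng_cont, rng_cat = stream(), stream()
    rng_diab, rng_hba1c, rng_income = stream(), stream(), stream()
    rng_time, rng_cause = stream(), stream()

    is_male = rng_sex.random(n) < config.fraction_male
    sexes = np.where(is_male, "male", "female").astype(object)
    is_female = (~is_male).astype(float)

    dist = config.entry_age_distribution
    u_age = rng_age.random(n)
    if dist.kind == "uniform":
        entry_age = dist.low + u_age * (dist.high - dist.low)
    else:
        a = (dist.low - dist.mean) / dist.sd
        b = (dist.high - dist.mean) / dist.sd
        entry_age = stats.truncnorm.ppf(u_age, a, b, loc=dist.mean, scale=dist.sd)
        entry_age = np.clip(entry_age, dist.low, np.nextafter(dist.high, -np.inf))

    window_days = (config.recruitment_end - config.recruitment_start).days
    offset_days = np.floor(rng_date.random(n) * (window_days + 1)).astype(int)
    entry_date = pd.Timestamp(config.recruitment_start) + pd.to_timedelta(offset_days, unit="D")

    edu_idx = np.empty(n, dtype=int)
    u_edu = rng_edu.random(n)
    for sex in SEXES:
        m = sexes == sex
        cdf = np.cumsum(config.education_probs_by_sex[sex])
        edu_idx[m] = np.searchsorted(cdf, u_edu[m], side="left")
    edu_idx = np.minimum(edu_idx, len(EDUCATION_LEVELS) - 1)

    cols: dict[str, np.ndarray] = {}
    mm = config.mediator_model
    for name, spec in mm.continuous.items():
        x = rng_cont.normal(spec.mean_for(edu_idx, is_female), spec.sd)
        if spec.lower is not None:
            x = np.maximum(x, spec.lower)
        cols[name] = x
    cols["sdi"] = np.minimum(cols["sdi"], 1.0) if "sdi" in cols else np.full(n, np.nan)
    for name, spec in mm.categorical.items():
        cum = np.cumsum(np.asarray(spec.probs, dtype=float), axis=1)[edu_idx]
        u = rng_cat.random(n)
        cols[name] = np.minimum(np.sum(cum < u[:, None], axis=1), len(spec.levels) - 1)

    diagnosed = rng_diab.random(n) < np.asarray(mm.diabetes_prevalence)[edu_idx]
    cols["diabetes_diagnosed"] = diagnosed.astype(int)
    hba1c_mean = np.asarray(mm.hba1c_means)[edu_idx] + mm.hba1c_diagnosed_shift * diagnosed
    hba1c_sd = np.where(diagnosed, mm.hba1c_diagnosed_sd, mm.hba1c_sd)
    hba1c = np.maximum(rng_hba1c.normal(hba1c_mean, hba1c_sd), 3.5)

    no_income = rng_income.random(n) < np.where(is_male, _P_NO_INCOME["male"],
                                                _P_NO_INCOME["female"])
    income = np.exp(rng_income.normal(
        _INCOME_LOG_MEDIAN[edu_idx] + _INCOME_FEMALE_LOG_SHIFT * is_female, _INCOME_LOG_SD))
    income[no_income] = np.nan

    lp = _linear_predictors(config.hazard_model, edu_idx, cols)
    event_age, cause_idx = _simulate_events(
        entry_age, sexes, lp, config.hazard_model,
        rng_time.random(n), rng_cause.random(n))

    died = ~np.isnan(event_age)
    death_date = pd.Series(pd.NaT, index=range(n), dtype="datetime64[ns]")
    death_date[died] = entry_date[died] + pd.to_timedelta(
        (event_age[died] - entry_age[died]) * DAYS_PER_YEAR, unit="D")
    death_date = death_date.dt.normalize().copy()
    # Administrative censoring: deaths after the censor date are not observed.
    late = died & (death_date > pd.Timestamp(config.admin_censor_date)).to_numpy()
    died &= ~late
    death_date = death_date.where(pd.Series(died, index=death_date.index), pd.NaT)

    causes = np.asarray(config.hazard_model.causes, dtype=object)
    death_cause = np.where(died, causes[np.maximum(cause_idx, 0)], None)

    smoking_levels = np.asarray(mm.categorical["smoking"].levels, dtype=object)
    alcohol_levels = np.asarray(mm.categorical["alcohol"].levels, dtype=object)
    activity_levels = np.asarray(mm.categorical["activity"].levels, dtype=object)

    return pd.DataFrame({
        "id": [f"P{i:07d}" for i in range(n)],
        "sex": sexes,
        "entry_age": np.round(entry_age, 6),
        "entry_date": entry_date.normalize(),
        "education": np.asarray(EDUCATION_LEVELS, dtype=object)[edu_idx],
        "income_monthly": np.round(income, 2),
        "sdi": np.round(cols["sdi"], 4),
        "smoking": smoking_levels[cols["smoking"]],
        "alcohol": alcohol_levels[cols["alcohol"]],
        "activity": activity_levels[cols["activity"]],
        "height": np.round(cols["height"], 1),
        "weight": np.round(cols["weight"], 1),
        "waist": np.round(cols["waist"], 1),
        "hip": np.round(cols["hip"], 1),
        "sbp": np.round(cols["sbp"], 1),
        "dbp": np.round(cols["dbp"], 1),
        "hba1c": np.round(hba1c, 2),
        "diabetes_diagnosed": diagnosed,
        "death_date": death_date,
        "death_cause": death_cause,
        "cause_uncertain": np.zeros(n, dtype=bool),
    })


def inject_defects(cohort: pd.DataFrame, n_overage: int, n_missing: int,
                   n_extreme: int, n_uncertain: int, seed: int,
                   extreme_field: str = "height") -> pd.DataFrame:
    """Make disjoint row sets ineligible, one defect class per set.

    * ``n_overage`` rows get an entry age of 85 or older;
    * ``n_missing`` rows lose their education value;
    * ``n_extreme`` rows get ``extreme_field`` pushed past its plausibility
      threshold (height defaults to 112 cm, below the 120 cm floor);
    * ``n_uncertain`` rows are flagged as having uncertain mortality linkage.
    """
    counts = (n_overage, n_missing, n_extreme, n_uncertain)
    if any(c < 0 for c in counts):
        raise ValueError("defect counts must be non-negative")
    total = sum(counts)
    if total > len(cohort):
        raise ValueError(f"requested {total} defect rows but table has {len(cohort)}")
    out = cohort.copy()
    rng = np.random.default_rng(seed)
    pick = rng.permutation(len(out))[:total]
    splits = np.cumsum(counts)[:-1]
    overage, missing, extreme, uncertain = np.split(pick, splits)

    out.iloc[overage, out.columns.get_loc("entry_age")] = 85.0 + 10.0 * rng.random(len(overage))
    out.iloc[missing, out.columns.get_loc("education")] = None
    extreme_values = {"height": 112.0, "weight": 20.0, "waist": 30.0, "hip": 40.0}
    if extreme_field not in extreme_values:
        raise ValueError(f"no extreme value defined for field {extreme_field!r}")
    out.iloc[extreme, out.columns.get_loc(extreme_field)] = extreme_values[extreme_field]
    out.iloc[uncertain, out.columns.get_loc("cause_uncertain")] = True
    return out
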