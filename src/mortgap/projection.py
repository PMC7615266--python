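"""Calibrating study rate ratios to national death rates and projecting survival.

Given a national life table (annual death rates by sex and 5-year age band),
education prevalences p_k and study rate ratios r_k (reference level r = 1),
the anchor rate for a band with national rate N is

    A = N / sum_k p_k r_k,

so level k's absolute rate is r_k * A and the prevalence-weighted average of
the calibrated rates reproduces N exactly. Survival from the window start and
partial (truncated) life expectancy follow from the piecewise-constant hazard:

    S(a_{m}) = exp(-sum_{bands below m} width * rate),
    PLE = sum_bands S(a) * (1 - exp(-width * rate)) / rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from ._vocab import EDUCATION_LEVELS, EDUCATION_REFERENCE, SEXES
from .config import DEFAULT_EDUCATION_PROBS

__all__ = [
    "LifeTable",
    "ProjectionResult",
    "calibrate_rates",
    "survival_curve",
    "partial_life_expectancy",
    "EducationProjection",
    "synthetic_national_life_table",
]


@dataclass(frozen=True)
class LifeTable:
    """National annual death rates per (sex, 5-year age band)."""

    table: pd.DataFrame  # columns: sex, age_lo, age_hi, rate

    def __post_init__(self) -> None:
        required = {"sex", "age_lo", "age_hi", "rate"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"life table missing columns: {sorted(missing)}")
        if (self.table["rate"] < 0).any():
            raise ValueError("life-table rates must be non-negative")

    def bands(self, sex: str, start: float, end: float) -> tuple[np.ndarray, np.ndarray]:
        """Band edges and rates covering [start, end); raises on gaps."""
        sub = self.table[self.table["sex"] == sex].sort_values("age_lo")
        sel = sub[(sub["age_hi"] > start) & (sub["age_lo"] < end)]
        if sel.empty:
            raise ValueError(f"life table has no {sex} bands covering [{start}, {end})")
        lo = sel["age_lo"].to_numpy(dtype=float)
        hi = sel["age_hi"].to_numpy(dtype=float)
        if lo[0] > start or hi[-1] < end or np.any(lo[1:] != hi[:-1]):
            raise ValueError(f"life table bands do not tile [{start}, {end}) for {sex}")
        edges = np.concatenate([np.maximum(lo, start), [min(hi[-1], end)]])
        edges[-1] = min(edges[-1], end)
        return edges, sel["rate"].to_numpy(dtype=float)


def calibrate_rates(national_rate: float, prevalences: Sequence[float],
                    rr: Sequence[float], tol: float = 1e-9) -> np.ndarray:
    """Education-specific absolute rates whose prevalence-weighted mean is national.

    ``rr`` carries the rate ratio per level with the reference equal to 1;
    level k receives rate r_k * A with A = national / sum(p * r).
    """
    p = np.asarray(prevalences, dtype=float)
    r = np.asarray(rr, dtype=float)
    if p.shape != r.shape:
        raise ValueError("prevalences and rate ratios must have equal length")
    if abs(p.sum() - 1.0) > tol:
        raise ValueError(f"prevalences must sum to 1 (got {p.sum()!r})")
    if np.any(r <= 0):
        raise ValueError("rate ratios must be strictly positive")
    if national_rate < 0:
        raise ValueError("national rate must be non-negative")
    anchor = national_rate / float(p @ r)
    return r * anchor


def survival_curve(rates: Sequence[float], edges: Sequence[float]) -> np.ndarray:
    """Survival at band edges under a piecewise-constant hazard; S(edges[0]) = 1."""
    rates = np.asarray(rates, dtype=float)
    edges = np.asarray(edges, dtype=float)
    if len(edges) != len(rates) + 1 or np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be increasing with one more entry than rates")
    cumhaz = np.concatenate([[0.0], np.cumsum(rates * np.diff(edges))])
    return np.exp(-cumhaz)


def partial_life_expectancy(survival: Sequence[float], edges: Sequence[float]) -> float:
    """Expected years lived in [edges[0], edges[-1]): the integral of S.

    Within each band the hazard implied by the survival curve is constant, so
    the band contribution is S(a) * (1 - e^{-w*lam}) / lam, with the w * S(a)
    limit as lam -> 0.
    """
    S = np.asarray(survival, dtype=float)
    edges = np.asarray(edges, dtype=float)
    if len(S) != len(edges) or np.any(np.diff(edges) <= 0):
        raise ValueError("survival must be evaluated at the band edges")
    if S[0] != 1.0 and not np.isclose(S[0], 1.0):
        raise ValueError("survival must start at 1")
    if np.any(np.diff(S) > 1e-12):
        raise ValueError("survival must be non-increasing")
    w = np.diff(edges)
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = -(np.log(S[1:]) - np.log(S[:-1])) / w
    out = 0.0
    for Sa, width, l in zip(S[:-1], w, lam):
        if l <= 1e-12:
            out += width * Sa
        else:
            out += Sa * (1.0 - np.exp(-width * l)) / l
    return float(out)


@dataclass
class ProjectionResult:
    """Calibrated education-specific rates, survival curves and expectancy gaps."""

    rates: pd.DataFrame        # sex, education, age_lo, age_hi, annual_rate
    survival: pd.DataFrame     # sex, education (or 'national'), age, survival
    life_expectancy: pd.DataFrame  # sex, education, ple_years, gap_vs_reference_years
    start: float
    end: float
    reference: str = EDUCATION_REFERENCE

    def gap(self, sex: str, level_a: str, level_b: str) -> float:
        le = self.life_expectancy
        a = float(le.loc[(le["sex"] == sex) & (le["education"] == level_a), "ple_years"].iloc[0])
        b = float(le.loc[(le["sex"] == sex) & (le["education"] == level_b), "ple_years"].iloc[0])
        return a - b

    def summary(self) -> str:
        lines = [f"Projection over ages [{self.start:g}, {self.end:g}) "
                 f"(reference: {self.reference})"]
        for sex in self.life_expectancy["sex"].unique():
            sub = self.life_expectancy[self.life_expectancy["sex"] == sex]
            for _, row in sub.iterrows():
                lines.append(
                    f"  {sex:<7} {row['education']:<20} PLE {row['ple_years']:6.2f} y   "
                    f"gap vs {self.reference}: {row['gap_vs_reference_years']:+5.2f} y")
        return "\n".join(lines)


class EducationProjection:
    """Project education-specific survival by calibrating RRs to a life table.

    Parameters
    ----------
    life_table
        National annual death rates by sex and age band.
    rr_by_sex
        Per sex, either one rate-ratio vector over the education levels
        (reference = 1) or a mapping of age ranges to vectors, e.g.
        ``{(35, 60): rr_young, (60, 70): rr_old}``; the band's lower edge
        selects the applicable vector.
    prevalences_by_sex
        Education prevalences per sex; defaults to the study distribution.
    """

    def __init__(self, life_table: LifeTable,
                 rr_by_sex: Mapping[str, object],
                 prevalences_by_sex: Mapping[str, Sequence[float]] | None = None,
                 levels: Sequence[str] = EDUCATION_LEVELS,
                 reference: str = EDUCATION_REFERENCE,
                 start: float = 35.0, end: float = 70.0):
        self.life_table = life_table
        self.rr_by_sex = rr_by_sex
        self.prevalences_by_sex = prevalences_by_sex or DEFAULT_EDUCATION_PROBS
        self.levels = tuple(levels)
        self.reference = reference
        self.start = float(start)
        self.end = float(end)

    def _rr_for_band(self, sex: str, band_lo: float) -> np.ndarray:
        spec = self.rr_by_sex[sex]
        if isinstance(spec, Mapping):
            for (lo, hi), vec in spec.items():
                if lo <= band_lo < hi:
                    return np.asarray(vec, dtype=float)
            raise ValueError(f"no rate-ratio vector covers band starting at {band_lo}")
        return np.asarray(spec, dtype=float)

    def run(self) -> ProjectionResult:
        rate_rows, surv_rows, le_rows = [], [], []
        ref_idx = self.levels.index(self.reference)
        for sex in SEXES:
            if sex not in self.rr_by_sex:
                continue
            edges, national = self.life_table.bands(sex, self.start, self.end)
            p = np.asarray(self.prevalences_by_sex[sex], dtype=float)
            per_level = np.empty((len(self.levels), len(national)))
            for b, (lo, nat) in enumerate(zip(edges[:-1], national)):
                rr = self._rr_for_band(sex, lo)
                per_level[:, b] = calibrate_rates(nat, p, rr)
            nat_S = survival_curve(national, edges)
            for age, s in zip(edges, nat_S):
                surv_rows.append({"sex": sex, "education": "national",
                                  "age": age, "survival": s})
            ples = []
            for k, level in enumerate(self.levels):
                S = survival_curve(per_level[k], edges)
                ple = partial_life_expectancy(S, edges)
                ples.append(ple)
                for b, lo in enumerate(edges[:-1]):
                    rate_rows.append({"sex": sex, "education": level, "age_lo": lo,
                                      "age_hi": edges[b + 1],
                                      "annual_rate": per_level[k, b]})
                for age, s in zip(edges, S):
                    surv_rows.append({"sex": sex, "education": level,
                                      "age": age, "survival": s})
            for k, level in enumerate(self.levels):
                le_rows.append({"sex": sex, "education": level, "ple_years": ples[k],
                                "gap_vs_reference_years": ples[k] - ples[ref_idx]})
        return ProjectionResult(
            rates=pd.DataFrame(rate_rows), survival=pd.DataFrame(surv_rows),
            life_expectancy=pd.DataFrame(le_rows), start=self.start, end=self.end,
            reference=self.reference)


def synthetic_national_life_table(start: float = 35.0, end: float = 75.0) -> LifeTable:
    """A synthetic stand-in national life table (NOT observed national data).

    Gompertz-like annual death rates by sex on 5-year bands, with male rates
    above female, for demonstrations and tests when no national life table
    file is supplied.
    """
    rows = []
    for sex, scale in (("male", 0.0020), ("female", 0.0013)):
        for lo in np.arange(start, end, 5.0):
            rate = scale * np.exp(np.log(2.0) / 8.0 * (lo - 35.0))
            rows.append({"sex": sex, "age_lo": lo, "age_hi": lo + 5.0,
                         "rate": round(float(rate), 6)})
    return LifeTable(pd.DataFrame(rows))
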