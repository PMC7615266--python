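"""Generator contracts: determinism, marginal fidelity, event-time sampling."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

import mortgap as mg
from mortgap.config import ConfigurationError, default_hazard_model
from mortgap.simulate import _simulate_events


def _flat_hazard_model(rate, edges=None, causes=("other",)):
    edges = tuple(edges) if edges is not None else tuple(float(a) for a in range(35, 90, 5))
    n_bands = len(edges) - 1
    return mg.HazardModel(
        baseline_rates={c: {"male": (rate,) * n_bands, "female": (rate,) * n_bands}
                        for c in causes},
        education_log_rr={c: (0.0,) * 5 for c in causes},
        band_edges=edges,
    )


class TestGenerateCohort:
    def test_deterministic_and_sized(self):
        cfg = mg.study_cohort_config(2_000, seed=42)
        a = mg.generate_cohort(cfg)
        b = mg.generate_cohort(mg.study_cohort_config(2_000, seed=42))
        assert len(a) == 2_000
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_zero_hazard_means_everyone_censored(self):
        cfg = mg.CohortConfig(n_participants=500, seed=1,
                              hazard_model=_flat_hazard_model(0.0))
        cohort = mg.generate_cohort(cfg)
        assert cohort["death_date"].isna().all()

    def test_education_marginals_match_config(self, recovery_cohort):
        cfg, cohort = recovery_cohort
        for sex in ("male", "female"):
            sub = cohort[cohort["sex"] == sex]
            probs = np.asarray(cfg.education_probs_by_sex[sex])
            obs = (sub["education"].value_counts(normalize=True)
                   .reindex(mg.EDUCATION_LEVELS).fillna(0.0).to_numpy())
            se = np.sqrt(probs * (1 - probs) / len(sub))
            assert np.all(np.abs(obs - probs) <= 3 * se)

    def test_no_death_after_admin_censoring(self, small_cohort):
        cfg, cohort = small_cohort
        deaths = cohort["death_date"].dropna()
        assert (deaths <= pd.Timestamp(cfg.admin_censor_date)).all()
        # a death date implies a cause, and vice versa
        assert (cohort["death_cause"].notna() == cohort["death_date"].notna()).all()

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ConfigurationError):
            mg.CohortConfig(n_participants=10, education_probs_by_sex={
                "male": (0.5, 0.2, 0.1, 0.1, 0.05), "female": (0.2,) * 5})
        with pytest.raises(ConfigurationError):
            mg.CohortConfig(n_participants=0)

    def test_negative_baseline_rate_rejected(self):
        with pytest.raises(ConfigurationError):
            mg.CohortConfig(n_participants=10, hazard_model=_flat_hazard_model(-0.01))


class TestEventSampler:
    def test_exponential_mean_recovered(self):
        # Constant hazard 0.02/yr on an effectively unbounded grid: the event
        # age is 35 + Exp(0.02), mean 85.
        lam = 0.02
        hm = _flat_hazard_model(lam, edges=np.arange(35.0, 2035.0, 100.0))
        n = 100_000
        rng = np.random.default_rng(7)
        ages, _ = _simulate_events(np.full(n, 35.0), np.array(["male"] * n, dtype=object),
                                   np.zeros((n, 1)), hm, rng.random(n), rng.random(n))
        assert np.isnan(ages).mean() < 1e-3
        mean = np.nanmean(ages)
        se = (1 / lam) / np.sqrt(n)
        assert abs(mean - (35 + 1 / lam)) <= 3 * se

    def test_competing_cause_share(self):
        # Hazards lam and 2*lam: two thirds of events carry the second cause.
        lam = 0.01
        edges = tuple(np.arange(35.0, 2035.0, 100.0))
        n_bands = len(edges) - 1
        hm = mg.HazardModel(
            baseline_rates={"cancer": {"male": (lam,) * n_bands, "female": (lam,) * n_bands},
                            "other": {"male": (2 * lam,) * n_bands,
                                      "female": (2 * lam,) * n_bands}},
            education_log_rr={"cancer": (0.0,) * 5, "other": (0.0,) * 5},
            band_edges=edges)
        n = 50_000
        rng = np.random.default_rng(8)
        ages, cidx = _simulate_events(np.full(n, 35.0), np.array(["female"] * n, dtype=object),
                                      np.zeros((n, 2)), hm, rng.random(n), rng.random(n))
        events = cidx[~np.isnan(ages)]
        share = (events == 1).mean()
        se = np.sqrt(share * (1 - share) / len(events))
        assert abs(share - 2 / 3) <= 3 * se

    def test_doubling_rates_halves_times(self):
        # With a constant total hazard, inversion maps the same uniform to a
        # time exactly half as long when every rate doubles.
        n = 2_000
        rng = np.random.default_rng(9)
        u_t, u_c = rng.random(n), rng.random(n)
        entry = np.full(n, 35.0)
        sexes = np.array(["male"] * n, dtype=object)
        edges = np.arange(35.0, 4035.0, 200.0)
        t1, _ = _simulate_events(entry, sexes, np.zeros((n, 1)),
                                 _flat_hazard_model(0.005, edges), u_t, u_c)
        t2, _ = _simulate_events(entry, sexes, np.zeros((n, 1)),
                                 _flat_hazard_model(0.010, edges), u_t, u_c)
        both = ~np.isnan(t1) & ~np.isnan(t2)
        np.testing.assert_allclose(t2[both] - 35.0, (t1[both] - 35.0) / 2.0, rtol=1e-10)
        assert abs(np.median(t2[both] - 35.0) * 2 - np.median(t1[both] - 35.0)) < 1e-9

    def test_scalar_interface_and_grid_exit(self):
        hm = _flat_hazard_model(0.02)
        # total cumulative hazard over [40, 85) is 0.9, so a uniform below
        # exp(-0.9) maps beyond the grid: no event
        age, cause = mg.simulate_event_time(40.0, "male", {"other": 0.0}, hm,
                                            u_time=0.1, u_cause=0.5)
        assert age is None and cause is None
        age, cause = mg.simulate_event_time(40.0, "male", {"other": 0.0}, hm,
                                            u_time=0.5, u_cause=0.5)
        assert cause == "other"
        # inversion of a constant hazard: age = 40 + (-ln u)/0.02
        assert age == pytest.approx(40.0 + (-np.log(0.5)) / 0.02)

    def test_entry_age_outside_grid_rejected(self):
        hm = _flat_hazard_model(0.01)
        with pytest.raises(ValueError):
            mg.simulate_event_time(90.0, "male", {"other": 0.0}, hm,
                                   u_time=0.5, u_cause=0.5)


class TestInjectDefects:
    def test_requested_counts_created(self, small_cohort):
        _, cohort = small_cohort
        clean, _ = mg.apply_exclusions(cohort)
        clean = clean.head(1_000).reset_index(drop=True)
        out = mg.inject_defects(clean, 10, 5, 3, 2, seed=5)
        assert (out["entry_age"] >= 85).sum() == 10
        assert out["education"].isna().sum() == 5
        assert ((out["height"] < 120) | (out["height"] > 200)).sum() == 3
        assert out["cause_uncertain"].sum() == 2

    def test_zero_counts_identity(self, small_cohort):
        _, cohort = small_cohort
        clean = cohort.head(100).reset_index(drop=True)
        out = mg.inject_defects(clean, 0, 0, 0, 0, seed=1)
        pd.testing.assert_frame_equal(out, clean)

    def test_overflow_rejected(self, small_cohort):
        _, cohort = small_cohort
        with pytest.raises(ValueError):
            mg.inject_defects(cohort.head(10), 5, 4, 3, 2, seed=1)
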