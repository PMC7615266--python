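"""Rate calibration, survival curves and partial life expectancy."""

import numpy as np
import pandas as pd
import pytest

import mortgap as mg
from tests._oracles import quadrature_life_expectancy

EDGES_35_70 = np.arange(35.0, 71.0, 5.0)


class TestCalibrateRates:
    def test_unit_rr_degenerates_to_national(self):
        rates = mg.calibrate_rates(0.013, [0.2] * 5, [1.0] * 5)
        np.testing.assert_allclose(rates, 0.013)

    def test_prevalence_weighted_identity(self):
        # male education prevalences with the study's male all-cause RRs;
        # the printed percentages sum to 99% and are renormalised.
        p = np.array([0.07, 0.16, 0.24, 0.27, 0.25]) / 0.99
        r = np.array([1.62, 1.67, 1.62, 1.34, 1.0])
        rates = mg.calibrate_rates(0.01, p, r)
        anchor = 0.01 / float(p @ r)        # independent arithmetic
        np.testing.assert_allclose(rates, r * anchor, rtol=1e-14)
        assert float(p @ rates) == pytest.approx(0.01, abs=1e-12)
        # against the unnormalised prevalences the anchor is 0.01/1.3812
        assert 0.01 / float(np.array([0.07, 0.16, 0.24, 0.27, 0.25]) @ r) \
            == pytest.approx(0.0072401, abs=5e-7)

    def test_homogeneous_in_national_rate(self):
        p = [0.2, 0.2, 0.2, 0.2, 0.2]
        r = [2.0, 1.7, 1.4, 1.2, 1.0]
        np.testing.assert_allclose(mg.calibrate_rates(0.02, p, r),
                                   2.0 * mg.calibrate_rates(0.01, p, r), rtol=1e-14)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            mg.calibrate_rates(0.01, [0.3, 0.3, 0.3, 0.3, 0.3], [1.0] * 5)
        with pytest.raises(ValueError, match="positive"):
            mg.calibrate_rates(0.01, [0.2] * 5, [1.0, 1.0, 0.0, 1.0, 1.0])


class TestSurvivalCurve:
    def test_constant_hazard_closed_form(self):
        S = mg.survival_curve([0.02] * 7, EDGES_35_70)
        assert S[0] == 1.0
        assert S[-1] == pytest.approx(np.exp(-0.7), abs=1e-10)

    def test_zero_hazard_is_flat_one(self):
        np.testing.assert_allclose(mg.survival_curve([0.0] * 7, EDGES_35_70), 1.0)

    def test_pointwise_monotone_in_rates(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            a = rng.uniform(0, 0.05, size=7)
            b = a + rng.uniform(0, 0.02, size=7)
            Sa = mg.survival_curve(a, EDGES_35_70)
            Sb = mg.survival_curve(b, EDGES_35_70)
            assert np.all(Sb <= Sa + 1e-15)

    def test_band_gap_rejected(self):
        lt = mg.LifeTable(pd.DataFrame({
            "sex": ["male", "male"], "age_lo": [35.0, 45.0],
            "age_hi": [40.0, 50.0], "rate": [0.01, 0.02]}))
        with pytest.raises(ValueError, match="tile"):
            lt.bands("male", 35.0, 50.0)


class TestPartialLifeExpectancy:
    def test_constant_hazard_closed_form(self):
        S = mg.survival_curve([0.02] * 7, EDGES_35_70)
        ple = mg.partial_life_expectancy(S, EDGES_35_70)
        assert ple == pytest.approx((1 - np.exp(-0.7)) / 0.02, abs=1e-10)

    def test_zero_hazard_full_window(self):
        ple = mg.partial_life_expectancy(np.ones(len(EDGES_35_70)), EDGES_35_70)
        assert ple == pytest.approx(35.0, abs=1e-12)

    def test_gap_matches_quadrature_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(5):
            ra = rng.uniform(0.001, 0.04, size=7)
            rb = rng.uniform(0.001, 0.04, size=7)
            gap = (mg.partial_life_expectancy(mg.survival_curve(ra, EDGES_35_70),
                                              EDGES_35_70)
                   - mg.partial_life_expectancy(mg.survival_curve(rb, EDGES_35_70),
                                                EDGES_35_70))
            oracle = (quadrature_life_expectancy(ra, EDGES_35_70)
                      - quadrature_life_expectancy(rb, EDGES_35_70))
            assert gap == pytest.approx(oracle, abs=1e-6)


class TestEducationProjection:
    def _lt(self):
        return mg.synthetic_national_life_table(35.0, 70.0)

    def test_unit_rr_reduces_to_national_curve(self):
        proj = mg.EducationProjection(self._lt(), {"male": np.ones(5),
                                                   "female": np.ones(5)}).run()
        surv = proj.survival
        for sex in ("male", "female"):
            nat = surv[(surv["sex"] == sex) & (surv["education"] == "national")]
            for level in mg.EDUCATION_LEVELS:
                grp = surv[(surv["sex"] == sex) & (surv["education"] == level)]
                np.testing.assert_allclose(grp["survival"].to_numpy(),
                                           nat["survival"].to_numpy(), rtol=1e-12)
        assert np.allclose(proj.life_expectancy["gap_vs_reference_years"], 0.0)

    def test_weighted_identity_in_every_band(self):
        rr = np.array([1.8, 1.75, 1.6, 1.35, 1.0])
        proj = mg.EducationProjection(self._lt(), {"male": rr, "female": rr}).run()
        lt = self._lt().table
        for (sex, lo), grp in proj.rates.groupby(["sex", "age_lo"]):
            p = np.asarray(mg.DEFAULT_EDUCATION_PROBS[sex])
            grp = grp.set_index("education").loc[list(mg.EDUCATION_LEVELS)]
            nat = float(lt[(lt["sex"] == sex) & (lt["age_lo"] == lo)]["rate"].iloc[0])
            assert float(p @ grp["annual_rate"].to_numpy()) == pytest.approx(
                nat, abs=1e-14)

    def test_age_range_specific_rr_vectors(self):
        rr_young = np.array([2.0, 1.8, 1.6, 1.3, 1.0])
        rr_old = np.array([1.5, 1.4, 1.3, 1.2, 1.0])
        spec = {(35.0, 60.0): rr_young, (60.0, 70.0): rr_old}
        proj = mg.EducationProjection(self._lt(), {"male": spec, "female": spec}).run()
        rates = proj.rates
        male_none = rates[(rates["sex"] == "male") & (rates["education"] == "none")]
        male_tert = rates[(rates["sex"] == "male") & (rates["education"] == "tertiary")]
        ratio = (male_none.set_index("age_lo")["annual_rate"]
                 / male_tert.set_index("age_lo")["annual_rate"])
        assert np.allclose(ratio[ratio.index < 60], 2.0)
        assert np.allclose(ratio[ratio.index >= 60], 1.5)

    def test_gap_antisymmetry_and_ordering(self):
        rr = np.array([1.8, 1.75, 1.6, 1.35, 1.0])
        proj = mg.EducationProjection(self._lt(), {"male": rr, "female": rr}).run()
        g = proj.gap("male", "none", "tertiary")
        assert g == pytest.approx(-proj.gap("male", "tertiary", "none"))
        assert g < 0  # the uneducated group loses years
        ple = proj.life_expectancy.query("sex == 'male'").set_index("education")[
            "ple_years"]
        assert ple["none"] < ple["secondary"] < ple["tertiary"]

    def test_raising_one_rr_hurts_that_group_and_helps_the_rest(self):
        # The calibration holds the prevalence-weighted average fixed, so
        # raising one level's RR raises that level's absolute rates (its PLE
        # falls) while the anchor rate drops, lowering every other level's
        # rates (their PLEs rise, the reference's included).
        rng = np.random.default_rng(30)
        lt = self._lt()
        for _ in range(10):
            rr = np.concatenate([np.sort(rng.uniform(1.0, 2.5, size=4))[::-1], [1.0]])
            bumped = rng.integers(0, 4)
            worse = rr.copy()
            worse[bumped] += rng.uniform(0.1, 0.5)
            a = mg.EducationProjection(lt, {"male": rr, "female": rr}).run()
            b = mg.EducationProjection(lt, {"male": worse, "female": worse}).run()
            pa = a.life_expectancy.query("sex=='male'").set_index("education")["ple_years"]
            pb = b.life_expectancy.query("sex=='male'").set_index("education")["ple_years"]
            for k, level in enumerate(mg.EDUCATION_LEVELS):
                if k == bumped:
                    assert pb[level] < pa[level]
                else:
                    assert pb[level] >= pa[level] - 1e-12
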