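"""Phenotyping: eGFR equation, cleaning, currency resolution, CKD ontology."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from ckdtrials.errors import ConfigurationError, DomainError
from ckdtrials.phenotyping import (build_profiles, clean_observations,
                                   creatinine_for_egfr, egfr_ckdepi2021,
                                   identify_ckd, resolve_current_profile)
from conftest import INDEX_DATE, make_codes, make_obs, make_patient, make_rx


class TestEGFR:
    @pytest.mark.parametrize("creat,age,sex,expected", [
        # creatinine exactly at kappa: eGFR = 142 * 0.9938^age * sex factor
        (0.700 * 88.42, 50, "female", 142 * 0.9938 ** 50 * 1.012),
        (0.900 * 88.42, 50, "male", 142 * 0.9938 ** 50),
        # below kappa, female: 142 * (Scr/0.7)^-0.241 * 0.9938^age * 1.012
        (0.4 * 88.42, 40, "female",
         142 * (0.4 / 0.7) ** -0.241 * 0.9938 ** 40 * 1.012),
        # above kappa, male: 142 * (Scr/0.9)^-1.2 * 0.9938^age
        (1.8 * 88.42, 60, "male", 142 * 2.0 ** -1.2 * 0.9938 ** 60),
    ])
    def test_closed_form(self, creat, age, sex, expected):
        assert egfr_ckdepi2021(creat, age, sex) == pytest.approx(expected, rel=1e-10)

    def test_female_factor_is_1_012_at_kappa(self):
        f = egfr_ckdepi2021(0.7 * 88.42, 55, "female")
        m = egfr_ckdepi2021(0.9 * 88.42, 55, "male")
        assert f / m == pytest.approx(1.012, rel=1e-12)

    @given(creat=hst.floats(20, 1500), age=hst.floats(18, 100),
           female=hst.booleans())
    @settings(max_examples=200, deadline=None)
    def test_monotone_decreasing_in_creatinine_and_age(self, creat, age, female):
        sex = "female" if female else "male"
        assert egfr_ckdepi2021(2 * creat, age, sex) < egfr_ckdepi2021(creat, age, sex)
        assert egfr_ckdepi2021(creat, age + 5, sex) < egfr_ckdepi2021(creat, age, sex)

    @pytest.mark.parametrize("sex,kappa", [("female", 0.7), ("male", 0.9)])
    def test_continuity_at_kappa(self, sex, kappa):
        eps = 1e-9
        below = egfr_ckdepi2021((kappa - eps) * 88.42, 60, sex)
        above = egfr_ckdepi2021((kappa + eps) * 88.42, 60, sex)
        assert below == pytest.approx(above, rel=1e-6)

    def test_nonpositive_creatinine_rejected(self):
        with pytest.raises(DomainError):
            egfr_ckdepi2021(0.0, 50, "male")

    @given(g=hst.floats(5, 150), age=hst.floats(20, 95), female=hst.booleans())
    @settings(max_examples=100, deadline=None)
    def test_inversion_roundtrip(self, g, age, female):
        sex = "female" if female else "male"
        assert egfr_ckdepi2021(creatinine_for_egfr(g, age, sex), age, sex) \
            == pytest.approx(g, rel=1e-9)


class TestCleanObservations:
    def test_out_of_range_removed_in_range_kept(self):
        rows = [("P1", "serum_creatinine", 15.0, 10),      # below lo
                ("P1", "serum_creatinine", 90.0, 20),
                ("P1", "bmi", 400.0, 30),                   # above hi
                ("P1", "sbp", 30.0, 40),                    # below lo
                ("P1", "sbp", 130.0, 50),
                ("P2", "hba1c", 55.0, 60),
                ("P2", "urine_acr", 12.0, 70),
                ("P2", "weight", 80.0, 80),
                ("P2", "dbp", 75.0, 90),
                ("P2", "bmi", 31.0, 95)]
        obs = make_obs(rows)
        out = clean_observations(obs)
        assert len(out) == 7
        kept = clean_observations(out)
        pd.testing.assert_frame_equal(kept, out)  # idempotent / identity

    def test_unknown_concept_in_ranges_is_config_error(self):
        obs = make_obs([("P1", "bmi", 30.0, 10)])
        with pytest.raises(ConfigurationError):
            clean_observations(obs, {"serum_chromium": (0, 1)})


class TestCurrentProfile:
    def test_most_recent_in_window_selected(self):
        patient = make_patient()
        obs = make_obs([("P1", "urine_acr", 50.0, 30),
                        ("P1", "urine_acr", 10.0, 400)])
        prof = resolve_current_profile(patient, obs, make_codes([]), make_rx([]),
                                       INDEX_DATE)
        assert prof["acr"] == 50.0

    def test_measure_older_than_two_years_is_missing(self):
        patient = make_patient()
        obs = make_obs([("P1", "urine_acr", 50.0, 800)])
        prof = resolve_current_profile(patient, obs, make_codes([]), make_rx([]),
                                       INDEX_DATE)
        assert np.isnan(prof["acr"])

    @pytest.mark.parametrize("days,current", [(89, True), (91, False)])
    def test_prescription_window_90_days(self, days, current):
        patient = make_patient()
        rx = make_rx([("P1", "ACEi", days)])
        prof = resolve_current_profile(patient, make_obs([]), make_codes([]),
                                       rx, INDEX_DATE)
        assert bool(prof["rx_acei"]) is current
        assert bool(prof["ras_current"]) is current

    def test_missing_ethnicity_and_imd_resolution(self):
        patient = make_patient(ethnicity=np.nan, imd=np.nan, practice_imd=4)
        prof = resolve_current_profile(patient, make_obs([]), make_codes([]),
                                       make_rx([]), INDEX_DATE)
        assert prof["ethnicity"] == "White"
        assert prof["imd_quintile"] == 4

    def test_missing_index_date_is_config_error(self):
        with pytest.raises(ConfigurationError):
            build_profiles(pd.DataFrame([make_patient()]), make_obs([]),
                           make_codes([]), make_rx([]), None)

    def test_deterministic(self):
        patient = make_patient()
        obs = make_obs([("P1", "urine_acr", 50.0, 30), ("P1", "bmi", 30.0, 40)])
        a = resolve_current_profile(patient, obs, make_codes([]), make_rx([]), INDEX_DATE)
        b = resolve_current_profile(patient, obs, make_codes([]), make_rx([]), INDEX_DATE)
        pd.testing.assert_series_equal(a, b)


def _creat_for(egfr, age, sex):
    return round(creatinine_for_egfr(egfr, age, sex), 1)


class TestIdentifyCKD:
    def _status(self, obs_rows, code_rows=()):
        patient = make_patient(age=70, sex="male")
        return identify_ckd(patient, make_obs(obs_rows),
                            make_codes(list(code_rows)), INDEX_DATE)

    def test_two_low_egfr_90_days_apart(self):
        rows = [("P1", "serum_creatinine", _creat_for(55, 70, "male"), 200),
                ("P1", "serum_creatinine", _creat_for(58, 70, "male"), 100)]
        status = self._status(rows)
        assert status.is_ckd and "egfr_repeat" in status.basis

    def test_low_egfr_pair_too_close_is_not_ckd(self):
        rows = [("P1", "serum_creatinine", _creat_for(55, 70, "male"), 130),
                ("P1", "serum_creatinine", _creat_for(55, 70, "male"), 100)]
        assert not self._status(rows).is_ckd

    def test_repeated_acr_above_3(self):
        rows = [("P1", "urine_acr", 5.0, 400), ("P1", "urine_acr", 5.0, 280)]
        status = self._status(rows)
        assert status.is_ckd and status.basis == ("proteinuria_repeat",)

    def test_acr_and_pcr_do_not_mix(self):
        rows = [("P1", "urine_acr", 5.0, 400), ("P1", "urine_pcr", 20.0, 280)]
        assert not self._status(rows).is_ckd

    def test_diagnostic_code_alone(self):
        status = self._status([], [("P1", "CKD_diagnosis", 500)])
        assert status.is_ckd and status.basis == ("diagnostic_code",)

    def test_empty_history_not_ckd(self):
        assert not self._status([]).is_ckd

    def test_monotone_adding_evidence_never_removes_ckd(self):
        base = [("P1", "urine_acr", 5.0, 400), ("P1", "urine_acr", 5.0, 280)]
        extra = base + [("P1", "serum_creatinine", _creat_for(50, 70, "male"), 300),
                        ("P1", "serum_creatinine", _creat_for(50, 70, "male"), 50)]
        assert self._status(base).is_ckd
        assert self._status(extra).is_ckd

    @given(hst.lists(
        hst.tuples(hst.sampled_from(["serum_creatinine", "urine_acr", "urine_pcr"]),
                   hst.floats(25, 400), hst.integers(0, 1000)),
        min_size=0, max_size=10))
    @settings(max_examples=150, deadline=None)
    def test_pairwise_oracle_on_random_histories(self, rows):
        """Route (b)/(c) agree with brute-force enumeration of measurement pairs."""
        obs_rows = [("P1", c, round(v, 1), d) for c, v, d in rows]
        status = self._status(obs_rows)

        def egfr_of(value, days):
            # age at the measurement date, exactly as the implementation
            # evaluates it (birth date is stored at whole-day resolution)
            age = (round(70 * 365.25) - days) / 365.25
            return egfr_ckdepi2021(value, age, "male")

        creats = [(d, round(v, 1)) for c, v, d in rows if c == "serum_creatinine"]
        low = [(d, v) for d, v in creats if egfr_of(v, d) < 60]
        expect_egfr = any(abs(a[0] - b[0]) >= 90
                          for i, a in enumerate(low) for b in low[i + 1:])
        acr = [(d, v) for c, v, d in rows if c == "urine_acr" and round(v, 1) > 3]
        pcr = [(d, v) for c, v, d in rows if c == "urine_pcr" and round(v, 1) > 15]
        expect_prot = any(abs(a[0] - b[0]) >= 90
                          for i, a in enumerate(acr) for b in acr[i + 1:]) or \
            any(abs(a[0] - b[0]) >= 90 for i, a in enumerate(pcr) for b in pcr[i + 1:])
        assert ("egfr_repeat" in status.basis) == expect_egfr
        assert ("proteinuria_repeat" in status.basis) == expect_prot
        assert status.is_ckd == (expect_egfr or expect_prot)


class TestClassifyDiabetes:
    def _profile(self, obs_rows=(), code_rows=(), rx_rows=()):
        patient = make_patient()
        return resolve_current_profile(patient, make_obs(list(obs_rows)),
                                       make_codes(list(code_rows)),
                                       make_rx(list(rx_rows)), INDEX_DATE)

    def test_t2d_code_route(self):
        assert self._profile(code_rows=[("P1", "T2D", 500)])["diabetes_class"] == "T2D"

    def test_t1d_precedence(self):
        prof = self._profile(code_rows=[("P1", "T1D", 500), ("P1", "T2D", 400)])
        assert prof["diabetes_class"] == "T1D"

    def test_repeated_hba1c_route(self):
        obs = [("P1", "hba1c", 52.0, 200), ("P1", "hba1c", 55.0, 80)]
        assert self._profile(obs_rows=obs)["diabetes_class"] == "T2D"

    def test_single_high_hba1c_insufficient(self):
        obs = [("P1", "hba1c", 52.0, 200)]
        assert self._profile(obs_rows=obs)["diabetes_class"] == "none"
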