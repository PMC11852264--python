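"""Eligibility engine: unit conversions, criterion evaluation, reasons, rates."""

import numpy as np
import pandas as pd
import pytest

from ckdtrials.eligibility import (assess, assess_cohort,
                                   attribute_primary_reason,
                                   attribute_primary_reasons,
                                   convert_acr_mg_per_g_to_mg_per_mmol,
                                   convert_hba1c_ngsp_to_ifcc,
                                   eligibility_rates, load_all_trial_specs,
                                   load_trial_spec, save_trial_spec)
from ckdtrials.errors import ConfigurationError, ContractError, DomainError
from conftest import make_profile
from oracle import ORACLES

SPECS = load_all_trial_specs()


class TestConversions:
    @pytest.mark.parametrize("mg_g,expected", [
        (300, 33.9),   # CREDENCE lower ACR bound
        (200, 22.6),   # DAPA-CKD lower ACR bound
        (0, 0.0),
    ])
    def test_acr_mg_per_g_to_mg_per_mmol(self, mg_g, expected):
        assert round(convert_acr_mg_per_g_to_mg_per_mmol(mg_g), 1) == expected

    def test_acr_negative_rejected(self):
        with pytest.raises(DomainError):
            convert_acr_mg_per_g_to_mg_per_mmol(-1)

    @pytest.mark.parametrize("pct,expected", [
        (6.5, 47.5),    # CREDENCE lower HbA1c bound
        (12.0, 107.7),  # CREDENCE upper HbA1c bound
        (2.15 + 1 / 10.929, 1.0),
    ])
    def test_hba1c_ngsp_to_ifcc(self, pct, expected):
        assert round(convert_hba1c_ngsp_to_ifcc(pct), 1) == expected

    def test_hba1c_domain(self):
        with pytest.raises(DomainError):
            convert_hba1c_ngsp_to_ifcc(2.15)


class TestAssess:
    def test_credence_checklist_eligible(self):
        prof = make_profile(age=60, hba1c=60, egfr=50, acr=80, rx_acei=True)
        res = assess(prof, SPECS["CREDENCE"])
        assert res.eligible
        assert res.failed_inclusion == [] and res.met_exclusion == []

    def test_credence_acr_threshold_is_strict(self):
        res = assess(make_profile(acr=30.0), SPECS["CREDENCE"])
        assert not res.eligible and res.failed_inclusion == ["acr_range"]
        # exactly at the bound: >33.9 is strict
        res = assess(make_profile(acr=33.9), SPECS["CREDENCE"])
        assert "acr_range" in res.failed_inclusion

    def test_empa_low_egfr_arm_needs_no_albuminuria(self):
        prof = make_profile(egfr=40, acr=np.nan, rx_acei=False, rx_arb=True)
        assert assess(prof, SPECS["EMPA-KIDNEY"]).eligible
        res = assess(prof, SPECS["DAPA-CKD"])
        assert not res.eligible and res.missing_required == ["acr"]

    def test_t1d_excluded_everywhere(self):
        prof = make_profile(t1d_code=True)
        for spec in SPECS.values():
            res = assess(prof, spec)
            assert not res.eligible and "t1d" in res.met_exclusion

    def test_missing_lab_never_eligible(self):
        for col, trial in [("egfr", "CREDENCE"), ("acr", "DAPA-CKD"),
                           ("hba1c", "CREDENCE"), ("egfr", "EMPA-KIDNEY")]:
            prof = make_profile(**{col: np.nan})
            res = assess(prof, SPECS[trial])
            assert not res.eligible
            assert col in res.missing_required

    def test_unknown_criterion_kind_is_config_error(self, tmp_path):
        import yaml
        raw = {"name": "X", "inclusion": [
            {"id": "a", "kind": "phase_of_moon", "params": {}}], "exclusion": []}
        path = tmp_path / "bad.yaml"
        path.write_text(yaml.safe_dump(raw))
        with pytest.raises(ConfigurationError):
            load_trial_spec(str(path))


class TestSpecRoundTrip:
    def test_serialised_spec_gives_identical_assessments(self, tmp_path, phenotyped):
        profiles, _, _ = phenotyped
        cohort = profiles.head(200)
        for trial, spec in SPECS.items():
            path = tmp_path / f"{trial}.yaml"
            save_trial_spec(spec, path)
            reloaded = load_trial_spec(str(path))
            a = assess_cohort(cohort, spec)
            b = assess_cohort(cohort, reloaded)
            pd.testing.assert_frame_equal(a, b)


def _random_profiles(n, seed):
    """Random profiles spanning the criterion space, with boundary mass."""
    rng = np.random.default_rng(seed)

    def lab(vals, p_missing):
        # mix of exact threshold values and continuous draws
        anchors = rng.choice(vals, n)
        cont = rng.uniform(min(vals) * 0.2, max(vals) * 1.4, n)
        out = np.where(rng.random(n) < 0.4, anchors, cont)
        return np.where(rng.random(n) < p_missing, np.nan, np.round(out, 1))

    rows = []
    egfr = lab([20, 25, 30, 45, 60, 75, 90], 0.15)
    acr = lab([3, 22.6, 33.9, 113, 565, 565.5], 0.3)
    pcr = lab([15, 33.9], 0.7)
    hba1c = lab([47.5, 107.7], 0.3)
    for i in range(n):
        rows.append(make_profile(
            patient_id=f"R{i}",
            age=float(rng.choice([17.9, 18, 29.9, 30, rng.uniform(18, 95)])),
            egfr=egfr[i], acr=acr[i], pcr=pcr[i], hba1c=hba1c[i],
            t2d=bool(rng.random() < 0.5),
            t2d_code=bool(rng.random() < 0.5),
            t1d_code=bool(rng.random() < 0.1),
            rx_acei=bool(rng.random() < 0.5),
            rx_arb=bool(rng.random() < 0.3),
            ihd=bool(rng.random() < 0.2), stroke=bool(rng.random() < 0.1),
            tia=bool(rng.random() < 0.1), pad=bool(rng.random() < 0.1),
            nyha_iv_hf=bool(rng.random() < 0.05),
            cirrhosis=bool(rng.random() < 0.05),
            dialysis_eskd=bool(rng.random() < 0.05),
            kidney_transplant=bool(rng.random() < 0.05),
            organ_transplant_other=bool(rng.random() < 0.05),
            adpkd=bool(rng.random() < 0.05), arpkd=bool(rng.random() < 0.03),
            lupus_nephritis=bool(rng.random() < 0.05),
            anca_vasculitis=bool(rng.random() < 0.03),
        ))
    return pd.DataFrame(rows)


class TestBruteForceEquivalence:
    def test_engine_matches_oracle_on_random_profiles(self):
        """Complete failed/met lists equal brute-force evaluation (no short-circuit)."""
        profiles = _random_profiles(300, seed=5)
        for trial, spec in SPECS.items():
            audit = assess_cohort(profiles, spec)
            oracle = ORACLES[trial]
            for i, (_, prof) in enumerate(profiles.iterrows()):
                exp_elig, exp_failed, exp_excl, exp_missing = oracle(prof)
                row = audit.iloc[i]
                assert bool(row["eligible"]) == exp_elig, (trial, prof.to_dict())
                assert set(row["failed_inclusion"]) == exp_failed
                assert set(row["met_exclusion"]) == exp_excl
                assert set(row["missing_required"]) == exp_missing


class TestSubsetLaws:
    def test_cohort_subset_laws(self, phenotyped):
        profiles, _, _ = phenotyped
        audits = {t: assess_cohort(profiles, s) for t, s in SPECS.items()}
        prof = profiles.set_index("patient_id")
        for trial, audit in audits.items():
            elig = audit.loc[audit["eligible"], "patient_id"]
            assert prof.loc[elig, "ras_current"].all()
        cred = set(audits["CREDENCE"].loc[audits["CREDENCE"]["eligible"], "patient_id"])
        assert prof.loc[list(cred), "t2d"].all()
        dapa = audits["DAPA-CKD"]
        acr = prof.loc[dapa.loc[dapa["eligible"], "patient_id"], "acr"]
        assert ((acr >= 22.6) & (acr <= 565)).all()

    def test_removing_required_lab_breaks_eligibility(self, phenotyped):
        profiles, _, _ = phenotyped
        for trial, spec in SPECS.items():
            audit = assess_cohort(profiles, spec)
            elig_ids = audit.loc[audit["eligible"], "patient_id"].head(20)
            if elig_ids.empty:
                continue
            sub = profiles.loc[profiles["patient_id"].isin(elig_ids)].copy()
            for lab in ("egfr", "acr", "hba1c"):
                masked = sub.copy()
                masked[lab] = np.nan
                res = assess_cohort(masked, spec)
                if trial == "CREDENCE" or lab == "egfr":
                    assert not res["eligible"].any()
                elif trial == "DAPA-CKD" and lab == "acr":
                    assert not res["eligible"].any()


class TestPrimaryReason:
    def test_no_ras_takes_priority_over_albuminuria(self):
        prof = make_profile(rx_acei=False, rx_arb=False, acr=10.0)
        res = assess(prof, SPECS["CREDENCE"])
        res = attribute_primary_reason(res, prof, SPECS["CREDENCE"])
        assert res.primary_reason == "not_on_RAS"
        assert "acr_range" in res.failed_inclusion  # cross-tab still sees it

    def test_albuminuria_not_assessed(self):
        prof = make_profile(acr=np.nan)
        res = assess(prof, SPECS["DAPA-CKD"])
        res = attribute_primary_reason(res, prof, SPECS["DAPA-CKD"])
        assert res.primary_reason == "albuminuria_not_assessed"

    def test_exclusion_only(self):
        prof = make_profile(egfr=50, acr=80, adpkd=True)
        res = assess(prof, SPECS["DAPA-CKD"])
        res = attribute_primary_reason(res, prof, SPECS["DAPA-CKD"])
        assert res.primary_reason == "exclusion_criterion"

    def test_eligible_result_is_contract_error(self):
        prof = make_profile()
        res = assess(prof, SPECS["CREDENCE"])
        assert res.eligible
        with pytest.raises(ContractError):
            attribute_primary_reason(res, prof, SPECS["CREDENCE"])

    def test_vectorised_attribution_matches_single(self):
        profiles = _random_profiles(120, seed=9)
        for trial, spec in SPECS.items():
            audit = assess_cohort(profiles, spec)
            vec = attribute_primary_reasons(audit, profiles, spec)
            for i, (_, prof) in enumerate(profiles.iterrows()):
                if audit.iloc[i]["eligible"]:
                    assert vec.iloc[i]["primary_reason"] is None
                    continue
                res = assess(prof, spec)
                res = attribute_primary_reason(res, prof, spec)
                assert vec.iloc[i]["primary_reason"] == res.primary_reason


class TestRates:
    @staticmethod
    def _audit(trial, numerator, denominator):
        return pd.DataFrame({
            "patient_id": np.arange(denominator),
            "trial": trial,
            "eligible": np.arange(denominator) < numerator,
        })

    def test_one_decimal_percent(self):
        audit = self._audit("EMPA-KIDNEY", 22114, 169443)
        t2d = pd.Series(True, index=np.arange(169443))
        rates = eligibility_rates({"EMPA-KIDNEY": audit}, t2d)
        row = rates[(rates["stratum"] == "CKD_T2D")].iloc[0]
        assert row["percent"] == 13.1

    def test_zero_numerator(self):
        audit = self._audit("DAPA-CKD", 0, 50)
        rates = eligibility_rates({"DAPA-CKD": audit},
                                  pd.Series(False, index=np.arange(50)))
        assert (rates["percent"] == 0.0).all()

    def test_credence_has_no_non_t2d_stratum(self):
        audit = self._audit("CREDENCE", 5, 100)
        rates = eligibility_rates({"CREDENCE": audit},
                                  pd.Series([True] * 60 + [False] * 40,
                                            index=np.arange(100)))
        assert set(rates["stratum"]) == {"all_CKD", "CKD_T2D"}

    def test_zero_denominator_row_not_emitted(self):
        audit = self._audit("DAPA-CKD", 2, 10)
        rates = eligibility_rates({"DAPA-CKD": audit},
                                  pd.Series(True, index=np.arange(10)))
        assert "CKD_no_T2D" not in set(rates["stratum"])

    def test_rates_match_ground_truth_on_complete_data(self, phenotyped):
        profiles, register, truth = phenotyped
        audits = {t: assess_cohort(profiles, s) for t, s in SPECS.items()}
        rates = eligibility_rates(audits, profiles.set_index("patient_id")["t2d"])
        for trial in SPECS:
            planted = truth.loc[profiles["patient_id"], f"eligible_{trial}"]
            row = rates[(rates["trial"] == trial)
                        & (rates["stratum"] == "all_CKD")].iloc[0]
            assert row["numerator"] == int(planted.sum())
            assert row["percent"] == round(100 * planted.mean(), 1)
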