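"""Patient scoring: logit, probability, LP relative-risk score, risk class."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retinorisk import (
    PatientProfile,
    classify,
    compute_logit,
    load_patients_csv,
    probability_from_logit,
    relative_risk,
    score_patient,
    worked_example_profile,
)
from retinorisk.scoring import ProfileError


def oracle_logit(profile, coeffs):
    """Brute-force: enumerate the coefficient table and sum matches."""
    total = coeffs.alpha
    for (fid, level), beta in coeffs.betas.items():
        if profile.exposures.get(fid) == level:
            total += beta
    return total


def random_profile(rng, coeffs):
    return PatientProfile(
        exposures={
            fid: rng.choice(coeffs.levels_for(fid)) for fid in coeffs.factor_ids
        }
    )


class TestComputeLogit:
    def test_worked_example_sums_to_printed_value(self, printed_coeffs):
        logit, contributions = compute_logit(worked_example_profile(), printed_coeffs)
        assert logit == pytest.approx(1.177, abs=1e-12)
        assert logit == pytest.approx(printed_coeffs.alpha + sum(contributions.values()))
        # protective smoking term present, absent factors contribute zero
        assert contributions["smoking"] == -0.083
        assert contributions["bariatric_surgery"] == 0.0

    def test_all_baseline_profile_scores_alpha(self, printed_coeffs):
        profile = PatientProfile(
            exposures={
                fid: printed_coeffs.baseline_levels[fid]
                for fid in printed_coeffs.factor_ids
            }
        )
        logit, _ = compute_logit(profile, printed_coeffs)
        assert logit == printed_coeffs.alpha

    def test_matches_brute_force_oracle_on_random_profiles(self, printed_coeffs):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            profile = random_profile(rng, printed_coeffs)
            logit, _ = compute_logit(profile, printed_coeffs)
            assert logit == pytest.approx(oracle_logit(profile, printed_coeffs), abs=1e-12)

    def test_unknown_factor_and_level_reported(self, printed_coeffs):
        profile = worked_example_profile()
        profile.exposures["myopia"] = "severe"
        profile.exposures["ghost"] = "present"
        with pytest.raises(ProfileError) as exc:
            compute_logit(profile, printed_coeffs)
        assert "myopia" in str(exc.value) and "ghost" in str(exc.value)

    def test_missing_factor_rejected(self, printed_coeffs):
        profile = worked_example_profile()
        del profile.exposures["insulin"]
        with pytest.raises(ProfileError, match="insulin"):
            compute_logit(profile, printed_coeffs)


class TestProbabilityAndLP:
    @pytest.mark.parametrize(
        "logit,expected",
        [(0.0, 0.5), (1.177, math.exp(1.177) / (1 + math.exp(1.177)))],
    )
    def test_inverse_logit_values(self, logit, expected):
        assert probability_from_logit(logit) == pytest.approx(expected, abs=1e-12)

    def test_saturates_without_overflow(self):
        assert probability_from_logit(-750.0) == 0.0
        assert probability_from_logit(750.0) == 1.0

    def test_worked_example_lp_is_2_75(self, printed_coeffs):
        result = score_patient(worked_example_profile(), printed_coeffs)
        assert round(result.lp, 2) == 2.75
        assert result.risk_class == "high"  # 2.75 > 2.24

    @pytest.mark.parametrize(
        "prob,prev,expected",
        [(0.278, 0.278, 1.0), (0.5, 0.278, 0.5 / 0.278)],
    )
    def test_lp_is_probability_over_prevalence(self, prob, prev, expected):
        assert relative_risk(prob, prev) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_prevalence_rejected(self):
        with pytest.raises(Exception, match="prevalence"):
            relative_risk(0.5, 0.0)


class TestClassify:
    def test_lp_cutoff_is_strict_and_p_half_inclusive(self):
        assert classify(2.75, rule="lp_cutoff", lp_cutoff=2.24) == "high"
        assert classify(2.24, rule="lp_cutoff", lp_cutoff=2.24) == "low"
        assert classify(1.0, rule="lp_cutoff", lp_cutoff=2.24) == "low"
        assert classify(0.0, rule="p_half", probability=0.5) == "high"
        assert classify(0.0, rule="p_half", probability=0.499) == "low"

    def test_unknown_rule_rejected(self):
        with pytest.raises(ProfileError, match="rule"):
            classify(1.0, rule="median")

    def test_p_half_agrees_with_logit_sign(self, printed_coeffs):
        rng = np.random.default_rng(7)
        for _ in range(100):
            profile = random_profile(rng, printed_coeffs)
            r = score_patient(profile, printed_coeffs, rule="p_half")
            assert (r.risk_class == "high") == (r.logit >= 0)


class TestInvariants:
    def test_flipping_factor_moves_score_with_beta_sign(self, printed_coeffs):
        base = worked_example_profile()
        for (fid, level), beta in printed_coeffs.betas.items():
            lo = PatientProfile(exposures=dict(base.exposures))
            lo.exposures[fid] = printed_coeffs.baseline_levels[fid]
            hi = PatientProfile(exposures=dict(lo.exposures))
            hi.exposures[fid] = level
            r_lo = score_patient(lo, printed_coeffs)
            r_hi = score_patient(hi, printed_coeffs)
            if beta > 0:
                assert r_hi.logit > r_lo.logit
                assert r_hi.probability > r_lo.probability
                assert r_hi.lp > r_lo.lp
            elif beta < 0:
                assert r_hi.logit < r_lo.logit
                assert r_hi.probability < r_lo.probability
                assert r_hi.lp < r_lo.lp

    def test_logit_probability_lp_rank_patients_identically(self, printed_coeffs):
        rng = np.random.default_rng(11)
        results = [
            score_patient(random_profile(rng, printed_coeffs), printed_coeffs)
            for _ in range(50)
        ]
        by_logit = np.argsort([r.logit for r in results], kind="stable")
        by_prob = np.argsort([r.probability for r in results], kind="stable")
        by_lp = np.argsort([r.lp for r in results], kind="stable")
        assert (by_logit == by_prob).all() and (by_logit == by_lp).all()

    def test_result_internal_identities(self, printed_coeffs):
        r = score_patient(worked_example_profile(), printed_coeffs)
        assert r.probability == pytest.approx(
            math.exp(r.logit) / (1 + math.exp(r.logit)), abs=1e-12
        )
        assert r.lp == pytest.approx(r.probability / printed_coeffs.prevalence, abs=1e-12)


class TestPatientCsv:
    def test_continuous_columns_auto_binarized(self, tmp_path, printed_coeffs):
        p = tmp_path / "patients.csv"
        p.write_text(
            "patient_id,male,bariatric_surgery,myopia,lipid_lowering,fpg_mmol_l,"
            "duration,hba1c_pct,intensive_control,hypertension,insulin,rural,smoking\n"
            "a,present,absent,absent,none,6.5,present,7.0,present,present,present,present,present\n"
            "b,absent,absent,absent,none,5.0,absent,6.0,absent,absent,absent,absent,absent\n"
        )
        profiles = load_patients_csv(p, printed_coeffs)
        assert profiles[0].exposures["fpg"] == "present"    # 6.5 > 6.1
        assert profiles[0].exposures["hba1c"] == "present"  # 7.0 >= 6.5
        assert profiles[1].exposures["fpg"] == "absent"
        assert profiles[1].exposures["hba1c"] == "absent"
        r = score_patient(profiles[0], printed_coeffs)
        assert r.logit == pytest.approx(1.177, abs=1e-12)

    def test_demographics_carried_but_not_scored(self, printed_coeffs):
        profile = worked_example_profile()
        assert profile.demographics["height_cm"] == 170
        _, contributions = compute_logit(profile, printed_coeffs)
        assert set(contributions) == set(printed_coeffs.factor_ids)
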