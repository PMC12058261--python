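import math

import numpy as np
import pandas as pd
import pytest

from bcrisk import (
    Factor,
    RelativeRiskModel,
    RiskFactorProfile,
    combined_rr,
    combined_rr_frame,
    calibrate_baseline,
    expand_variant,
    predict_cohort,
    predict_window_risk,
    standardize_prs,
)
from bcrisk.errors import ConfigError, DataError, PredictionWindowError
from bcrisk.model import population_mean_rr

from oracles import riemann_cumulative_risk


def toy_model(beta_prs=0.4):
    return RelativeRiskModel(
        beta_prs=beta_prs,
        pv_log_rr={"brca1": math.log(5.0), "chek2": math.log(2.0)},
        pv_freq={"brca1": 0.001, "chek2": 0.005},
        factors={
            "bmi": Factor("bmi", ("low", "mid", "high"), np.log([0.9, 1.0, 1.2]), (0.25, 0.5, 0.25)),
            "alcohol": Factor("alcohol", ("none", "some"), np.log([1.0, 1.1]), (0.4, 0.6)),
            "family_history": Factor("family_history", ("0", "1", "2"), np.log([1.0, 1.8, 2.9]), (0.88, 0.105, 0.015)),
        },
    )


class TestStandardizePrs:
    def test_published_mean_maps_to_zero(self):
        assert standardize_prs(-0.424) == pytest.approx(0.0, abs=1e-15)

    def test_one_sd_shift(self):
        assert standardize_prs(-0.424 + 0.603) == pytest.approx(1.0, rel=1e-12)

    def test_raw_zero(self):
        assert standardize_prs(0.0) == pytest.approx(0.424 / 0.603, rel=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(DataError):
            standardize_prs(float("nan"))


class TestCombinedRR:
    def test_fully_missing_profile_is_exactly_one(self):
        m = toy_model()
        assert combined_rr(RiskFactorProfile(), m) == pytest.approx(1.0, abs=1e-15)

    def test_hand_product_on_toy_model(self):
        m = toy_model(beta_prs=0.4)
        profile = RiskFactorProfile(
            prs=0.0, pv={g: 0 for g in ("brca1", "chek2")},
            questionnaire={"bmi": "mid", "alcohol": "none"}, family_history=0,
        )
        expect = (
            (1.0 / math.exp(0.4**2 / 2))
            * (1.0 / (0.994 + 0.001 * 5 + 0.005 * 2))
            * (1.0 / (0.25 * 0.9 + 0.5 * 1.0 + 0.25 * 1.2))
            * (1.0 / (0.4 * 1.0 + 0.6 * 1.1))
            * (1.0 / (0.88 + 0.105 * 1.8 + 0.015 * 2.9))
        )
        assert combined_rr(profile, m) == pytest.approx(expect, rel=1e-12)

    def test_enabling_superset_unchanged_at_population_average_state(self):
        m = toy_model()
        profile = RiskFactorProfile(prs=None, questionnaire={"bmi": "mid"})
        small = combined_rr(profile, m, {"bmi"})
        # enabling factors that are missing (population-average) changes nothing
        big = combined_rr(profile, m, {"bmi", "alcohol", "prs", "pv", "family_history"})
        assert big == pytest.approx(small, rel=1e-12)

    def test_normalization_invariant_each_factor(self):
        m = toy_model()
        for fac in m.factors.values():
            assert float(fac.freq @ fac.normalized_rr()) == pytest.approx(1.0, abs=1e-12)

    def test_unknown_category_names_factor(self):
        m = toy_model()
        profile = RiskFactorProfile(questionnaire={"bmi": "huge"})
        with pytest.raises(DataError, match="bmi"):
            combined_rr(profile, m, {"bmi"})

    def test_multiple_pv_assigned_highest_risk_gene(self):
        m = toy_model()
        both = RiskFactorProfile(pv={"brca1": 1, "chek2": 1})
        brca1_only = RiskFactorProfile(pv={"brca1": 1, "chek2": 0})
        assert combined_rr(both, m, {"pv"}) == pytest.approx(
            combined_rr(brca1_only, m, {"pv"}), rel=1e-12
        )

    def test_frame_agrees_with_scalar(self, rng):
        m = toy_model()
        rows = []
        profiles = []
        for _ in range(60):
            prs = float(rng.standard_normal()) if rng.random() < 0.8 else None
            bmi = str(rng.choice(["low", "mid", "high"])) if rng.random() < 0.7 else None
            alc = str(rng.choice(["none", "some"])) if rng.random() < 0.7 else None
            fh = int(rng.integers(0, 3)) if rng.random() < 0.5 else None
            carrier = {"brca1": int(rng.random() < 0.05), "chek2": int(rng.random() < 0.1)}
            profiles.append(
                RiskFactorProfile(prs=prs, pv=carrier, questionnaire={"bmi": bmi, "alcohol": alc}, family_history=fh)
            )
            rows.append(
                {
                    "prs": np.nan if prs is None else prs,
                    "brca1": carrier["brca1"], "chek2": carrier["chek2"],
                    "bmi": bmi or "", "alcohol": alc or "",
                    "fh_count": np.nan if fh is None else float(fh),
                }
            )
        df = pd.DataFrame(rows)
        enabled = {"prs", "pv", "bmi", "alcohol", "family_history"}
        vec = combined_rr_frame(df, m, enabled)
        scal = np.array([combined_rr(p, m, enabled) for p in profiles])
        np.testing.assert_allclose(vec, scal, rtol=1e-12)


class TestBaselineCalibration:
    def test_normalized_model_baseline_is_population_hazard(self, toy_table):
        b = calibrate_baseline(toy_model(), toy_table)
        assert b.mean_rr == 1.0
        assert b(52.0) == toy_table.hazard_at(52.0)

    def test_symmetric_binary_factor_mean_one(self, toy_table):
        m = RelativeRiskModel(
            beta_prs=0.0, pv_log_rr={}, pv_freq={},
            factors={"bmi": Factor("bmi", ("a", "b"), np.log([0.5, 1.5]), (0.5, 0.5))},
        )
        assert population_mean_rr(m, {"bmi"}, normalize=False) == pytest.approx(1.0)

    def test_unnormalized_mean_rr_analytic(self, toy_table):
        m = toy_model(beta_prs=0.4)
        mean = population_mean_rr(m, normalize=False)
        expect = (
            math.exp(0.4**2 / 2)
            * (0.994 + 0.001 * 5 + 0.005 * 2)
            * (0.25 * 0.9 + 0.5 * 1.0 + 0.25 * 1.2)
            * (0.4 * 1.0 + 0.6 * 1.1)
            * (0.88 + 0.105 * 1.8 + 0.015 * 2.9)
        )
        assert mean == pytest.approx(expect, rel=1e-12)
        b = calibrate_baseline(m, toy_table, normalize=False)
        assert b(60.0) == pytest.approx(toy_table.hazard_at(60.0) / expect, rel=1e-12)


class TestPredictWindow:
    def test_null_profile_equals_population_risk(self, toy_table):
        pred = predict_window_risk(RiskFactorProfile(), 47.0, None, toy_model(), toy_table)
        assert pred.relative_risk == pytest.approx(1.0)
        assert pred.absolute_risk == pytest.approx(toy_table.cumulative_risk(48.0, 58.0))
        assert pred.risk_ratio == pytest.approx(1.0)

    def test_window_capped_at_80(self, toy_table):
        pred = predict_window_risk(RiskFactorProfile(), 69.5, None, toy_model(), toy_table)
        assert (pred.window_start, pred.window_end) == (70.5, 80.0)

    def test_censored_window_truncated(self, toy_table):
        pred = predict_window_risk(RiskFactorProfile(), 50.0, 56.5, toy_model(), toy_table)
        assert pred.window_end == 56.5

    def test_rr2_matches_integration_oracle(self, toy_table):
        m = toy_model()
        profile = RiskFactorProfile(questionnaire={"bmi": "high"})
        pred = predict_window_risk(profile, 55.0, None, m, toy_table, factors_enabled={"bmi"})
        rr = pred.relative_risk
        oracle = riemann_cumulative_risk(toy_table, 56.0, 66.0, rr, step=1 / 365)
        assert pred.absolute_risk == pytest.approx(oracle, abs=5e-6)
        assert pred.absolute_risk == pytest.approx(
            1 - math.exp(-rr * toy_table.cumulative_hazard(56.0, 66.0)), rel=1e-12
        )

    def test_empty_window_raises(self, toy_table):
        with pytest.raises(PredictionWindowError):
            predict_window_risk(RiskFactorProfile(), 50.0, 50.8, toy_model(), toy_table)

    def test_monotone_in_rr_and_window_length(self, toy_table):
        m = toy_model()
        lowr = predict_window_risk(RiskFactorProfile(questionnaire={"bmi": "low"}), 50, None, m, toy_table)
        highr = predict_window_risk(RiskFactorProfile(questionnaire={"bmi": "high"}), 50, None, m, toy_table)
        assert highr.absolute_risk > lowr.absolute_risk
        short = predict_window_risk(RiskFactorProfile(), 50, 55.0, m, toy_table)
        full = predict_window_risk(RiskFactorProfile(), 50, None, m, toy_table)
        assert full.absolute_risk > short.absolute_risk


class TestVariantsAndConfig:
    def test_expand_variant_groups(self):
        assert expand_variant("NULL") == frozenset()
        full = expand_variant("FH+QRF+PRS+PV")
        assert {"prs", "pv", "family_history", "bmi", "alcohol"} <= set(full)
        with pytest.raises(ConfigError):
            expand_variant("FH+XYZ")

    def test_model_yaml_roundtrip(self, tmp_path):
        m = toy_model()
        path = tmp_path / "model.yaml"
        m.to_yaml(path)
        back = RelativeRiskModel.from_yaml(path)
        assert back.beta_prs == m.beta_prs
        assert back.pv_log_rr == pytest.approx(m.pv_log_rr)
        np.testing.assert_allclose(back.factors["bmi"].log_rr, m.factors["bmi"].log_rr)

    def test_bad_frequencies_rejected(self):
        with pytest.raises(ConfigError):
            Factor("bmi", ("a", "b"), np.log([1.0, 1.0]), (0.5, 0.6))


def test_predict_cohort_cases_keep_full_window(toy_table):
    m = toy_model()
    cohort = pd.DataFrame(
        {
            "id": [0, 1],
            "entry_age": [50.0, 50.0],
            "prs": [np.nan, np.nan],
            "brca1": [0, 0], "chek2": [0, 0],
            "bmi": ["", ""], "alcohol": ["", ""],
            "fh_count": [np.nan, np.nan],
            "event": [1, 0],
            "exit_age": [56.0, 56.0],
        }
    )
    pred = predict_cohort(cohort, m, toy_table, factors_enabled={"prs", "bmi"})
    assert pred.loc[0, "window_end"] == 61.0  # case: full 10-year window
    assert pred.loc[1, "window_end"] == 56.0  # censored: truncated
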