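import io

import numpy as np
import pandas as pd
import pytest

from bcrisk import (
    CohortConfig,
    apply_eligibility,
    predict_cohort,
    sample_profiles,
    simulate_cohort,
    simulate_events,
    write_cohort_csv,
)
from bcrisk.errors import ConfigError


def small_config(**kw):
    kw.setdefault("n_women", 2000)
    kw.setdefault("seed", 11)
    return CohortConfig(**kw)


class TestSampling:
    def test_no_carriers_when_frequency_zero(self, model):
        m = model
        zero = type(m)(
            beta_prs=m.beta_prs,
            pv_log_rr=m.pv_log_rr,
            pv_freq={g: 0.0 for g in m.pv_freq},
            factors=m.factors,
        )
        df = sample_profiles(small_config(), zero)
        assert df[list(m.pv_freq)].to_numpy().sum() == 0

    def test_carrier_fraction_within_binomial_bounds(self, model):
        n = 200_000
        df = sample_profiles(CohortConfig(n_women=n, seed=5), model)
        freq = model.pv_freq["brca2"]
        sd = np.sqrt(freq * (1 - freq) / n)
        assert abs(df["brca2"].mean() - freq) <= 3 * sd

    def test_prs_standard_normal(self, model):
        n = 200_000
        df = sample_profiles(CohortConfig(n_women=n, seed=6), model)
        assert abs(df["prs"].mean()) <= 3 / np.sqrt(n)
        assert abs(df["prs"].std() - 1.0) <= 0.02

    def test_entry_ages_within_bands(self, model):
        df = sample_profiles(small_config(), model)
        assert df["entry_age"].between(40, 70, inclusive="left").all()


class TestEvents:
    def test_zero_incidence_gives_zero_cases(self, model, zero_table):
        cfg = small_config()
        profiles = sample_profiles(cfg, model)
        rec = simulate_events(profiles, model, zero_table, cfg)
        assert rec["event"].sum() == 0

    def test_band_specific_incidence_matches_population(self, model, synthetic_table):
        # truth = prediction model, multiplier 1: observed events per age band
        # should match population rate x person-time within 3 Poisson SDs
        cfg = CohortConfig(n_women=100_000, seed=7)
        cohort, _ = simulate_cohort(cfg, model, synthetic_table)
        entry = cohort["entry_age"].to_numpy()
        exit_age = cohort["exit_age"].to_numpy()
        ws = entry + 1.0
        for lo in range(45, 75, 5):
            hi = lo + 5
            pt = np.clip(np.minimum(exit_age, hi) - np.maximum(ws, lo), 0, None)
            rate = synthetic_table.hazard_at(lo + 0.5)
            expected = rate * pt.sum()
            observed = (
                (cohort["event"] == 1)
                & (exit_age >= lo)
                & (exit_age < hi)
            ).sum()
            assert abs(observed - expected) <= 3 * np.sqrt(expected) + 1, (lo, observed, expected)

    def test_age_multiplier_scales_observed_incidence(self, model, synthetic_table):
        # 58.19% excess below age 50 applied at the current age
        cfg = CohortConfig(
            n_women=150_000, seed=8,
            age_multipliers=[(0.0, 50.0, 1.5819), (50.0, 200.0, 1.0)],
        )
        cohort, _ = simulate_cohort(cfg, model, synthetic_table)
        entry = cohort["entry_age"].to_numpy()
        exit_age = cohort["exit_age"].to_numpy()
        ws = entry + 1.0
        pt_u50 = np.clip(np.minimum(exit_age, 50.0) - ws, 0, None)
        # expected events under age 50 at population rates (no multiplier)
        mask = pt_u50 > 0
        expected = sum(
            synthetic_table.cumulative_hazard(a, min(b, 50.0))
            for a, b in zip(ws[mask], exit_age[mask])
            if min(b, 50.0) > a
        )
        observed = ((cohort["event"] == 1) & (exit_age < 50.0)).sum()
        ratio = observed / expected
        assert abs(ratio - 1.5819) <= 3 * np.sqrt(observed) / expected

    def test_exit_age_respects_window_cap(self, model, synthetic_table):
        cohort, _ = simulate_cohort(small_config(), model, synthetic_table)
        assert (
            cohort["exit_age"]
            <= np.minimum(cohort["entry_age"] + 11.0, 80.0) + 1e-9
        ).all()
        cases = cohort[cohort["event"] == 1]
        assert (cases["censor_cause"] == "").all()


class TestEligibility:
    def test_short_followup_excluded(self):
        df = pd.DataFrame(
            {"entry_age": [50.0], "event": [0], "exit_age": [50.9],
             "prior_cancer": [0], "mastectomy_history": [0]}
        )
        kept, tally = apply_eligibility(df)
        assert len(kept) == 0
        assert tally["short_followup"] == 1

    def test_empty_rule_set_is_identity(self):
        df = pd.DataFrame(
            {"entry_age": [30.0], "event": [1], "exit_age": [30.5],
             "prior_cancer": [1], "mastectomy_history": [1]}
        )
        kept, tally = apply_eligibility(df, rules=())
        assert len(kept) == 1 and tally == {}

    def test_one_exclusion_per_rule_on_constructed_records(self):
        rows = [
            # violates entry age
            dict(entry_age=35.0, event=0, exit_age=45.0, prior_cancer=0, mastectomy_history=0),
            # prior cancer
            dict(entry_age=50.0, event=0, exit_age=60.0, prior_cancer=1, mastectomy_history=0),
            # mastectomy history
            dict(entry_age=50.0, event=0, exit_age=60.0, prior_cancer=0, mastectomy_history=1),
            # event in the first year (prevalent)
            dict(entry_age=50.0, event=1, exit_age=50.7, prior_cancer=0, mastectomy_history=0),
            # censored with <= 1 year of follow-up
            dict(entry_age=50.0, event=0, exit_age=50.8, prior_cancer=0, mastectomy_history=0),
            # fully eligible
            dict(entry_age=50.0, event=0, exit_age=61.0, prior_cancer=0, mastectomy_history=0),
        ]
        kept, tally = apply_eligibility(pd.DataFrame(rows))
        assert tally == {
            "entry_age": 1, "prior_cancer": 1, "mastectomy": 1,
            "prevalent_event": 1, "short_followup": 1,
        }
        assert len(kept) == 1

    def test_generator_flags_reach_tally(self, model, synthetic_table):
        cfg = small_config(prior_cancer_prob=0.05, mastectomy_prob=0.02)
        _, tally = simulate_cohort(cfg, model, synthetic_table)
        assert tally["prior_cancer"] > 0 and tally["mastectomy"] > 0


class TestDeterminismAndStructure:
    def test_identical_seed_gives_byte_identical_csv(self, model, synthetic_table):
        outs = []
        for _ in range(2):
            cohort, _ = simulate_cohort(small_config(), model, synthetic_table)
            buf = io.StringIO()
            write_cohort_csv(cohort, buf)
            outs.append(buf.getvalue())
        assert outs[0] == outs[1]

    def test_different_seeds_differ(self, model, synthetic_table):
        a, _ = simulate_cohort(small_config(), model, synthetic_table)
        b, _ = simulate_cohort(small_config(seed=12), model, synthetic_table)
        assert not a["exit_age"].equals(b["exit_age"])

    def test_case_fraction_in_plausible_band(self, model, synthetic_table):
        cohort, _ = simulate_cohort(CohortConfig(n_women=50_000, seed=13), model, synthetic_table)
        assert 0.02 <= cohort["event"].mean() <= 0.04

    def test_missingness_applied_at_configured_rates(self, model, synthetic_table):
        cohort, _ = simulate_cohort(CohortConfig(n_women=20_000, seed=14), model, synthetic_table)
        frac = (cohort["menopause"] == "").mean()
        assert abs(frac - 0.44) < 0.02
        assert (cohort.loc[cohort["parity"] == "0", "first_birth"] == "").all()

    def test_config_yaml_roundtrip(self, tmp_path):
        cfg = small_config(age_multipliers=[(0.0, 50.0, 1.5819)])
        path = tmp_path / "cohort.yaml"
        cfg.to_yaml(path)
        back = CohortConfig.from_yaml(path)
        assert back == cfg

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            CohortConfig(n_women=0)
        with pytest.raises(ConfigError):
            CohortConfig(age_multipliers=[(50.0, 40.0, 1.0)])
        with pytest.raises(ConfigError):
            CohortConfig(missingness={"bmi": 1.5})


def test_self_consistent_expected_close_to_observed(model, synthetic_table):
    """Truth = prediction model: E tracks O at Monte-Carlo accuracy."""
    cohort, _ = simulate_cohort(CohortConfig(n_women=50_000, seed=15), model, synthetic_table)
    pred = predict_cohort(cohort, model, synthetic_table)
    E = pred["abs_risk"].sum()
    O = cohort["event"].sum()
    assert abs(E - O) <= 3 * np.sqrt(O)
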