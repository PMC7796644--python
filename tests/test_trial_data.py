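import numpy as np
import pandas as pd
import pytest

from wcetrial.trial_data import (build_counting_process, read_trial_csv,
                                 read_long_csv, shift_baseline,
                                 validate_counting_process, write_long_csv,
                                 write_trial_csv, Cohort)


def _mini_trial():
    patients = pd.DataFrame({
        "patient_id": ["a", "b", "c"],
        "arm": ["maintenance", "control", "maintenance"],
        "age_group": ["<65", "65-74", ">=75"],
        "sex": ["F", "M", "M"],
        "primary_resected": [True, False, True],
        "alk_phos_gt300": [False, False, True],
        "tumor_site": ["left", "rectum", "unspecified_colon"],
        "randomization_time": [0.0, 0.0, 0.0],
    })
    doses = pd.DataFrame({
        "patient_id": ["a", "a", "b"],
        "time": [100.0, 200.0, 150.0],
        "dose": [1.0, 1.0, 1.0],
    })
    updates = pd.DataFrame({
        "patient_id": ["a", "a", "b", "c"],
        "time": [0.0, 232.0, 0.0, 0.0],
        "who_ps": [0, 1, 1, 2],
        "any_toxicity": [False, True, False, False],
        "weight_kg": [70.0, 68.0, 80.0, 60.0],
        "hemoglobin": [13.0, 12.5, 11.0, 12.0],
        "bilirubin": [8.0, 9.0, 7.0, 8.0],
        "blood_pressure": [130.0, 128.0, 140.0, 120.0],
    })
    outcomes = pd.DataFrame({
        "patient_id": ["a", "b", "c"],
        "followup_end": [400.0, 150.0, 282.0],
        "event": [True, True, False],
        "progression_day": [np.nan, np.nan, np.nan],
    })
    return patients, doses, updates, outcomes


class TestShiftBaseline:
    def test_death_before_landmark_excluded(self):
        patients, doses, updates, outcomes = _mini_trial()
        cohort = shift_baseline(patients, doses, updates, outcomes, 182.0)
        # b died at day 150 < 182
        assert cohort.exclusions["died_before_baseline"] == 1
        assert set(cohort.patients.patient_id) == {"a", "c"}

    def test_times_shifted(self):
        patients, doses, updates, outcomes = _mini_trial()
        cohort = shift_baseline(patients, doses, updates, outcomes, 182.0)
        out_a = cohort.outcomes.set_index("patient_id").loc["a"]
        assert out_a["followup_end"] == 400.0 - 182.0
        dose_times = cohort.doses[cohort.doses.patient_id == "a"]["time"].tolist()
        assert dose_times == [100.0 - 182.0, 200.0 - 182.0]

    def test_induction_doses_flagged_not_dropped(self):
        patients, doses, updates, outcomes = _mini_trial()
        cohort = shift_baseline(patients, doses, updates, outcomes, 182.0)
        d = cohort.doses[cohort.doses.patient_id == "a"]
        assert d["induction_period"].tolist() == [True, False]

    def test_exclusion_accounting(self, small_cohort):
        c = small_cohort
        cohort = shift_baseline(c.patients, c.doses, c.updates, c.outcomes)
        assert len(c.patients) == cohort.n_patients + sum(cohort.exclusions.values())

    def test_missing_covariates_excluded(self):
        patients, doses, updates, outcomes = _mini_trial()
        patients.loc[patients.patient_id == "c", "tumor_site"] = np.nan
        cohort = shift_baseline(patients, doses, updates, outcomes, 182.0)
        assert cohort.exclusions["missing_covariates"] == 1
        assert "c" not in set(cohort.patients.patient_id)

    def test_progression_before_landmark_excluded(self):
        patients, doses, updates, outcomes = _mini_trial()
        outcomes.loc[outcomes.patient_id == "c", "progression_day"] = 90.0
        cohort = shift_baseline(patients, doses, updates, outcomes, 182.0)
        assert cohort.exclusions["progressed_before_baseline"] == 1

    def test_invalid_landmark(self):
        patients, doses, updates, outcomes = _mini_trial()
        with pytest.raises(ValueError):
            shift_baseline(patients, doses, updates, outcomes, 0.0)

    def test_outcome_before_randomization_rejected(self):
        patients, doses, updates, outcomes = _mini_trial()
        outcomes.loc[0, "followup_end"] = -1.0
        with pytest.raises(ValueError):
            shift_baseline(patients, doses, updates, outcomes, 182.0)


class TestCountingProcess:
    def _one_patient_cohort(self, extra_event_time=None):
        patients, doses, updates, outcomes = _mini_trial()
        cohort = shift_baseline(patients, doses, updates, outcomes, 182.0)
        return cohort

    def test_partition_at_event_times(self):
        patients, doses, updates, outcomes = _mini_trial()
        cohort = shift_baseline(patients, doses, updates, outcomes, 182.0)
        table = build_counting_process(cohort, cut_policy="event_times")
        # single cohort event at 218 (patient a); patient c censored at 100
        rows_a = table[table.patient_id == "a"]
        assert rows_a["stop"].max() == pytest.approx(218.0)
        validate_counting_process(table)

    def test_locf_covariate_change(self):
        patients, doses, updates, outcomes = _mini_trial()
        cohort = shift_baseline(patients, doses, updates, outcomes, 182.0)
        table = build_counting_process(cohort, cut_policy="union_of_change_times")
        rows_a = table[table.patient_id == "a"].sort_values("start")
        # update at shifted time 50 (=232-182): who_ps changes 0 -> 1 from 50 on
        before = rows_a[rows_a["stop"] <= 50.0]
        after = rows_a[rows_a["start"] >= 50.0]
        assert (before["who_ps"] == 0).all()
        assert (after["who_ps"] == 1).all()
        assert 50.0 in rows_a["start"].to_numpy()

    def test_event_only_on_final_row(self, small_table):
        _, table = small_table
        validate_counting_process(table)
        per = table.groupby("patient_id")["event"].sum()
        assert set(per.unique()) <= {0, 1}

    def test_partition_covers_followup(self, small_table):
        cohort, table = small_table
        ends = cohort.outcomes.set_index("patient_id")["followup_end"]
        for pid, g in table.groupby("patient_id"):
            g = g.sort_values("start")
            assert g["start"].iloc[0] == 0.0
            assert g["stop"].iloc[-1] == pytest.approx(ends[pid])
            np.testing.assert_allclose(g["start"].to_numpy()[1:],
                                       g["stop"].to_numpy()[:-1])

    def test_locf_invariant_against_raw_updates(self, small_table):
        cohort, table = small_table
        upd = cohort.updates
        rng = np.random.default_rng(0)
        sample = table.sample(60, random_state=1)
        for row in sample.itertuples():
            u = upd[(upd.patient_id == row.patient_id) & (upd.time <= row.start)]
            if len(u):
                assert row.who_ps == u.sort_values("time")["who_ps"].iloc[-1]

    def test_update_after_followup_warns(self):
        patients, doses, updates, outcomes = _mini_trial()
        updates.loc[len(updates)] = ["a", 500.0, 1, False, 70, 13, 8, 130]
        cohort = shift_baseline(patients, doses, updates, outcomes, 182.0)
        with pytest.warns(UserWarning, match="after follow-up"):
            build_counting_process(cohort)

    def test_unknown_cut_policy(self):
        patients, doses, updates, outcomes = _mini_trial()
        cohort = shift_baseline(patients, doses, updates, outcomes, 182.0)
        with pytest.raises(ValueError):
            build_counting_process(cohort, cut_policy="weekly")


class TestCsvRoundTrip:
    def test_trial_round_trip(self, tmp_path):
        patients, doses, updates, outcomes = _mini_trial()
        write_trial_csv(tmp_path, patients, doses, updates, outcomes)
        p2, d2, u2, o2 = read_trial_csv(tmp_path)
        pd.testing.assert_frame_equal(p2, patients)
        pd.testing.assert_frame_equal(d2, doses)
        pd.testing.assert_frame_equal(u2, updates)
        pd.testing.assert_frame_equal(o2, outcomes)

    def test_missing_column_named(self, tmp_path):
        patients, doses, updates, outcomes = _mini_trial()
        write_trial_csv(tmp_path, patients, doses, updates, outcomes)
        (tmp_path / "patients.csv").write_text(
            patients.drop(columns=["arm"]).to_csv(index=False))
        with pytest.raises(ValueError, match="arm"):
            read_trial_csv(tmp_path)

    def test_long_round_trip(self, tmp_path, small_table):
        _, table = small_table
        path = tmp_path / "long.csv"
        write_long_csv(table, path)
        back = read_long_csv(path)
        assert len(back) == len(table)
        np.testing.assert_allclose(back["stop"].to_numpy(),
                                   table["stop"].to_numpy())
        assert back["event"].sum() == table["event"].sum()
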