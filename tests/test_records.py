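"""Record builder: inclusion filters, window aggregation, record assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hbforecast import (
    aggregate_dose_window,
    apply_inclusion_criteria,
    build_records,
    extract_lab_features,
    extract_session_features,
)
from hbforecast.records import InclusionReport, load_records, save_records
from hbforecast.simulate import Cohort


def toy_profiles(rows):
    return pd.DataFrame(rows, columns=["patient_id", "vintage",
                                       "followup_start", "followup_end"])


def toy_doses(rows):
    return pd.DataFrame(rows, columns=["patient_id", "date", "drug", "amount"])


START = pd.Timestamp("2006-01-01")


class TestInclusionCriteria:
    @staticmethod
    def five_patient_cohort():
        """A ok; B short follow-up; C no darbepoetin; D 450 ug; E 350 mg iron."""
        profiles = toy_profiles([
            ("A", 2.0, START, START + pd.Timedelta(days=300)),
            ("B", 2.0, START, START + pd.Timedelta(days=150)),   # ~5 months
            ("C", 2.0, START, START + pd.Timedelta(days=300)),
            ("D", 2.0, START, START + pd.Timedelta(days=300)),
            ("E", 2.0, START, START + pd.Timedelta(days=300)),
        ])
        d = START + pd.Timedelta(days=30)
        doses = toy_doses([
            ("A", d, "darbepoetin", 20.0), ("A", d, "iron", 100.0),
            ("B", d, "darbepoetin", 20.0),
            ("C", d, "iron", 100.0),
            ("D", d, "darbepoetin", 450.0),
            ("E", d, "darbepoetin", 20.0), ("E", d, "iron", 350.0),
        ])
        return profiles, doses

    def test_five_patient_toy_cohort(self):
        profiles, doses = self.five_patient_cohort()
        kept, report = apply_inclusion_criteria(profiles, doses)
        assert kept == ["A"]
        reasons = {e["patient_id"]: e["reason"] for e in report.excluded}
        assert reasons == {
            "B": "followup_lt_6_months",
            "C": "no_iv_darbepoetin",
            "D": "darbepoetin_dose_gt_400ug",
            "E": "iron_dose_gt_300mg",
        }
        assert (report.n_initial, report.n_after_followup_filter,
                report.n_after_esa_filter, report.n_after_dose_filter) == (5, 4, 3, 1)

    def test_all_compliant_keeps_everyone(self):
        profiles, doses = self.five_patient_cohort()
        profiles = profiles[profiles["patient_id"] == "A"]
        doses = doses[doses["patient_id"] == "A"]
        kept, report = apply_inclusion_criteria(profiles, doses)
        assert kept == ["A"] and report.excluded == []

    def test_all_short_followup_keeps_nobody(self):
        profiles = toy_profiles([
            (p, 2.0, START, START + pd.Timedelta(days=100)) for p in "XYZ"])
        doses = toy_doses([(p, START, "darbepoetin", 20.0) for p in "XYZ"])
        kept, report = apply_inclusion_criteria(profiles, doses)
        assert kept == [] and report.n_after_followup_filter == 0

    def test_incident_patient_excluded(self):
        profiles = toy_profiles([("N", 0.1, START, START + pd.Timedelta(days=300))])
        doses = toy_doses([("N", START, "darbepoetin", 20.0)])
        kept, report = apply_inclusion_criteria(profiles, doses)
        assert kept == [] and report.excluded[0]["reason"] == "not_prevalent"

    def test_idempotent(self, small_cohort):
        kept1, _ = apply_inclusion_criteria(small_cohort.profiles, small_cohort.doses)
        sub_profiles = small_cohort.profiles[
            small_cohort.profiles["patient_id"].isin(kept1)]
        sub_doses = small_cohort.doses[small_cohort.doses["patient_id"].isin(kept1)]
        kept2, report2 = apply_inclusion_criteria(sub_profiles, sub_doses)
        assert kept2 == sorted(kept1) or set(kept2) == set(kept1)
        assert report2.excluded == []

    def test_missing_column_named_in_error(self):
        profiles, doses = self.five_patient_cohort()
        with pytest.raises(ValueError, match="vintage"):
            apply_inclusion_criteria(profiles.drop(columns=["vintage"]), doses)
        with pytest.raises(ValueError, match="amount"):
            apply_inclusion_criteria(profiles, doses.drop(columns=["amount"]))

    def test_report_json_round_trip(self):
        profiles, doses = self.five_patient_cohort()
        _, report = apply_inclusion_criteria(profiles, doses)
        assert InclusionReport.from_json(report.to_json()) == report


class TestDoseWindows:
    T = pd.Timestamp("2006-06-30")

    def boundary_doses(self):
        return toy_doses([
            ("A", self.T + pd.Timedelta(days=d), "darbepoetin", a)
            for d, a in [(-91, 20.0), (-90, 20.0), (0, 20.0),
                         (1, 30.0), (90, 30.0), (91, 30.0)]
        ])

    def test_boundary_enumeration(self):
        """Half-open windows: anchor day counts in the lookback only."""
        doses = self.boundary_doses()
        back = aggregate_dose_window(doses, "A", self.T, -90, 0, "darbepoetin")
        fwd = aggregate_dose_window(doses, "A", self.T, 0, 90, "darbepoetin")
        assert back == 20.0        # t-90 and t-91 fall outside (t-90, t]
        assert fwd == 60.0         # t+1 and t+90 inside (t, t+90]; t, t+91 outside

    def test_empty_window_is_zero(self):
        assert aggregate_dose_window(self.boundary_doses(), "A", self.T,
                                     -90, 0, "iron") == 0.0

    def test_degenerate_window_rejected(self):
        with pytest.raises(ValueError, match="interval"):
            aggregate_dose_window(self.boundary_doses(), "A", self.T, 0, 0, "iron")

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(-120, 120), st.floats(0, 100)), max_size=12),
           st.integers(-100, 10))
    def test_matches_brute_force_oracle(self, pairs, start):
        doses = toy_doses([("A", self.T + pd.Timedelta(days=d), "darbepoetin", a)
                           for d, a in pairs])
        end = start + 90
        expected = sum(a for d, a in pairs if start < d <= end)
        got = aggregate_dose_window(doses, "A", self.T, start, end, "darbepoetin")
        assert got == pytest.approx(expected, abs=1e-9)


class TestLabAndSessionFeatures:
    T = pd.Timestamp("2006-06-30")

    def test_most_recent_wins(self):
        labs = pd.DataFrame({
            "patient_id": "A", "analyte": "ferritin",
            "date": [self.T - pd.Timedelta(days=80), self.T - pd.Timedelta(days=10)],
            "value": [300.0, 400.0],
        })
        assert extract_lab_features(labs, "A", self.T)["ferritin"] == 400.0

    def test_outside_window_is_missing(self):
        labs = pd.DataFrame({
            "patient_id": "A", "analyte": "ferritin",
            "date": [self.T - pd.Timedelta(days=100)], "value": [300.0],
        })
        assert np.isnan(extract_lab_features(labs, "A", self.T)["ferritin"])

    def test_session_means_and_sd(self):
        sessions = pd.DataFrame({
            "patient_id": "A",
            "date": [self.T - pd.Timedelta(days=d) for d in (6, 4, 2)],
            "duration": [230.0, 230.0, 230.0], "ektv": [1.2, 1.4, 1.6],
            "pre_weight": [72.0, 73.0, 74.0], "post_weight": [70.0, 70.0, 70.0],
        })
        feats = extract_session_features(sessions, "A", self.T)
        assert feats["ektv_mean"] == pytest.approx(1.4)
        assert feats["ektv_sd"] == pytest.approx(0.2)
        assert feats["pre_weight"] == pytest.approx(73.0)

    def test_single_session_sd_missing(self):
        sessions = pd.DataFrame({
            "patient_id": "A", "date": [self.T], "duration": [230.0],
            "ektv": [1.4], "pre_weight": [72.0], "post_weight": [70.0],
        })
        feats = extract_session_features(sessions, "A", self.T)
        assert np.isnan(feats["ektv_sd"]) and feats["ektv_mean"] == 1.4

    def test_sessions_per_week_uses_covered_span(self):
        """13 sessions whose span covers 30 days -> 13 / (30/7) sessions/week."""
        days = np.linspace(29, 0, 13).round().astype(int)
        sessions = pd.DataFrame({
            "patient_id": "A",
            "date": [self.T - pd.Timedelta(days=int(d)) for d in days],
            "duration": 230.0, "ektv": 1.4, "pre_weight": 72.0, "post_weight": 70.0,
        })
        feats = extract_session_features(sessions, "A", self.T)
        assert feats["sessions_per_week"] == pytest.approx(13 / (30 / 7))

    def test_no_sessions_all_missing(self):
        sessions = pd.DataFrame(columns=["patient_id", "date", "duration", "ektv",
                                         "pre_weight", "post_weight"])
        feats = extract_session_features(sessions, "A", self.T)
        assert all(np.isnan(v) for v in feats.values())


def minimal_cohort(hb_by_patient, extra_labs=None):
    """Cohort with monthly Hb labs only (day 15 of each month)."""
    profiles, labs = [], []
    for pid, values in hb_by_patient.items():
        profiles.append({
            "patient_id": pid, "age": 60.0, "sex": "male", "height": 170.0,
            "dry_weight": 70.0, "vintage": 3.0, "diabetes": 0,
            "vascular_access": "fistula", "modality": "HDF",
            "esa_sensitivity": 0.1, "rbc_lifespan": 75.0, "maturation_lag": 13.0,
            "baseline_production": 0.08,
            "followup_start": pd.Timestamp("2006-01-01"),
            "followup_end": pd.Timestamp("2008-01-01"),
        })
        for m, v in enumerate(values):
            labs.append({"patient_id": pid,
                         "date": pd.Timestamp("2006-01-15") + pd.DateOffset(months=m),
                         "analyte": "Hb", "value": v})
    labs = pd.DataFrame(labs + (extra_labs or []))
    empty_doses = pd.DataFrame(columns=["patient_id", "date", "drug", "amount", "route"])
    empty_sessions = pd.DataFrame(columns=["patient_id", "date", "duration", "ektv",
                                           "pre_weight", "post_weight"])
    empty_events = pd.DataFrame(columns=["patient_id", "date", "etype", "hb_effect"])
    return Cohort(pd.DataFrame(profiles), empty_doses, labs, empty_sessions, empty_events)


class TestBuildRecords:
    def test_monthly_series_pairing(self):
        cohort = minimal_cohort({"A": [11.0 + 0.1 * i for i in range(12)]})
        records = build_records(cohort)
        assert len(records) == 12
        assert records["valid"].sum() == 9          # last 3 anchors lack Hb(t+3)
        assert not records["valid"].iloc[-3:].any()
        first = records.iloc[0]
        assert first["delta_hb"] == pytest.approx(0.3)   # 3 months ahead, +0.1/month

    def test_single_measurement_invalid(self):
        records = build_records(minimal_cohort({"A": [11.0]}))
        assert len(records) == 1 and not records["valid"].iloc[0]

    def test_one_record_per_hb(self):
        cohort = minimal_cohort({"A": [11.0] * 10, "B": [12.0] * 10})
        assert len(build_records(cohort)) == 20

    def test_duplicate_hb_rejected(self):
        extra = [{"patient_id": "A", "date": pd.Timestamp("2006-01-15"),
                  "analyte": "Hb", "value": 9.0}]
        cohort = minimal_cohort({"A": [11.0] * 4}, extra_labs=extra)
        with pytest.raises(ValueError, match="duplicate Hb"):
            build_records(cohort)

    def test_no_lookahead_leakage(self, small_cohort, small_records):
        """Deleting everything after t leaves past-history features unchanged."""
        future_cols = {"esa_future", "iron_future", "delta_hb", "valid", "target_date"}
        sample = small_records[small_records["valid"]].iloc[5]
        pid, t = sample["patient_id"], sample["anchor_date"]

        def truncate(df, date_col="date"):
            keep = (df["patient_id"] != pid) | (pd.to_datetime(df[date_col]) <= t)
            return df[keep].reset_index(drop=True)

        truncated = Cohort(
            profiles=small_cohort.profiles,
            doses=truncate(small_cohort.doses),
            labs=truncate(small_cohort.labs),
            sessions=truncate(small_cohort.sessions),
            events=truncate(small_cohort.events),
        )
        records2 = build_records(truncated, [pid])
        row2 = records2[records2["record_id"] == sample["record_id"]].iloc[0]
        for col in small_records.columns:
            if col in future_cols:
                continue
            a, b = sample[col], row2[col]
            if isinstance(a, float):
                assert a == pytest.approx(b, nan_ok=True), col
            else:
                assert a == b, col

    def test_record_count_equals_hb_count(self, small_cohort, small_records):
        kept = set(small_records["patient_id"])
        hb = small_cohort.labs[(small_cohort.labs["analyte"] == "Hb")
                               & small_cohort.labs["patient_id"].isin(kept)]
        assert len(small_records) == len(hb)

    def test_csv_round_trip(self, small_records, tmp_path):
        path = tmp_path / "records.csv"
        save_records(small_records, path)
        back = load_records(path)
        assert list(back.columns) == list(small_records.columns)
        assert len(back) == len(small_records)
        np.testing.assert_allclose(back["delta_hb"], small_records["delta_hb"])
        assert (back["valid"] == small_records["valid"]).all()
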