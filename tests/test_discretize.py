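"""Observation-row construction: carry-forward, censoring, labels, splits."""

import numpy as np
import pandas as pd
import pytest

from akipredict import (
    build_rows,
    complete_case_filter,
    label_rows,
    split_cohort,
)
from akipredict.covariates import EXPOSURES, LAB_ANALYTES, class_covariates
from akipredict.errors import AkiPredictError, ConfigurationError

from oracles import bf_locf, bf_window_min

PATIENT = {
    "patient_id": "p1",
    "age": 60.0,
    "sex_male": 1.0,
    "race_black": 0.0,
    "surgical_admission": 0.0,
    "chf": 0.0,
    "hypertension": 0.0,
    "diabetes": 0.0,
    "liver_disease": 0.0,
    "elixhauser": 3.0,
    "rrt_time_h": np.nan,
    "death_time_h": np.nan,
}


def meas(rows):
    return pd.DataFrame(rows, columns=["time_h", "analyte", "value"]).assign(patient_id="p1")


def expo(rows):
    return pd.DataFrame(rows, columns=["time_h", "exposure"]).assign(patient_id="p1")


def test_one_row_per_event_with_carry_forward():
    m = meas([(0, "creatinine", 1.0), (6, "sodium", 140.0), (24, "creatinine", 1.1)])
    rows = build_rows(PATIENT, m, expo([]))
    assert list(rows["time_h"]) == [0, 6, 24]
    assert np.isnan(rows["sodium"].iloc[0])  # sodium not yet measured at 0h
    assert rows["last_creatinine"].iloc[1] == 1.0  # carried forward to 6h
    assert rows["sodium"].iloc[2] == 140.0


def test_rows_censored_at_and_after_onset():
    m = meas([(t, "creatinine", 1.0) for t in (10, 20, 30, 40)])
    rows = build_rows(PATIENT, m, expo([]), onset_time=30.0)
    assert list(rows["time_h"]) == [10, 20]


def test_rows_before_first_creatinine_have_missing_state():
    m = meas([(2, "sodium", 139.0), (8, "creatinine", 1.0)])
    rows = build_rows(PATIENT, m, expo([]))
    assert np.isnan(rows["last_creatinine"].iloc[0])
    assert np.isnan(rows["delta_creatinine_48h"].iloc[0])


def test_exposures_are_absorbing_and_create_rows():
    m = meas([(0, "creatinine", 1.0), (50, "creatinine", 1.0)])
    rows = build_rows(PATIENT, m, expo([(12, "icu")]))
    assert list(rows["time_h"]) == [0, 12, 50]
    assert list(rows["icu"]) == [0.0, 1.0, 1.0]


def test_unsorted_measurements_rejected():
    m = meas([(24, "creatinine", 1.0), (0, "creatinine", 1.0)])
    with pytest.raises(AkiPredictError):
        build_rows(PATIENT, m, expo([]))


class TestLabels:
    def test_gap_within_horizon_is_positive(self):
        assert label_rows(np.array([10.0]), 30.0).tolist() == [1]

    def test_gap_beyond_horizon_is_negative(self):
        assert label_rows(np.array([5.0]), 30.0).tolist() == [0]

    def test_row_exactly_horizon_before_event_is_positive(self):
        assert label_rows(np.array([6.0]), 30.0).tolist() == [1]

    def test_row_at_event_time_is_negative(self):
        assert label_rows(np.array([30.0]), 30.0).tolist() == [0]

    def test_no_event_all_zero(self):
        assert label_rows(np.arange(5, dtype=float), None).sum() == 0

    def test_negative_horizon_rejected(self):
        with pytest.raises(ConfigurationError):
            label_rows(np.array([0.0]), 10.0, horizon=-1.0)


def test_locf_matches_brute_force_on_fuzzed_patients():
    rng = np.random.default_rng(11)
    analytes = [a for a in LAB_ANALYTES if a != "creatinine"]
    for _ in range(50):
        recs = [(float(t), "creatinine", float(rng.uniform(0.5, 2)))
                for t in np.sort(rng.uniform(0, 200, rng.integers(2, 8)))]
        for a in rng.choice(analytes, size=3, replace=False):
            for t in np.sort(rng.uniform(0, 200, rng.integers(1, 6))):
                recs.append((float(t), a, float(rng.uniform(1, 100))))
        m = meas(recs).sort_values("time_h", kind="stable").reset_index(drop=True)
        rows = build_rows(PATIENT, m, expo([]))
        for a in set(r[1] for r in recs) - {"creatinine"}:
            sub = m[m["analyte"] == a]
            for _, row in rows.iterrows():
                expected = bf_locf(sub["time_h"].tolist(), sub["value"].tolist(), row["time_h"])
                got = row[a]
                assert (np.isnan(expected) and np.isnan(got)) or got == pytest.approx(expected)


def test_delta_creatinine_rederivable_from_raw_series():
    rng = np.random.default_rng(13)
    for _ in range(30):
        times = np.sort(rng.uniform(0, 300, rng.integers(3, 10)))
        values = rng.uniform(0.5, 3.0, times.size)
        m = meas([(float(t), "creatinine", float(v)) for t, v in zip(times, values)])
        rows = build_rows(PATIENT, m, expo([]))
        for _, row in rows.iterrows():
            t = row["time_h"]
            last = bf_locf(times.tolist(), values.tolist(), t)
            m48 = bf_window_min(times.tolist(), values.tolist(), t, 48.0)
            expected = 0.0 if m48 is None else last - m48
            assert row["delta_creatinine_48h"] == pytest.approx(expected, abs=1e-12)


class TestCompleteCase:
    def test_missing_lab_dropped_for_lab_class_kept_for_demographic(self, small_matrix):
        _, matrix, _ = small_matrix
        missing_k = matrix[matrix["potassium"].isna()]
        assert len(missing_k) > 0
        lab_rows, _ = complete_case_filter(matrix, "laboratory")
        assert lab_rows["potassium"].notna().all()
        demo_rows, dropped = complete_case_filter(matrix, "demographic")
        assert len(demo_rows) == len(matrix) and dropped == 0.0

    def test_unknown_class_rejected(self, small_matrix):
        _, matrix, _ = small_matrix
        with pytest.raises(ValueError):
            complete_case_filter(matrix, "nope")

    def test_dropped_fraction_matches_enumeration(self, small_matrix):
        _, matrix, _ = small_matrix
        required = list(class_covariates("laboratory"))
        expected = matrix[required].isna().any(axis=1).mean()
        _, dropped = complete_case_filter(matrix, "laboratory")
        assert dropped == pytest.approx(expected)


class TestSplit:
    def _patients(self, n, hospital="H1"):
        return pd.DataFrame({"patient_id": [f"p{i}" for i in range(n)], "hospital": hospital})

    def test_exact_two_thirds_split(self):
        part = split_cohort(self._patients(9), seed=4)
        assert (part == "train").sum() == 6
        assert (part == "validation").sum() == 3

    def test_deterministic_under_seed(self):
        a = split_cohort(self._patients(50), seed=9)
        b = split_cohort(self._patients(50), seed=9)
        pd.testing.assert_series_equal(a, b)

    def test_external_hospitals_pass_through(self):
        pats = pd.concat([self._patients(6), self._patients(4, "H2").assign(
            patient_id=lambda d: "x" + d["patient_id"])], ignore_index=True)
        part = split_cohort(pats, seed=0)
        assert (part.loc[pats.loc[pats.hospital == "H2", "patient_id"]] == "H2").all()

    def test_every_patient_in_exactly_one_partition(self, small_matrix):
        included, matrix, _ = small_matrix
        per_patient = matrix.groupby("patient_id")["partition"].nunique()
        assert (per_patient == 1).all()

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ConfigurationError):
            split_cohort(self._patients(5), fractions=(0.5, 0.2), seed=0)


def test_no_positive_label_at_or_after_event(small_matrix):
    _, matrix, events = small_matrix
    ev = events.set_index("patient_id")["onset_time_h"]
    joined = matrix.join(ev, on="patient_id")
    with_event = joined[joined["onset_time_h"].notna()]
    # rows at/after onset must not exist at all
    assert (with_event["time_h"] < with_event["onset_time_h"]).all()
    # positives only within the 24h window before onset
    pos = with_event[with_event["label_aki_24h"] == 1]
    assert ((pos["onset_time_h"] - pos["time_h"]) <= 24 + 1e-9).all()


def test_every_onset_with_a_row_in_prior_24h_has_a_positive(small_matrix):
    _, matrix, events = small_matrix
    for _, ev in events.iterrows():
        sub = matrix[matrix["patient_id"] == ev["patient_id"]]
        in_window = sub[(sub["time_h"] < ev["onset_time_h"])
                        & (sub["time_h"] >= ev["onset_time_h"] - 24)]
        if len(in_window):
            assert in_window["label_aki_24h"].sum() >= 1
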