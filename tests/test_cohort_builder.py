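import datetime as dt

import pandas as pd
import pytest

from conftest import CUTOFF, make_events, make_patients
from riskprofile.cohort_builder import (
    ExposureWindow,
    SchemaError,
    apply_exclusions,
    build_exposure_lists,
    read_events,
    read_patients,
    write_events,
    write_patients,
)

WINDOW = ExposureWindow(CUTOFF)


class TestWindow:
    def test_120_days_inclusive_of_cutoff(self):
        assert WINDOW.start == dt.date(2020, 7, 9)
        assert dt.date(2020, 7, 9) in WINDOW
        assert dt.date(2020, 7, 8) not in WINDOW
        assert CUTOFF in WINDOW
        assert dt.date(2020, 11, 6) not in WINDOW

    def test_degenerate_length_rejected(self):
        with pytest.raises(ValueError):
            ExposureWindow(CUTOFF, 0)


class TestIO:
    def test_round_trip(self, tmp_path, small_dataset):
        _, patients, events, _ = small_dataset
        write_events(events, tmp_path / "events.csv")
        write_patients(patients, tmp_path / "patients.csv")
        ev = read_events(tmp_path / "events.csv")
        pt = read_patients(tmp_path / "patients.csv")
        assert len(ev) == len(events)
        assert len(pt) == len(patients)
        pd.testing.assert_frame_equal(ev, events.reset_index(drop=True))

    def test_unknown_event_type_rejected(self, tmp_path):
        ev = make_events([("p1", "dispensed", "N06AA09", "tablet", "2020-08-01")])
        ev.loc[0, "event_type"] = "faxed"
        write_events(ev, tmp_path / "e.csv")
        with pytest.raises(SchemaError, match="event_type"):
            read_events(tmp_path / "e.csv")

    def test_empty_file_with_header_gives_empty_frame(self, tmp_path):
        write_events(make_events([]), tmp_path / "e.csv")
        assert len(read_events(tmp_path / "e.csv")) == 0

    def test_missing_column_named(self, tmp_path):
        (tmp_path / "e.csv").write_text("patient_id,atc\np1,N06AA09\n")
        with pytest.raises(SchemaError, match="event_type"):
            read_events(tmp_path / "e.csv")

    def test_death_before_birth_rejected(self, tmp_path):
        pt = make_patients([("p1", "F", "1950-01-01", "1940-01-01")])
        write_patients(pt, tmp_path / "p.csv")
        with pytest.raises(SchemaError, match="death_date"):
            read_patients(tmp_path / "p.csv")


class TestExclusions:
    def test_no_contamination_is_identity(self):
        ev = make_events([("p1", "dispensed", "N06AA09", "tablet", "2020-08-01")])
        pt = make_patients([("p1", "F", "1950-01-01")])
        ev2, pt2, report = apply_exclusions(ev, pt, WINDOW)
        assert len(ev2) == 1 and len(pt2) == 1
        assert report.veterinary_events == 0
        assert report.deceased_patients == 0
        assert report.nonresident_patients == 0
        assert report.events_outside_window == 0
        assert report.patients_without_events == 0

    def test_event_outside_window_removed(self):
        ev = make_events([
            ("p1", "dispensed", "N06AA09", "tablet", "2020-07-08"),  # one day early
            ("p1", "dispensed", "N06AA09", "tablet", "2020-07-09"),
        ])
        pt = make_patients([("p1", "F", "1950-01-01")])
        ev2, _, report = apply_exclusions(ev, pt, WINDOW)
        assert report.events_outside_window == 1
        assert len(ev2) == 1

    def test_veterinary_atc_and_prescriber_removed(self):
        ev = make_events([
            ("p1", "dispensed", "QN02AA05", "tablet", "2020-08-01"),
            ("p1", "dispensed", "N06AA09", "tablet", "2020-08-01"),
        ])
        ev.loc[1, "prescriber_category"] = "veterinarian"
        pt = make_patients([("p1", "F", "1950-01-01")])
        ev2, pt2, report = apply_exclusions(ev, pt, WINDOW)
        assert report.veterinary_events == 2
        assert report.patients_without_events == 1
        assert len(ev2) == 0 and len(pt2) == 0

    def test_deceased_mid_window_excluded(self):
        ev = make_events([("p1", "dispensed", "N06AA09", "tablet", "2020-08-01")])
        pt = make_patients([("p1", "F", "1950-01-01", "2020-09-01")])
        _, pt2, report = apply_exclusions(ev, pt, WINDOW)
        assert report.deceased_patients == 1
        assert len(pt2) == 0

    def test_death_after_cutoff_kept(self):
        ev = make_events([("p1", "dispensed", "N06AA09", "tablet", "2020-08-01")])
        pt = make_patients([("p1", "F", "1950-01-01", "2020-11-06")])
        _, pt2, report = apply_exclusions(ev, pt, WINDOW)
        assert report.deceased_patients == 0
        assert len(pt2) == 1

    def test_nonresident_removed_with_events(self):
        ev = make_events([("p1", "dispensed", "N06AA09", "tablet", "2020-08-01")])
        pt = make_patients([("p1", "F", "1950-01-01", None, False)])
        ev2, pt2, report = apply_exclusions(ev, pt, WINDOW)
        assert report.nonresident_patients == 1
        assert report.nonresident_events == 1
        assert len(ev2) == 0 and len(pt2) == 0

    def test_idempotent(self, small_dataset):
        _, patients, events, _ = small_dataset
        ev1, pt1, _ = apply_exclusions(events, patients, WINDOW)
        ev2, pt2, report2 = apply_exclusions(ev1, pt1, WINDOW)
        pd.testing.assert_frame_equal(ev1, ev2)
        pd.testing.assert_frame_equal(pt1, pt2)
        assert report2.n_events_in == report2.n_events_out


class TestExposureLists:
    def test_same_substance_counted_once(self):
        ev = make_events([
            ("p1", "dispensed", "N06AA09", "tablet", "2020-08-01"),
            ("p1", "dispensed", "N06AA09", "tablet", "2020-09-01"),
        ])
        (exp,) = build_exposure_lists(ev, WINDOW)
        assert exp.substances == frozenset({"N06AA09"})
        assert exp.n_unique == 1

    def test_topical_only_substance_excluded(self):
        ev = make_events([
            ("p1", "dispensed", "D07AC01", "cream", "2020-08-01"),
            ("p1", "dispensed", "N06AA09", "cream", "2020-08-01"),
            ("p1", "dispensed", "N06AA09", "tablet", "2020-08-02"),
        ])
        (exp,) = build_exposure_lists(ev, WINDOW, exclude_topical=True)
        # systemic use of the same substance keeps it in
        assert exp.substances == frozenset({"N06AA09"})
        (exp2,) = build_exposure_lists(ev, WINDOW, exclude_topical=False)
        assert exp2.substances == frozenset({"D07AC01", "N06AA09"})

    def test_orders_active_on_cutoff_day(self):
        ev = make_events([
            ("p1", "order", "N06AA09", "tablet", "2020-08-01", "2020-08-01", "2020-11-05"),
            ("p1", "order", "B01AF02", "tablet", "2020-08-01", "2020-08-01", "2020-11-04"),
            ("p1", "order", "N02AA05", "tablet", "2020-08-01", "2020-08-01", None),
        ])
        (exp,) = build_exposure_lists(ev, WINDOW, source_mode="orders_on_day")
        assert exp.substances == frozenset({"N06AA09", "N02AA05"})

    def test_unknown_source_mode_rejected(self):
        with pytest.raises(ValueError, match="source_mode"):
            build_exposure_lists(make_events([]), WINDOW, source_mode="all")

    def test_dispensed_only_subset_of_combined(self, small_dataset, kb):
        _, patients, events, _ = small_dataset
        ev, pt, _ = apply_exclusions(events, patients, WINDOW)
        ids = pt["patient_id"]
        combined = {e.patient_id: e.substances for e in build_exposure_lists(
            ev, WINDOW, source_mode="combined", patient_ids=ids)}
        dispensed = {e.patient_id: e.substances for e in build_exposure_lists(
            ev, WINDOW, source_mode="dispensed_only", patient_ids=ids)}
        assert set(combined) == set(dispensed)
        for pid in combined:
            assert dispensed[pid] <= combined[pid]

    def test_fixed_cohort_includes_empty_lists(self):
        ev = make_events([("p1", "dispensed", "N06AA09", "tablet", "2020-08-01")])
        exps = build_exposure_lists(ev, WINDOW, patient_ids=["p1", "p2"])
        assert [e.patient_id for e in exps] == ["p1", "p2"]
        assert exps[1].n_unique == 0
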