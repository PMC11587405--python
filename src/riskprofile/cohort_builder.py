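"""Cohort and exposure-window construction from medication-event streams.

Raw inputs are two CSV tables:

``patients.csv``
    ``patient_id,gender,birth_date,death_date,resident`` — demographics and
    exclusion attributes.
``events.csv``
    ``patient_id,event_type,atc,drug_form,event_date,order_start,order_end,
    prescriber_category,private_provider`` — one row per medication event
    (prescription issued, pharmacy dispensation, in-care administration, or
    an EHR medication order).

The exposure window is the 120 days up to and including a cutoff day
(``[cutoff - 119, cutoff]``): concurrent medication use is approximated by
every unique substance the patient received during that window, because
dispensations typically cover up to three months of use.

Exclusion filters are applied in a fixed, reported order:

1. events outside the window (orders are kept if their active interval
   intersects the window);
2. veterinary events (ATC starting with "Q" or prescriber is a
   veterinarian);
3. non-resident patients with all their events;
4. patients who died on or before the window end;
5. patients left with no events.

Events flagged as coming from private providers are dropped before step 1.
The surviving events are reduced to per-patient unique substance sets under
one of three measures of concurrent medication: ``combined`` (dispensed +
administered during the window — the primary measure), ``dispensed_only``
(measure A), or ``orders_on_day`` (measure B: EHR orders active on the
cutoff day).  Topical drug forms can be dropped before deduplication, since
topically applied substances are not scored for systemic risk.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "EVENT_TYPES",
    "DRUG_FORMS",
    "TOPICAL_FORMS_DEFAULT",
    "SOURCE_MODES",
    "ExposureWindow",
    "ExposureList",
    "ExclusionReport",
    "SchemaError",
    "read_events",
    "read_patients",
    "write_events",
    "write_patients",
    "apply_exclusions",
    "build_exposure_lists",
]

EVENT_TYPES = frozenset({"prescribed", "dispensed", "administered", "order"})
DRUG_FORMS = frozenset(
    {
        "tablet", "capsule", "injection", "oral_solution", "patch", "cream",
        "ointment", "gel", "eye_drops", "nasal_spray", "inhalation",
        "suppository", "other",
    }
)
#: Drug forms treated as topical (excluded from risk scoring by default).
TOPICAL_FORMS_DEFAULT = frozenset({"cream", "ointment", "gel", "eye_drops"})
PRESCRIBER_CATEGORIES = frozenset({"physician", "nurse", "dentist", "veterinarian", "other"})
SOURCE_MODES = ("combined", "dispensed_only", "orders_on_day")

EVENT_COLUMNS = [
    "patient_id", "event_type", "atc", "drug_form", "event_date",
    "order_start", "order_end", "prescriber_category", "private_provider",
]
PATIENT_COLUMNS = ["patient_id", "gender", "birth_date", "death_date", "resident"]


class SchemaError(ValueError):
    """A CSV input violated the documented schema."""


@dataclass(frozen=True)
class ExposureWindow:
    """Closed date window ``[cutoff - (length_days - 1), cutoff]``."""

    cutoff_date: dt.date
    length_days: int = 120

    def __post_init__(self) -> None:
        if self.length_days < 1:
            raise ValueError("window length must be >= 1 day")

    @property
    def start(self) -> dt.date:
        return self.cutoff_date - dt.timedelta(days=self.length_days - 1)

    def __contains__(self, day: dt.date) -> bool:
        return self.start <= day <= self.cutoff_date


@dataclass(frozen=True)
class ExposureList:
    """A patient's unique substances surviving all filters."""

    patient_id: str
    substances: frozenset[str]

    @property
    def n_unique(self) -> int:
        return len(self.substances)


@dataclass
class ExclusionReport:
    """Counts of removals per filter step (events or patients as noted)."""

    private_provider_events: int = 0
    events_outside_window: int = 0
    veterinary_events: int = 0
    nonresident_patients: int = 0
    nonresident_events: int = 0
    deceased_patients: int = 0
    deceased_events: int = 0
    patients_without_events: int = 0
    n_events_in: int = 0
    n_patients_in: int = 0
    n_events_out: int = 0
    n_patients_out: int = 0

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.__dict__, fh, indent=1)
            fh.write("\n")


# ---------------------------------------------------------------------------
# I/O

_DATE_COLS_EVENTS = ["event_date", "order_start", "order_end"]
_DATE_COLS_PATIENTS = ["birth_date", "death_date"]


def read_events(path: str | Path) -> pd.DataFrame:
    """Read and validate an events CSV; dates become ``datetime64`` columns."""
    df = pd.read_csv(path, dtype={"patient_id": str, "atc": str}, keep_default_na=False,
                     na_values=[""])
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing event columns {missing}")
    df = df[EVENT_COLUMNS].copy()
    for col in _DATE_COLS_EVENTS:
        df[col] = _parse_dates(df[col], path, col)
    bad = ~df["event_type"].isin(EVENT_TYPES)
    if bad.any():
        row = df.index[bad][0]
        raise SchemaError(f"{path}: row {row}: unknown event_type {df.loc[row, 'event_type']!r}")
    bad = ~df["drug_form"].isin(DRUG_FORMS)
    if bad.any():
        row = df.index[bad][0]
        raise SchemaError(f"{path}: row {row}: unknown drug_form {df.loc[row, 'drug_form']!r}")
    bad = ~df["prescriber_category"].isin(PRESCRIBER_CATEGORIES)
    if bad.any():
        row = df.index[bad][0]
        raise SchemaError(
            f"{path}: row {row}: unknown prescriber_category "
            f"{df.loc[row, 'prescriber_category']!r}"
        )
    if (df["atc"].isna() | (df["atc"] == "")).any():
        raise SchemaError(f"{path}: empty atc code")
    both = df["order_start"].notna() & df["order_end"].notna()
    if (df.loc[both, "order_start"] > df.loc[both, "order_end"]).any():
        raise SchemaError(f"{path}: order_start after order_end")
    df["private_provider"] = _parse_bool(df["private_provider"], path, "private_provider")
    return df


def read_patients(path: str | Path) -> pd.DataFrame:
    """Read and validate a patients CSV."""
    df = pd.read_csv(path, dtype={"patient_id": str}, keep_default_na=False, na_values=[""])
    missing = [c for c in PATIENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing patient columns {missing}")
    df = df[PATIENT_COLUMNS].copy()
    for col in _DATE_COLS_PATIENTS:
        df[col] = _parse_dates(df[col], path, col)
    if not df["gender"].isin({"F", "M"}).all():
        raise SchemaError(f"{path}: gender must be F or M")
    if df["patient_id"].duplicated().any():
        raise SchemaError(f"{path}: duplicate patient_id")
    df["resident"] = _parse_bool(df["resident"], path, "resident")
    has_death = df["death_date"].notna()
    if (df.loc[has_death, "death_date"] < df.loc[has_death, "birth_date"]).any():
        raise SchemaError(f"{path}: death_date before birth_date")
    return df


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    _write_csv(events, EVENT_COLUMNS, _DATE_COLS_EVENTS, path)


def write_patients(patients: pd.DataFrame, path: str | Path) -> None:
    _write_csv(patients, PATIENT_COLUMNS, _DATE_COLS_PATIENTS, path)


def _write_csv(df: pd.DataFrame, columns: Sequence[str], date_cols: Sequence[str],
               path: str | Path) -> None:
    out = df[list(columns)].copy()
    for col in date_cols:
        out[col] = out[col].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, lineterminator="\n")


def _parse_dates(col: pd.Series, path, name: str) -> pd.Series:
    parsed = pd.to_datetime(col, format="%Y-%m-%d", errors="coerce")
    bad = parsed.isna() & col.notna() & (col != "")
    if bad.any():
        row = col.index[bad][0]
        raise SchemaError(f"{path}: row {row}: column {name}: bad date {col[row]!r}")
    return parsed


def _parse_bool(col: pd.Series, path, name: str) -> pd.Series:
    mapping = {"True": True, "False": False, True: True, False: False, 1: True, 0: False,
               "1": True, "0": False}
    out = col.map(mapping)
    if out.isna().any():
        row = col.index[out.isna()][0]
        raise SchemaError(f"{path}: row {row}: column {name}: bad boolean {col[row]!r}")
    return out.astype(bool)


# ---------------------------------------------------------------------------
# Exclusion filters


def apply_exclusions(
    events: pd.DataFrame,
    patients: pd.DataFrame,
    window: ExposureWindow,
) -> tuple[pd.DataFrame, pd.DataFrame, ExclusionReport]:
    """Apply the exclusion chain in its fixed order; idempotent.

    Returns filtered copies of both tables and a report counting removals
    per step.
    """
    report = ExclusionReport(n_events_in=len(events), n_patients_in=len(patients))
    ev = events.copy()
    pt = patients.copy()
    cutoff = pd.Timestamp(window.cutoff_date)
    start = pd.Timestamp(window.start)

    # 0. private-provider data are not part of the study material
    priv = ev["private_provider"].fillna(False).astype(bool)
    report.private_provider_events = int(priv.sum())
    ev = ev[~priv]

    # 1. events outside the window; orders kept if their active interval
    #    intersects the window (open-ended orders extend indefinitely)
    is_order = ev["event_type"] == "order"
    in_window = (ev["event_date"] >= start) & (ev["event_date"] <= cutoff)
    o_start = ev["order_start"].fillna(pd.Timestamp.min)
    o_end = ev["order_end"].fillna(pd.Timestamp.max)
    order_ok = (o_start <= cutoff) & (o_end >= start)
    keep = in_window.where(~is_order, order_ok)
    report.events_outside_window = int((~keep).sum())
    ev = ev[keep]

    # 2. veterinary events
    vet = ev["atc"].str.startswith("Q") | (ev["prescriber_category"] == "veterinarian")
    report.veterinary_events = int(vet.sum())
    ev = ev[~vet]

    # 3. non-resident patients and all their events
    nonres = ~pt["resident"]
    report.nonresident_patients = int(nonres.sum())
    gone = set(pt.loc[nonres, "patient_id"])
    report.nonresident_events = int(ev["patient_id"].isin(gone).sum())
    pt = pt[~nonres]
    ev = ev[~ev["patient_id"].isin(gone)]

    # 4. patients deceased before or during the window
    dead = pt["death_date"].notna() & (pt["death_date"] <= cutoff)
    report.deceased_patients = int(dead.sum())
    gone = set(pt.loc[dead, "patient_id"])
    report.deceased_events = int(ev["patient_id"].isin(gone).sum())
    pt = pt[~dead]
    ev = ev[~ev["patient_id"].isin(gone)]

    # 5. patients with no surviving medication events
    with_events = set(ev["patient_id"])
    no_events = ~pt["patient_id"].isin(with_events)
    report.patients_without_events = int(no_events.sum())
    pt = pt[~no_events]
    # events for patients absent from the patient table are also dropped
    ev = ev[ev["patient_id"].isin(set(pt["patient_id"]))]

    report.n_events_out = len(ev)
    report.n_patients_out = len(pt)
    return ev.reset_index(drop=True), pt.reset_index(drop=True), report


def build_exposure_lists(
    events: pd.DataFrame,
    window: ExposureWindow,
    source_mode: str = "combined",
    exclude_topical: bool = True,
    topical_forms: Iterable[str] = TOPICAL_FORMS_DEFAULT,
    patient_ids: Iterable[str] | None = None,
) -> list[ExposureList]:
    """Reduce filtered events to per-patient unique substance sets.

    ``source_mode``:

    - ``combined``: dispensed + administered events (primary measure);
    - ``dispensed_only``: dispensed events only (measure A);
    - ``orders_on_day``: EHR orders active on the cutoff day (measure B).

    ``patient_ids``, when given, fixes the cohort: every listed patient gets
    an exposure list (possibly empty), which keeps denominators comparable
    across source modes.  Otherwise only patients with a contributing event
    appear.
    """
    if source_mode not in SOURCE_MODES:
        raise ValueError(f"unknown source_mode {source_mode!r}; expected one of {SOURCE_MODES}")

    ev = events
    if source_mode == "combined":
        ev = ev[ev["event_type"].isin(["dispensed", "administered"])]
    elif source_mode == "dispensed_only":
        ev = ev[ev["event_type"] == "dispensed"]
    else:  # orders_on_day
        cutoff = pd.Timestamp(window.cutoff_date)
        is_order = ev["event_type"] == "order"
        o_start = ev["order_start"].fillna(pd.Timestamp.min)
        o_end = ev["order_end"].fillna(pd.Timestamp.max)
        ev = ev[is_order & (o_start <= cutoff) & (o_end >= cutoff)]

    if exclude_topical:
        ev = ev[~ev["drug_form"].isin(set(topical_forms))]

    grouped = ev.groupby("patient_id")["atc"].agg(frozenset).to_dict()
    if patient_ids is None:
        ids = sorted(grouped)
    else:
        ids = list(dict.fromkeys(patient_ids))
    return [ExposureList(pid, grouped.get(pid, frozenset())) for pid in ids]
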