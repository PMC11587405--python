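"""Synthetic regional population and medication-event stream.

The generator emulates the statistical shape of a regional pharmacoepidemiology
extract at desk scale: age/gender marginals of a medication-using population,
age-dependent polypharmacy (over-dispersed counts of distinct substances per
patient, rising with age), Zipf-like substance popularity over a formulary
that contains the risk-annotated reference substances plus risk-free filler
codes, event dates inside a 120-day exposure window, and contamination
records (veterinary events, deceased patients, non-residents, topical drug
forms) that exercise every exclusion filter.

It makes no attempt to reproduce any real region's prevalence figures — the
purpose is recovery testing: the generator exports exact ground truth
(post-filter substance sets, risk profiles and finite-population prevalences)
that an end-to-end pipeline run must reproduce exactly, because the scoring
is deterministic.

Randomness is driven by one global seed through a documented stream-splitting
scheme (``numpy.random.SeedSequence.spawn``): child 0 drives the population
table, child 1 the formulary popularity permutation, child 2 the event
stream.  Outputs are byte-identical across runs with the same parameters.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort_builder as cb
from .knowledge_base import KnowledgeBase, RiskCategory
from .risk_engine import LevelThresholds, compute_profiles, profiles_to_frame

__all__ = ["SimulationParams", "GroundTruth", "generate_population",
           "generate_events", "export_ground_truth", "simulate_dataset"]

AGE_GROUPS = ("<65", "65-74", ">=75")
_AGE_BOUNDS = {"<65": (0, 64), "65-74": (65, 74), ">=75": (75, 95)}

_SYSTEMIC_FORMS = ["tablet", "capsule", "oral_solution", "injection", "patch",
                   "nasal_spray", "inhalation", "suppository"]
_TOPICAL_FORMS = sorted(cb.TOPICAL_FORMS_DEFAULT)
_PRESCRIBERS = ["physician", "nurse", "dentist", "other"]
_PRESCRIBER_P = [0.90, 0.07, 0.02, 0.01]


@dataclass(frozen=True)
class SimulationParams:
    """Study-condition parameters of the synthetic region.

    Defaults: cutoff 2020-11-05 with a 120-day window; age mix of a
    medication-using population (62% under 65, 18% aged 65-74, 20% aged 75+);
    mean distinct substances per patient rising from 3 (under 65) to 8 (75+)
    with negative-binomial dispersion 2, covering the published per-cluster
    medians of roughly 2-12; Zipf exponent 1 for substance popularity; a few
    percent contamination per exclusion channel.
    """

    n_patients: int = 5000
    seed: int = 0
    cutoff_date: dt.date = dt.date(2020, 11, 5)
    window_days: int = 120
    gender_female_prob: float = 0.52
    age_group_probs: tuple[float, float, float] = (0.62, 0.18, 0.20)
    meds_mean_by_age_group: tuple[float, float, float] = (3.0, 6.0, 8.0)
    meds_dispersion: float = 2.0
    substance_zipf_exponent: float = 1.0
    frac_veterinary: float = 0.01
    frac_deceased: float = 0.02
    frac_nonresident: float = 0.02
    frac_topical_events: float = 0.05
    frac_administered_events: float = 0.15
    n_filler_substances: int = 200
    order_length_days: int = 90

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name in ("gender_female_prob", "frac_veterinary", "frac_deceased",
                     "frac_nonresident", "frac_topical_events",
                     "frac_administered_events"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability, got {v}")
        if abs(sum(self.age_group_probs) - 1.0) > 1e-9:
            raise ValueError("age_group_probs must sum to 1")
        if min(self.age_group_probs) < 0:
            raise ValueError("age_group_probs must be non-negative")
        if self.meds_dispersion <= 0 or self.substance_zipf_exponent <= 0:
            raise ValueError("dispersion and Zipf exponent must be positive")

    @property
    def window(self) -> cb.ExposureWindow:
        return cb.ExposureWindow(self.cutoff_date, self.window_days)

    def rngs(self) -> tuple[np.random.Generator, np.random.Generator, np.random.Generator]:
        """(population, formulary, events) generators from the global seed."""
        children = np.random.SeedSequence(self.seed).spawn(3)
        return tuple(np.random.default_rng(c) for c in children)  # type: ignore[return-value]

    def to_json(self, path: str | Path) -> None:
        doc = dataclasses.asdict(self)
        doc["cutoff_date"] = self.cutoff_date.isoformat()
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationParams":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        doc["cutoff_date"] = dt.date.fromisoformat(doc["cutoff_date"])
        for key in ("age_group_probs", "meds_mean_by_age_group"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)


@dataclass
class GroundTruth:
    """Exact post-filter truth exported alongside a simulated dataset."""

    exposures: dict[str, list[str]]
    profile_frame: pd.DataFrame
    prevalence: dict[str, dict[str, float]]

    def to_json(self, path: str | Path) -> None:
        doc = {
            "exposures": self.exposures,
            "profiles": self.profile_frame.to_dict(orient="list"),
            "prevalence": self.prevalence,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        return cls(
            exposures={k: list(v) for k, v in doc["exposures"].items()},
            profile_frame=pd.DataFrame(doc["profiles"]),
            prevalence=doc["prevalence"],
        )


def generate_population(params: SimulationParams) -> pd.DataFrame:
    """Simulate the patient table (schema of ``patients.csv``)."""
    rng, _, _ = params.rngs()
    n = params.n_patients
    cutoff = pd.Timestamp(params.cutoff_date)

    gender = np.where(rng.random(n) < params.gender_female_prob, "F", "M")
    group = rng.choice(3, size=n, p=np.asarray(params.age_group_probs))
    lo = np.array([_AGE_BOUNDS[g][0] for g in AGE_GROUPS])[group]
    hi = np.array([_AGE_BOUNDS[g][1] for g in AGE_GROUPS])[group]
    # age uniform within the group's completed-year span
    age_days = ((lo + rng.random(n) * (hi - lo + 1)) * 365.25).astype(np.int64)
    birth = cutoff - pd.to_timedelta(age_days, unit="D")

    dead = rng.random(n) < params.frac_deceased
    # death inside or shortly before the window, never before birth
    span = params.window_days + 60
    death_offset = rng.integers(0, span, size=n)
    death_np = (cutoff - pd.to_timedelta(death_offset, unit="D")).to_numpy()
    death_np = np.maximum(death_np, np.asarray(birth))
    death = pd.Series(death_np).where(dead, pd.NaT)

    resident = rng.random(n) >= params.frac_nonresident

    return pd.DataFrame(
        {
            "patient_id": [f"P{i:06d}" for i in range(1, n + 1)],
            "gender": gender,
            "birth_date": birth,
            "death_date": death,
            "resident": resident,
        }
    )


def _formulary(kb: KnowledgeBase, params: SimulationParams,
               rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Formulary codes and Zipf sampling weights.

    Fillers are ATC-shaped codes under the unused first letter ``X`` so that
    they pass format checks, never collide with annotated substances and
    never trip the veterinary (Q) filter.  Popularity ranks are a random
    permutation of the formulary, so annotated and filler substances mix.
    """
    if len(kb) == 0:
        raise ValueError("empty knowledge base")
    fillers = [f"X{i // 100:02d}ZZ{i % 100:02d}" for i in range(params.n_filler_substances)]
    codes = np.array(kb.substance_ids() + fillers)
    order = rng.permutation(len(codes))
    ranks = np.empty(len(codes), dtype=np.int64)
    ranks[order] = np.arange(1, len(codes) + 1)
    weights = 1.0 / ranks.astype(float) ** params.substance_zipf_exponent
    return codes, weights / weights.sum()


def _truncated_negbin(rng: np.random.Generator, mean: np.ndarray,
                      dispersion: float) -> np.ndarray:
    """Negative-binomial draws truncated to >= 1 by rejection."""
    p = dispersion / (dispersion + mean)
    out = rng.negative_binomial(dispersion, p)
    while True:
        zero = out == 0
        if not zero.any():
            return out
        out[zero] = rng.negative_binomial(dispersion, p[zero])


def generate_events(
    patients: pd.DataFrame, kb: KnowledgeBase, params: SimulationParams
) -> pd.DataFrame:
    """Simulate the medication-event stream (schema of ``events.csv``).

    Per patient: a truncated negative-binomial number of distinct substances
    (mean set by age group) sampled without replacement by Zipf weights; each
    substance yields 1-2 dispensed events at uniform dates in the window,
    plus an administered event with probability ``frac_administered_events``.
    Every dispensed/administered event is mirrored as an EHR order row active
    for ``order_length_days`` from its date.  Veterinary contamination is
    appended as extra events flagged by a Q-prefixed ATC code or a
    veterinarian prescriber.
    """
    _, rng_form, rng = params.rngs()
    codes, weights = _formulary(kb, params, rng_form)
    window = params.window
    start = pd.Timestamp(window.start)
    n_days = params.window_days

    cutoff = pd.Timestamp(params.cutoff_date)
    age_years = ((cutoff - patients["birth_date"]).dt.days / 365.25).to_numpy()
    group = np.digitize(age_years, [65, 75])  # 0: <65, 1: 65-74, 2: >=75
    means = np.asarray(params.meds_mean_by_age_group)[group]
    n_subst = _truncated_negbin(rng, means, params.meds_dispersion)
    n_subst = np.minimum(n_subst, len(codes))

    rows: list[tuple] = []

    def _add(pid: str, etype: str, atc: str, day_offset: int,
             prescriber: str | None = None) -> None:
        form = (
            _TOPICAL_FORMS[rng.integers(len(_TOPICAL_FORMS))]
            if rng.random() < params.frac_topical_events
            else _SYSTEMIC_FORMS[rng.integers(len(_SYSTEMIC_FORMS))]
        )
        date = start + pd.Timedelta(days=int(day_offset))
        if prescriber is None:
            prescriber = _PRESCRIBERS[rng.choice(len(_PRESCRIBERS), p=_PRESCRIBER_P)]
        rows.append((pid, etype, atc, form, date, pd.NaT, pd.NaT, prescriber, False))
        if etype in ("dispensed", "administered"):
            # mirror as an EHR medication order active from the event date
            rows.append(
                (pid, "order", atc, form, date, date,
                 date + pd.Timedelta(days=params.order_length_days), prescriber, False)
            )

    for pid, k in zip(patients["patient_id"], n_subst):
        chosen = rng.choice(len(codes), size=int(k), replace=False, p=weights)
        for idx in chosen:
            atc = str(codes[idx])
            for _ in range(int(rng.integers(1, 3))):
                _add(pid, "dispensed", atc, rng.integers(0, n_days))
            if rng.random() < params.frac_administered_events:
                _add(pid, "administered", atc, rng.integers(0, n_days))

    # veterinary contamination: extra events that the Q/veterinarian filter removes
    n_core = len(rows)
    n_vet = int(round(params.frac_veterinary * n_core))
    pids = patients["patient_id"].to_numpy()
    for _ in range(n_vet):
        pid = str(pids[rng.integers(len(pids))])
        if rng.random() < 0.5:
            _add(pid, "dispensed", f"QA01AA{rng.integers(1, 100):02d}",
                 rng.integers(0, n_days))
        else:
            idx = rng.integers(len(codes))
            _add(pid, "dispensed", str(codes[idx]), rng.integers(0, n_days),
                 prescriber="veterinarian")

    events = pd.DataFrame(rows, columns=cb.EVENT_COLUMNS)
    for col in ("event_date", "order_start", "order_end"):
        events[col] = pd.to_datetime(events[col])
    return events


def export_ground_truth(
    patients: pd.DataFrame,
    events: pd.DataFrame,
    kb: KnowledgeBase,
    params: SimulationParams,
    thresholds: LevelThresholds = LevelThresholds(),
) -> GroundTruth:
    """Exact post-filter exposure sets, risk profiles and prevalences.

    The exposure sets come from the same deterministic filter chain and
    scoring engine the pipeline uses — recovery tests check that an
    end-to-end run over the CSV round-trip reproduces these numbers exactly.
    Prevalences here are computed by direct counting, independently of the
    analysis module's tabulation.
    """
    window = params.window
    ev, pt, _ = cb.apply_exclusions(events, patients, window)
    exposures = cb.build_exposure_lists(
        ev, window, source_mode="combined", exclude_topical=True,
        patient_ids=pt["patient_id"],
    )
    profiles = compute_profiles(exposures, kb, thresholds)
    frame = profiles_to_frame(profiles)

    n = len(profiles)
    prevalence: dict[str, dict[str, float]] = {}
    for c in RiskCategory:
        counts = [0, 0, 0, 0]
        for p in profiles:
            counts[p.category_levels[c]] += 1
        prevalence[c.key] = {
            **{f"level_{lv}": counts[lv] / n for lv in range(4)},
            "any_risk": (counts[1] + counts[2] + counts[3]) / n,
        }
    return GroundTruth(
        exposures={e.patient_id: sorted(e.substances) for e in exposures},
        profile_frame=frame,
        prevalence=prevalence,
    )


def simulate_dataset(
    params: SimulationParams, kb: KnowledgeBase, outdir: str | Path | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate patients, events and ground truth; optionally write CSV/JSON."""
    patients = generate_population(params)
    events = generate_events(patients, kb, params)
    truth = export_ground_truth(patients, events, kb, params)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cb.write_patients(patients, outdir / "patients.csv")
        cb.write_events(events, outdir / "events.csv")
        truth.to_json(outdir / "ground_truth.json")
        params.to_json(outdir / "params.json")
    return patients, events, truth
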