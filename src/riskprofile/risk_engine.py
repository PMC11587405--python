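"""Per-patient nine-category risk scoring.

For a patient p with unique-substance exposure set E(p), the category sum is

    S(p, c) = sum over s in E(p) of r(s, c)

where r(s, c) in {0,1,2,3} is the knowledge-base risk value.  The sum is
mapped to an ordinal risk level L(p, c) in {0, I, II, III} by thresholds
(t_I, t_II, t_III), default (1, 2, 3):

    L = 0 if S < t_I;  I if t_I <= S < t_II;  II if t_II <= S < t_III;
    III if S >= t_III.

With the defaults a single value-3 substance reaches level III on its own,
and three value-1 substances are needed to reach level III — the behaviour
documented for the renal-toxicity category.  The 9-vector of levels is the
patient's *risk profile*; its total (the profile sum) ranges 0-27.  No dose,
duration or patient-factor adjustment is applied: the rule base scores
substances only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .knowledge_base import CATEGORY_KEYS, KnowledgeBase, RiskCategory

__all__ = [
    "LevelThresholds",
    "RiskProfile",
    "category_sum",
    "sum_to_level",
    "compute_profile",
    "compute_profiles",
    "profiles_to_frame",
    "MAX_PROFILE_SUM",
]

#: Nine categories, each capped at level 3.
MAX_PROFILE_SUM = 3 * len(RiskCategory)


@dataclass(frozen=True)
class LevelThresholds:
    """Minimum category sums for levels I, II and III (strictly increasing)."""

    t_I: int = 1
    t_II: int = 2
    t_III: int = 3

    def __post_init__(self) -> None:
        if not (0 < self.t_I < self.t_II < self.t_III):
            raise ValueError(
                f"thresholds must be positive and strictly increasing, "
                f"got ({self.t_I}, {self.t_II}, {self.t_III})"
            )


@dataclass(frozen=True)
class RiskProfile:
    """A patient's category sums, ordinal levels and profile sum."""

    patient_id: str
    category_sums: Mapping[RiskCategory, int]
    category_levels: Mapping[RiskCategory, int]
    profile_sum: int

    def level_vector(self) -> np.ndarray:
        """Levels as an int array in category-index order (input to clustering)."""
        return np.array([self.category_levels[c] for c in RiskCategory], dtype=np.int64)


def category_sum(
    substances: Iterable[str], kb: KnowledgeBase, category: RiskCategory
) -> int:
    """Sum of risk values over unique substances; unknown substances add 0."""
    return sum(kb.risk(s, category) for s in set(substances))


def sum_to_level(s: int, thresholds: LevelThresholds = LevelThresholds()) -> int:
    if s < 0:
        raise ValueError(f"category sum must be non-negative, got {s}")
    if s >= thresholds.t_III:
        return 3
    if s >= thresholds.t_II:
        return 2
    if s >= thresholds.t_I:
        return 1
    return 0


def compute_profile(
    exposure,
    kb: KnowledgeBase,
    thresholds: LevelThresholds = LevelThresholds(),
) -> RiskProfile:
    """Score one patient.

    ``exposure`` is either an object with ``patient_id`` and ``substances``
    attributes (an exposure list) or a ``(patient_id, substances)`` pair.
    """
    patient_id, substances = _unpack_exposure(exposure)
    unique = set(substances)
    sums = {c: sum(kb.risk(s, c) for s in unique) for c in RiskCategory}
    levels = {c: sum_to_level(v, thresholds) for c, v in sums.items()}
    return RiskProfile(
        patient_id=patient_id,
        category_sums=sums,
        category_levels=levels,
        profile_sum=sum(levels.values()),
    )


def compute_profiles(
    exposures: Sequence,
    kb: KnowledgeBase,
    thresholds: LevelThresholds = LevelThresholds(),
) -> list[RiskProfile]:
    """Score a batch of patients via a vectorized long-format join.

    Element-wise equal to :func:`compute_profile`, but computed by exploding
    the exposure lists into (patient, substance) rows, joining the knowledge
    base's value table and aggregating — the natural shape at population scale.
    """
    unpacked = [_unpack_exposure(e) for e in exposures]
    if not unpacked:
        return []
    ids = [pid for pid, _ in unpacked]

    rows = [
        (i, s) for i, (_, substances) in enumerate(unpacked) for s in set(substances)
    ]
    n = len(unpacked)
    sums = np.zeros((n, len(CATEGORY_KEYS)), dtype=np.int64)
    if rows:
        long = pd.DataFrame(rows, columns=["_i", "atc"])
        value_table = pd.DataFrame(
            {
                "atc": list(kb.records),
                **{
                    c.key: [kb.records[sid].risk(c) for sid in kb.records]
                    for c in RiskCategory
                },
            }
        )
        merged = long.merge(value_table, on="atc", how="left").fillna(0)
        agg = merged.groupby("_i")[CATEGORY_KEYS].sum()
        sums[agg.index.to_numpy()] = agg.to_numpy(dtype=np.int64)

    thr = np.array([thresholds.t_I, thresholds.t_II, thresholds.t_III])
    levels = (sums[..., None] >= thr).sum(axis=-1)

    out = []
    for i, pid in enumerate(ids):
        s = {c: int(sums[i, j]) for j, c in enumerate(RiskCategory)}
        lv = {c: int(levels[i, j]) for j, c in enumerate(RiskCategory)}
        out.append(RiskProfile(pid, s, lv, int(levels[i].sum())))
    return out


def profiles_to_frame(profiles: Sequence[RiskProfile]) -> pd.DataFrame:
    """Wide table: one row per patient, sum and level columns per category."""
    data: dict[str, list] = {"patient_id": [p.patient_id for p in profiles]}
    for c in RiskCategory:
        data[f"{c.key}_sum"] = [p.category_sums[c] for p in profiles]
        data[f"{c.key}_level"] = [p.category_levels[c] for p in profiles]
    data["profile_sum"] = [p.profile_sum for p in profiles]
    return pd.DataFrame(data)


def _unpack_exposure(exposure) -> tuple[str, set[str]]:
    if hasattr(exposure, "patient_id") and hasattr(exposure, "substances"):
        return exposure.patient_id, set(exposure.substances)
    patient_id, substances = exposure
    return patient_id, set(substances)
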