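"""Population-level analysis of risk profiles.

Three pieces:

* prevalence tables — per category, the exact finite-population proportion
  of patients at each risk level 0-III and with any increased risk
  (level >= I), optionally stratified by gender or by the three age groups
  (<65, 65-74, >=75 completed years at the cutoff day);
* non-parametric group comparisons on the ordinal risk level (0,1,2,3):
  Mann-Whitney U between two groups and Kruskal-Wallis H between several,
  both on midranks with the standard tie corrections.  With tens of
  thousands of heavily tied ordinal observations, the normal / chi-square
  approximations are the appropriate tool; exact permutation is reserved
  for test oracles at tiny n;
* the summarized-risk-value (SRV) medication ranking — among patients at
  level III for a category, each substance is scored r(s,c) x (number of
  level-III patients exposed to s), ranking the substances that contribute
  most to the highest risk level (a high-risk niche drug and a low-risk
  ubiquitous drug can rank similarly).

No multiple-testing adjustment is applied across the nine categories;
per-category p-values are reported as-is.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .knowledge_base import KnowledgeBase, RiskCategory
from .risk_engine import RiskProfile

__all__ = [
    "AGE_GROUP_LABELS",
    "TestResult",
    "age_group",
    "prevalence_table",
    "stratified_prevalence",
    "mann_whitney_u",
    "kruskal_wallis",
    "summarized_risk_values",
]

AGE_GROUP_LABELS = ("<65", "65-74", ">=75")


@dataclass(frozen=True)
class TestResult:
    """Outcome of a rank test on ordinal risk levels.

    ``statistic`` is U (Mann-Whitney, for the first sample) or the
    tie-corrected H (Kruskal-Wallis).  ``z`` is the normal deviate
    (Mann-Whitney only).  ``tie_factor`` is the tie-correction multiplier in
    (0, 1]; when it reaches 0 (all observations identical) the test is
    degenerate and ``p_value`` is reported as 1.
    """

    statistic: float
    p_value: float
    group_sizes: tuple[int, ...]
    tie_factor: float
    z: float | None = None
    degenerate: bool = False


def age_group(birth_date: dt.date | pd.Timestamp, cutoff_date: dt.date | pd.Timestamp) -> str:
    """Age group from completed years at the cutoff day."""
    birth = pd.Timestamp(birth_date)
    cutoff = pd.Timestamp(cutoff_date)
    if birth > cutoff:
        raise ValueError("birth_date after cutoff_date")
    years = cutoff.year - birth.year - (
        (cutoff.month, cutoff.day) < (birth.month, birth.day)
    )
    if years < 65:
        return "<65"
    if years < 75:
        return "65-74"
    return ">=75"


def _age_groups_vector(birth_dates: pd.Series, cutoff_date) -> pd.Series:
    cutoff = pd.Timestamp(cutoff_date)
    bd = pd.to_datetime(birth_dates)
    years = cutoff.year - bd.dt.year - (
        (bd.dt.month * 100 + bd.dt.day) > (cutoff.month * 100 + cutoff.day)
    ).astype(int)
    return pd.cut(years, bins=[-1, 64, 74, 1000], labels=AGE_GROUP_LABELS).astype(str)


def _levels_frame(profiles) -> pd.DataFrame:
    """Accept a profile frame or a sequence of RiskProfile; return the frame."""
    if isinstance(profiles, pd.DataFrame):
        return profiles
    from .risk_engine import profiles_to_frame

    return profiles_to_frame(list(profiles))


def prevalence_table(profiles) -> pd.DataFrame:
    """Exact per-category proportions at each level and with any risk.

    Returns a frame indexed by category key with columns ``level_0`` ...
    ``level_3``, ``any_risk`` and ``n``.  Raises on an empty cohort.
    """
    frame = _levels_frame(profiles)
    n = len(frame)
    if n == 0:
        raise ValueError("prevalence_table requires a non-empty cohort")
    rows = {}
    for c in RiskCategory:
        levels = frame[f"{c.key}_level"]
        counts = levels.value_counts().reindex(range(4), fill_value=0)
        props = (counts / n).to_numpy(dtype=float)
        rows[c.key] = {
            **{f"level_{lv}": props[lv] for lv in range(4)},
            "any_risk": float(props[1:].sum()),
            "n": n,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "category"
    return out


def stratified_prevalence(
    profiles, patients: pd.DataFrame, by: str, cutoff_date=None
) -> dict[str, pd.DataFrame]:
    """Per-stratum prevalence tables; strata partition the cohort.

    ``by`` is ``"gender"`` (strata F, M) or ``"age_group"`` (requires
    ``cutoff_date``).  Empty strata yield an empty frame with ``n = 0``.
    """
    frame = _levels_frame(profiles).merge(
        patients[["patient_id", "gender", "birth_date"]], on="patient_id", how="left"
    )
    if by == "gender":
        frame["_stratum"] = frame["gender"]
        strata = ["F", "M"]
    elif by == "age_group":
        if cutoff_date is None:
            raise ValueError("age_group stratification requires cutoff_date")
        frame["_stratum"] = _age_groups_vector(frame["birth_date"], cutoff_date)
        strata = list(AGE_GROUP_LABELS)
    else:
        raise ValueError(f"unknown stratification {by!r}")

    out: dict[str, pd.DataFrame] = {}
    for s in strata:
        sub = frame[frame["_stratum"] == s]
        if len(sub) == 0:
            empty = pd.DataFrame(
                {f"level_{lv}": np.nan for lv in range(4)}
                | {"any_risk": np.nan, "n": 0},
                index=pd.Index([c.key for c in RiskCategory], name="category"),
            )
            out[s] = empty
        else:
            out[s] = prevalence_table(sub)
    return out


# ---------------------------------------------------------------------------
# Rank tests


def _tie_term(values: np.ndarray) -> float:
    """Sum of (t^3 - t) over tie groups."""
    _, counts = np.unique(values, return_counts=True)
    return float((counts.astype(float) ** 3 - counts).sum())


def mann_whitney_u(
    levels_a: Sequence[int],
    levels_b: Sequence[int],
    continuity: bool = False,
    method: str = "asymptotic",
) -> TestResult:
    """Two-sided Mann-Whitney U test on midranks with tie-corrected variance.

    U is reported for the first sample; the normal deviate is
    ``z = (U - n1 n2 / 2) / sigma`` with
    ``sigma^2 = (n1 n2 / 12) [(N + 1) - sum(t^3 - t) / (N (N - 1))]``.
    The continuity correction is off by default.  When every observation is
    identical the variance vanishes and the result is flagged degenerate
    with p = 1.

    ``method="exact"`` replaces the normal p-value by full enumeration of
    all N-choose-n1 group assignments of the pooled values
    (p = proportion of assignments with ``|U - n1 n2 / 2|`` at least as
    extreme); only sensible at small N.
    """
    a = np.asarray(levels_a, dtype=float)
    b = np.asarray(levels_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    n = n1 + n2
    ranks = stats.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0

    tie = _tie_term(pooled)
    tie_factor = 1.0 - tie / (n**3 - n) if n > 1 else 1.0
    var = (n1 * n2 / 12.0) * ((n + 1) - tie / (n * (n - 1)))
    if var <= 0:
        return TestResult(statistic=u1, p_value=1.0, group_sizes=(n1, n2),
                          tie_factor=max(tie_factor, 0.0), z=0.0, degenerate=True)
    num = u1 - n1 * n2 / 2.0
    if continuity and num != 0:
        num -= 0.5 * np.sign(num)
    z = num / np.sqrt(var)
    if method == "exact":
        p = _exact_mw_p(pooled, n1, abs(u1 - n1 * n2 / 2.0))
    elif method == "asymptotic":
        p = 2.0 * stats.norm.sf(abs(z))
    else:
        raise ValueError(f"unknown method {method!r}")
    return TestResult(statistic=u1, p_value=min(p, 1.0), group_sizes=(n1, n2),
                      tie_factor=tie_factor, z=float(z))


def _exact_mw_p(pooled: np.ndarray, n1: int, dev_obs: float) -> float:
    """Permutation p: share of group assignments with |U - n1 n2/2| >= observed."""
    from itertools import combinations

    n = pooled.size
    n2 = n - n1
    ranks = stats.rankdata(pooled)
    offset = n1 * (n1 + 1) / 2.0
    hits = total = 0
    for idx in combinations(range(n), n1):
        u = ranks[list(idx)].sum() - offset
        total += 1
        if abs(u - n1 * n2 / 2.0) >= dev_obs - 1e-12:
            hits += 1
    return hits / total


def kruskal_wallis(groups: Sequence[Sequence[int]], method: str = "asymptotic") -> TestResult:
    """Kruskal-Wallis H on midranks with tie correction; chi-square p-value.

    ``H = [12 / (N (N+1))] sum R_j^2 / n_j - 3 (N + 1)`` divided by the tie
    correction ``1 - sum(t^3 - t) / (N^3 - N)``; p from chi-square with
    g - 1 degrees of freedom.  ``method="exact"`` enumerates all multiset
    group assignments instead (p = proportion with H at least as large);
    only sensible at small N.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size == 0 for a in arrays):
        raise ValueError("need >= 2 non-empty groups")
    sizes = tuple(a.size for a in arrays)
    pooled = np.concatenate(arrays)
    n = pooled.size
    ranks = stats.rankdata(pooled)
    h = 0.0
    offset = 0
    for a in arrays:
        rj = ranks[offset : offset + a.size].sum()
        h += rj**2 / a.size
        offset += a.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)

    tie = _tie_term(pooled)
    tie_factor = 1.0 - tie / (n**3 - n)
    if tie_factor <= 0:
        return TestResult(statistic=0.0, p_value=1.0, group_sizes=sizes,
                          tie_factor=0.0, degenerate=True)
    h /= tie_factor
    if method == "exact":
        p = _exact_kw_p(pooled, sizes, h)
    elif method == "asymptotic":
        p = float(stats.chi2.sf(h, df=len(arrays) - 1))
    else:
        raise ValueError(f"unknown method {method!r}")
    return TestResult(statistic=float(h), p_value=p, group_sizes=sizes,
                      tie_factor=tie_factor)


def _exact_kw_p(pooled: np.ndarray, sizes: tuple[int, ...], h_obs: float) -> float:
    """Permutation p: share of group assignments with H >= observed."""
    from itertools import combinations

    n = pooled.size
    ranks = stats.rankdata(pooled)
    tie_factor = 1.0 - _tie_term(pooled) / (n**3 - n)

    def h_of(split: list[np.ndarray]) -> float:
        h = sum(ranks[idx].sum() ** 2 / len(idx) for idx in split)
        return (12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)) / tie_factor

    hits = total = 0

    def recurse(remaining: tuple[int, ...], gi: int, split: list[np.ndarray]) -> None:
        nonlocal hits, total
        if gi == len(sizes) - 1:
            split = split + [np.array(remaining, dtype=int)]
            total += 1
            if h_of(split) >= h_obs - 1e-12:
                hits += 1
            return
        for idx in combinations(remaining, sizes[gi]):
            rest = tuple(x for x in remaining if x not in set(idx))
            recurse(rest, gi + 1, split + [np.array(idx, dtype=int)])

    recurse(tuple(range(n)), 0, [])
    return hits / total


# ---------------------------------------------------------------------------
# Medication ranking


def summarized_risk_values(
    profiles: Sequence[RiskProfile] | pd.DataFrame,
    exposures,
    kb: KnowledgeBase,
    category: RiskCategory,
    top_n: int = 10,
) -> pd.DataFrame:
    """Rank substances by summarized risk value among level-III patients.

    Restricted to patients with level III in ``category``; for each substance
    with a nonzero risk value, ``srv = r(s, c) x n_patients``.  Sorted by
    srv descending, then n_patients descending, then ATC code.  Returns at
    most ``top_n`` rows with columns ``atc, risk_value, n_patients, srv``.
    """
    frame = _levels_frame(profiles)
    level3 = set(frame.loc[frame[f"{category.key}_level"] == 3, "patient_id"])
    counts: dict[str, int] = {}
    for exp in exposures:
        pid, substances = (exp.patient_id, exp.substances) if hasattr(exp, "patient_id") else exp
        if pid not in level3:
            continue
        for s in set(substances):
            if kb.risk(s, category) > 0:
                counts[s] = counts.get(s, 0) + 1
    rows = [
        {"atc": s, "risk_value": kb.risk(s, category), "n_patients": n,
         "srv": kb.risk(s, category) * n}
        for s, n in counts.items()
    ]
    out = pd.DataFrame(rows, columns=["atc", "risk_value", "n_patients", "srv"])
    out = out.sort_values(
        ["srv", "n_patients", "atc"], ascending=[False, False, True]
    ).reset_index(drop=True)
    return out.head(top_n)
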