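"""k-modes clustering of nine-dimensional categorical risk profiles.

The risk profile is a categorical 9-vector with values in {0,1,2,3}; k-modes
(the k-means analogue for categorical data) groups patients by the matching
(Hamming) dissimilarity d(x, y) = number of positions where x != y, and
represents each cluster by its per-position mode.  The fit alternates
assignment and mode update from a random initialization of k distinct
observed vectors, keeps the best of ``n_init`` restarts by total cost, and
re-seeds any emptied cluster with the point farthest from its current mode.
Total cost is non-increasing across iterations within a run.

The number of clusters is chosen with the elbow rule on the cost curve:
the interior k maximizing the discrete curvature
``cost[k-1] - 2 cost[k] + cost[k+1]`` (ties broken toward the smallest k).

Cluster descriptives summarize each cluster the way cohort tables do:
size, gender split, age-group split, and median/IQR (plus mean) of the
number of unique medications and of the risk-profile sum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .knowledge_base import RiskCategory
from .population_analysis import AGE_GROUP_LABELS, _age_groups_vector, _levels_frame

__all__ = [
    "ClusterResult",
    "matching_dissimilarity",
    "kmodes_fit",
    "elbow_select",
    "elbow_point",
    "describe_clusters",
]

N_CATEGORIES = len(RiskCategory)


@dataclass(frozen=True)
class ClusterResult:
    """Fitted k-modes model: modes, assignments and total matching cost."""

    k: int
    modes: np.ndarray            # (k, 9) int
    assignments: np.ndarray      # (n,) int in [0, k)
    cost: int
    n_iter: int
    seed: int
    n_init: int


def matching_dissimilarity(x: Sequence[int], y: Sequence[int]) -> int:
    """Number of positions at which the two categorical vectors differ."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    return int((x != y).sum())


def _pairwise(x: np.ndarray, modes: np.ndarray) -> np.ndarray:
    """(n, k) matrix of matching dissimilarities."""
    return (x[:, None, :] != modes[None, :, :]).sum(axis=2)


def _column_modes(x: np.ndarray) -> np.ndarray:
    """Per-column mode; ties resolved toward the lowest category value."""
    out = np.empty(x.shape[1], dtype=x.dtype)
    for j in range(x.shape[1]):
        values, counts = np.unique(x[:, j], return_counts=True)
        out[j] = values[np.argmax(counts)]  # np.unique sorts, argmax takes first max
    return out


def _single_fit(x: np.ndarray, k: int, rng: np.random.Generator,
                max_iter: int) -> tuple[np.ndarray, np.ndarray, int, int]:
    distinct = np.unique(x, axis=0)
    idx = rng.choice(len(distinct), size=k, replace=False)
    modes = distinct[idx].copy()

    assign = np.full(len(x), -1)
    prev_cost = None
    for it in range(1, max_iter + 1):
        d = _pairwise(x, modes)
        assign = d.argmin(axis=1)
        # re-seed empty clusters with the point farthest from its mode
        for c in range(k):
            if not (assign == c).any():
                worst = int(d[np.arange(len(x)), assign].argmax())
                assign[worst] = c
        cost = int(_pairwise(x, modes)[np.arange(len(x)), assign].sum())
        if prev_cost is not None and cost > prev_cost:  # pragma: no cover
            raise AssertionError("k-modes cost increased")
        if prev_cost is not None and cost == prev_cost:
            return modes, assign, cost, it
        prev_cost = cost
        for c in range(k):
            modes[c] = _column_modes(x[assign == c])
    d = _pairwise(x, modes)
    assign = d.argmin(axis=1)
    cost = int(d[np.arange(len(x)), assign].sum())
    return modes, assign, cost, max_iter


def _as_matrix(profiles) -> np.ndarray:
    if isinstance(profiles, np.ndarray):
        return profiles.astype(np.int64)
    frame = _levels_frame(profiles)
    cols = [f"{c.key}_level" for c in RiskCategory]
    return frame[cols].to_numpy(dtype=np.int64)


def kmodes_fit(
    profiles,
    k: int,
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 100,
) -> ClusterResult:
    """Fit k-modes; best of ``n_init`` random restarts, deterministic per seed.

    ``profiles`` may be a profile frame, a sequence of profiles, or an
    (n, 9) integer array of levels.  ``k`` must not exceed the number of
    distinct level vectors.
    """
    x = _as_matrix(profiles)
    n_distinct = len(np.unique(x, axis=0))
    if not (1 <= k <= n_distinct):
        raise ValueError(f"k={k} must be in [1, {n_distinct}] (distinct profile vectors)")
    rng = np.random.default_rng(np.random.SeedSequence([seed, k]))
    best: tuple[np.ndarray, np.ndarray, int, int] | None = None
    for _ in range(n_init):
        fit = _single_fit(x, k, rng, max_iter)
        if best is None or fit[2] < best[2]:
            best = fit
    modes, assign, cost, n_iter = best  # type: ignore[misc]
    return ClusterResult(k=k, modes=modes, assignments=assign, cost=cost,
                         n_iter=n_iter, seed=seed, n_init=n_init)


def elbow_select(
    profiles,
    k_range: Sequence[int],
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 100,
) -> tuple[int, dict[int, int]]:
    """Choose k by maximal discrete curvature of the cost curve.

    Fits every k in ``k_range`` (must be >= 3 consecutive-sorted values) and
    returns the interior k maximizing ``cost[k-1] - 2 cost[k] + cost[k+1]``,
    together with the full cost curve for inspection.  Ties break toward the
    smallest k; a non-monotone curve triggers a warning but the rule still
    applies.
    """
    ks = sorted(set(int(k) for k in k_range))
    if len(ks) < 3:
        raise ValueError("k_range must contain at least 3 values")
    costs = {k: kmodes_fit(profiles, k, seed=seed, n_init=n_init,
                           max_iter=max_iter).cost for k in ks}
    return elbow_point(costs), costs


def elbow_point(costs: Mapping[int, float]) -> int:
    """The elbow of a cost curve: interior k of maximal discrete curvature.

    Ties break toward the smallest k.  A non-monotone curve triggers a
    warning; the rule still applies.
    """
    ks = sorted(costs)
    if len(ks) < 3:
        raise ValueError("need at least 3 curve points")
    curve = [costs[k] for k in ks]
    if any(curve[i + 1] > curve[i] for i in range(len(curve) - 1)):
        warnings.warn("k-modes cost curve is not monotonically decreasing", stacklevel=2)
    curvature = [curve[i - 1] - 2 * curve[i] + curve[i + 1] for i in range(1, len(ks) - 1)]
    best_i = int(np.argmax(curvature)) + 1  # argmax takes the first (smallest k) on ties
    return ks[best_i]


def describe_clusters(
    result: ClusterResult,
    patients: pd.DataFrame,
    exposures,
    profiles,
    cutoff_date,
) -> pd.DataFrame:
    """Per-cluster descriptives in the style of a cohort characteristics table.

    One row per cluster: ``n``, percent female, percent per age group,
    median / IQR / mean of the number of unique medications and of the
    profile sum.  IQR is Q3 - Q1 with linear-interpolation quartiles.
    """
    frame = _levels_frame(profiles).copy()
    if len(frame) != len(result.assignments):
        raise ValueError("profiles and assignments disagree in length")
    frame["cluster"] = result.assignments
    n_unique = {
        (exp.patient_id if hasattr(exp, "patient_id") else exp[0]):
        (len(set(exp.substances)) if hasattr(exp, "substances") else len(set(exp[1])))
        for exp in exposures
    }
    frame["n_medications"] = frame["patient_id"].map(n_unique)
    if frame["n_medications"].isna().any():
        raise ValueError("every profile needs a matching exposure list")
    frame = frame.merge(patients[["patient_id", "gender", "birth_date"]],
                        on="patient_id", how="left")
    frame["age_group"] = _age_groups_vector(frame["birth_date"], cutoff_date)

    rows = []
    for c in range(result.k):
        sub = frame[frame["cluster"] == c]
        n = len(sub)
        row: dict[str, float | int] = {"cluster": c, "n": n}
        row["pct_female"] = 100.0 * (sub["gender"] == "F").mean() if n else np.nan
        for g in AGE_GROUP_LABELS:
            row[f"pct_age_{g}"] = 100.0 * (sub["age_group"] == g).mean() if n else np.nan
        for col, name in (("n_medications", "medications"), ("profile_sum", "profile_sum")):
            v = sub[col].to_numpy(dtype=float)
            row[f"{name}_median"] = float(np.median(v)) if n else np.nan
            row[f"{name}_iqr"] = (
                float(np.percentile(v, 75) - np.percentile(v, 25)) if n else np.nan
            )
            row[f"{name}_mean"] = float(v.mean()) if n else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
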