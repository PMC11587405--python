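import datetime as dt
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import CUTOFF, make_patients
from riskprofile.knowledge_base import RiskCategory
from riskprofile.population_analysis import (
    age_group,
    kruskal_wallis,
    mann_whitney_u,
    prevalence_table,
    stratified_prevalence,
    summarized_risk_values,
)
from riskprofile.risk_engine import compute_profiles, profiles_to_frame


# --- independent oracles ----------------------------------------------------


def brute_force_u(a, b):
    """U for sample a by pairwise counting (ties count one half)."""
    return sum(1.0 if x > y else 0.5 if x == y else 0.0 for x in a for y in b)


def brute_force_exact_mw(a, b):
    """Exact two-sided permutation p for the U statistic, by enumeration."""
    pooled = list(a) + list(b)
    n1 = len(a)
    mean = n1 * len(b) / 2.0
    dev_obs = abs(brute_force_u(a, b) - mean)
    hits = total = 0
    for idx in combinations(range(len(pooled)), n1):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in set(idx)]
        total += 1
        if abs(brute_force_u(ga, gb) - mean) >= dev_obs - 1e-12:
            hits += 1
    return hits / total


def brute_force_exact_kw(groups):
    """Exact permutation p for Kruskal-Wallis H (H >= observed), by enumeration."""
    h_obs = stats.kruskal(*groups).statistic
    pooled = [x for g in groups for x in g]
    sizes = [len(g) for g in groups]
    hits = total = 0

    def split(remaining, gi, acc):
        nonlocal hits, total
        if gi == len(sizes) - 1:
            parts = acc + [remaining]
            total += 1
            if stats.kruskal(*parts).statistic >= h_obs - 1e-12:
                hits += 1
            return
        for idx in combinations(range(len(remaining)), sizes[gi]):
            chosen = [remaining[i] for i in idx]
            rest = [remaining[i] for i in range(len(remaining)) if i not in set(idx)]
            split(rest, gi + 1, acc + [chosen])

    split(pooled, 0, [])
    return hits / total


# --- age groups -------------------------------------------------------------


class TestAgeGroup:
    @pytest.mark.parametrize(
        "years,expected", [(64, "<65"), (65, "65-74"), (74, "65-74"), (75, ">=75")]
    )
    def test_boundaries_in_completed_years(self, years, expected):
        birth = dt.date(CUTOFF.year - years, CUTOFF.month, CUTOFF.day)
        assert age_group(birth, CUTOFF) == expected

    def test_birthday_not_yet_reached(self):
        # turns 65 the day after cutoff: still 64 completed years
        birth = dt.date(CUTOFF.year - 65, CUTOFF.month, CUTOFF.day + 1)
        assert age_group(birth, CUTOFF) == "<65"

    def test_birth_after_cutoff_rejected(self):
        with pytest.raises(ValueError):
            age_group(dt.date(2021, 1, 1), CUTOFF)


# --- prevalence -------------------------------------------------------------


def _profiles(kb, exposures):
    return profiles_to_frame(compute_profiles(exposures, kb))


class TestPrevalence:
    def test_half_cohort_at_risk(self, kb):
        frame = _profiles(kb, [
            ("p1", {"B01AF02"}), ("p2", {"B01AA03"}), ("p3", set()), ("p4", set()),
        ])
        table = prevalence_table(frame)
        assert table.loc["bleeding", "any_risk"] == 0.5

    def test_all_zero_profiles(self, kb):
        frame = _profiles(kb, [("p1", set()), ("p2", {"X00ZZ00"})])
        table = prevalence_table(frame)
        assert (table["any_risk"] == 0).all()

    def test_levels_sum_to_one_and_order_invariance(self, kb, small_dataset):
        _, _, _, truth = small_dataset
        frame = truth.profile_frame
        table = prevalence_table(frame)
        level_cols = [f"level_{i}" for i in range(4)]
        assert np.allclose(table[level_cols].sum(axis=1), 1.0)
        shuffled = prevalence_table(frame.sample(frac=1, random_state=0))
        pd.testing.assert_frame_equal(table, shuffled)

    def test_empty_cohort_rejected(self, kb):
        with pytest.raises(ValueError):
            prevalence_table(_profiles(kb, []))


class TestStratifiedPrevalence:
    def test_strata_partition_cohort(self, kb):
        patients = make_patients([
            ("p1", "F", "1950-01-01"), ("p2", "M", "1990-01-01"),
            ("p3", "F", "1948-06-01"),
        ])
        frame = _profiles(kb, [("p1", {"B01AF02"}), ("p2", set()), ("p3", set())])
        strata = stratified_prevalence(frame, patients, by="gender")
        assert strata["F"]["n"].iloc[0] + strata["M"]["n"].iloc[0] == 3

    def test_single_gender_cohort(self, kb):
        patients = make_patients([("p1", "F", "1950-01-01")])
        frame = _profiles(kb, [("p1", set())])
        strata = stratified_prevalence(frame, patients, by="gender")
        assert strata["F"]["n"].iloc[0] == 1
        assert strata["M"]["n"].iloc[0] == 0

    def test_pooled_equals_weighted_mean_of_strata(self, kb, small_dataset):
        _, patients, _, truth = small_dataset
        frame = truth.profile_frame
        pooled = prevalence_table(frame)
        strata = stratified_prevalence(frame, patients, by="age_group",
                                       cutoff_date=CUTOFF)
        n_total = pooled["n"].iloc[0]
        for cat in [c.key for c in RiskCategory]:
            weighted = sum(
                t.loc[cat, "any_risk"] * t["n"].iloc[0]
                for t in strata.values() if t["n"].iloc[0] > 0
            ) / n_total
            assert pooled.loc[cat, "any_risk"] == pytest.approx(weighted)


# --- rank tests -------------------------------------------------------------


class TestMannWhitney:
    def test_identical_samples_degenerate(self):
        r = mann_whitney_u([1, 1, 1], [1, 1])
        assert r.degenerate and r.p_value == 1.0

    def test_swapping_samples_mirrors_u(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.integers(0, 4, size=rng.integers(2, 12))
            b = rng.integers(0, 4, size=rng.integers(2, 12))
            if len(set(a) | set(b)) == 1:
                continue
            ab = mann_whitney_u(a, b)
            ba = mann_whitney_u(b, a)
            assert ab.statistic == pytest.approx(len(a) * len(b) - ba.statistic)
            assert ab.p_value == pytest.approx(ba.p_value)

    def test_u_matches_pairwise_counting(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a = rng.integers(0, 4, size=rng.integers(1, 15))
            b = rng.integers(0, 4, size=rng.integers(1, 15))
            assert mann_whitney_u(a, b).statistic == pytest.approx(brute_force_u(a, b))

    def test_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            a = rng.integers(0, 4, size=50)
            b = rng.integers(0, 4, size=60)
            ours = mann_whitney_u(a, b)
            ref = stats.mannwhitneyu(a, b, method="asymptotic", use_continuity=False)
            assert ours.statistic == pytest.approx(ref.statistic)
            assert ours.p_value == pytest.approx(ref.pvalue)

    def test_exact_example_instance(self):
        a, b = [0, 0, 1], [2, 3]
        r = mann_whitney_u(a, b, method="exact")
        assert r.statistic == brute_force_u(a, b) == 0.0
        assert r.p_value == pytest.approx(brute_force_exact_mw(a, b))
        # all 10 assignments enumerate; observed split is the most extreme
        assert r.p_value == pytest.approx(0.2)


class TestKruskalWallis:
    def test_identical_groups_degenerate(self):
        r = kruskal_wallis([[2, 2], [2, 2], [2]])
        assert r.degenerate and r.p_value == 1.0 and r.statistic == 0.0

    def test_matches_scipy(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            groups = [rng.integers(0, 4, size=rng.integers(5, 40)) for _ in range(3)]
            if len(set(np.concatenate(groups))) == 1:
                continue
            ours = kruskal_wallis(groups)
            ref = stats.kruskal(*groups)
            assert ours.statistic == pytest.approx(ref.statistic)
            assert ours.p_value == pytest.approx(ref.pvalue)

    def test_two_groups_h_equals_z_squared(self):
        rng = np.random.default_rng(4)
        done = 0
        while done < 100:
            a = rng.integers(0, 4, size=rng.integers(3, 30))
            b = rng.integers(0, 4, size=rng.integers(3, 30))
            if len(set(a) | set(b)) == 1:
                continue
            mw = mann_whitney_u(a, b)
            kw = kruskal_wallis([a, b])
            assert kw.statistic == pytest.approx(mw.z**2)
            done += 1


# --- SRV ranking ------------------------------------------------------------


class TestSummarizedRiskValues:
    def test_four_level_three_patients_on_apixaban(self, kb):
        exposures = [(f"p{i}", {"B01AF02", "B01AA03", "B01AC04"}) for i in range(4)]
        frame = _profiles(kb, exposures)
        srv = summarized_risk_values(frame, exposures, kb, RiskCategory.BLEEDING)
        row = srv[srv["atc"] == "B01AF02"].iloc[0]
        assert row["risk_value"] == 3 and row["n_patients"] == 4 and row["srv"] == 12

    def test_no_level_three_patients_gives_empty(self, kb):
        exposures = [("p1", {"A02BC01"})]
        frame = _profiles(kb, exposures)
        srv = summarized_risk_values(frame, exposures, kb, RiskCategory.RENAL_TOXICITY)
        assert len(srv) == 0

    def test_matches_brute_force_recount(self, kb, small_dataset):
        _, _, _, truth = small_dataset
        frame = truth.profile_frame
        exposures = list(truth.exposures.items())
        for c in RiskCategory:
            srv = summarized_risk_values(frame, exposures, kb, c, top_n=10_000)
            # independent recount straight from the raw exposure table
            level3 = set(frame.loc[frame[f"{c.key}_level"] == 3, "patient_id"])
            counts: dict[str, int] = {}
            for pid, subs in exposures:
                if pid in level3:
                    for s in subs:
                        counts[s] = counts.get(s, 0) + 1
            expected = {
                s: kb.risk(s, c) * n for s, n in counts.items() if kb.risk(s, c) > 0
            }
            assert dict(zip(srv["atc"], srv["srv"])) == expected
            assert list(srv["srv"]) == sorted(srv["srv"], reverse=True)
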