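"""Evaluation metrics: AUROC, top-N selection, PPV/IR, SIR, calibration."""

import numpy as np
import pandas as pd
import pytest

from pancrisk.metrics import (
    EvalRecord,
    auroc_with_ci,
    calibration_curve,
    expected_cases,
    horizon_year_offsets,
    ppv_and_ir,
    sir_with_ci,
    subgroup_report,
    time_to_event_distribution,
    top_n_cohort,
)
from pancrisk.synthetic import IncidenceTable


def _rec(pid, score, outcome=0, age=60.0, race="White", sex="Male", gap=None):
    return EvalRecord(patient_id=pid, score=score, outcome=outcome, observed=True,
                      age_years=age, race=race, sex=sex, days_to_event=gap)


def _flat_table(rate, races=("White",), sexes=("Male",)):
    bands = ["50-54", "55-59", "60-64", "65-69", "70-74", "75-79", "80-84", "85+"]
    rows = [
        {"age_group": b, "race": r, "sex": s, "annual_rate": rate}
        for b in bands for r in races for s in sexes
    ]
    return IncidenceTable(pd.DataFrame(rows))


class TestAuroc:
    def test_perfect_separation(self):
        a, lo, hi = auroc_with_ci([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], rng=0)
        assert a == 1.0

    def test_reversed_scores(self):
        a, _, _ = auroc_with_ci([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0], rng=0)
        assert a == 0.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.random(10_000)
        labels = np.repeat([0, 1], 5000)
        a, _, _ = auroc_with_ci(scores, labels, rng=1)
        assert abs(a - 0.5) < 0.02

    def test_matches_pairwise_oracle_with_ties(self):
        rng = np.random.default_rng(4)
        scores = rng.integers(0, 10, size=150).astype(float)  # many ties
        labels = rng.integers(0, 2, size=150)
        if labels.sum() in (0, len(labels)):
            labels[0] = 1 - labels[0]
        a, _, _ = auroc_with_ci(scores, labels, n_boot=5, rng=0)
        # O(n^2) pairwise comparison, ties get half credit
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert a == pytest.approx(wins / (len(pos) * len(neg)))

    def test_ci_brackets_point_estimate(self):
        rng = np.random.default_rng(5)
        scores = np.concatenate([rng.normal(1, 1, 200), rng.normal(0, 1, 200)])
        labels = np.repeat([1, 0], 200)
        a, lo, hi = auroc_with_ci(scores, labels, rng=2)
        assert lo <= a <= hi
        assert hi - lo < 0.2

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc_with_ci([0.1, 0.2], [1, 1])


class TestTopN:
    def test_selects_largest_scores(self):
        recs = [_rec(f"P{i}", score=i / 10) for i in range(10)]
        top = top_n_cohort(recs, 5)
        assert sorted(r.score for r in top) == [0.5, 0.6, 0.7, 0.8, 0.9]

    def test_ties_broken_by_patient_id(self):
        recs = [_rec("P3", 0.5), _rec("P1", 0.5), _rec("P2", 0.5), _rec("P0", 0.9)]
        top = top_n_cohort(recs, 2)
        assert [r.patient_id for r in top] == ["P0", "P1"]

    def test_repeated_calls_identical(self):
        recs = [_rec(f"P{i}", 0.5) for i in range(6)]
        assert [r.patient_id for r in top_n_cohort(recs, 3)] == [
            r.patient_id for r in top_n_cohort(recs, 3)
        ]

    def test_age_floor_filters(self):
        recs = [_rec("P0", 0.9, age=45.0), _rec("P1", 0.5, age=60.0)]
        top = top_n_cohort(recs, 1, min_age=50)
        assert top[0].patient_id == "P1"

    def test_out_of_range_n_rejected(self):
        recs = [_rec("P0", 0.1)]
        with pytest.raises(ValueError):
            top_n_cohort(recs, 0)
        with pytest.raises(ValueError):
            top_n_cohort(recs, 2)


class TestPpvIr:
    def test_direct_ratio(self):
        high = [_rec(f"P{i}", 0.9, outcome=int(i < 8)) for i in range(1000)]
        ppv, ir = ppv_and_ir(high, 0.0001)
        assert ppv == pytest.approx(0.008)
        assert ir == pytest.approx(80.0)

    def test_ir_identity(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(10, 200))
            high = [_rec(f"P{i}", 0.5, outcome=int(rng.random() < 0.3)) for i in range(n)]
            inc = float(rng.uniform(1e-5, 0.1))
            ppv, ir = ppv_and_ir(high, inc)
            assert ir == pytest.approx(ppv / inc)

    def test_all_positive(self):
        high = [_rec(f"P{i}", 0.9, outcome=1) for i in range(10)]
        ppv, ir = ppv_and_ir(high, 0.001)
        assert ppv == 1.0
        assert ir == pytest.approx(1000.0)

    def test_zero_incidence_rejected(self):
        with pytest.raises(ValueError):
            ppv_and_ir([_rec("P0", 0.5)], 0.0)


class TestExpectedCases:
    def test_flat_rate_36_months(self):
        table = _flat_table(0.0001)
        cohort = [_rec(f"P{i}", 0.5, age=60.0) for i in range(1000)]
        assert expected_cases(cohort, table, 36) == pytest.approx(0.3)

    def test_flat_rate_12_months_single_term(self):
        table = _flat_table(0.0001)
        cohort = [_rec(f"P{i}", 0.5, age=60.0) for i in range(1000)]
        assert expected_cases(cohort, table, 12) == pytest.approx(0.1)

    def test_aging_crosses_band_boundary(self):
        bands = ["50-54", "55-59", "60-64", "65-69", "70-74", "75-79", "80-84", "85+"]
        rows = [
            {"age_group": b, "race": "White", "sex": "Male",
             "annual_rate": 0.001 if b == "50-54" else 0.002}
            for b in bands
        ]
        table = IncidenceTable(pd.DataFrame(rows))
        # age 54: t=0 queries 50-54, t in {1,2} query 55-59
        got = expected_cases([_rec("P0", 0.5, age=54.4)], table, 36)
        assert got == pytest.approx(0.001 + 0.002 + 0.002)

    def test_printed_variant_adds_one_year(self):
        table = _flat_table(0.0001)
        cohort = [_rec("P0", 0.5, age=60.0)]
        assert horizon_year_offsets(36) == [0, 1, 2]
        assert horizon_year_offsets(36, printed_T=True) == [0, 1, 2, 3]
        assert expected_cases(cohort, table, 36, printed_T=True) == pytest.approx(0.0004)

    def test_additive_over_disjoint_sets(self):
        table = _flat_table(0.0003)
        a = [_rec(f"A{i}", 0.5, age=52 + i) for i in range(10)]
        b = [_rec(f"B{i}", 0.5, age=70 + i) for i in range(10)]
        assert expected_cases(a + b, table, 36) == pytest.approx(
            expected_cases(a, table, 36) + expected_cases(b, table, 36)
        )

    def test_missing_stratum_named(self):
        table = _flat_table(0.0001)  # only White Male strata
        with pytest.raises(KeyError, match="Black"):
            expected_cases([_rec("P0", 0.5, race="Black")], table, 12)


class TestSir:
    def test_direct_ratio(self):
        sir, _, _ = sir_with_ci(5, 0.05)
        assert sir == pytest.approx(100.0)

    def test_ci_worked_example(self):
        # (sqrt(5) -/+ 0.98)^2 / 0.05
        _, lo, hi = sir_with_ci(5, 0.05)
        assert lo == pytest.approx((np.sqrt(5) - 0.98) ** 2 / 0.05, rel=1e-12)
        assert hi == pytest.approx((np.sqrt(5) + 0.98) ** 2 / 0.05, rel=1e-12)
        assert lo == pytest.approx(31.6, abs=0.1)
        assert hi == pytest.approx(206.9, abs=0.1)

    def test_equal_observed_expected_gives_one(self):
        sir, lo, hi = sir_with_ci(10, 10.0)
        assert sir == 1.0
        assert lo < 1.0 < hi

    def test_zero_observed_lower_bound_zero(self):
        _, lo, _ = sir_with_ci(0, 1.0)
        assert lo == 0.0

    def test_nonpositive_expected_rejected(self):
        with pytest.raises(ValueError):
            sir_with_ci(1, 0.0)


class TestSubgroups:
    def test_identical_distributions_give_close_aurocs(self):
        rng = np.random.default_rng(3)
        recs = []
        for g, race in enumerate(["White", "Black"]):
            for i in range(300):
                y = int(rng.random() < 0.3)
                recs.append(_rec(f"{race}{i}", score=y + rng.normal(0, 0.8), outcome=y, race=race))
        df = subgroup_report(recs, "race", rng=0)
        aurocs = df.set_index("group")["auroc"]
        assert abs(aurocs["White"] - aurocs["Black"]) < 0.08

    def test_single_class_group_flagged_nan(self):
        recs = [_rec(f"A{i}", 0.5, outcome=0, race="Other") for i in range(5)]
        recs += [_rec(f"B{i}", float(i % 2), outcome=i % 2, race="White") for i in range(10)]
        df = subgroup_report(recs, "race", rng=0)
        assert np.isnan(df.set_index("group").loc["Other", "auroc"])

    def test_invalid_grouping_rejected(self):
        with pytest.raises(ValueError):
            subgroup_report([], "height")


class TestTimeToEvent:
    def test_fraction_beyond_threshold(self):
        high = [_rec("P0", 0.9, 1, gap=50), _rec("P1", 0.9, 1, gap=120), _rec("P2", 0.9, 1, gap=200)]
        counts, edges, frac = time_to_event_distribution(high)
        assert frac == pytest.approx(2 / 3)
        assert counts.sum() == 3

    def test_all_within_threshold(self):
        high = [_rec("P0", 0.9, 1, gap=10), _rec("P1", 0.9, 1, gap=99)]
        _, _, frac = time_to_event_distribution(high)
        assert frac == 0.0

    def test_no_cases_flagged(self, caplog):
        with caplog.at_level("WARNING", logger="pancrisk"):
            counts, edges, frac = time_to_event_distribution([_rec("P0", 0.9, 0)])
        assert frac is None
        assert counts.size == 0


class TestCalibration:
    def test_self_consistent_simulation(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(0.0, 1.0, size=50_000)
        y = rng.random(50_000) < p
        mean_pred, obs_rate, counts = calibration_curve(p, y, n_bins=10)
        for mp, orate, n in zip(mean_pred, obs_rate, counts):
            se = np.sqrt(mp * (1 - mp) / n)
            assert abs(orate - mp) <= 3 * se + 1e-3

    def test_all_probs_in_one_bin(self):
        p = np.full(100, 0.55)
        y = np.zeros(100)
        mean_pred, obs_rate, counts = calibration_curve(p, y)
        assert len(mean_pred) == 1
        assert counts[0] == 100

    def test_anti_diagonal_when_miscalibrated(self):
        rng = np.random.default_rng(9)
        y = rng.integers(0, 2, 2000)
        p = np.where(y == 1, 0.05, 0.95)
        mean_pred, obs_rate, _ = calibration_curve(p, y)
        assert obs_rate[np.argmin(mean_pred)] == 1.0
        assert obs_rate[np.argmax(mean_pred)] == 0.0
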