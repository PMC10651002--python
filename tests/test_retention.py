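"""Window assignment and sequential/cumulative retention definitions."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from anccov.cohort import apply_exclusions, resolve_anchors
from anccov.retention import (
    ATTENDED_COLS,
    WindowAssignmentError,
    assign_windows,
    cumulative_retention,
    cumulative_through,
    flow_table,
    sequential_after,
    sequential_retention,
    window_of_ga_days,
)

from conftest import LMP, make_cohort, make_row, make_visits


def make_flags(patterns, deliveries):
    """Flags frame from [(a1,a2,a3,a4), ...] and delivery GAs in weeks."""
    return pd.DataFrame(
        {
            "woman_id": [f"F{i}" for i in range(len(patterns))],
            **{
                col: [bool(p[k]) for p in patterns]
                for k, col in enumerate(ATTENDED_COLS)
            },
            "delivery_ga_weeks": deliveries,
        }
    )


class TestWindowAssignment:
    @pytest.mark.parametrize(
        "ga_days,window",
        [(0, 1), (111, 1), (112, 2), (195, 2), (196, 3), (251, 3), (252, 4), (300, 4)],
    )
    def test_half_open_bounds(self, ga_days, window):
        assert window_of_ga_days(ga_days) == window

    def test_exactly_16_weeks_is_window_two(self):
        assert window_of_ga_days(16 * 7) == 2

    def test_negative_ga_rejected(self):
        with pytest.raises(WindowAssignmentError):
            window_of_ga_days(-1)

    def _flags_for(self, rows, visit_rows):
        cohort = make_cohort(rows)
        analysis, _ = apply_exclusions(cohort)
        visits = make_visits(visit_rows)
        return assign_windows(analysis, visits, resolve_anchors(analysis))

    def test_selfreport_sets_only_window_one(self):
        rows = [make_row(woman_id="A", self_visits_enroll=1,
                         enrollment_date=LMP + dt.timedelta(days=63))]  # 9 weeks
        flags = self._flags_for(rows, [])
        assert list(flags.loc[0, ATTENDED_COLS]) == [True, False, False, False]

    def test_dated_visits_mapped_by_ga(self):
        rows = [make_row(woman_id="A")]
        flags = self._flags_for(rows, [
            ("A", LMP + dt.timedelta(days=112), "chart_prospective"),  # 16.0 wk
            ("A", LMP + dt.timedelta(days=260), "chart_prospective"),  # 37.1 wk
        ])
        assert list(flags.loc[0, ATTENDED_COLS]) == [False, True, False, True]

    def test_visit_after_delivery_rejected(self):
        rows = [make_row(woman_id="A", delivery_date=LMP + dt.timedelta(days=270))]
        with pytest.raises(WindowAssignmentError, match="A"):
            self._flags_for(rows, [("A", LMP + dt.timedelta(days=280),
                                    "chart_prospective")])

    def test_assignment_matches_simulator_truth(self, clean_sim):
        _, cohort, visits, truth = clean_sim
        analysis, _ = apply_exclusions(cohort, visits)
        flags = assign_windows(analysis, visits, resolve_anchors(analysis))
        merged = flags.merge(
            truth.window_flags, on="woman_id", suffixes=("", "_true")
        )
        for col in ATTENDED_COLS:
            assert (merged[col] == merged[f"{col}_true"]).all()


def brute_force_sequential(flags, x):
    """Per-woman enumeration straight from the definitions."""
    n = num = 0
    for _, r in flags.iterrows():
        att = [r[c] for c in ATTENDED_COLS]
        if not att[x - 1]:
            continue
        if x == 3 and r["delivery_ga_weeks"] < 36:
            continue
        n += 1
        if any(att[x:]):
            num += 1
    return num, n


def brute_force_cumulative(flags, k):
    n = num = 0
    for _, r in flags.iterrows():
        if k == 4 and r["delivery_ga_weeks"] < 36:
            continue
        n += 1
        if all(r[c] for c in ATTENDED_COLS[:k]):
            num += 1
    return num, n


class TestSequentialRetention:
    def test_skipping_a_window_still_counts_as_retained(self):
        flags = make_flags([(0, 1, 0, 1)], [39.0])
        res = sequential_after(flags, 2)
        assert (res.numerator, res.denominator) == (1, 1)

    def test_hand_enumeration_two_of_three(self):
        flags = make_flags([(1, 1, 0, 0), (1, 0, 1, 0), (1, 0, 0, 0)], [39, 39, 39])
        res = sequential_after(flags, 1)
        assert (res.numerator, res.denominator) == (2, 3)

    def test_early_delivery_leaves_anc3_denominator(self):
        flags = make_flags([(1, 1, 1, 0), (1, 1, 1, 1)], [34.0, 39.0])
        res = sequential_after(flags, 3)
        assert res.denominator == 1  # the 34-week delivery is excluded

    def test_no_window_after_anc4(self):
        flags = make_flags([(1, 1, 1, 1)], [39.0])
        with pytest.raises(ValueError):
            sequential_after(flags, 4)

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            pats = rng.integers(0, 2, size=(20, 4))
            deliv = rng.choice([33.0, 39.0], size=20)
            flags = make_flags([tuple(p) for p in pats], deliv)
            for x in (1, 2, 3):
                try:
                    res = sequential_after(flags, x)
                except Exception:
                    num, n = brute_force_sequential(flags, x)
                    assert n == 0
                    continue
                assert (res.numerator, res.denominator) == brute_force_sequential(flags, x)


class TestCumulativeRetention:
    def test_all_attenders_fully_retained(self):
        flags = make_flags([(1, 1, 1, 1)] * 4, [39.0] * 4)
        for r in cumulative_retention(flags):
            assert r.numerator == r.denominator

    def test_gap_breaks_the_chain(self):
        flags = make_flags([(1, 0, 1, 1)], [39.0])
        assert cumulative_through(flags, 1).numerator == 1
        for k in (2, 3, 4):
            assert cumulative_through(flags, k).numerator == 0

    def test_week36_rule_applies_only_to_k4(self):
        flags = make_flags([(1, 1, 1, 0), (1, 1, 1, 1)], [34.0, 39.0])
        assert cumulative_through(flags, 3).denominator == 2
        assert cumulative_through(flags, 4).denominator == 1

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            pats = rng.integers(0, 2, size=(20, 4))
            deliv = rng.choice([33.0, 39.0], size=20)
            flags = make_flags([tuple(p) for p in pats], deliv)
            for k in (1, 2, 3, 4):
                try:
                    res = cumulative_through(flags, k)
                except Exception:
                    assert brute_force_cumulative(flags, k)[1] == 0
                    continue
                assert (res.numerator, res.denominator) == brute_force_cumulative(flags, k)


class TestFlowTable:
    def test_empty_cohort_all_zero(self):
        flow = flow_table(make_flags([], []))
        assert len(flow) == 16 and flow["count"].sum() == 0

    def test_margins_recover_window_attendance(self, clean_sim):
        _, cohort, visits, _ = clean_sim
        analysis, _ = apply_exclusions(cohort, visits)
        flags = assign_windows(analysis, visits, resolve_anchors(analysis))
        flow = flow_table(flags)
        assert flow["count"].sum() == len(flags)
        for k, col in enumerate(ATTENDED_COLS):
            margin = flow.loc[
                flow["pattern"].str[k] == "T", "count"
            ].sum()
            assert margin == int(flags[col].sum())
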