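"""Agresti-Coull intervals, visit-count assembly, and summaries."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.proportion import proportion_confint

from anccov.cohort import apply_exclusions
from anccov.coverage import (
    UndefinedEstimateError,
    agresti_coull,
    assemble_visit_counts,
    coverage_indicators,
    median_iqr,
    selfreport_agreement,
    visit_distribution,
)

from conftest import LMP, make_cohort, make_row, make_visits


class TestAgrestiCoull:
    @pytest.mark.parametrize("x,n", [(0, 5), (3, 7), (51, 150), (146, 150), (999, 1000)])
    def test_matches_statsmodels(self, x, n):
        est = agresti_coull(x, n)
        lo, hi = proportion_confint(x, n, alpha=0.05, method="agresti_coull")
        assert est.ci_low == pytest.approx(max(lo, 0.0), abs=1e-12)
        assert est.ci_high == pytest.approx(min(hi, 1.0), abs=1e-12)

    def test_zero_successes_clips_lower_bound_to_zero(self):
        est = agresti_coull(0, 10)
        assert est.ci_low == 0.0 and est.proportion == 0.0

    def test_symmetric_at_half(self):
        est = agresti_coull(75, 150)
        assert est.ci_high - 0.5 == pytest.approx(0.5 - est.ci_low)

    def test_interval_contains_raw_proportion_exhaustively(self):
        for level in (0.90, 0.95):
            for n in range(1, 201):
                for x in range(n + 1):
                    est = agresti_coull(x, n, level)
                    assert est.ci_low <= x / n <= est.ci_high

    def test_empty_denominator_rejected(self):
        with pytest.raises(UndefinedEstimateError):
            agresti_coull(0, 0)


class TestAssembleCounts:
    def test_selfreport_plus_prospective_are_additive(self):
        cohort = make_cohort([make_row(woman_id="A", self_visits_enroll=1)])
        enroll = cohort["enrollment_date"].iloc[0].date()
        visits = make_visits(
            [("A", enroll + dt.timedelta(days=7 * k), "chart_prospective") for k in range(3)]
        )
        counts = assemble_visit_counts(cohort, visits)
        assert counts.loc[0, "n_total"] == 4
        assert counts.loc[0, "n_prospective"] == 3

    def test_same_day_duplicates_collapse(self):
        cohort = make_cohort([make_row(woman_id="A")])
        d = cohort["enrollment_date"].iloc[0].date() + dt.timedelta(days=5)
        visits = make_visits([("A", d, "chart_prospective")] * 3)
        assert assemble_visit_counts(cohort, visits).loc[0, "n_total"] == 1

    def test_retrospective_rows_excluded_from_totals(self):
        cohort = make_cohort([make_row(woman_id="A", self_visits_enroll=2)])
        visits = make_visits([("A", LMP + dt.timedelta(days=30), "chart_retrospective")])
        assert assemble_visit_counts(cohort, visits).loc[0, "n_total"] == 2

    def test_early_prospective_reassigned_only_when_selfreport_zero(self):
        cohort = make_cohort([
            make_row(woman_id="A", self_visits_enroll=0),
            make_row(woman_id="B", self_visits_enroll=2),
        ])
        before = LMP + dt.timedelta(days=40)  # before both enrollments
        visits = make_visits([
            ("A", before, "chart_prospective"),
            ("B", before, "chart_prospective"),
        ])
        with pytest.warns(UserWarning):
            counts = assemble_visit_counts(cohort, visits).set_index("woman_id")
        assert counts.loc["A", "n_pre_enrollment_selfreport"] == 1
        assert counts.loc["A", "n_total"] == 1
        assert counts.loc["B", "n_total"] == 2  # early chart row dropped

    def test_totals_equal_simulator_truth(self, clean_sim):
        _, cohort, visits, truth = clean_sim
        analysis, _ = apply_exclusions(cohort, visits)
        counts = assemble_visit_counts(analysis, visits).set_index("woman_id")
        expected = truth.total_visits
        assert (counts["n_total"].reindex(expected.index) == expected).all()


class TestIndicators:
    def test_nonincreasing_in_threshold(self, clean_sim):
        _, cohort, visits, _ = clean_sim
        analysis, _ = apply_exclusions(cohort, visits)
        counts = assemble_visit_counts(analysis, visits)
        ests = coverage_indicators(counts, (1, 4, 8))
        assert ests["ge_1"].proportion >= ests["ge_4"].proportion >= ests["ge_8"].proportion

    def test_all_zero_counts(self):
        counts = pd.DataFrame({"n_total": [0, 0, 0]})
        ests = coverage_indicators(counts, (1, 4, 8))
        assert all(ests[f"ge_{k}"].proportion == 0 for k in (1, 4, 8))
        assert ests["zero"].proportion == 1.0

    def test_row_order_invariance(self):
        counts = pd.DataFrame({"n_total": [0, 1, 4, 2, 8]})
        shuffled = counts.sample(frac=1, random_state=0)
        a = coverage_indicators(counts)
        b = coverage_indicators(shuffled)
        assert a == b

    def test_empty_cohort_rejected(self):
        with pytest.raises(UndefinedEstimateError):
            coverage_indicators(pd.DataFrame({"n_total": []}))


class TestDistributionAndQuartiles:
    def test_frequencies_sum_to_denominator(self, demo_sim):
        _, cohort, visits, _ = demo_sim
        analysis, _ = apply_exclusions(cohort, visits)
        counts = assemble_visit_counts(analysis, visits)
        dist = visit_distribution(counts)
        assert dist["frequency"].sum() == len(counts)
        assert dist["percent"].sum() == pytest.approx(100.0)

    def test_single_woman_single_bin(self):
        dist = visit_distribution(pd.DataFrame({"n_total": [2]}))
        assert len(dist) == 1 and dist.loc[0, "percent"] == 100.0

    def test_known_fraction(self):
        counts = pd.DataFrame({"n_total": [3] * 44 + [1] * 106})
        dist = visit_distribution(counts).set_index("n_visits")
        assert dist.loc[3, "percent"] == pytest.approx(100 * 44 / 150)

    def test_constant_counts(self):
        assert median_iqr(pd.DataFrame({"n_total": [3, 3, 3]})) == (3, 3, 3)

    def test_median_of_five(self):
        med, q1, q3 = median_iqr([1, 2, 3, 4, 5])
        assert med == 3 and q1 <= med <= q3

    def test_rounded_rank_matches_sort_oracle(self):
        rng = np.random.default_rng(42)
        x = rng.integers(0, 9, size=10_000)
        med, q1, q3 = median_iqr(list(x))
        s = np.sort(x)
        n = len(s)

        def oracle(q):
            rank = int(np.floor(q * (n + 1) + 0.5))  # round half up
            return float(s[min(max(rank, 1), n) - 1])

        assert (q1, q3) == (oracle(0.25), oracle(0.75))
        assert med == float(np.median(s))

    def test_linear_method_delegates_to_percentile(self):
        x = [1, 2, 3, 4, 5, 6, 7, 8]
        _, q1, q3 = median_iqr(x, method="linear")
        assert (q1, q3) == tuple(np.percentile(x, [25, 75]))


class TestSelfReportAgreement:
    def test_all_equal_pairs(self):
        res = selfreport_agreement(pd.DataFrame({"reported": [2, 3], "chart": [2, 3]}))
        assert res["agreement"] == 1.0 and res["over_report"] == 0.0

    def test_symmetric_disagreement(self):
        res = selfreport_agreement(pd.DataFrame({"reported": [2, 1], "chart": [1, 2]}))
        assert res == {
            "n_pairs": 2, "agreement": 0.0, "over_report": 0.5, "under_report": 0.5,
        }

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({
            "reported": rng.integers(0, 5, 500), "chart": rng.integers(0, 5, 500),
        })
        res = selfreport_agreement(df)
        assert res["agreement"] + res["over_report"] + res["under_report"] == pytest.approx(1.0)
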