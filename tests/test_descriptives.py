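"""Statistical tests, quantiles, TTO, and the descriptive table."""
import datetime as dt
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from faerspv.cohort import SelectionConfig, select_cohort
from faerspv.descriptives import (
    TwoByTwo,
    build_table1,
    compute_tto,
    mann_whitney_u,
    median_iqr,
    table1_to_frame,
    yates_chi_square,
)
from faerspv.records import DrugEntry, PartialDate, ReportRecord


class TestYatesChiSquare:
    def test_gender_table_reproduces_known_p(self):
        _, p = yates_chi_square(TwoByTwo(230, 141, 2384, 1991))
        assert round(p, 3) == 0.006

    def test_perfect_independence(self):
        stat, p = yates_chi_square(TwoByTwo(10, 10, 10, 10))
        assert stat == 0.0 and p == 1.0

    def test_closed_form_hand_value(self):
        # N=10, |ad-bc|=25, corrected (25-5)^2 = 400; denominator 5^4
        stat, _ = yates_chi_square(TwoByTwo(5, 0, 0, 5))
        assert stat == pytest.approx(10 * 400 / 625)

    def test_zero_margin_undefined(self):
        stat, p = yates_chi_square(TwoByTwo(0, 0, 5, 5))
        assert math.isnan(stat) and p is None

    @given(st.tuples(*[st.integers(1, 500)] * 4))
    def test_row_and_column_swap_invariance(self, cells):
        a, b, c, d = cells
        stat1, _ = yates_chi_square(TwoByTwo(a, b, c, d))
        stat2, _ = yates_chi_square(TwoByTwo(d, c, b, a))  # both swapped
        stat3, _ = yates_chi_square(TwoByTwo(c, d, a, b))  # rows swapped
        stat4, _ = yates_chi_square(TwoByTwo(b, a, d, c))  # columns swapped
        assert stat1 == pytest.approx(stat2) == pytest.approx(stat3) == pytest.approx(stat4)

    @given(st.tuples(*[st.integers(1, 300)] * 4))
    def test_matches_scipy_continuity_corrected(self, cells):
        a, b, c, d = cells
        stat, p = yates_chi_square(TwoByTwo(a, b, c, d))
        ref_stat, ref_p, _, _ = stats.chi2_contingency(
            np.array([[a, b], [c, d]]), correction=True
        )
        assert stat == pytest.approx(ref_stat)
        assert p == pytest.approx(ref_p)


class TestMannWhitney:
    def test_exact_small_sample(self):
        u, p = mann_whitney_u([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(1 / 3)

    def test_identical_multisets_p_one(self):
        _, p = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_all_tied_p_one(self):
        _, p = mann_whitney_u([5, 5, 5], [5, 5])
        assert p == 1.0

    def test_exact_with_ties_matches_enumeration_symmetry(self):
        # pooled [1,1,2,2] split evenly: every assignment is rank-symmetric
        _, p = mann_whitney_u([1, 2], [1, 2])
        assert p == 1.0

    def test_asymptotic_matches_scipy_no_continuity(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 60)
        y = rng.normal(0.3, 1, 55)
        _, p = mann_whitney_u(x, y)
        _, ref = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        assert p == pytest.approx(ref, rel=1e-9)

    def test_exact_close_to_normal_approximation_moderate_n(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            x = rng.normal(0, 1, 20)
            y = rng.normal(0.4, 1, 20)
            _, p_exact = mann_whitney_u(x, y)  # nx*ny = 400 -> exact DP
            _, p_norm = mann_whitney_u(x, y, exact_limit=0)
            assert abs(p_exact - p_norm) < 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1])


class TestMedianIqr:
    def test_odd_symmetric(self):
        assert median_iqr([1, 2, 3, 4, 5]) == (3, 2, 4)

    def test_singleton(self):
        assert median_iqr([7]) == (7, 7, 7)

    @pytest.mark.parametrize(
        "convention, expected",
        [("type7", (14.0, 6.0, 25.5)), ("type6", (14.0, 5.0, 30.0))],
    )
    def test_conventions_frozen_oracle(self, convention, expected):
        # hand-computed order statistics for [0,5,7,14,21,30,60]:
        # type 7: h=(n-1)p -> Q1 at 1.5 => 5+0.5*(7-5)=6; Q3 at 4.5 => 25.5
        # type 6: h=(n+1)p -> Q1 at 2 => 5; Q3 at 6 => 30
        med, q1, q3 = median_iqr([0, 5, 7, 14, 21, 30, 60], convention)
        assert (med, q1, q3) == expected

    @given(st.lists(st.floats(0, 1e6), min_size=1, max_size=50))
    def test_ordering_invariant(self, values):
        med, q1, q3 = median_iqr(values)
        assert q1 <= med <= q3


class TestComputeTTO:
    def _report(self, start, event):
        return ReportRecord(
            case_id="1",
            case_version=1,
            fda_receipt_date=PartialDate(2020, 6, 1),
            event_date=event,
            drugs=(
                DrugEntry("REGORAFENIB", "PS", therapy_start=start),
            ),
            reaction_pts=frozenset({"Chromaturia"}),
        )

    def test_simple_difference(self):
        r = self._report(PartialDate(2020, 1, 1), PartialDate(2020, 1, 15))
        assert compute_tto(r, {"REGORAFENIB"}) == 14

    def test_event_before_start_is_implausible(self):
        r = self._report(PartialDate(2020, 2, 1), PartialDate(2020, 1, 15))
        assert compute_tto(r, {"REGORAFENIB"}) is None

    def test_month_precision_policy(self):
        r = self._report(PartialDate(2020, 1), PartialDate(2020, 3, 1))
        assert compute_tto(r, {"REGORAFENIB"}) is None
        assert compute_tto(r, {"REGORAFENIB"}, impute_mid_month=True) == 46

    def test_earliest_start_used(self):
        r = ReportRecord(
            case_id="1",
            case_version=1,
            fda_receipt_date=PartialDate(2020, 6, 1),
            event_date=PartialDate(2020, 1, 20),
            drugs=(
                DrugEntry("REGORAFENIB", "PS", therapy_start=PartialDate(2020, 1, 10)),
                DrugEntry("REGORAFENIB", "SS", therapy_start=PartialDate(2020, 1, 1)),
            ),
            reaction_pts=frozenset({"Chromaturia"}),
        )
        assert compute_tto(r, {"REGORAFENIB"}) == 19

    def test_other_drug_dates_ignored(self):
        r = ReportRecord(
            case_id="1",
            case_version=1,
            fda_receipt_date=PartialDate(2020, 6, 1),
            event_date=PartialDate(2020, 1, 20),
            drugs=(
                DrugEntry("REGORAFENIB", "PS"),
                DrugEntry("CETUXIMAB", "C", therapy_start=PartialDate(2020, 1, 1)),
            ),
            reaction_pts=frozenset({"Chromaturia"}),
        )
        assert compute_tto(r, {"REGORAFENIB"}) is None


class TestBuildTable1:
    def test_single_report_cohort_degenerate(self, make_report):
        cohort, _, _ = select_cohort(
            [make_report(pts=("Chromaturia",))], SelectionConfig()
        )
        rows = build_table1(cohort)
        for r in rows:
            if r.pct_cases is not None:
                assert r.pct_cases in (0.0, 100.0)
            if r.test_used == "chi2_yates":
                # one-group tables have a zero margin -> p undefined
                assert r.p_value is None or r.p_value == 1.0

    def test_percentages_sum_within_sections(self, make_report):
        reports = [
            make_report(case_id=str(i), pts=("Chromaturia",) if i % 3 == 0 else ("Nausea",),
                        gender="male" if i % 2 else "female", age=40 + i)
            for i in range(30)
        ]
        cohort, _, _ = select_cohort(reports, SelectionConfig())
        df = table1_to_frame(build_table1(cohort))
        for section in ("Gender", "Outcome"):
            sub = df[df.section == section]
            assert sub.cases_n.sum() == len(cohort.cases())
            assert sub.others_n.sum() == len(cohort.non_cases())
            assert abs(sub.cases_pct.sum() - 100.0) < 0.5 or sub.cases_pct.sum() == 0
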