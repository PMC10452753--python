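"""Contingency construction, ROR, information component, and signals."""
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from faerspv import meddra, synthetic
from faerspv.dispro import (
    ContingencyTable,
    SignalThresholds,
    annotate_expectedness,
    build_contingency,
    detect_signals,
    ic_credibility_bounds,
    information_component,
    ror,
)


class TestBuildContingency:
    def test_four_report_example(self, make_report):
        reports = [
            make_report(case_id="1", drugs=(("A", "PS"),), pts=("X",)),
            make_report(case_id="2", drugs=(("A", "PS"),), pts=("Y",)),
            make_report(case_id="3", drugs=(("B", "PS"),), pts=("X",)),
            make_report(case_id="4", drugs=(("B", "PS"),), pts=("Y",)),
        ]
        t = build_contingency(
            reports, lambda r: r.primary_suspect.active_substance == "A", "X"
        )
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)

    def test_absent_pt(self, make_report):
        reports = [make_report(case_id=str(i)) for i in range(3)]
        t = build_contingency(reports, lambda r: True, "Ghost PT")
        assert t.a == 0 and t.b == 0 and t.N == 3

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            build_contingency([], lambda r: True, "X")


class TestRor:
    def test_unit_table(self):
        est, lo, hi = ror(ContingencyTable(1, 1, 1, 1))
        assert est == 1.0
        assert lo * hi == pytest.approx(1.0)  # symmetric about 1 on log scale

    def test_hand_computed_value(self):
        # ROR = 400/600; SE = sqrt(1/10+1/20+1/30+1/40) = sqrt(0.208333)
        est, lo, hi = ror(ContingencyTable(10, 20, 30, 40))
        assert est == pytest.approx(2 / 3)
        assert lo == pytest.approx(0.27251, abs=1e-4)
        assert hi == pytest.approx(1.63093, abs=1e-4)

    def test_zero_cell_undefined_unless_haldane(self):
        t = ContingencyTable(0, 5, 5, 5)
        assert math.isnan(ror(t)[0])
        est, lo, hi = ror(t, haldane=True)
        assert 0 < est < 1 and lo < est < hi

    @given(st.tuples(*[st.integers(1, 500)] * 4))
    def test_row_swap_gives_reciprocal(self, cells):
        a, b, c, d = cells
        est, lo, hi = ror(ContingencyTable(a, b, c, d))
        est_r, lo_r, hi_r = ror(ContingencyTable(b, a, d, c))
        assert est * est_r == pytest.approx(1.0)
        assert lo_r == pytest.approx(1 / hi)
        assert hi_r == pytest.approx(1 / lo)


class TestInformationComponent:
    def test_plain_zero_at_independence(self):
        # a*N = n_drug*n_event: (10,10,10,10) -> E = 20*20/40 = 10 = a
        ic, lo, hi = information_component(ContingencyTable(10, 10, 10, 10), "plain")
        assert ic == 0.0
        assert hi - ic == pytest.approx(2 / math.sqrt(10))

    def test_shrunk_pulls_toward_zero(self):
        t = ContingencyTable(10, 10, 10, 70)
        plain, _, _ = information_component(t, "plain")
        shrunk, _, _ = information_component(t, "shrunk")
        assert 0 < shrunk < plain

    def test_monotone_in_a_holding_margins(self):
        # same N, n_drug, n_event; larger a
        ics = []
        for a in (5, 10, 15):
            t = ContingencyTable(a, 20 - a, 20 - a, 60 + a)
            ics.append(information_component(t, "plain")[0])
        assert ics == sorted(ics)

    @pytest.mark.parametrize(
        "printed_ic, n, expected_lo, expected_hi",
        [
            (2.36, 44, 2.06, 2.66),
            (1.39, 53, 1.12, 1.66),
            (1.53, 27, 1.15, 1.91),
            (0.49, 38, 0.17, 0.81),
        ],
    )
    def test_credibility_bounds_from_point_estimate(
        self, printed_ic, n, expected_lo, expected_hi
    ):
        lo, hi = ic_credibility_bounds(printed_ic, n)
        assert round(lo, 2) == expected_lo
        assert round(hi, 2) == expected_hi

    def test_noren_bounds_asymmetric(self):
        ic, lo, hi = information_component(ContingencyTable(20, 30, 50, 900), "noren")
        assert lo < ic < hi
        assert (ic - lo) > (hi - ic)  # lower bound is the wider side

    def test_interval_halfwidth_exact(self):
        for a in (1, 4, 25, 100):
            t = ContingencyTable(a, 10, 10, 100)
            ic, lo, hi = information_component(t)
            assert hi - ic == pytest.approx(2 / math.sqrt(a))
            assert ic - lo == pytest.approx(2 / math.sqrt(a))


class TestDetectSignals:
    def _corpus(self, seed=21, n=900, signals=None):
        cfg = synthetic.default_config(seed=seed, n_reports=n, signals=signals or {})
        reports, _ = synthetic.generate_reports(cfg)
        return reports

    def test_below_min_n_marked_na(self, make_report):
        reports = [
            make_report(case_id="1", drugs=(("A", "PS"),), pts=("Chromaturia",)),
            make_report(case_id="2", drugs=(("A", "PS"),), pts=("Chromaturia",)),
        ] + [
            make_report(case_id=str(i), drugs=(("B", "PS"),), pts=("Nausea",))
            for i in range(3, 30)
        ]
        results = detect_signals(
            reports,
            "A",
            lambda r: r.primary_suspect.active_substance == "A",
            {"Chromaturia"},
        )
        [res] = results
        assert res.n == 2
        assert math.isnan(res.ror) and not res.is_signal

    def test_matches_brute_force_loop(self):
        corpus = self._corpus(signals={("REGORAFENIB", "Chromaturia"): 8.0})
        pred = lambda r: r.primary_suspect.active_substance == "REGORAFENIB"
        results = detect_signals(corpus, "REG", pred, meddra.RENAL_PTS)
        # independent oracle: naive double loop per PT
        for res in results:
            a = b = c = d = 0
            for r in corpus:
                is_idx = r.primary_suspect.active_substance == "REGORAFENIB"
                has = res.pt in r.reaction_pts
                if is_idx and has:
                    a += 1
                elif is_idx:
                    c += 1
                elif has:
                    b += 1
                else:
                    d += 1
            assert res.n == a
            if not math.isnan(res.ror):
                assert res.ror == pytest.approx((a * d) / (b * c))

    def test_sorted_by_n_then_pt(self):
        corpus = self._corpus(n=2000)
        results = detect_signals(
            corpus,
            "REG",
            lambda r: r.primary_suspect.active_substance == "REGORAFENIB",
            meddra.RENAL_PTS,
        )
        keys = [(-r.n, r.pt) for r in results]
        assert keys == sorted(keys)

    def test_min_n_threshold_respected(self):
        corpus = self._corpus()
        results = detect_signals(
            corpus,
            "REG",
            lambda r: r.primary_suspect.active_substance == "REGORAFENIB",
            meddra.RENAL_PTS,
            thresholds=SignalThresholds(min_n=5),
        )
        for r in results:
            if r.n < 5:
                assert math.isnan(r.ror) and not r.is_signal


class TestExpectedness:
    def test_label_lookup(self):
        from faerspv.dispro import DisproportionalityResult

        results = [
            DisproportionalityResult("REG", "Proteinuria", 5, 1, 1, 1, 0, 0, 0, False),
            DisproportionalityResult("REG", "Chromaturia", 5, 1, 1, 1, 0, 0, 0, False),
            DisproportionalityResult("XXX", "Chromaturia", 5, 1, 1, 1, 0, 0, 0, False),
        ]
        out = annotate_expectedness(results, meddra.LABEL_EXPECTED_PTS)
        assert out[0].expected is True
        assert out[1].expected is False
        assert out[2].expected is None
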