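"""Quarterly ASCII parsing, record assembly, and round-trip fidelity."""
import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from faerspv import synthetic
from faerspv.faers_io import (
    assemble_reports,
    normalize_age,
    normalize_weight,
    read_quarter,
    write_fixture,
)


def _write(tmp_path, name, lines):
    (tmp_path / name).write_text("\n".join(lines) + "\n")


@pytest.fixture
def tiny_quarter(tmp_path):
    q = tmp_path / "2012Q4"
    q.mkdir()
    _write(q, "DEMO.txt", [
        "primaryid$caseid$caseversion$fda_dt$event_dt$sex$age$age_cod$wt$wt_cod$reporter_country$occp_cod",
        "1001$100$1$20121101$20121015$M$65$YR$70$KG$US$MD",
        "1002$101$1$20121102$$F$6$DEC$$$JP$CN",
    ])
    _write(q, "DRUG.txt", [
        "primaryid$drug_seq$role_cod$drugname$prod_ai",
        "1001$1$PS$STIVARGA$REGORAFENIB",
        "1001$2$C$ASPIRIN$ASPIRIN",
        "1002$1$PS$BRAFTOVI$ENCORAFENIB",
        "9999$1$PS$GHOST$GHOST",  # orphan: no DEMO row
    ])
    _write(q, "REAC.txt", [
        "primaryid$pt",
        "1001$Chromaturia",
        "1001$Nausea",
        "1001$Nausea",  # duplicate PT row
        "1002$Rash",
    ])
    _write(q, "OUTC.txt", ["primaryid$outc_cod", "1001$HO"])
    _write(q, "INDI.txt", [
        "primaryid$indi_drug_seq$indi_pt",
        "1001$1$Colorectal cancer metastatic",
    ])
    return q


class TestReadQuarter:
    def test_row_counts_equal_lines_minus_header(self, tiny_quarter):
        raw = read_quarter(tiny_quarter)
        assert raw.n_rows("DEMO") == 2
        assert raw.n_rows("DRUG") == 4
        assert raw.n_rows("RPSR") == 0  # absent optional table -> empty

    def test_missing_mandatory_table_is_fatal(self, tmp_path):
        q = tmp_path / "2013Q1"
        q.mkdir()
        _write(q, "DEMO.txt", ["primaryid$caseid$caseversion$fda_dt", "1$1$1$20130101"])
        with pytest.raises(FileNotFoundError):
            read_quarter(q)

    def test_unknown_column_warned_and_ignored(self, tmp_path, caplog):
        q = tmp_path / "2013Q2"
        q.mkdir()
        _write(q, "DEMO.txt", ["primaryid$caseid$caseversion$fda_dt$mystery", "1$1$1$20130101$x"])
        _write(q, "DRUG.txt", ["primaryid$drug_seq$role_cod$drugname$prod_ai", "1$1$PS$A$A"])
        _write(q, "REAC.txt", ["primaryid$pt", "1$Nausea"])
        raw = read_quarter(q)
        assert "mystery" not in raw.tables["DEMO"].columns


class TestAssemble:
    def test_joins_and_set_semantics(self, tiny_quarter):
        reports = assemble_reports(read_quarter(tiny_quarter))
        by_id = {r.case_id: r for r in reports}
        assert set(by_id) == {"100", "101"}  # orphan DRUG row excluded
        r = by_id["100"]
        assert len(r.drugs) == 2
        assert r.drugs[0].role == "PS"
        assert r.drugs[0].indication_pts == {"Colorectal cancer metastatic"}
        assert r.reaction_pts == {"Chromaturia", "Nausea"}  # deduplicated
        assert r.serious
        assert by_id["101"].age_years == 60.0  # 6 decades
        assert by_id["101"].gender == "female"

    def test_versions_both_retained_across_quarters(self, tmp_path):
        for q, version in [("2013Q1", 1), ("2013Q2", 2)]:
            d = tmp_path / q
            d.mkdir()
            _write(d, "DEMO.txt", [
                "primaryid$caseid$caseversion$fda_dt",
                f"100{version}$100${version}$2013010{version}",
            ])
            _write(d, "DRUG.txt", ["primaryid$drug_seq$role_cod$drugname$prod_ai",
                                   f"100{version}$1$PS$A$A"])
            _write(d, "REAC.txt", ["primaryid$pt", f"100{version}$Nausea"])
        reports = assemble_reports(*[read_quarter(tmp_path / q) for q in ("2013Q1", "2013Q2")])
        assert sorted(r.case_version for r in reports) == [1, 2]
        assert {r.case_id for r in reports} == {"100"}


class TestNormalizeAge:
    @pytest.mark.parametrize(
        "value, unit, expected",
        [
            (65, "YR", 65.0),
            (6, "DEC", 60.0),
            (18, "MON", 1.5),
            (730.5, "DY", 2.0),
            (70, None, 70.0),  # missing unit, plausible years
            (700, None, None),  # missing unit, implausible
            (-5, "YR", None),
            ("abc", "YR", None),
            ("", "YR", None),
        ],
    )
    def test_conversions(self, value, unit, expected):
        out = normalize_age(value, unit)
        if expected is None:
            assert out is None
        else:
            assert out == pytest.approx(expected)

    @given(st.floats(min_value=0, max_value=120), st.floats(min_value=0, max_value=120))
    def test_monotone_in_value(self, v1, v2):
        lo, hi = sorted([v1, v2])
        for unit in ("YR", "MON", "WK", "DY", "DEC", "HR"):
            assert normalize_age(lo, unit) <= normalize_age(hi, unit)

    def test_weight_units(self):
        assert normalize_weight(100, "LBS") == pytest.approx(45.3592)
        assert normalize_weight(70000, "GMS") == pytest.approx(70.0)


class TestRoundTrip:
    def test_synthetic_corpus_round_trips(self, tmp_path):
        cfg = synthetic.default_config(seed=3, n_reports=40,
                                       multi_version_fraction=0.1)
        reports, _ = synthetic.generate_reports(cfg)
        out = write_fixture(reports, tmp_path, quarter="2020Q1")
        back = assemble_reports(read_quarter(out))
        key = lambda r: (r.case_id, r.case_version)
        assert sorted(back, key=key) == sorted(reports, key=key)

    def test_empty_corpus_writes_valid_headers(self, tmp_path):
        out = write_fixture([], tmp_path, quarter="2020Q2")
        assert assemble_reports(read_quarter(out)) == []

    def test_missing_weight_written_as_empty_not_zero(self, tmp_path, make_report):
        rec = make_report(weight=None)
        out = write_fixture([rec], tmp_path, quarter="2020Q3")
        demo_lines = (out / "DEMO.txt").read_text().splitlines()
        header = demo_lines[0].split("$")
        row = demo_lines[1].split("$")
        assert row[header.index("wt")] == ""
        [back] = assemble_reports(read_quarter(out))
        assert back.weight_kg is None
        assert back == rec
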