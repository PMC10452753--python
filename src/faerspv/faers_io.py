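"""Reading and writing FAERS quarterly ASCII extracts.

A FAERS quarter is a directory of $-delimited text tables (DEMO, DRUG, REAC,
OUTC, INDI, THER, RPSR), one header row each, joined on a primary report
identifier. ``read_quarter`` parses the tables, ``assemble_reports`` joins
them into :class:`~faerspv.records.ReportRecord` objects, and
``write_fixture`` emits the same dialect so synthetic corpora round-trip
through the ingestion path.

The reader accepts a configurable column map because column names drifted
across FAERS vintages (e.g. ``gndr_cod`` vs ``sex``); the bundled defaults
match the post-2014 layout. The $ delimiter carries no quoting convention,
so embedded delimiters are unsupported and surface as malformed-row warnings.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .records import (
    CONSUMER,
    FEMALE,
    HEALTHCARE_PROFESSIONAL,
    MALE,
    UNSPECIFIED,
    DrugEntry,
    PartialDate,
    ReportRecord,
    normalize_substance,
    parse_partial_date,
)

logger = logging.getLogger("faerspv")

TABLES = ("DEMO", "DRUG", "REAC", "OUTC", "INDI", "THER", "RPSR")
MANDATORY_TABLES = ("DEMO", "DRUG", "REAC")

#: Canonical (lower-case) columns consumed per table.
TABLE_COLUMNS: dict[str, tuple[str, ...]] = {
    "DEMO": (
        "primaryid", "caseid", "caseversion", "fda_dt", "event_dt", "sex",
        "age", "age_cod", "wt", "wt_cod", "reporter_country", "occp_cod",
    ),
    "DRUG": ("primaryid", "drug_seq", "role_cod", "drugname", "prod_ai"),
    "REAC": ("primaryid", "pt"),
    "OUTC": ("primaryid", "outc_cod"),
    "INDI": ("primaryid", "indi_drug_seq", "indi_pt"),
    "THER": ("primaryid", "dsg_drug_seq", "start_dt", "end_dt"),
    "RPSR": ("primaryid", "rpsr_cod"),
}

#: Age unit code -> factor converting the value to years.
AGE_UNIT_TO_YEARS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.1775,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

WEIGHT_UNIT_TO_KG = {"KG": 1.0, "KGS": 1.0, "LBS": 0.453592, "GMS": 0.001}

_OCCP_TO_QUALIFICATION = {
    "CN": CONSUMER,
    "LW": CONSUMER,  # lawyers report on behalf of consumers
    "MD": HEALTHCARE_PROFESSIONAL,
    "PH": HEALTHCARE_PROFESSIONAL,
    "RN": HEALTHCARE_PROFESSIONAL,
    "OT": HEALTHCARE_PROFESSIONAL,  # other health professional
}
_QUALIFICATION_TO_OCCP = {CONSUMER: "CN", HEALTHCARE_PROFESSIONAL: "MD"}


@dataclass(frozen=True)
class Dialect:
    """Parsing dialect for one family of quarterly files."""

    delimiter: str = "$"
    encoding: str = "utf-8"
    header: bool = True
    #: source column name (lower-case) -> canonical column name
    column_synonyms: dict[str, str] = field(
        default_factory=lambda: {"gndr_cod": "sex", "isr": "primaryid"}
    )


DEFAULT_DIALECT = Dialect()


@dataclass
class RawQuarter:
    """Parsed tables of one quarter, as string-typed DataFrames."""

    quarter: str
    tables: dict[str, pd.DataFrame]
    malformed: dict[str, int] = field(default_factory=dict)

    def n_rows(self, table: str) -> int:
        return len(self.tables[table])


def _empty_table(name: str) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=str) for c in TABLE_COLUMNS[name]})


def _find_table_file(path: Path, table: str) -> Path | None:
    hits = sorted(
        p
        for p in path.iterdir()
        if p.is_file() and p.name.lower().startswith(table.lower())
    )
    return hits[0] if hits else None


def read_quarter(path: str | Path, dialect: Dialect | None = None) -> RawQuarter:
    """Read one quarter directory into string-typed tables.

    Malformed rows (wrong field count) are counted and logged, never
    silently dropped from the tally; unknown columns are warned about and
    ignored; a missing DEMO/DRUG/REAC table is fatal.
    """
    path = Path(path)
    dialect = dialect or DEFAULT_DIALECT
    if not path.is_dir():
        raise FileNotFoundError(f"quarter directory not found: {path}")
    tables: dict[str, pd.DataFrame] = {}
    malformed: dict[str, int] = {}
    for table in TABLES:
        f = _find_table_file(path, table)
        if f is None:
            if table in MANDATORY_TABLES:
                raise FileNotFoundError(
                    f"mandatory table {table} missing from {path}"
                )
            tables[table] = _empty_table(table)
            malformed[table] = 0
            continue
        bad = []

        def _on_bad(line, _bad=bad):  # noqa: ANN001
            _bad.append(line)
            return None

        df = pd.read_csv(
            f,
            sep=dialect.delimiter,
            dtype=str,
            keep_default_na=False,
            encoding=dialect.encoding,
            header=0 if dialect.header else None,
            engine="python",
            on_bad_lines=_on_bad,
        )
        if bad:
            logger.warning(
                "%s/%s: %d malformed row(s) skipped", path.name, table, len(bad)
            )
        df.columns = [str(c).strip().lower() for c in df.columns]
        df = df.rename(columns=dialect.column_synonyms)
        expected = TABLE_COLUMNS[table]
        unknown = [c for c in df.columns if c not in expected]
        if unknown:
            logger.warning("%s/%s: ignoring unknown column(s) %s", path.name, table, unknown)
            df = df.drop(columns=unknown)
        for c in expected:
            if c not in df.columns:
                df[c] = ""
        tables[table] = df[list(expected)]
        malformed[table] = len(bad)
    return RawQuarter(quarter=path.name, tables=tables, malformed=malformed)


def normalize_age(value: str | float | None, unit_code: str | None) -> float | None:
    """Convert a FAERS AGE/AGE_COD pair to years.

    A missing unit with a value <= 120 is taken as years; negative or
    non-numeric values are logged and treated as missing.
    """
    if value is None:
        return None
    s = str(value).strip()
    if not s:
        return None
    try:
        v = float(s)
    except ValueError:
        logger.warning("non-numeric age %r", value)
        return None
    if v < 0:
        logger.warning("negative age %r", value)
        return None
    unit = (unit_code or "").strip().upper()
    if not unit:
        return v if v <= 120 else None
    factor = AGE_UNIT_TO_YEARS.get(unit)
    if factor is None:
        logger.warning("unknown age unit %r", unit_code)
        return None
    return v * factor


def normalize_weight(value: str | float | None, unit_code: str | None) -> float | None:
    """Convert a FAERS WT/WT_COD pair to kilograms (missing unit => kg)."""
    if value is None:
        return None
    s = str(value).strip()
    if not s:
        return None
    try:
        v = float(s)
    except ValueError:
        logger.warning("non-numeric weight %r", value)
        return None
    if v < 0:
        logger.warning("negative weight %r", value)
        return None
    unit = (unit_code or "").strip().upper()
    factor = WEIGHT_UNIT_TO_KG.get(unit, 1.0 if not unit else None)
    if factor is None:
        logger.warning("unknown weight unit %r", unit_code)
        return None
    return v * factor


def _parse_gender(code: str) -> str:
    code = code.strip().upper()
    if code == "M":
        return MALE
    if code == "F":
        return FEMALE
    return UNSPECIFIED


def _group_rows(df: pd.DataFrame) -> dict[str, list[dict[str, str]]]:
    out: dict[str, list[dict[str, str]]] = {}
    for row in df.to_dict("records"):
        out.setdefault(row["primaryid"], []).append(row)
    return out


def assemble_reports(*quarters: RawQuarter) -> list[ReportRecord]:
    """Join the per-quarter tables into one record per report identifier.

    Drugs are ordered by FAERS drug sequence number, reaction PTs are
    deduplicated, and rows referencing an identifier absent from DEMO
    (orphans) are logged and excluded. A primary id appearing in several
    quarters keeps the last-read DEMO row; distinct case versions have
    distinct primary ids and are all retained here — version resolution
    belongs to the dedup stage.
    """
    if not quarters:
        raise ValueError("at least one quarter required")
    demo = pd.concat([q.tables["DEMO"] for q in quarters], ignore_index=True)
    joined = {
        name: _group_rows(
            pd.concat([q.tables[name] for q in quarters], ignore_index=True)
        )
        for name in TABLES
        if name != "DEMO"
    }
    demo_ids = set(demo["primaryid"])
    n_orphans = sum(
        sum(1 for pid in rows if pid not in demo_ids) for rows in joined.values()
    )
    if n_orphans:
        logger.warning("%d orphan id(s) in child tables excluded", n_orphans)

    records: dict[str, ReportRecord] = {}
    for row in demo.to_dict("records"):
        pid = row["primaryid"]
        drugs = []
        drug_rows = joined["DRUG"].get(pid, [])
        indi_by_seq: dict[str, list[str]] = {}
        for r in joined["INDI"].get(pid, []):
            indi_by_seq.setdefault(r["indi_drug_seq"], []).append(r["indi_pt"])
        ther_by_seq: dict[str, dict[str, str]] = {
            r["dsg_drug_seq"]: r for r in joined["THER"].get(pid, [])
        }

        def _seq_key(r: dict[str, str]) -> tuple[int, str]:
            s = r["drug_seq"]
            return (int(s), "") if s.isdigit() else (10**9, s)

        for r in sorted(drug_rows, key=_seq_key):
            substance = r["prod_ai"].strip() or r["drugname"].strip()
            if not substance:
                continue
            seq = r["drug_seq"]
            ther = ther_by_seq.get(seq, {})
            role = r["role_cod"].strip().upper()
            if role not in ("PS", "SS", "C", "I"):
                logger.warning("unknown drug role %r on %s; treated as C", role, pid)
                role = "C"
            drugs.append(
                DrugEntry(
                    active_substance=normalize_substance(substance),
                    role=role,
                    indication_pts=frozenset(
                        p.strip() for p in indi_by_seq.get(seq, []) if p.strip()
                    ),
                    therapy_start=parse_partial_date(ther.get("start_dt", "")),
                    therapy_end=parse_partial_date(ther.get("end_dt", "")),
                )
            )
        pts = frozenset(
            r["pt"].strip() for r in joined["REAC"].get(pid, []) if r["pt"].strip()
        )
        outcomes = frozenset(
            r["outc_cod"].strip().upper()
            for r in joined["OUTC"].get(pid, [])
            if r["outc_cod"].strip()
        )
        sources = frozenset(
            r["rpsr_cod"].strip().upper()
            for r in joined["RPSR"].get(pid, [])
            if r["rpsr_cod"].strip()
        )
        receipt = parse_partial_date(row["fda_dt"])
        if receipt is None:
            logger.warning("report %s has no receipt date; skipped", pid)
            continue
        version_s = row["caseversion"].strip()
        records[pid] = ReportRecord(
            case_id=row["caseid"].strip() or pid,
            case_version=int(version_s) if version_s.isdigit() else 1,
            fda_receipt_date=receipt,
            event_date=parse_partial_date(row["event_dt"]),
            gender=_parse_gender(row["sex"]),
            age_years=normalize_age(row["age"], row["age_cod"]),
            weight_kg=normalize_weight(row["wt"], row["wt_cod"]),
            reporter_country=row["reporter_country"].strip().upper(),
            reporter_qualification=_OCCP_TO_QUALIFICATION.get(
                row["occp_cod"].strip().upper(), UNSPECIFIED
            ),
            report_sources=sources,
            drugs=tuple(drugs),
            reaction_pts=pts,
            outcome_codes=outcomes,
        )
    return list(records.values())


def _fmt_float(v: float | None) -> str:
    if v is None:
        return ""
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def _fmt_date(d: PartialDate | None) -> str:
    return "" if d is None else d.to_faers()


def write_fixture(
    reports: list[ReportRecord],
    out_dir: str | Path,
    quarter: str = "2023Q1",
    dialect: Dialect | None = None,
) -> Path:
    """Write reports as one quarterly-format directory and return its path.

    The emitted dialect is the same one ``read_quarter`` consumes, so
    ``assemble_reports(read_quarter(write_fixture(reports)))`` recovers the
    input records field-by-field. Missing numeric fields are written as
    empty strings, never as zeros.
    """
    dialect = dialect or DEFAULT_DIALECT
    out = Path(out_dir) / quarter
    out.mkdir(parents=True, exist_ok=True)
    rows: dict[str, list[dict[str, str]]] = {t: [] for t in TABLES}
    for rec in reports:
        pid = f"{rec.case_id}-{rec.case_version}"
        rows["DEMO"].append(
            {
                "primaryid": pid,
                "caseid": rec.case_id,
                "caseversion": str(rec.case_version),
                "fda_dt": _fmt_date(rec.fda_receipt_date),
                "event_dt": _fmt_date(rec.event_date),
                "sex": {MALE: "M", FEMALE: "F"}.get(rec.gender, ""),
                "age": _fmt_float(rec.age_years),
                "age_cod": "YR" if rec.age_years is not None else "",
                "wt": _fmt_float(rec.weight_kg),
                "wt_cod": "KG" if rec.weight_kg is not None else "",
                "reporter_country": rec.reporter_country,
                "occp_cod": _QUALIFICATION_TO_OCCP.get(rec.reporter_qualification, ""),
            }
        )
        for i, d in enumerate(rec.drugs, start=1):
            rows["DRUG"].append(
                {
                    "primaryid": pid,
                    "drug_seq": str(i),
                    "role_cod": d.role,
                    "drugname": d.active_substance,
                    "prod_ai": d.active_substance,
                }
            )
            for ind in sorted(d.indication_pts):
                rows["INDI"].append(
                    {"primaryid": pid, "indi_drug_seq": str(i), "indi_pt": ind}
                )
            if d.therapy_start is not None or d.therapy_end is not None:
                rows["THER"].append(
                    {
                        "primaryid": pid,
                        "dsg_drug_seq": str(i),
                        "start_dt": _fmt_date(d.therapy_start),
                        "end_dt": _fmt_date(d.therapy_end),
                    }
                )
        for pt in sorted(rec.reaction_pts):
            rows["REAC"].append({"primaryid": pid, "pt": pt})
        for oc in sorted(rec.outcome_codes):
            rows["OUTC"].append({"primaryid": pid, "outc_cod": oc})
        for src in sorted(rec.report_sources):
            rows["RPSR"].append({"primaryid": pid, "rpsr_cod": src})
    for table in TABLES:
        cols = list(TABLE_COLUMNS[table])
        df = pd.DataFrame(rows[table], columns=cols)
        df.to_csv(
            out / f"{table}.txt",
            sep=dialect.delimiter,
            index=False,
            encoding=dialect.encoding,
            lineterminator="\n",
        )
    return out
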