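"""Core report-level data structures shared by every pipeline stage.

Spontaneous safety reports carry dates of variable precision (FAERS dates
are 4-, 6-, or 8-digit strings), so dates are modelled as :class:`PartialDate`
with an explicit precision rather than forced onto ``datetime.date``.
"""
from __future__ import annotations

import calendar
import datetime as dt
import logging
from dataclasses import dataclass, field

logger = logging.getLogger("faerspv")

# Gender categories
MALE = "male"
FEMALE = "female"
UNSPECIFIED = "unspecified"

# Reporter qualification categories
CONSUMER = "consumer"
HEALTHCARE_PROFESSIONAL = "healthcare_professional"

# FAERS drug role codes: primary suspect, secondary suspect, concomitant,
# interacting.
DRUG_ROLES = ("PS", "SS", "C", "I")

# FAERS outcome codes: death, life-threatening, hospitalization, disability,
# required intervention, congenital anomaly, other serious outcome.
OUTCOME_CODES = ("DE", "LT", "HO", "DS", "RI", "CA", "OT")

# FAERS report-source code for literature reports.
SOURCE_LITERATURE = "LIT"


@dataclass(frozen=True, slots=True)
class PartialDate:
    """A calendar date known to year, month, or day precision."""

    year: int
    month: int | None = None
    day: int | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.year <= 9999:
            raise ValueError(f"year out of range: {self.year}")
        if self.month is not None and not 1 <= self.month <= 12:
            raise ValueError(f"month out of range: {self.month}")
        if self.day is not None:
            if self.month is None:
                raise ValueError("day requires month")
            last = calendar.monthrange(self.year, self.month)[1]
            if not 1 <= self.day <= last:
                raise ValueError(
                    f"day {self.day} invalid for {self.year}-{self.month:02d}"
                )

    @property
    def precision(self) -> str:
        if self.day is not None:
            return "day"
        if self.month is not None:
            return "month"
        return "year"

    def sort_key(self) -> tuple[int, int, int]:
        """Chronological ordering key; absent components sort earliest."""
        return (self.year, self.month or 0, self.day or 0)

    def to_date(self) -> dt.date | None:
        """Exact calendar date, or None unless day-precise."""
        if self.day is None:
            return None
        return dt.date(self.year, self.month, self.day)

    def to_faers(self) -> str:
        if self.day is not None:
            return f"{self.year:04d}{self.month:02d}{self.day:02d}"
        if self.month is not None:
            return f"{self.year:04d}{self.month:02d}"
        return f"{self.year:04d}"

    @classmethod
    def from_date(cls, d: dt.date) -> "PartialDate":
        return cls(d.year, d.month, d.day)

    def days_until(self, other: "PartialDate") -> int | None:
        """Signed day count self -> other; None unless both day-precise."""
        a, b = self.to_date(), other.to_date()
        if a is None or b is None:
            return None
        return (b - a).days


def parse_partial_date(s: str | None) -> PartialDate | None:
    """Parse a FAERS date string (YYYY, YYYYMM, or YYYYMMDD).

    Empty/missing input returns None. Calendar-invalid values (e.g. a 30
    February) are logged and returned as None rather than raising, because
    FAERS extracts contain them.
    """
    if s is None:
        return None
    s = s.strip()
    if not s:
        return None
    if not s.isdigit() or len(s) not in (4, 6, 8):
        logger.warning("unparseable date %r", s)
        return None
    try:
        year = int(s[:4])
        month = int(s[4:6]) if len(s) >= 6 else None
        day = int(s[6:8]) if len(s) == 8 else None
        return PartialDate(year, month, day)
    except ValueError:
        logger.warning("invalid calendar date %r", s)
        return None


def normalize_substance(name: str) -> str:
    """Uppercase, trim, and collapse internal whitespace.

    No synonym dictionary is applied; callers may supply one via the
    selection configuration.
    """
    return " ".join(name.upper().split())


@dataclass(frozen=True, slots=True)
class DrugEntry:
    """One drug mention on a report: substance, FAERS role, indications,
    and therapy episode dates."""

    active_substance: str
    role: str
    indication_pts: frozenset[str] = frozenset()
    therapy_start: PartialDate | None = None
    therapy_end: PartialDate | None = None

    def __post_init__(self) -> None:
        if self.role not in DRUG_ROLES:
            raise ValueError(f"unknown drug role {self.role!r}")


@dataclass(frozen=True, slots=True)
class ReportRecord:
    """One safety report after table assembly (one row per report id)."""

    case_id: str
    case_version: int
    fda_receipt_date: PartialDate
    event_date: PartialDate | None = None
    gender: str = UNSPECIFIED
    age_years: float | None = None
    weight_kg: float | None = None
    reporter_country: str = ""
    reporter_qualification: str = UNSPECIFIED
    report_sources: frozenset[str] = frozenset()
    drugs: tuple[DrugEntry, ...] = ()
    reaction_pts: frozenset[str] = frozenset()
    outcome_codes: frozenset[str] = frozenset()

    @property
    def serious(self) -> bool:
        """A report is serious iff it carries at least one outcome code.

        Every FAERS OUTC code (including OT, "other serious outcome")
        denotes a serious outcome; reports with no outcome row are
        non-serious.
        """
        return len(self.outcome_codes) > 0

    @property
    def primary_suspect(self) -> DrugEntry | None:
        for d in self.drugs:
            if d.role == "PS":
                return d
        return None

    def suspect_substances(self) -> frozenset[str]:
        """Substances in suspect roles (PS or SS)."""
        return frozenset(
            d.active_substance for d in self.drugs if d.role in ("PS", "SS")
        )

    def all_substances(self) -> frozenset[str]:
        return frozenset(d.active_substance for d in self.drugs)
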