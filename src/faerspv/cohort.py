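"""Cohort selection and case/non-case classification.

The analysis frame is every deduplicated-by-version report that mentions an
index drug (regorafenib or encorafenib) within the study window. Reports
are then excluded, in order, when they are (1) pre-marketing reports
supported by the literature, (2) related to an indication other than
colorectal cancer, (3) attributed to another primary-suspect drug, or
(4) cross-case duplicates. Each report lands in exactly one bucket (the
first that applies), which makes the flow counts telescope.

Among included reports, a *case* is any report with at least one reaction
PT in the target SOC ("Renal and urinary disorders" by default); reports
with several renal PTs still count as one case.
"""
from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import dedup as _dedup
from . import meddra
from .records import PartialDate, ReportRecord, SOURCE_LITERATURE, normalize_substance

logger = logging.getLogger("faerspv")

#: Default colorectal-cancer indication terms (editable via config).
DEFAULT_CRC_TERMS: frozenset[str] = frozenset(
    {
        "Colorectal cancer",
        "Colorectal cancer metastatic",
        "Colon cancer",
        "Colon cancer metastatic",
        "Rectal cancer",
        "Rectal cancer metastatic",
        "Metastases to colon",
    }
)

#: US approval dates used by the pre-marketing literature rule:
#: regorafenib for mCRC (2012-09-27) and encorafenib's CRC indication (2020).
DEFAULT_APPROVAL_DATES: dict[str, dt.date] = {
    "REG": dt.date(2012, 9, 27),
    "ENC": dt.date(2020, 4, 8),
}


@dataclass
class SelectionConfig:
    """Cohort definition: index drugs, indication, window, target SOC."""

    index_drugs: dict[str, frozenset[str]] = field(
        default_factory=lambda: {
            "REG": frozenset({"REGORAFENIB"}),
            "ENC": frozenset({"ENCORAFENIB"}),
        }
    )
    indication_terms: frozenset[str] = DEFAULT_CRC_TERMS
    window_start: PartialDate = PartialDate(2012, 10, 1)
    window_end: PartialDate = PartialDate(2022, 12, 31)
    target_soc: str = meddra.RENAL_SOC
    pt_to_soc: dict[str, str] = field(default_factory=lambda: dict(meddra.PT_TO_SOC))
    exclude_literature: bool = True
    approval_dates: dict[str, dt.date] = field(
        default_factory=lambda: dict(DEFAULT_APPROVAL_DATES)
    )
    #: "drug": match indication on the primary-suspect drug's INDI terms
    #: (default); "report": match on any drug's INDI terms.
    indication_scope: str = "drug"

    def __post_init__(self) -> None:
        for name, syns in self.index_drugs.items():
            if not syns:
                raise ValueError(f"index drug {name!r} has an empty synonym set")
            self.index_drugs[name] = frozenset(normalize_substance(s) for s in syns)
        names = list(self.index_drugs)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if self.index_drugs[a] & self.index_drugs[b]:
                    raise ValueError(f"index drug synonym sets overlap: {a}/{b}")
        if self.window_start.sort_key() > self.window_end.sort_key():
            raise ValueError("window start after window end")
        self._terms_lower = frozenset(t.lower() for t in self.indication_terms)
        self._all_synonyms = frozenset().union(*self.index_drugs.values())

    # -- helpers -----------------------------------------------------------

    def index_name_of(self, substance: str) -> str | None:
        for name, syns in self.index_drugs.items():
            if substance in syns:
                return name
        return None

    def target_pts(self) -> frozenset[str]:
        return frozenset(
            pt for pt, soc in self.pt_to_soc.items() if soc == self.target_soc
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SelectionConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        if "index_drugs" in raw:
            kwargs["index_drugs"] = {
                k: frozenset(v) for k, v in raw["index_drugs"].items()
            }
        if "indication_terms" in raw:
            kwargs["indication_terms"] = frozenset(raw["indication_terms"])
        for key in ("target_soc", "exclude_literature", "indication_scope"):
            if key in raw:
                kwargs[key] = raw[key]
        if "pt_to_soc" in raw:
            kwargs["pt_to_soc"] = dict(raw["pt_to_soc"])
        if "window" in raw:
            start, end = raw["window"]
            kwargs["window_start"] = PartialDate.from_date(dt.date.fromisoformat(start))
            kwargs["window_end"] = PartialDate.from_date(dt.date.fromisoformat(end))
        if "approval_dates" in raw:
            kwargs["approval_dates"] = {
                k: dt.date.fromisoformat(v) for k, v in raw["approval_dates"].items()
            }
        return cls(**kwargs)


@dataclass(frozen=True)
class FlowCounts:
    """Report-selection flow: one count per exclusion bucket."""

    total: int
    excluded_literature: int
    excluded_other_indication: int
    excluded_other_ps: int
    excluded_duplicates: int
    included: int

    def __post_init__(self) -> None:
        excl = (
            self.excluded_literature
            + self.excluded_other_indication
            + self.excluded_other_ps
            + self.excluded_duplicates
        )
        if self.included != self.total - excl:
            raise ValueError("flow counts do not telescope")
        if min(
            self.total,
            self.excluded_literature,
            self.excluded_other_indication,
            self.excluded_other_ps,
            self.excluded_duplicates,
            self.included,
        ) < 0:
            raise ValueError("negative flow count")

    def as_dict(self) -> dict[str, int]:
        return {
            "total": self.total,
            "excluded_literature": self.excluded_literature,
            "excluded_other_indication": self.excluded_other_indication,
            "excluded_other_ps": self.excluded_other_ps,
            "excluded_duplicates": self.excluded_duplicates,
            "included": self.included,
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.as_dict(), indent=2) + "\n")
        return path

    def as_text(self) -> str:
        lines = [
            f"Reports mentioning an index drug in window   {self.total:>7,}",
            f"  - pre-marketing literature reports         {self.excluded_literature:>7,}",
            f"  - other indications                        {self.excluded_other_indication:>7,}",
            f"  - other primary suspect drug               {self.excluded_other_ps:>7,}",
            f"  - duplicates                               {self.excluded_duplicates:>7,}",
            f"Included in the analysis                     {self.included:>7,}",
        ]
        return "\n".join(lines)


@dataclass
class CohortEntry:
    record: ReportRecord
    index_drug: str
    is_case: bool = False
    secondary_suspects: frozenset[str] = frozenset()


@dataclass
class CohortTable:
    """Included reports with their index-drug and case labels."""

    entries: list[CohortEntry]

    def __post_init__(self) -> None:
        ids = [e.record.case_id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate case ids in cohort")

    def __len__(self) -> int:
        return len(self.entries)

    def cases(self) -> list[CohortEntry]:
        return [e for e in self.entries if e.is_case]

    def non_cases(self) -> list[CohortEntry]:
        return [e for e in self.entries if not e.is_case]

    def case_ids(self, index_drug: str | None = None) -> frozenset[str]:
        return frozenset(
            e.record.case_id
            for e in self.entries
            if index_drug is None or e.index_drug == index_drug
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "case_id": [e.record.case_id for e in self.entries],
                "index_drug": [e.index_drug for e in self.entries],
                "is_case": [e.is_case for e in self.entries],
                "secondary_suspects": [
                    ";".join(sorted(e.secondary_suspects)) for e in self.entries
                ],
            }
        )


def _event_before(event: PartialDate | None, cutoff: dt.date) -> bool:
    """True when the event date is (at its known precision) before cutoff.

    Missing components are filled with their earliest value, so a
    year-precision date compares by January 1st.
    """
    if event is None:
        return False
    key = (event.year, event.month or 1, event.day or 1)
    return key < (cutoff.year, cutoff.month, cutoff.day)


def _in_window(receipt: PartialDate, config: SelectionConfig) -> bool:
    return (
        config.window_start.sort_key()
        <= receipt.sort_key()
        <= config.window_end.sort_key()
    )


def _indication_match(report: ReportRecord, config: SelectionConfig) -> bool:
    if config.indication_scope == "report":
        terms: set[str] = set()
        for d in report.drugs:
            terms.update(t.lower() for t in d.indication_pts)
    else:
        ps = report.primary_suspect
        if ps is None:
            return False
        terms = {t.lower() for t in ps.indication_pts}
    return bool(terms & config._terms_lower)


def select_cohort(
    reports: Sequence[ReportRecord], config: SelectionConfig
) -> tuple[CohortTable, FlowCounts, _dedup.DedupResult]:
    """Apply the selection flow and return (cohort, flow counts, dedup audit).

    Input should already be version-resolved; cross-case dedup is applied
    here as the final exclusion step and its audit is returned.
    """
    frame = [
        r
        for r in reports
        if (r.all_substances() & config._all_synonyms)
        and _in_window(r.fda_receipt_date, config)
    ]
    total = len(frame)
    survivors: list[ReportRecord] = []
    n_lit = n_ind = n_ps = 0
    for r in frame:
        if config.exclude_literature and SOURCE_LITERATURE in r.report_sources:
            mentioned = [
                name
                for name, syns in config.index_drugs.items()
                if r.all_substances() & syns
            ]
            cutoff = min(
                (config.approval_dates[m] for m in mentioned if m in config.approval_dates),
                default=None,
            )
            if cutoff is not None and _event_before(r.event_date, cutoff):
                n_lit += 1
                continue
        if not _indication_match(r, config):
            n_ind += 1
            continue
        ps = r.primary_suspect
        if ps is None or config.index_name_of(ps.active_substance) is None:
            n_ps += 1
            continue
        survivors.append(r)
    dedup_result = _dedup.deduplicate(survivors)
    included = dedup_result.reports
    flow = FlowCounts(
        total=total,
        excluded_literature=n_lit,
        excluded_other_indication=n_ind,
        excluded_other_ps=n_ps,
        excluded_duplicates=dedup_result.n_removed,
        included=len(included),
    )
    entries = []
    for r in included:
        name = config.index_name_of(r.primary_suspect.active_substance)
        entries.append(
            CohortEntry(
                record=r,
                index_drug=name,
                secondary_suspects=frozenset(
                    d.active_substance for d in r.drugs if d.role == "SS"
                ),
            )
        )
    cohort = classify_cases(
        CohortTable(entries), config.pt_to_soc, config.target_soc
    )
    return cohort, flow, dedup_result


def classify_cases(
    cohort: CohortTable,
    pt_to_soc: dict[str, str] | None = None,
    target_soc: str = meddra.RENAL_SOC,
) -> CohortTable:
    """Set the case flag: a report is a case iff any reaction PT belongs to
    the target SOC. Idempotent; a report with several target-SOC PTs is
    still a single case."""
    target_pts = frozenset(
        pt
        for pt, soc in (pt_to_soc or meddra.PT_TO_SOC).items()
        if soc == target_soc
    )
    entries = [
        replace(e, is_case=bool(e.record.reaction_pts & target_pts))
        for e in cohort.entries
    ]
    return CohortTable(entries)


def pt_case_counts(
    cohort: CohortTable,
    pt_to_soc: dict[str, str] | None = None,
    target_soc: str = meddra.RENAL_SOC,
) -> pd.DataFrame:
    """Report-level counts of each target-SOC PT among cases.

    One row per (index_drug, PT) plus an "ALL" drug aggregate; a report
    carrying a PT counts once for that PT, and percentages are over the
    total case count.
    """
    target_pts = frozenset(
        pt
        for pt, soc in (pt_to_soc or meddra.PT_TO_SOC).items()
        if soc == target_soc
    )
    cases = cohort.cases()
    n_cases = len(cases)
    counts: dict[tuple[str, str], int] = {}
    for e in cases:
        for pt in e.record.reaction_pts & target_pts:
            for drug in (e.index_drug, "ALL"):
                counts[(drug, pt)] = counts.get((drug, pt), 0) + 1
    rows = [
        {
            "index_drug": drug,
            "pt": pt,
            "n": n,
            "pct": round(100.0 * n / n_cases, 1) if n_cases else float("nan"),
        }
        for (drug, pt), n in counts.items()
    ]
    df = pd.DataFrame(rows, columns=["index_drug", "pt", "n", "pct"])
    return df.sort_values(
        ["index_drug", "n", "pt"], ascending=[True, False, True]
    ).reset_index(drop=True)
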