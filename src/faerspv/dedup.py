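"""Duplicate-report removal.

Two stages, mirroring how spontaneous-report databases accumulate noise:

1. *Version resolution* — FAERS cases are resubmitted as new versions under
   the same case id; only the latest version of each case is analysable.
2. *Cross-case deduplication* — the same clinical episode may be reported
   under several case ids. Reports are considered duplicates when they
   agree on every key field: reaction PT set, event date, gender, age,
   body weight, reporting country, and suspected active substances.

Matching is deliberately conservative: a missing key field never matches a
missing key field, so sparse reports are never merged; age and weight are
compared after integer rounding to absorb unit-conversion jitter; and the
suspected-substance set covers PS and SS roles only.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Hashable, Sequence

from .records import UNSPECIFIED, ReportRecord

DedupKey = tuple


def dedup_key(report: ReportRecord) -> DedupKey | None:
    """Matching key of a report, or None if any key field is missing.

    A report returning None can never be part of a duplicate cluster.
    """
    suspects = report.suspect_substances()
    if (
        not report.reaction_pts
        or report.event_date is None
        or report.gender == UNSPECIFIED
        or report.age_years is None
        or report.weight_kg is None
        or not report.reporter_country
        or not suspects
    ):
        return None
    return (
        report.reaction_pts,
        report.event_date,
        report.gender,
        round(report.age_years),
        round(report.weight_kg),
        report.reporter_country,
        suspects,
    )


def _case_id_order(case_id: str) -> tuple[int, int | str]:
    """Numeric-aware ordering so '9' sorts before '10'."""
    return (0, int(case_id)) if case_id.isdigit() else (1, case_id)


def resolve_versions(reports: Sequence[ReportRecord]) -> list[ReportRecord]:
    """Keep exactly one record per case id.

    Preference: highest case version, then latest FDA receipt date, then
    last-seen input order. Output preserves the input order of the kept
    records.
    """
    best: dict[str, tuple[tuple, int]] = {}
    for i, r in enumerate(reports):
        pref = (r.case_version, r.fda_receipt_date.sort_key(), i)
        cur = best.get(r.case_id)
        if cur is None or pref > cur[0]:
            best[r.case_id] = (pref, i)
    keep = {i for _, i in best.values()}
    return [r for i, r in enumerate(reports) if i in keep]


def find_duplicate_clusters(
    reports: Sequence[ReportRecord],
) -> list[list[str]]:
    """Equivalence classes of case ids sharing a complete dedup key.

    Expects version-resolved input. Clusters (size >= 2) are returned in
    order of first appearance; ids within a cluster keep input order.
    """
    groups: dict[Hashable, list[str]] = {}
    for r in reports:
        key = dedup_key(r)
        if key is None:
            continue
        groups.setdefault(key, []).append(r.case_id)
    return [ids for ids in groups.values() if len(ids) >= 2]


@dataclass
class DedupResult:
    reports: list[ReportRecord]
    n_removed: int
    #: one row per cluster: (cluster index, kept case id, removed case ids)
    audit: list[tuple[int, str, list[str]]]

    def write_audit(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["cluster_id", "kept_case_id", "removed_case_ids"])
            for cid, kept, removed in self.audit:
                w.writerow([cid, kept, ";".join(removed)])
        return path


def deduplicate(reports: Sequence[ReportRecord]) -> DedupResult:
    """Drop cross-case duplicates; idempotent and order-insensitive.

    Within each cluster the record with the latest FDA receipt date is
    kept; ties go to the lowest case id.
    """
    by_id = {r.case_id: r for r in reports}
    removed: set[str] = set()
    audit: list[tuple[int, str, list[str]]] = []
    for i, cluster in enumerate(find_duplicate_clusters(reports)):
        best_date = max(by_id[c].fda_receipt_date.sort_key() for c in cluster)
        tied = [c for c in cluster if by_id[c].fda_receipt_date.sort_key() == best_date]
        kept = min(tied, key=_case_id_order)
        losers = [c for c in cluster if c != kept]
        removed.update(losers)
        audit.append((i, kept, losers))
    out = [r for r in reports if r.case_id not in removed]
    return DedupResult(reports=out, n_removed=len(reports) - len(out), audit=audit)
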