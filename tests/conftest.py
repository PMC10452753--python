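import datetime as dt

import pytest
from hypothesis import HealthCheck, settings

from faerspv.records import DrugEntry, PartialDate, ReportRecord

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def make_report():
    """Factory for hand-built reports with sensible defaults."""

    def _make(
        case_id="100",
        case_version=1,
        receipt=dt.date(2020, 6, 1),
        event=dt.date(2020, 5, 1),
        gender="male",
        age=65.0,
        weight=70.0,
        country="US",
        drugs=(("REGORAFENIB", "PS"),),
        pts=("Nausea",),
        outcomes=(),
        sources=(),
        indications=("Colorectal cancer metastatic",),
        therapy_start=None,
        reporter="healthcare_professional",
    ):
        entries = []
        for i, (sub, role) in enumerate(drugs):
            entries.append(
                DrugEntry(
                    active_substance=sub,
                    role=role,
                    indication_pts=frozenset(indications) if role == "PS" else frozenset(),
                    therapy_start=(
                        PartialDate.from_date(therapy_start)
                        if (therapy_start and role == "PS")
                        else None
                    ),
                )
            )
        return ReportRecord(
            case_id=case_id,
            case_version=case_version,
            fda_receipt_date=PartialDate.from_date(receipt),
            event_date=PartialDate.from_date(event) if event else None,
            gender=gender,
            age_years=age,
            weight_kg=weight,
            reporter_country=country,
            reporter_qualification=reporter,
            report_sources=frozenset(sources),
            drugs=tuple(entries),
            reaction_pts=frozenset(pts),
            outcome_codes=frozenset(outcomes),
        )

    return _make
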