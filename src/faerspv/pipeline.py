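"""End-to-end orchestration: quarters in, analysis bundle out.

The pipeline is deterministic: identical inputs and configuration yield
byte-identical output tables. Every artifact is plain text (CSV, Markdown,
JSON) so runs can be diffed.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, dedup, dispro, meddra
from .cohort import CohortTable, FlowCounts, SelectionConfig, select_cohort
from .descriptives import build_table1, table1_to_frame, tto_summary
from .faers_io import Dialect, assemble_reports, read_quarter
from .records import ReportRecord

logger = logging.getLogger("faerspv")


@dataclass
class RunConfig:
    quarters: list[Path]
    out_dir: Path
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    thresholds: dispro.SignalThresholds = field(default_factory=dispro.SignalThresholds)
    ic_variant: str = "shrunk"
    #: reference group for the 2x2: the whole ingested corpus minus the
    #: index group ("corpus"), or the included cohort only ("cohort")
    reference: str = "corpus"
    expectedness: dict[str, frozenset[str]] = field(
        default_factory=lambda: dict(meddra.LABEL_EXPECTED_PTS)
    )
    quantile_convention: str = "type7"
    impute_mid_month: bool = False
    dialect: Dialect = field(default_factory=Dialect)
    seed: int = 0


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


@_stage("ingest")
def ingest(config: RunConfig) -> list[ReportRecord]:
    if not config.quarters:
        raise ValueError("no quarter directories given")
    raw = [read_quarter(q, config.dialect) for q in config.quarters]
    return assemble_reports(*raw)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run ingest -> versions -> cohort -> descriptives -> signals and
    write the artifact bundle. Returns artifact name -> path."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    reports = ingest(config)
    n_raw = len(reports)
    reports = dedup.resolve_versions(reports)
    logger.info("%d report(s) after version resolution (from %d)", len(reports), n_raw)

    cohort, flow, dedup_result = select_cohort(reports, config.selection)

    artifacts["flowchart_json"] = flow.to_json(out / "flowchart.json")
    (out / "flowchart.txt").write_text(flow.as_text() + "\n")
    artifacts["flowchart_txt"] = out / "flowchart.txt"
    artifacts["dedup_audit"] = dedup_result.write_audit(out / "dedup_audit.csv")
    cohort.to_frame().to_csv(out / "cohort.csv", index=False)
    artifacts["cohort"] = out / "cohort.csv"

    rows = build_table1(cohort, config.quantile_convention)
    t1 = table1_to_frame(rows)
    t1.to_csv(out / "table1.csv", index=False)
    (out / "table1.md").write_text(t1.to_markdown(index=False) + "\n")
    artifacts["table1_csv"] = out / "table1.csv"
    artifacts["table1_md"] = out / "table1.md"

    summary, _ = tto_summary(
        cohort,
        config.selection,
        config.impute_mid_month,
        config.quantile_convention,
    )
    (out / "tto.json").write_text(json.dumps(summary.to_dict(), indent=2) + "\n")
    artifacts["tto"] = out / "tto.json"

    # disproportionality against the chosen reference corpus
    corpus = (
        dedup.deduplicate(reports).reports
        if config.reference == "corpus"
        else [e.record for e in cohort.entries]
    )
    soc_pts = config.selection.target_pts()
    results_by_drug = {}
    for drug in sorted(config.selection.index_drugs):
        ids = cohort.case_ids(drug)
        results_by_drug[drug] = dispro.detect_signals(
            corpus,
            drug,
            index_predicate=lambda r, _ids=ids: r.case_id in _ids,
            soc_filter=soc_pts,
            thresholds=config.thresholds,
            expectedness=config.expectedness,
            ic_variant=config.ic_variant,
        )
    t2 = dispro.results_to_frame(results_by_drug)
    t2.to_csv(out / "table2.csv", index=False)
    (out / "table2.md").write_text(t2.to_markdown(index=False) + "\n")
    artifacts["table2_csv"] = out / "table2.csv"
    artifacts["table2_md"] = out / "table2.md"

    log = {
        "faerspv_version": __version__,
        "seed": config.seed,
        "n_quarters": len(config.quarters),
        "n_reports_raw": n_raw,
        "n_reports_versions_resolved": len(reports),
        "flow": flow.as_dict(),
        "n_cases": len(cohort.cases()),
        "ic_variant": config.ic_variant,
        "reference": config.reference,
        "quantile_convention": config.quantile_convention,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2) + "\n")
    artifacts["run_log"] = out / "run_log.json"
    return artifacts
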