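"""Seeded generator of FAERS-format corpora with known ground truth.

Two generation modes:

* **Sampled** (default): each report draws one primary-suspect drug from a
  catalogue of marginal probabilities; each event PT is then included
  independently with probability ``p_event * lambda(drug, PT)`` truncated
  at 1, where lambda is the injected reporting-rate ratio (1 everywhere
  except the configured signals). Demographics, dates, missingness,
  cross-case duplicates, and superseded case versions are layered on top.
  A report whose event draw comes up empty receives the fallback PT (kept
  outside the sampled catalogue) so catalogue marginals stay exactly
  Bernoulli.

* **Forced-margin scenario** (``scenario_reference_margins``): a fully
  deterministic corpus whose selection-flow and descriptive margins equal
  a fixed reference table (counts forced, not sampled), for exact
  end-to-end pipeline checks.

All randomness flows from the single seed; identical configs produce
byte-identical fixture files.
"""
from __future__ import annotations

import datetime as dt
import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.stats import norm

from . import meddra
from .faers_io import write_fixture
from .records import (
    CONSUMER,
    FEMALE,
    HEALTHCARE_PROFESSIONAL,
    MALE,
    UNSPECIFIED,
    DrugEntry,
    PartialDate,
    ReportRecord,
)

logger = logging.getLogger("faerspv")


@dataclass
class SyntheticConfig:
    """Generative parameters for a FAERS-like spontaneous-report corpus."""

    seed: int = 0
    n_reports: int = 10_000
    #: substance -> marginal probability of being the primary suspect
    drugs: dict[str, float] = field(default_factory=dict)
    #: PT -> background inclusion probability per report
    events: dict[str, float] = field(default_factory=dict)
    #: (substance, PT) -> reporting-rate ratio lambda (>= 0)
    signals: dict[tuple[str, str], float] = field(default_factory=dict)
    #: substance -> {indication PT: probability}
    indications: dict[str, dict[str, float]] = field(default_factory=dict)
    gender_probs: dict[str, float] = field(
        default_factory=lambda: {MALE: 0.52, FEMALE: 0.43, UNSPECIFIED: 0.05}
    )
    reporter_probs: dict[str, float] = field(
        default_factory=lambda: {
            CONSUMER: 0.43,
            HEALTHCARE_PROFESSIONAL: 0.55,
            UNSPECIFIED: 0.02,
        }
    )
    country_probs: dict[str, float] = field(
        default_factory=lambda: {
            "US": 0.45, "JP": 0.18, "IT": 0.05, "FR": 0.05, "DE": 0.05,
            "CN": 0.05, "BR": 0.03, "GB": 0.04, "CA": 0.04, "AU": 0.02,
            "ZA": 0.01, "": 0.03,
        }
    )
    #: outcome code -> probability; "" = no outcome row (non-serious)
    outcome_probs: dict[str, float] = field(
        default_factory=lambda: {
            "DE": 0.20, "HO": 0.28, "LT": 0.02, "DS": 0.01, "RI": 0.001,
            "OT": 0.39, "": 0.099,
        }
    )
    age_mean: float = 63.0
    age_sd: float = 12.0
    weight_mean: float = 72.0
    weight_sd: float = 15.0
    #: per-field missingness rates
    missing_rates: dict[str, float] = field(
        default_factory=lambda: {
            "age": 0.15, "weight": 0.30, "event_date": 0.10,
            "gender": 0.0, "country": 0.05,
        }
    )
    ss_prob: float = 0.15
    duplicate_fraction: float = 0.0
    multi_version_fraction: float = 0.0
    window_start: dt.date = dt.date(2012, 10, 1)
    window_end: dt.date = dt.date(2022, 12, 31)
    #: substance -> median time-to-onset in days (log-normal)
    tto_median_days: dict[str, float] = field(default_factory=dict)
    tto_sigma: float = 1.0
    tto_default_median: float = 10.0
    fallback_pt: str = "Drug ineffective"
    scenario: str | None = None
    quarter: str = "2099Q1"

    def __post_init__(self) -> None:
        for name, probs in [
            ("gender", self.gender_probs),
            ("reporter", self.reporter_probs),
            ("country", self.country_probs),
            ("outcome", self.outcome_probs),
        ]:
            if probs and not math.isclose(sum(probs.values()), 1.0, abs_tol=1e-9):
                raise ValueError(f"{name} probabilities must sum to 1")
        for p in self.events.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("event probabilities must lie in [0, 1]")
        for lam in self.signals.values():
            if lam < 0:
                raise ValueError("reporting-rate ratio must be >= 0")
        if not 0.0 <= self.duplicate_fraction < 1.0:
            raise ValueError("duplicate_fraction must be in [0, 1)")
        if self.fallback_pt in self.events:
            raise ValueError("fallback PT must stay outside the event catalogue")


def default_config(**overrides) -> SyntheticConfig:
    """A realistic mCRC-flavoured corpus: the two index drugs plus common
    comparator chemotherapies, renal PTs at low background rates, and the
    frequent background ADRs of this population."""
    kwargs: dict = dict(
        drugs={
            "REGORAFENIB": 0.22,
            "ENCORAFENIB": 0.06,
            "CETUXIMAB": 0.12,
            "FLUOROURACIL": 0.15,
            "BEVACIZUMAB": 0.15,
            "OXALIPLATIN": 0.10,
            "IRINOTECAN": 0.10,
            "CAPECITABINE": 0.10,
        },
        events={
            # renal and urinary PTs (low background rates)
            "Acute kidney injury": 0.012,
            "Renal impairment": 0.008,
            "Renal failure": 0.008,
            "Chromaturia": 0.003,
            "Proteinuria": 0.005,
            "Urinary retention": 0.004,
            "Dysuria": 0.004,
            "Haematuria": 0.005,
            "Hydronephrosis": 0.002,
            "Nephrotic syndrome": 0.001,
            # background PTs
            "Nausea": 0.12,
            "Diarrhoea": 0.12,
            "Vomiting": 0.08,
            "Fatigue": 0.10,
            "Asthenia": 0.05,
            "Decreased appetite": 0.06,
            "Palmar-plantar erythrodysaesthesia syndrome": 0.05,
            "Rash": 0.06,
            "Hypertension": 0.05,
            "Pyrexia": 0.04,
            "Anaemia": 0.04,
            "Abdominal pain": 0.06,
            "Headache": 0.05,
            "Urinary tract infection": 0.02,
        },
        indications={
            "REGORAFENIB": {
                "Colorectal cancer metastatic": 0.60,
                "Hepatocellular carcinoma": 0.25,
                "Gastrointestinal stromal tumour": 0.15,
            },
            "ENCORAFENIB": {
                "Colorectal cancer metastatic": 0.45,
                "Malignant melanoma": 0.55,
            },
            "CETUXIMAB": {
                "Colorectal cancer metastatic": 0.70,
                "Squamous cell carcinoma of head and neck": 0.30,
            },
        },
        tto_median_days={"REGORAFENIB": 7.0, "ENCORAFENIB": 14.0},
    )
    kwargs.update(overrides)
    return SyntheticConfig(**kwargs)


@dataclass
class GroundTruth:
    """What the generator actually injected, for oracle-style checks."""

    duplicate_case_ids: tuple[str, ...] = ()
    superseded_case_ids: tuple[str, ...] = ()
    lambdas: dict[tuple[str, str], float] = field(default_factory=dict)
    case_status: dict[str, bool] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "duplicate_case_ids": list(self.duplicate_case_ids),
            "superseded_case_ids": list(self.superseded_case_ids),
            "lambdas": {f"{d}|{p}": v for (d, p), v in self.lambdas.items()},
            "case_status": self.case_status,
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return path


def _choice(rng: np.random.Generator, probs: dict[str, float], size: int) -> np.ndarray:
    keys = list(probs)
    p = np.array([probs[k] for k in keys], dtype=float)
    p = p / p.sum()
    idx = rng.choice(len(keys), size=size, p=p)
    return np.array(keys, dtype=object)[idx]


def generate_reports(
    config: SyntheticConfig,
) -> tuple[list[ReportRecord], GroundTruth]:
    """Generate an in-memory corpus and its ground truth."""
    if config.scenario == "reference_margins":
        return _reference_margin_reports()
    if config.scenario is not None:
        raise ValueError(f"unknown scenario {config.scenario!r}")
    if not config.drugs or not config.events:
        raise ValueError("drug and event catalogues must be non-empty")
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    drug_names = list(config.drugs)
    pt_names = list(config.events)
    p_drug = np.array([config.drugs[d] for d in drug_names], dtype=float)
    p_drug = p_drug / p_drug.sum()
    p_event = np.array([config.events[p] for p in pt_names], dtype=float)

    lam = np.ones((len(drug_names), len(pt_names)))
    for (drug, pt), value in config.signals.items():
        if drug in drug_names and pt in pt_names:
            lam[drug_names.index(drug), pt_names.index(pt)] = value
    probs = p_event[None, :] * lam
    if (probs > 1.0).any():
        logger.warning("event probability > 1 after lambda scaling; truncated")
        probs = np.clip(probs, 0.0, 1.0)

    drug_idx = rng.choice(len(drug_names), size=n, p=p_drug)
    event_matrix = rng.random((n, len(pt_names))) < probs[drug_idx]

    genders = _choice(rng, config.gender_probs, n)
    reporters = _choice(rng, config.reporter_probs, n)
    countries = _choice(rng, config.country_probs, n)
    outcomes = _choice(rng, config.outcome_probs, n)
    ages = np.clip(rng.normal(config.age_mean, config.age_sd, n), 18.0, 95.0).round(1)
    weights = np.clip(
        rng.normal(config.weight_mean, config.weight_sd, n), 35.0, 150.0
    ).round(1)

    span = (config.window_end - config.window_start).days + 1
    receipt_offsets = rng.integers(0, span, size=n)
    event_lags = rng.integers(0, 90, size=n)
    medians = np.array(
        [
            config.tto_median_days.get(d, config.tto_default_median)
            for d in drug_names
        ]
    )
    ttos = np.round(
        np.exp(
            np.log(medians[drug_idx]) + config.tto_sigma * rng.standard_normal(n)
        )
    ).astype(int)

    miss = {
        f: rng.random(n) < rate for f, rate in config.missing_rates.items()
    }
    ss_mask = rng.random(n) < config.ss_prob
    ss_idx = rng.integers(0, len(drug_names), size=n)

    indication_draws: dict[str, np.ndarray] = {}
    for d, ind_probs in config.indications.items():
        indication_draws[d] = _choice(rng, ind_probs, n)

    reports: list[ReportRecord] = []
    event_lists = event_matrix.tolist()
    for i in range(n):
        drug = drug_names[drug_idx[i]]
        receipt = config.window_start + dt.timedelta(days=int(receipt_offsets[i]))
        event_day = receipt - dt.timedelta(days=int(event_lags[i]))
        start_day = event_day - dt.timedelta(days=int(ttos[i]))
        pts = frozenset(
            pt for pt, flag in zip(pt_names, event_lists[i]) if flag
        ) or frozenset({config.fallback_pt})
        indication = (
            frozenset({str(indication_draws[drug][i])})
            if drug in indication_draws
            else frozenset({"Colorectal cancer metastatic"})
        )
        drugs = [
            DrugEntry(
                active_substance=drug,
                role="PS",
                indication_pts=indication,
                therapy_start=PartialDate.from_date(start_day),
            )
        ]
        if ss_mask[i] and drug_names[ss_idx[i]] != drug:
            drugs.append(
                DrugEntry(active_substance=drug_names[ss_idx[i]], role="SS")
            )
        outcome = str(outcomes[i])
        reports.append(
            ReportRecord(
                case_id=str(10_000_000 + i),
                case_version=1,
                fda_receipt_date=PartialDate.from_date(receipt),
                event_date=None
                if miss.get("event_date", np.zeros(n, bool))[i]
                else PartialDate.from_date(event_day),
                gender=UNSPECIFIED
                if miss.get("gender", np.zeros(n, bool))[i]
                else str(genders[i]),
                age_years=None if miss["age"][i] else float(ages[i]),
                weight_kg=None if miss["weight"][i] else float(weights[i]),
                reporter_country=""
                if miss.get("country", np.zeros(n, bool))[i]
                else str(countries[i]),
                reporter_qualification=str(reporters[i]),
                drugs=tuple(drugs),
                reaction_pts=pts,
                outcome_codes=frozenset({outcome}) if outcome else frozenset(),
            )
        )

    truth = GroundTruth(
        lambdas={k: v for k, v in config.signals.items()},
    )

    # superseded versions: the selected cases become version 2 and an
    # earlier version-1 record is added under the same case id
    superseded: list[str] = []
    extras: list[ReportRecord] = []
    if config.multi_version_fraction > 0:
        k = int(round(config.multi_version_fraction * n))
        for i in map(int, rng.choice(n, size=k, replace=False)):
            base = reports[i]
            reports[i] = replace(base, case_version=2)
            old_receipt = base.fda_receipt_date.to_date() - dt.timedelta(days=30)
            extras.append(
                replace(
                    base,
                    case_version=1,
                    fda_receipt_date=PartialDate.from_date(old_receipt),
                )
            )
            superseded.append(base.case_id)
    reports.extend(extras)

    # cross-case duplicates: exact clones of complete-key reports under new,
    # numerically larger case ids (so dedup keeps the original)
    clones: list[ReportRecord] = []
    if config.duplicate_fraction > 0:
        from .dedup import dedup_key

        eligible = [r for r in reports if dedup_key(r) is not None]
        k = int(round(config.duplicate_fraction * n))
        if len(eligible) < k:
            raise ValueError("not enough complete-key reports to clone")
        chosen = rng.choice(len(eligible), size=k, replace=False)
        for j, src_i in enumerate(map(int, chosen)):
            clones.append(
                replace(eligible[src_i], case_id=str(90_000_000 + j))
            )
    reports.extend(clones)
    truth = replace(
        truth,
        duplicate_case_ids=tuple(c.case_id for c in clones),
        superseded_case_ids=tuple(superseded),
    )
    renal = frozenset(
        pt for pt, soc in meddra.PT_TO_SOC.items() if soc == meddra.RENAL_SOC
    )
    truth.case_status.update(
        {r.case_id: bool(r.reaction_pts & renal) for r in reports}
    )
    return reports, truth


def generate(
    config: SyntheticConfig, out_dir: str | Path
) -> tuple[Path, GroundTruth]:
    """Generate a corpus, write it as one FAERS-format quarter plus a
    ground-truth JSON, and return (quarter path, ground truth)."""
    reports, truth = generate_reports(config)
    out_dir = Path(out_dir)
    quarter_path = write_fixture(reports, out_dir, quarter=config.quarter)
    truth.to_json(out_dir / "ground_truth.json")
    return quarter_path, truth


# ---------------------------------------------------------------------------
# Forced-margin scenario
# ---------------------------------------------------------------------------

# Selection-flow margins the scenario reproduces exactly.
_FLOW = dict(
    total=14_323,
    literature=524,
    other_indication=7_768,
    other_ps=1_022,
    duplicates=25,
    included=4_984,
)
_N_REG, _N_ENC = 4_496, 488
_N_REG_CASES, _N_ENC_CASES = 353, 26
_N_ENC_WITH_CET = 150

# Per-PT case counts per index drug (report-level).
_CASE_PTS_REG: tuple[tuple[str, int], ...] = (
    ("Renal impairment", 53), ("Acute kidney injury", 43), ("Chromaturia", 44),
    ("Renal failure", 38), ("Proteinuria", 29), ("Urinary retention", 27),
    ("Haematuria", 22), ("Dysuria", 19), ("Renal disorder", 19),
    ("Urinary incontinence", 13), ("Hydronephrosis", 10), ("Pollakiuria", 8),
    ("Nephrotic syndrome", 7), ("Anuria", 6), ("Nocturia", 6),
    ("Renal pain", 6), ("Nephrolithiasis", 6), ("Oliguria", 5),
    ("Urinary tract obstruction", 5), ("Haemorrhage urinary tract", 4),
    ("Micturition urgency", 4), ("Prerenal failure", 4),
    ("Urine odour abnormal", 4), ("Bladder disorder", 3),
    ("Chronic kidney disease", 3), ("Micturition disorder", 3),
)
_CASE_PTS_ENC: tuple[tuple[str, int], ...] = (
    ("Acute kidney injury", 11), ("Dysuria", 4), ("Renal impairment", 3),
    ("Renal failure", 2), ("Pollakiuria", 2), ("Renal pain", 2),
    ("Renal disorder", 1), ("Hydronephrosis", 1), ("Nephrolithiasis", 1),
)

# Descriptive margins: (cases column, others column).
_GENDER = {"cases": (230, 141, 8), "others": (2384, 1991, 230)}  # M, F, unspecified
_REPORTER = {"cases": (184, 194, 1), "others": (1941, 2617, 47)}  # CN, HCP, unspec.
_COUNTRY_CODES = ("ZA", "JP", "IT", "US", "AU", "BR", "")
_COUNTRY = {"cases": (1, 98, 75, 177, 4, 12, 12),
            "others": (34, 1063, 783, 2199, 49, 141, 336)}
_OUTCOME_CODES = ("DE", "DS", "HO", "LT", "", "OT", "RI")
_OUTCOME = {"cases": (78, 5, 150, 15, 9, 122, 0),
            "others": (970, 53, 1273, 96, 483, 1727, 3)}
_AGE_GROUPS = ((18, 29), (30, 49), (50, 64), (65, 75), (76, 85), (86, 95), None)
_AGES = {"cases": (0, 40, 130, 125, 42, 3, 39),
         "others": (26, 399, 1565, 1283, 487, 60, 785)}
_YEARS = tuple(range(2012, 2023))
_YEAR_COUNTS = {"cases": (6, 40, 33, 47, 41, 38, 50, 34, 25, 34, 31),
                "others": (75, 619, 477, 491, 316, 437, 416, 366, 458, 515, 435)}

_CRC = frozenset({"Colorectal cancer metastatic"})
_NONCASE_PT_CYCLE = (
    "Nausea", "Fatigue", "Diarrhoea",
    "Palmar-plantar erythrodysaesthesia syndrome", "Decreased appetite",
    "Hypertension",
)


def scenario_reference_margins() -> SyntheticConfig:
    """Config for the deterministic forced-margin corpus (14,323 reports
    mentioning the index drugs, 4,984 included, 379 renal cases)."""
    return SyntheticConfig(scenario="reference_margins", n_reports=_FLOW["total"])


def _expand(counts, values):
    out = []
    for v, c in zip(values, counts):
        out.extend([v] * c)
    return out


def _expand_ages(counts):
    out: list[float | None] = []
    for group, c in zip(_AGE_GROUPS, counts):
        if group is None:
            out.extend([None] * c)
        else:
            lo, hi = group
            out.extend([float(lo + (k % (hi - lo + 1))) for k in range(c)])
    return out


def _assign_pt_sets(pair_counts, n_reports: int) -> list[frozenset[str]]:
    slots = [pt for pt, c in pair_counts for _ in range(c)]
    sets: list[set[str]] = [set() for _ in range(n_reports)]
    for k, pt in enumerate(slots):
        sets[k % n_reports].add(pt)
    if sum(len(s) for s in sets) != len(slots):  # a report got the same PT twice
        raise AssertionError("PT slot assignment collision")
    return [frozenset(s) for s in sets]


def _receipt_date(year: int, counter: int) -> dt.date:
    start = dt.date(year, 10, 1) if year == 2012 else dt.date(year, 1, 1)
    span = (dt.date(year, 12, 31) - start).days + 1
    return start + dt.timedelta(days=counter % span)


def _tto_quantiles(n: int, median: float, sigma: float) -> list[int]:
    qs = (np.arange(n) + 0.5) / n
    vals = np.round(np.exp(np.log(median) + sigma * norm.ppf(qs)))
    return [int(max(v, 0)) for v in vals]


def _reference_margin_reports() -> tuple[list[ReportRecord], GroundTruth]:
    reports: list[ReportRecord] = []

    # --- included reports: REG cases, ENC cases, REG non-cases, ENC non-cases
    case_pts = _assign_pt_sets(_CASE_PTS_REG, _N_REG_CASES) + _assign_pt_sets(
        _CASE_PTS_ENC, _N_ENC_CASES
    )
    case_tto = _tto_quantiles(_N_REG_CASES, 7.0, 1.6) + _tto_quantiles(
        _N_ENC_CASES, 14.0, 1.3
    )
    n_cases = _N_REG_CASES + _N_ENC_CASES
    n_others = _FLOW["included"] - n_cases

    attrs = {}
    for group, n_grp in (("cases", n_cases), ("others", n_others)):
        attrs[group] = {
            "gender": _expand(_GENDER[group], (MALE, FEMALE, UNSPECIFIED)),
            "reporter": _expand(
                _REPORTER[group], (CONSUMER, HEALTHCARE_PROFESSIONAL, UNSPECIFIED)
            ),
            "country": _expand(_COUNTRY[group], _COUNTRY_CODES),
            "outcome": _expand(_OUTCOME[group], _OUTCOME_CODES),
            "age": _expand_ages(_AGES[group]),
            "year": _expand(_YEAR_COUNTS[group], _YEARS),
        }
        for name, values in attrs[group].items():
            if len(values) != n_grp:
                raise AssertionError(f"{group}/{name} margin does not sum")

    def _index_entry(substance: str, start: dt.date | None) -> DrugEntry:
        return DrugEntry(
            active_substance=substance,
            role="PS",
            indication_pts=_CRC,
            therapy_start=None if start is None else PartialDate.from_date(start),
        )

    next_id = 1_000_000
    included_case_ids: list[str] = []
    clone_sources: list[ReportRecord] = []
    for pos in range(_FLOW["included"]):
        is_case = pos < n_cases
        group = "cases" if is_case else "others"
        g_idx = pos if is_case else pos - n_cases
        a = attrs[group]
        if is_case:
            drug = "REGORAFENIB" if pos < _N_REG_CASES else "ENCORAFENIB"
        else:
            drug = "REGORAFENIB" if g_idx < _N_REG - _N_REG_CASES else "ENCORAFENIB"
        receipt = _receipt_date(a["year"][g_idx], g_idx)
        event = receipt - dt.timedelta(days=20 if is_case else 15)
        if is_case:
            start = event - dt.timedelta(days=case_tto[g_idx])
            pts = case_pts[g_idx]
        else:
            start = None
            pts = frozenset({_NONCASE_PT_CYCLE[g_idx % len(_NONCASE_PT_CYCLE)]})
        drugs = [_index_entry(drug, start)]
        if (
            drug == "ENCORAFENIB"
            and not is_case
            and g_idx - (_N_REG - _N_REG_CASES) < _N_ENC_WITH_CET
        ):
            drugs.append(DrugEntry(active_substance="CETUXIMAB", role="SS"))
        outcome = a["outcome"][g_idx]
        # only the duplicate-clone sources carry a body weight, so the
        # missing-never-matches rule confines dedup clusters to the clones
        weight = None
        if not is_case and g_idx < _FLOW["duplicates"]:
            weight = 60.0 + g_idx
        rec = ReportRecord(
            case_id=str(next_id),
            case_version=1,
            fda_receipt_date=PartialDate.from_date(receipt),
            event_date=PartialDate.from_date(event),
            gender=a["gender"][g_idx],
            age_years=a["age"][g_idx],
            weight_kg=weight,
            reporter_country=a["country"][g_idx],
            reporter_qualification=a["reporter"][g_idx],
            drugs=tuple(drugs),
            reaction_pts=pts,
            outcome_codes=frozenset({outcome}) if outcome else frozenset(),
        )
        if weight is not None:
            clone_sources.append(rec)
        reports.append(rec)
        included_case_ids.append(rec.case_id)
        next_id += 1

    # --- excluded buckets -------------------------------------------------
    next_id = 2_000_000
    for i in range(_FLOW["literature"]):
        reports.append(
            ReportRecord(
                case_id=str(next_id + i),
                case_version=1,
                fda_receipt_date=PartialDate.from_date(
                    _receipt_date(_YEARS[i % len(_YEARS)], i)
                ),
                event_date=PartialDate(2012, 6, 15),
                gender=MALE,
                reporter_country="US",
                reporter_qualification=HEALTHCARE_PROFESSIONAL,
                report_sources=frozenset({"LIT"}),
                drugs=(_index_entry("REGORAFENIB", None),),
                reaction_pts=frozenset({"Fatigue"}),
            )
        )
    next_id = 3_000_000
    for i in range(_FLOW["other_indication"]):
        if i < 7_000:
            entry = DrugEntry(
                active_substance="REGORAFENIB",
                role="PS",
                indication_pts=frozenset({"Hepatocellular carcinoma"}),
            )
        else:
            entry = DrugEntry(
                active_substance="ENCORAFENIB",
                role="PS",
                indication_pts=frozenset({"Malignant melanoma"}),
            )
        reports.append(
            ReportRecord(
                case_id=str(next_id + i),
                case_version=1,
                fda_receipt_date=PartialDate.from_date(
                    _receipt_date(_YEARS[i % len(_YEARS)], i)
                ),
                gender=FEMALE,
                reporter_country="US",
                reporter_qualification=CONSUMER,
                drugs=(entry,),
                reaction_pts=frozenset({"Nausea"}),
            )
        )
    next_id = 4_000_000
    for i in range(_FLOW["other_ps"]):
        ss = "REGORAFENIB" if i < 700 else "ENCORAFENIB"
        reports.append(
            ReportRecord(
                case_id=str(next_id + i),
                case_version=1,
                fda_receipt_date=PartialDate.from_date(
                    _receipt_date(_YEARS[i % len(_YEARS)], i)
                ),
                gender=MALE,
                reporter_country="US",
                reporter_qualification=HEALTHCARE_PROFESSIONAL,
                drugs=(
                    DrugEntry(
                        active_substance="CETUXIMAB",
                        role="PS",
                        indication_pts=_CRC,
                    ),
                    DrugEntry(active_substance=ss, role="SS"),
                ),
                reaction_pts=frozenset({"Rash"}),
            )
        )

    # --- cross-case duplicate clones of the weighted sources --------------
    clone_ids = []
    for j, src in enumerate(clone_sources):
        cid = str(9_000_000 + j)
        reports.append(replace(src, case_id=cid))
        clone_ids.append(cid)
    if len(clone_ids) != _FLOW["duplicates"]:
        raise AssertionError("clone count does not match forced margin")
    if len(reports) != _FLOW["total"]:
        raise AssertionError("scenario total does not match forced margin")

    renal = frozenset(
        pt for pt, soc in meddra.PT_TO_SOC.items() if soc == meddra.RENAL_SOC
    )
    truth = GroundTruth(
        duplicate_case_ids=tuple(clone_ids),
        case_status={r.case_id: bool(r.reaction_pts & renal) for r in reports},
    )
    return reports, truth
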