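"""Descriptive comparison of cases versus other reports.

Implements the statistics behind the Table-1-style summary: Pearson's
chi-square on 2x2 tables with Yates' continuity correction for categorical
strata, the Mann-Whitney U test for continuous variables (age, time to
onset), and median/IQR summaries under a selectable quantile convention.

All p-values are two-sided; the significance threshold used downstream is
0.05 with no multiplicity adjustment (switchable via
:func:`adjust_p_values`).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import meddra
from .cohort import CohortTable, SelectionConfig
from .records import (
    CONSUMER,
    FEMALE,
    HEALTHCARE_PROFESSIONAL,
    MALE,
    UNSPECIFIED,
    ReportRecord,
)

logger = logging.getLogger("faerspv")

#: numpy quantile method per convention; "type6" is the SPSS-style
#: HAVERAGE definition, "type7" linear interpolation of order statistics.
_QUANTILE_METHODS = {"type6": "weibull", "type7": "linear"}


@dataclass(frozen=True)
class TwoByTwo:
    """2x2 contingency table; rows = groups, columns = attribute yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")
        if self.N == 0:
            raise ValueError("empty table")

    @property
    def N(self) -> int:
        return self.a + self.b + self.c + self.d


def yates_chi_square(t: TwoByTwo) -> tuple[float, float | None]:
    """Pearson chi-square with Yates' continuity correction, 1 df.

    statistic = N * (max(|ad - bc| - N/2, 0))^2
                / ((a+b)(c+d)(a+c)(b+d))

    Returns (statistic, upper-tail p). A zero margin makes the statistic
    undefined; the p-value is then returned as None with a warning.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    margins = ((a + b), (c + d), (a + c), (b + d))
    if 0 in margins:
        logger.warning("zero margin in 2x2 table; chi-square undefined")
        return math.nan, None
    num = max(abs(a * d - b * c) - t.N / 2.0, 0.0) ** 2
    statistic = t.N * num / math.prod(margins)
    return statistic, float(stats.chi2.sf(statistic, df=1))


def _mw_u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    ranks = stats.rankdata(np.concatenate([x, y]))
    nx = len(x)
    return float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)


def _mw_exact_enumeration(pooled: np.ndarray, nx: int, u_obs: float) -> float:
    """Two-sided exact p by symmetric-tail enumeration on midranks."""
    ranks = stats.rankdata(pooled)
    n = len(pooled)
    mu = nx * (n - nx) / 2.0
    dev = abs(u_obs - mu) - 1e-12
    hits = 0
    total = 0
    base = nx * (nx + 1) / 2.0
    for idx in combinations(range(n), nx):
        u = ranks[list(idx)].sum() - base
        total += 1
        if abs(u - mu) >= dev:
            hits += 1
    return hits / total


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    exact_limit: int = 400,
    enumeration_limit: int = 200_000,
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U for x, p).

    Method selection: with ``n_x * n_y <= exact_limit`` the exact null
    distribution is used — by direct enumeration over rank assignments
    (handles ties via midranks) when C(n, n_x) <= ``enumeration_limit``,
    otherwise by the no-ties exact distribution. Larger samples use the
    normal approximation with tie-corrected variance and no continuity
    correction (matching common statistical packages' asymptotic output).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    u = _mw_u_statistic(x, y)
    pooled = np.concatenate([x, y])
    nx, ny = len(x), len(y)
    n = nx + ny
    if np.all(pooled == pooled[0]):
        return u, 1.0
    has_ties = len(np.unique(pooled)) < n
    if nx * ny <= exact_limit:
        if math.comb(n, nx) <= enumeration_limit:
            return u, _mw_exact_enumeration(pooled, nx, u)
        if not has_ties:
            _, p = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            return u, float(p)
        # ties and too many combinations: fall through to the approximation
    mu = nx * ny / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (n * (n - 1))
    sigma2 = nx * ny / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return u, 1.0
    z = (u - mu) / math.sqrt(sigma2)
    return u, float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def median_iqr(
    values: Sequence[float], convention: str = "type7"
) -> tuple[float, float, float]:
    """(median, Q1, Q3) under the given quantile convention."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty sample")
    method = _QUANTILE_METHODS[convention]
    q1, med, q3 = (float(np.quantile(v, q, method=method)) for q in (0.25, 0.5, 0.75))
    return med, q1, q3


def compute_tto(
    report: ReportRecord,
    index_substances: Iterable[str],
    impute_mid_month: bool = False,
) -> int | None:
    """Time to onset: days from the earliest index-drug therapy start to
    the event date.

    Both dates must be day-precise by default; with ``impute_mid_month``
    month-precision dates are imputed to the 15th. Negative values are
    implausible (event before start) and return None with a log entry.
    """
    subs = set(index_substances)

    def _resolve(d):
        if d is None:
            return None
        if d.precision == "day":
            return d.to_date()
        if d.precision == "month" and impute_mid_month:
            import datetime as _dt

            return _dt.date(d.year, d.month, 15)
        return None

    starts = [
        _resolve(d.therapy_start)
        for d in report.drugs
        if d.active_substance in subs and d.therapy_start is not None
    ]
    starts = [s for s in starts if s is not None]
    event = _resolve(report.event_date)
    if not starts or event is None:
        return None
    days = (event - min(starts)).days
    if days < 0:
        logger.warning(
            "report %s: event precedes therapy start (%d d); TTO dropped",
            report.case_id,
            days,
        )
        return None
    return days


# ---------------------------------------------------------------------------
# Table-1 style descriptive rows
# ---------------------------------------------------------------------------


@dataclass
class DescriptiveRow:
    section: str
    label: str
    count_cases: int | None
    pct_cases: float | None
    count_others: int | None
    pct_others: float | None
    p_value: float | None
    test_used: str  # chi2_yates | mann_whitney | none
    display_cases: str = ""
    display_others: str = ""


def _pct(n: int, total: int) -> float | None:
    return round(100.0 * n / total, 1) if total else None


def _age_group(age: float | None) -> str:
    if age is None:
        return "Missing"
    a = math.floor(age)
    if a < 18:
        return "Under 18"
    if a <= 29:
        return "18-29 years"
    if a <= 49:
        return "30-49 years"
    if a <= 64:
        return "50-64 years"
    if a <= 75:
        return "65-75 years"
    if a <= 85:
        return "76-85 years"
    return ">85 years"


def _outcome_category(r: ReportRecord) -> str:
    """Single outcome category per report, by severity priority."""
    for code, label in (
        ("DE", "Died"),
        ("LT", "Life threatening"),
        ("HO", "Hospitalized"),
        ("DS", "Disabled"),
        ("CA", "Congenital anomaly"),
        ("RI", "Required intervention"),
        ("OT", "Other outcomes"),
    ):
        if code in r.outcome_codes:
            return label
    return "Non-serious"


def _strata_rows(
    section: str,
    labels: Sequence[str],
    case_values: Sequence[str],
    other_values: Sequence[str],
    n_cases: int,
    n_others: int,
    tested: dict[str, tuple[int, int, int, int]] | None = None,
) -> list[DescriptiveRow]:
    """Count each stratum in both groups; optionally attach chi-square p.

    ``tested`` maps a label to an explicit 2x2 (a, b, c, d); labels absent
    from it get a default stratum-vs-rest table over all counted values.
    """
    rows = []
    cc = pd.Series(case_values).value_counts()
    oc = pd.Series(other_values).value_counts()
    for label in labels:
        a = int(cc.get(label, 0))
        c = int(oc.get(label, 0))
        if tested is not None and label in tested:
            tbl = tested[label]
        elif tested is not None:
            tbl = None
        else:
            tbl = (a, len(case_values) - a, c, len(other_values) - c)
        p = None
        test = "none"
        if tbl is not None:
            try:
                _, p = yates_chi_square(TwoByTwo(*tbl))
                test = "chi2_yates"
            except ValueError:
                p = None
        rows.append(
            DescriptiveRow(
                section=section,
                label=label,
                count_cases=a,
                pct_cases=_pct(a, n_cases),
                count_others=c,
                pct_others=_pct(c, n_others),
                p_value=None if p is None else round(p, 3),
                test_used=test if p is not None else "none",
            )
        )
    return rows


def build_table1(
    cohort: CohortTable, quantile_convention: str = "type7"
) -> list[DescriptiveRow]:
    """Descriptive rows comparing cases to all other included reports.

    Comparison conventions: the gender test is male vs female (reports
    with unspecified gender excluded); the age-group test is adult (18-64)
    vs elderly (>=65) among known ages; country rows are tested stratum vs
    rest excluding unspecified; outcome rows use one category per report
    (highest-severity outcome code); median age uses the Mann-Whitney U
    test on known ages.
    """
    cases = [e.record for e in cohort.cases()]
    others = [e.record for e in cohort.non_cases()]
    n_cases, n_others = len(cases), len(others)
    rows: list[DescriptiveRow] = []

    # Gender -- male vs female 2x2
    g_case = [r.gender for r in cases]
    g_other = [r.gender for r in others]
    gm, gf = g_case.count(MALE), g_case.count(FEMALE)
    om, of = g_other.count(MALE), g_other.count(FEMALE)
    gender_tbl = {"Male": (gm, gf, om, of)}
    rows += _strata_rows(
        "Gender",
        ["Male", "Female", "Not specified"],
        ["Male" if g == MALE else "Female" if g == FEMALE else "Not specified" for g in g_case],
        ["Male" if g == MALE else "Female" if g == FEMALE else "Not specified" for g in g_other],
        n_cases,
        n_others,
        tested=gender_tbl,
    )

    # Median age (Mann-Whitney on known ages)
    ages_c = [r.age_years for r in cases if r.age_years is not None]
    ages_o = [r.age_years for r in others if r.age_years is not None]
    if ages_c and ages_o:
        med_c = median_iqr(ages_c, quantile_convention)
        med_o = median_iqr(ages_o, quantile_convention)
        _, p_age = mann_whitney_u(ages_c, ages_o)
        rows.append(
            DescriptiveRow(
                section="Age",
                label="Median age (Q1-Q3), years",
                count_cases=None,
                pct_cases=None,
                count_others=None,
                pct_others=None,
                p_value=round(p_age, 3),
                test_used="mann_whitney",
                display_cases=f"{med_c[0]:g} ({med_c[1]:g}-{med_c[2]:g})",
                display_others=f"{med_o[0]:g} ({med_o[1]:g}-{med_o[2]:g})",
            )
        )

    # Age groups; Adult row tested adult-vs-elderly among known ages
    def _is_adult(a):
        return a is not None and 18 <= math.floor(a) <= 64

    def _is_elderly(a):
        return a is not None and math.floor(a) >= 65

    ad_c = sum(1 for r in cases if _is_adult(r.age_years))
    el_c = sum(1 for r in cases if _is_elderly(r.age_years))
    ad_o = sum(1 for r in others if _is_adult(r.age_years))
    el_o = sum(1 for r in others if _is_elderly(r.age_years))
    adult_rows = _strata_rows(
        "Age group",
        ["Adult", "Elderly"],
        ["Adult" if _is_adult(r.age_years) else "Elderly" if _is_elderly(r.age_years) else "other" for r in cases],
        ["Adult" if _is_adult(r.age_years) else "Elderly" if _is_elderly(r.age_years) else "other" for r in others],
        n_cases,
        n_others,
        tested={"Adult": (ad_c, el_c, ad_o, el_o)},
    )
    rows += adult_rows
    rows += _strata_rows(
        "Age group",
        ["18-29 years", "30-49 years", "50-64 years", "65-75 years",
         "76-85 years", ">85 years", "Missing"],
        [_age_group(r.age_years) for r in cases],
        [_age_group(r.age_years) for r in others],
        n_cases,
        n_others,
        tested={},
    )

    # Reporter type -- consumer vs healthcare professional
    def _rep(r: ReportRecord) -> str:
        if r.reporter_qualification == CONSUMER:
            return "Consumer"
        if r.reporter_qualification == HEALTHCARE_PROFESSIONAL:
            return "Healthcare professional"
        return "Not specified"

    rc, ro = [_rep(r) for r in cases], [_rep(r) for r in others]
    rows += _strata_rows(
        "Reporter type",
        ["Consumer", "Healthcare professional", "Not specified"],
        rc,
        ro,
        n_cases,
        n_others,
        tested={
            "Consumer": (
                rc.count("Consumer"),
                rc.count("Healthcare professional"),
                ro.count("Consumer"),
                ro.count("Healthcare professional"),
            )
        },
    )

    # Reporter country by continent; stratum vs rest among specified
    cc = [meddra.continent_of(r.reporter_country) for r in cases]
    co = [meddra.continent_of(r.reporter_country) for r in others]
    continents = ["Africa", "Asia", "Europe", "North America", "Oceania", "South America"]
    known_c = sum(1 for v in cc if v != "Not specified")
    known_o = sum(1 for v in co if v != "Not specified")
    cont_tested = {
        cont: (cc.count(cont), known_c - cc.count(cont), co.count(cont), known_o - co.count(cont))
        for cont in continents
    }
    rows += _strata_rows(
        "Reporter country",
        continents + ["Not specified"],
        cc,
        co,
        n_cases,
        n_others,
        tested=cont_tested,
    )

    # Seriousness
    sc = sum(1 for r in cases if r.serious)
    so = sum(1 for r in others if r.serious)
    rows += _strata_rows(
        "Seriousness",
        ["Serious"],
        ["Serious" if r.serious else "Non-serious" for r in cases],
        ["Serious" if r.serious else "Non-serious" for r in others],
        n_cases,
        n_others,
        tested={"Serious": (sc, n_cases - sc, so, n_others - so)},
    )

    # Outcomes (single category per report)
    oc_c = [_outcome_category(r) for r in cases]
    oc_o = [_outcome_category(r) for r in others]
    outcome_labels = [
        "Died", "Disabled", "Hospitalized", "Life threatening",
        "Non-serious", "Other outcomes", "Required intervention",
    ]
    rows += _strata_rows("Outcome", outcome_labels, oc_c, oc_o, n_cases, n_others)

    # Year of reporting
    yr_c = [str(r.fda_receipt_date.year) for r in cases]
    yr_o = [str(r.fda_receipt_date.year) for r in others]
    years = sorted(set(yr_c) | set(yr_o))
    rows += _strata_rows("Year of reporting", years, yr_c, yr_o, n_cases, n_others)

    # Primary suspect drug
    d_c = [e.index_drug for e in cohort.cases()]
    d_o = [e.index_drug for e in cohort.non_cases()]
    drugs = sorted(set(d_c) | set(d_o))
    rows += _strata_rows("Primary suspect", drugs, d_c, d_o, n_cases, n_others)
    return rows


def table1_to_frame(rows: list[DescriptiveRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "section": [r.section for r in rows],
            "label": [r.label for r in rows],
            "cases_n": [r.count_cases for r in rows],
            "cases_pct": [r.pct_cases for r in rows],
            "others_n": [r.count_others for r in rows],
            "others_pct": [r.pct_others for r in rows],
            "cases_display": [r.display_cases for r in rows],
            "others_display": [r.display_others for r in rows],
            "p_value": [r.p_value for r in rows],
            "test": [r.test_used for r in rows],
        }
    )


def adjust_p_values(p_values: Sequence[float], method: str = "none") -> list[float]:
    """Optional multiplicity adjustment (off by default, matching the
    primary analysis). ``method``: none | bonferroni | fdr_bh."""
    p = np.asarray(p_values, dtype=float)
    if method == "none":
        return p.tolist()
    m = len(p)
    if method == "bonferroni":
        return np.minimum(p * m, 1.0).tolist()
    if method == "fdr_bh":
        order = np.argsort(p)
        ranked = p[order] * m / (np.arange(m) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(adj, 1.0)
        return out.tolist()
    raise ValueError(f"unknown adjustment {method!r}")


# ---------------------------------------------------------------------------
# Time to onset
# ---------------------------------------------------------------------------


@dataclass
class TTOSummary:
    """Per-drug time-to-onset summary with the between-drug comparison."""

    per_drug: dict[str, dict[str, float]]
    between_p: float | None
    convention: str

    def to_dict(self) -> dict:
        return {
            "per_drug": self.per_drug,
            "between_p": self.between_p,
            "quantile_convention": self.convention,
        }


def tto_summary(
    cohort: CohortTable,
    config: SelectionConfig,
    impute_mid_month: bool = False,
    quantile_convention: str = "type7",
) -> tuple[TTOSummary, dict[str, list[int]]]:
    """Median (Q1-Q3) TTO per index drug among cases, with the Mann-Whitney
    comparison across the two drugs. Also returns the raw day values and
    box-plot geometry (whiskers at the most extreme values within 1.5 IQR).
    """
    samples: dict[str, list[int]] = {}
    for e in cohort.cases():
        tto = compute_tto(
            e.record, config.index_drugs[e.index_drug], impute_mid_month
        )
        if tto is not None:
            samples.setdefault(e.index_drug, []).append(tto)
    per_drug = {}
    for drug, vals in sorted(samples.items()):
        med, q1, q3 = median_iqr(vals, quantile_convention)
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = [v for v in vals if lo_fence <= v <= hi_fence]
        per_drug[drug] = {
            "n": len(vals),
            "median": med,
            "q1": q1,
            "q3": q3,
            "whisker_low": float(min(inside)) if inside else q1,
            "whisker_high": float(max(inside)) if inside else q3,
        }
    drugs = sorted(samples)
    p = None
    if len(drugs) == 2 and all(samples[d] for d in drugs):
        _, p = mann_whitney_u(samples[drugs[0]], samples[drugs[1]])
        p = round(p, 3)
    return TTOSummary(per_drug=per_drug, between_p=p, convention=quantile_convention), samples
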