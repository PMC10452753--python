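"""Case/non-case disproportionality: ROR and information component.

For each (index drug, event PT) pair a 2x2 report-level table is formed:

    a = index-drug reports with the PT     b = other reports with the PT
    c = index-drug reports without it      d = other reports without it

The reporting odds ratio is ROR = ad / bc with the Woolf (log-normal)
95% confidence interval exp(ln ROR +/- z * sqrt(1/a + 1/b + 1/c + 1/d)).
The Bayesian information component is IC = log2 of observed over expected
with a half-unit shrinkage, IC = log2((a + 0.5) / (E + 0.5)) where
E = n_drug * n_event / N, and a 95% credibility interval IC +/- 2/sqrt(a);
an unshrunk variant and Noren's asymptotic credibility bounds are
available by flag.

A pair is flagged as a signal when it has at least ``min_n`` reports and
the lower ROR confidence limit exceeds 1; the IC lower bound above 0 is
reported alongside as the Bayesian corroboration. No multiplicity
correction is applied to signal flags — the n >= 3 minimum and the IC
criterion are the built-in mitigations.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import meddra
from .records import ReportRecord

IC_VARIANTS = ("shrunk", "plain", "noren")


@dataclass(frozen=True)
class ContingencyTable:
    """Report-level 2x2 for one (index group, event) pair."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")

    @property
    def N(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_drug(self) -> int:
        return self.a + self.c

    @property
    def n_event(self) -> int:
        return self.a + self.b


@dataclass(frozen=True)
class SignalThresholds:
    min_n: int = 3
    z: float = 1.96
    ic_halfwidth_constant: float = 2.0


@dataclass
class DisproportionalityResult:
    drug: str
    pt: str
    n: int  # = a, reports of the pair
    ror: float
    ror_low: float
    ror_high: float
    ic: float
    ic_low: float
    ic_high: float
    is_signal: bool
    expected: bool | None = None  # None = unknown (drug not in label list)

    @property
    def ror_defined(self) -> bool:
        return not math.isnan(self.ror)


def build_contingency(
    corpus: Sequence[ReportRecord],
    index_predicate: Callable[[ReportRecord], bool],
    pt: str,
) -> ContingencyTable:
    """Count the 2x2 for one PT; every report contributes to one cell."""
    if not corpus:
        raise ValueError("empty corpus")
    a = b = c = d = 0
    for r in corpus:
        has_pt = pt in r.reaction_pts
        if index_predicate(r):
            if has_pt:
                a += 1
            else:
                c += 1
        else:
            if has_pt:
                b += 1
            else:
                d += 1
    return ContingencyTable(a, b, c, d)


def ror(
    t: ContingencyTable, z: float = 1.96, haldane: bool = False
) -> tuple[float, float, float]:
    """(ROR, CI low, CI high). Any zero cell makes the estimate undefined
    (returned as NaNs) unless ``haldane`` applies the +0.5 correction."""
    a, b, c, d = t.a, t.b, t.c, t.d
    if haldane:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if min(a, b, c, d) <= 0:
        return math.nan, math.nan, math.nan
    est = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return (
        est,
        math.exp(math.log(est) - z * se),
        math.exp(math.log(est) + z * se),
    )


def ic_credibility_bounds(
    ic: float, n: int, halfwidth_constant: float = 2.0
) -> tuple[float, float]:
    """Credibility interval IC +/- k/sqrt(n) around a point IC with n
    reports of the pair (k = 2 by default)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    hw = halfwidth_constant / math.sqrt(n)
    return ic - hw, ic + hw


def information_component(
    t: ContingencyTable, variant: str = "shrunk", halfwidth_constant: float = 2.0
) -> tuple[float, float, float]:
    """(IC, lower, upper) under the chosen variant.

    "shrunk" (default): IC = log2((a+0.5)/(E+0.5)), interval IC +/- 2/sqrt(a);
    "plain": IC = log2(a/E), same interval;
    "noren": shrunk IC with Noren's asymptotic 95% credibility bounds
    IC - 3.3*(a+0.5)^-0.5 - 2*(a+0.5)^-1.5, IC + 2.4*(a+0.5)^-0.5 - 0.5*(a+0.5)^-1.5.
    """
    if variant not in IC_VARIANTS:
        raise ValueError(f"unknown IC variant {variant!r}")
    a = t.a
    if a < 1:
        raise ValueError("information component requires a >= 1")
    expected = t.n_drug * t.n_event / t.N
    if expected == 0:
        return math.nan, math.nan, math.nan
    if variant == "plain":
        ic = math.log2(a / expected)
    else:
        ic = math.log2((a + 0.5) / (expected + 0.5))
    if variant == "noren":
        s = a + 0.5
        return (
            ic,
            ic - 3.3 * s**-0.5 - 2.0 * s**-1.5,
            ic + 2.4 * s**-0.5 - 0.5 * s**-1.5,
        )
    lo, hi = ic_credibility_bounds(ic, a, halfwidth_constant)
    return ic, lo, hi


def detect_signals(
    corpus: Sequence[ReportRecord],
    drug: str,
    index_predicate: Callable[[ReportRecord], bool],
    soc_filter: Iterable[str],
    thresholds: SignalThresholds | None = None,
    expectedness: dict[str, frozenset[str]] | None = None,
    ic_variant: str = "shrunk",
) -> list[DisproportionalityResult]:
    """One result per (drug, PT) with a >= 1 among the SOC-filtered PTs.

    Pairs below the ``min_n`` report minimum have their ROR and IC fields
    marked not-available (NaN) and can never be signals. Results are
    sorted by n descending, then PT name.
    """
    thresholds = thresholds or SignalThresholds()
    soc_pts = frozenset(soc_filter)
    if not corpus:
        raise ValueError("empty corpus")
    index_flags = np.fromiter(
        (index_predicate(r) for r in corpus), dtype=bool, count=len(corpus)
    )
    n_index = int(index_flags.sum())
    n_total = len(corpus)
    # per-PT counts in one pass over reports
    a_counts: dict[str, int] = {}
    e_counts: dict[str, int] = {}
    for r, is_idx in zip(corpus, index_flags):
        for pt in r.reaction_pts & soc_pts:
            e_counts[pt] = e_counts.get(pt, 0) + 1
            if is_idx:
                a_counts[pt] = a_counts.get(pt, 0) + 1
    results = []
    for pt, a in a_counts.items():
        n_event = e_counts[pt]
        t = ContingencyTable(
            a=a, b=n_event - a, c=n_index - a, d=n_total - n_index - (n_event - a)
        )
        if a >= thresholds.min_n:
            r_est, r_lo, r_hi = ror(t, z=thresholds.z)
            ic, ic_lo, ic_hi = information_component(
                t, ic_variant, thresholds.ic_halfwidth_constant
            )
            is_signal = (not math.isnan(r_lo)) and r_lo > 1.0
        else:
            r_est = r_lo = r_hi = ic = ic_lo = ic_hi = math.nan
            is_signal = False
        results.append(
            DisproportionalityResult(
                drug=drug,
                pt=pt,
                n=a,
                ror=r_est,
                ror_low=r_lo,
                ror_high=r_hi,
                ic=ic,
                ic_low=ic_lo,
                ic_high=ic_hi,
                is_signal=is_signal,
            )
        )
    results.sort(key=lambda r: (-r.n, r.pt))
    if expectedness is not None:
        results = annotate_expectedness(results, expectedness)
    return results


def annotate_expectedness(
    results: list[DisproportionalityResult],
    label_pts: dict[str, frozenset[str]],
) -> list[DisproportionalityResult]:
    """Set the expected flag: PT listed in the drug's label list. A drug
    absent from the list yields expected=None (unknown)."""
    out = []
    for r in results:
        if r.drug in label_pts:
            out.append(replace(r, expected=r.pt in label_pts[r.drug]))
        else:
            out.append(replace(r, expected=None))
    return out


def results_to_frame(
    results_by_drug: dict[str, list[DisproportionalityResult]]
) -> pd.DataFrame:
    """Table-2-style frame: one row per PT, per-drug n/ROR/IC columns,
    sorted by total n descending then PT name; sub-minimum pairs render
    as NA."""
    pts: dict[str, dict[str, DisproportionalityResult]] = {}
    for drug, results in results_by_drug.items():
        for r in results:
            pts.setdefault(r.pt, {})[drug] = r
    drugs = sorted(results_by_drug)
    rows = []
    for pt, by_drug in pts.items():
        row: dict[str, object] = {"pt": pt}
        total = 0
        for drug in drugs:
            r = by_drug.get(drug)
            n = r.n if r else 0
            total += n
            if r is None:
                row[f"{drug}_n"] = 0
                row[f"{drug}_ror"] = ""
                row[f"{drug}_ic"] = ""
                row[f"{drug}_signal"] = False
                row[f"{drug}_unexpected"] = ""
            else:
                row[f"{drug}_n"] = n
                if r.ror_defined:
                    row[f"{drug}_ror"] = (
                        f"{r.ror:.2f} ({r.ror_low:.2f}-{r.ror_high:.2f})"
                    )
                    row[f"{drug}_ic"] = f"{r.ic:.2f} ({r.ic_low:.2f}-{r.ic_high:.2f})"
                else:
                    row[f"{drug}_ror"] = "NA"
                    row[f"{drug}_ic"] = "NA"
                row[f"{drug}_signal"] = r.is_signal
                row[f"{drug}_unexpected"] = (
                    "" if r.expected is None else ("No" if r.expected else "Yes")
                )
        row["total_n"] = total
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["total_n", "pt"], ascending=[False, True]
    ).reset_index(drop=True)
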