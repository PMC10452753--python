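# Methods and design notes

## The case/non-case design

Spontaneous reporting systems have no denominator of drug users, so
absolute risks cannot be estimated. Disproportionality analysis instead
asks whether an event is reported *relatively* more often with an index
drug than with everything else in the database. For a drug–event pair the
report-level 2×2 table is

|                      | event PT present | event PT absent |
|----------------------|------------------|-----------------|
| index-drug reports   | a                | c               |
| all other reports    | b                | d               |

Here "index-drug reports" means reports in the selected cohort with the
drug as primary suspect, and the reference group is, by default, every
other deduplicated report in the ingested corpus (`reference: corpus`;
`reference: cohort` restricts the comparison to the included cohort). Each
report contributes to exactly one cell: a report with several PTs of the
same SOC is one case, counted once per PT it mentions.

### Reporting odds ratio

`ROR = ad / bc`, with the Woolf log-normal confidence interval
`exp(ln ROR ± z·√(1/a + 1/b + 1/c + 1/d))`, `z = 1.96`. Any zero cell
leaves the estimate undefined (rendered `NA`); the Haldane–Anscombe +0.5
correction is available by flag but off by default, because the signal
criterion's minimum of 3 reports already excludes the `a = 0` corner and a
realistic reference corpus keeps `b > 0`. A pair is flagged a **signal**
when `a ≥ min_n` (default 3) and the lower CI bound exceeds 1.

### Information component

The Bayesian information component compares observed with expected
reporting on a log2 scale. With `E = (a+c)(a+b)/N`:

* `shrunk` (default): `IC = log2((a + 0.5)/(E + 0.5))` — the half-unit
  shrinkage pulls small-count estimates toward 0;
* `plain`: `IC = log2(a/E)`;
* credibility interval (both): `IC ± 2/√a`;
* `noren`: shrunk point estimate with the asymmetric asymptotic bounds
  `IC − 3.3(a+0.5)^{−1/2} − 2(a+0.5)^{−3/2}` and
  `IC + 2.4(a+0.5)^{−1/2} − 0.5(a+0.5)^{−3/2}`.

The `IC ± 2/√a` form is the default because it is self-contained: the
bounds recompute exactly, after two-decimal rounding, from a pair's point
IC and report count alone, which is how the bundled reference values for
the regorafenib pairs (chromaturia, renal impairment, urinary retention,
renal failure) were derived and how the acceptance tests verify them.
Residual ±0.01 differences on other pairs are consistent with rounding the
point IC before deriving bounds. The interval's bounds are named
generically (`ic_low`/`ic_high`) rather than "IC025/IC975", since naming
conventions for the upper credibility quantile vary across reporting
tools; under the symmetric ±2/√a form the labels do not alter the values.
Both the shrunk and plain point estimates are provided because the two are
indistinguishable at large report counts and a reference corpus is needed
to tell them apart at small ones.

No multiplicity adjustment is applied to signal flags; the `n ≥ 3` minimum
and the IC criterion are the built-in false-discovery mitigations, and an
optional Bonferroni/Benjamini–Hochberg switch exists for the descriptive
p-values (`adjust_p_values`, default off).

## Descriptive statistics

* **Categorical strata**: Pearson chi-square on 2×2 tables with Yates'
  continuity correction,
  `N·(max(|ad−bc|−N/2, 0))² / ((a+b)(c+d)(a+c)(b+d))`, upper tail of the
  χ²₁ distribution. Conventions that make the comparisons well-posed:
  gender is tested male vs female excluding unspecified; age groups are
  tested adult (18–64) vs elderly (≥65) among known ages; continents are
  tested stratum vs rest among specified countries; outcome rows use one
  category per report, by severity priority (death > life-threatening >
  hospitalization > disability > congenital anomaly > required
  intervention > other), so the outcome section partitions each group.
* **Seriousness**: a report is serious iff it carries at least one FAERS
  outcome code — including `OT` ("other serious outcome") — and
  non-serious when it has no outcome row. This matches FAERS semantics and
  makes the outcome section's serious categories sum to the serious count.
* **Continuous variables**: Mann–Whitney U, two-sided. The exact null
  distribution is used when `n_x·n_y ≤ 400` — by direct enumeration over
  rank assignments (midranks, so ties are handled) when `C(n, n_x) ≤ 2·10⁵`,
  otherwise by the no-ties exact distribution; beyond that, the normal
  approximation with tie-corrected variance and no continuity correction
  (the asymptotic output of the major statistics packages). Degenerate
  all-tied samples return p = 1.
* **Quantiles**: type 7 (linear interpolation of order statistics) by
  default; type 6 (SPSS-style HAVERAGE) selectable. Both are exposed
  because published medians (Q1–Q3) in this field come from either
  convention.
* **Time to onset**: days from the *earliest* therapy start of the index
  drug to the event date; both dates must be day-precise by default.
  Month-precision dates can be imputed to the 15th (`impute_mid_month`),
  off by default so no precision is fabricated. Negative differences
  (event before start) are implausible and dropped with a log entry.
  p-values are reported to 3 decimals, two-sided, α = 0.05.

## Deduplication

FAERS contains two kinds of redundancy. Case versions (resubmissions under
one case id) are resolved by keeping the highest version, breaking ties by
latest receipt date, then last-seen input order. Cross-case duplicates are
detected by exact agreement on the full key — reaction PT set, event date,
gender, age and weight after integer rounding (absorbing unit-conversion
jitter), reporting country, and the PS/SS substance set. Requiring *every*
key field to be present is deliberately conservative: sparse reports can
never be merged, so the step removes only near-certain clones. Whether
partial-field agreement should also merge is an open judgement call in the
field; strict full-key equality is what is implemented and audited (a CSV
lists each cluster, the kept id, and the removed ids). Within a cluster
the latest-received report is kept, ties going to the lowest case id.

## Cohort selection

The frame is every version-resolved report that mentions an index drug (in
any role) with a receipt date inside the window (default 2012-10-01 to
2022-12-31). Exclusions apply in a fixed order, each report landing in the
first applicable bucket, so the counts telescope:

1. **Pre-marketing literature reports**: report source includes the
   literature flag *and* the event date precedes the index drug's approval
   date (defaults: regorafenib 2012-09-27; encorafenib's CRC indication
   2020-04-08). Both conditions are required because a literature flag
   alone also covers ordinary post-marketing published case reports.
2. **Other indication**: the primary-suspect drug's indication terms do
   not intersect the colorectal-cancer term list (case-insensitive).
   Matching is at drug level — the indication belongs to the suspect drug,
   not the report — with a `indication_scope: report` switch for the
   alternative reading. The default CRC term list is editable config.
3. **Other primary suspect**: the PS substance is not an index drug.
4. **Duplicates**: cross-case dedup among the survivors.

A case is an included report with at least one reaction PT mapping to the
target SOC. MedDRA is proprietary, so the bundled PT→SOC table covers only
the renal/urinary PTs under study plus the background PTs the generator
uses; full mappings are supplied by the user as configuration, and unknown
PTs map to an `UNMAPPED` SOC (never silently to the target).

## Synthetic corpus generator

The generator emulates what the analysis assumes about a spontaneous
reporting database, with every quantity seeded and reproducible:

* one primary-suspect drug per report, drawn from a catalogue of marginal
  probabilities (defaults: the two index drugs plus six common mCRC
  comparators);
* event PTs included independently given the drug, with probability
  `p_event · λ(drug, PT)` truncated at 1 — λ is the injected
  reporting-rate ratio, 1 everywhere except configured signals. Reports
  whose draw comes up empty receive a fallback PT kept outside the
  catalogue, so catalogue marginals stay exactly Bernoulli(p) (a rejection
  scheme would inflate them);
* demographics, reporter type, country, and outcome codes from
  configurable categorical mixes; ages normal (mean 63, SD 12, clipped to
  18–95), consistent with an mCRC population;
* receipt dates uniform over the window; time to onset log-normal with
  per-drug medians (defaults 7 days REG-like, 14 days ENC-like, so the
  TTO comparison has a realistic discriminable shift);
* per-field missingness (defaults: age 15%, weight 30%, event date 10%,
  country 5%), duplicate clones (exact copies of complete-key reports
  under new, numerically larger case ids), and superseded case versions.

Ground truth (injected λ per pair, clone ids, superseded ids, case status)
is emitted alongside, so tests can compare pipeline output to construction
rather than to another estimate.

**What it does not emulate**: correlated events within a report (event
inclusion is independent given the drug), drug-name misspellings and
synonym drift, temporal reporting trends (Weber effect), multi-suspect
causality narratives, and real MedDRA coding noise. Passing tests on this
corpus therefore validate the *computational* pipeline — counting,
deduplication, estimation, calibration — not the clinical behaviour of any
drug on real FAERS data.

### Forced-margin scenario

`scenario_reference_margins()` builds a deterministic 14,323-report corpus
whose selection flow (524 literature, 7,768 other-indication, 1,022
other-PS, 25 duplicate exclusions, 4,984 included) and descriptive margins
(379 renal cases; gender, reporter, continent, outcome, year, and per-PT
case counts) are forced by construction, not sampled. Joint structure
across attributes is arbitrary (attributes are assigned independently by
position), which is immaterial for marginal statistics. Only the 25
duplicate-clone source reports carry a body weight — distinct integers —
so under the missing-never-matches rule the dedup stage provably removes
exactly the injected clones. This scenario is what the exact end-to-end
acceptance checks run on.

## Numerical and engineering choices

* Dates are partial (year/month/day precision) throughout; chronological
  comparisons fill absent components with their earliest value, and
  day-difference arithmetic requires day precision.
* Age unit conversion: decades ×10, months ÷12, weeks ÷52.1775, days
  ÷365.25, hours ÷8766; a missing unit with value ≤ 120 is taken as years.
* The `$`-delimited FAERS dialect has no quoting convention; malformed
  rows are counted and logged, never silently dropped from the tally.
  Column-name drift across FAERS vintages is handled by a configurable
  synonym map (e.g. `gndr_cod → sex`).
* Substance normalization is uppercase/trim/collapse-whitespace only; a
  synonym dictionary is user configuration, since no universal rule
  exists.
* Simulation-based checks are sized for a single CPU: rate-ratio coverage
  uses 200 replicates of 7,000 reports with background event rates of
  0.005 (keeping the odds ratio within a quarter of a standard error of
  the rate ratio even at λ = 10); null calibration uses 200 replicates of
  4,000 reports over 100 drug–event pairs.

## Known limitations

* The reference group at desk scale is a synthetic corpus; published
  point estimates that depend on the full FAERS background are out of
  reach by construction, and the pipeline's estimation machinery is
  validated by oracle equivalence, coverage, and calibration instead.
* Strict full-key dedup under-merges relative to probabilistic record
  linkage; that is the intended trade-off.
* The expectedness lists bundle only the two study drugs' renal/urinary
  label PTs (encorafenib's US label lists none); all other drugs return
  "unknown".
* No E2B/XML dialect, no openFDA JSON, no PRR/EBGM/regression-based
  signal statistics (out of scope by design).
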