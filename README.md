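# faerspv

Case/non-case pharmacovigilance analysis of FDA Adverse Event Reporting
System (FAERS) quarterly extracts, built as a reusable, tested pipeline.
The motivating application is the renal and urinary safety profile of the
oral tyrosine kinase inhibitors regorafenib (REG) and encorafenib (ENC) in
metastatic colorectal cancer (mCRC), but every stage is configurable: index
drugs, indication terms, study window, target MedDRA System Organ Class
(SOC), and label-expectedness lists are all inputs.

The package is aimed at pharmacoepidemiologists and drug-safety researchers
who want the full path from raw `$`-delimited quarterly files to
disproportionality tables to be scripted, deterministic, and unit-tested —
rather than a sequence of manual spreadsheet steps.

## What it does

1. **Ingestion** (`faerspv.faers_io`) — parses the DEMO/DRUG/REAC/OUTC/
   INDI/THER/RPSR tables of one or more quarters and assembles one record
   per report (demographics, drugs with roles and indications, reaction
   preferred terms, outcomes, partial-precision dates).
2. **Deduplication** (`faerspv.dedup`) — resolves case versions (latest
   version per case id), then removes cross-case duplicates that agree on
   *all* key fields: reaction PT set, event date, gender, age, weight,
   reporting country, and suspected active substances. A missing field
   never matches a missing field.
3. **Cohort selection** (`faerspv.cohort`) — applies the inclusion flow:
   reports mentioning an index drug in the window, minus pre-marketing
   literature reports, other indications, other primary suspects, and
   duplicates; classifies each included report as a *case* (at least one
   reaction PT in the target SOC) or *non-case*.
4. **Descriptives** (`faerspv.descriptives`) — cases vs other reports:
   chi-square on 2×2 tables with Yates' continuity correction, Mann–Whitney
   U for continuous variables, median (Q1–Q3) summaries, and time to onset
   (TTO, days from index-drug therapy start to event).
5. **Disproportionality** (`faerspv.dispro`) — per (drug, PT) pair with
   report counts `a, b, c, d`:

   - reporting odds ratio `ROR = ad / bc` with the Woolf 95% CI
     `exp(ln ROR ± 1.96 · √(1/a + 1/b + 1/c + 1/d))`;
   - Bayesian information component
     `IC = log2((a + 0.5) / (E + 0.5))`, `E = (a+c)(a+b)/N`, with the
     credibility interval `IC ± 2/√a` (unshrunk and Norén asymptotic
     variants by flag);
   - signal flag: at least 3 reports **and** lower ROR CI bound > 1;
   - expectedness annotation against the drug's FDA-label PT list.

6. **Synthetic data** (`faerspv.synthetic`) — a seeded generator of
   FAERS-format corpora with known ground truth (injected reporting-rate
   ratios, duplicate clones, superseded versions, missingness), plus a
   deterministic forced-margin scenario used for exact end-to-end checks.

## Worked example

Simulate a 5,000-report corpus with two injected renal signals for
regorafenib (rate ratios 8 for chromaturia, 3 for renal impairment) and 5%
duplicate clones, then run the whole pipeline:

```python
from faerspv import synthetic, generate
from faerspv.pipeline import RunConfig, run_pipeline

cfg = synthetic.default_config(
    seed=11, n_reports=5000, duplicate_fraction=0.05,
    signals={("REGORAFENIB", "Chromaturia"): 8.0,
             ("REGORAFENIB", "Renal impairment"): 3.0},
)
quarter, truth = generate(cfg, "corpus")
run_pipeline(RunConfig(quarters=[quarter], out_dir="out"))
print(open("out/flowchart.txt").read())
```

```
Reports mentioning an index drug in window     1,579
  - pre-marketing literature reports               0
  - other indications                            659
  - other primary suspect drug                   111
  - duplicates                                    37
Included in the analysis                         772
```

Of the 5,250 generated records (5,000 reports + 250 duplicate clones),
1,579 mention REG or ENC; 659 are excluded because the primary suspect's
indication is not colorectal cancer (the generator gives REG a realistic
mix of mCRC, hepatocellular carcinoma, and GIST indications), 111 because
another drug is the primary suspect, and 37 duplicates fall inside this
cohort frame. The top of the resulting `table2.csv` for REG:

```
               pt  REG_n          REG_ror            REG_ic  REG_signal REG_unexpected
      Chromaturia     15 4.72 (2.43-9.14)  1.56 (1.05-2.08)        True            Yes
 Renal impairment     13 2.07 (1.11-3.88)  0.81 (0.26-1.37)        True            Yes
          Dysuria      6 2.73 (1.06-7.07)  1.02 (0.21-1.84)        True            Yes
      Proteinuria      6 2.73 (1.06-7.07)  1.02 (0.21-1.84)        True             No
Urinary retention      4 1.29 (0.44-3.78) 0.28 (-0.72-1.28)       False            Yes
```

Both injected associations surface as signals (n ≥ 3, ROR lower bound > 1,
IC lower bound > 0) and are flagged `Yes` (unexpected, i.e. absent from the
bundled REG label list), whereas proteinuria — a labelled REG reaction —
is annotated `No` even when disproportionate. The 95% CI of the chromaturia
ROR (2.43–9.14) covers the injected rate ratio 8. `out/tto.json` reports
the REG cases' median TTO of 7 days (Q1–Q3 3.5–12), matching the
generator's log-normal TTO with median 7 for REG.

The same pipeline is available from the shell:

```bash
faerspv simulate -o corpus --seed 11 --n 5000
faerspv report -q corpus/2099Q1 -o out
faerspv signals -q corpus/2099Q1 -o out --ic-variant noren --min-n 5
```

## Layout

```
src/faerspv/
  records.py      partial dates, drug entries, report records
  faers_io.py     quarterly ASCII reader/writer, record assembly
  dedup.py        version resolution, cross-case duplicate removal
  cohort.py       selection flow, case classification
  descriptives.py chi-square (Yates), Mann-Whitney, quantiles, TTO, table 1
  dispro.py       2x2 construction, ROR, IC, signal detection, table 2
  synthetic.py    seeded corpus generator + forced-margin scenario
  meddra.py       bundled PT->SOC slice, label lists, country->continent
  pipeline.py     end-to-end orchestration
  cli.py          click subcommands
docs/methods.md   modelling and design notes
```

See `docs/methods.md` for the statistical conventions, generator design,
and known limitations.
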