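# pvscreen

Disproportionality screening of spontaneous adverse-event reports, built
around the case/non-case design used for drug-safety signal detection in
large pharmacovigilance databases. The package was written for the analysis
of drug-associated **hyperammonaemia** — a serious, treatable condition
defined by the MedDRA preferred terms *hyperammonaemia*, *hyperammonaemic
encephalopathy* and *hyperammonaemic crisis* — but every component (event
definition, exclusion rules, scoring vocabularies) is configurable, so any
drug–event question over an individual-case-safety-report (ICSR) database
can be screened the same way.

It is aimed at pharmacovigilance analysts and methods researchers who need
a transparent, fully testable implementation: real ICSR databases are
proprietary, so the package ships a synthetic-report generator with planted
relative reporting rates that makes every stage of the pipeline verifiable
end to end.

## The statistic

For a drug *D* and event *E*, with case-level counts
`N_observed` (cases reporting both), `N_drug` (cases reporting *D*),
`N_effect` (cases reporting *E*) and `N_total` (all cases), the expected
count under independent reporting is `E = N_drug · N_effect / N_total` and
the **information component** is the shrunk log2 observed-to-expected ratio

```
IC = log2( (N_observed + 0.5) / (E + 0.5) )
```

Uncertainty comes from the Gamma posterior of the shrunk ratio (shape
`N_observed + 0.5`, rate `E + 0.5`); `IC_025` is the log2 of its
2.5%-quantile and `IC_025 > 0` is the signal threshold. The +0.5 shrinkage
pulls rare pairs toward IC = 0, making the statistic conservative compared
with the reporting odds ratio.

Screened drugs then pass a three-stage exclusion cascade — drop
non-significant drugs, drop drugs whose event cases all come from a single
country, drop drugs used to *treat* the event (protopathic bias; default
list: lactulose, rifaximin, sodium phenylbutyrate, benzoic acid, carglumic
acid) — and the retained drugs get per-drug clinical summaries plus
French-method causality grades: case informativity NI0–NI2 (time to onset
and drug discontinuation described?) and extrinsic imputability B1–B4
(published evidence, from nothing to in-label).

## Worked example

```python
from pvscreen import ContingencyCounts, ic_result

counts = ContingencyCounts(n_observed=1722, n_drug=250_000,
                           n_effect=3547, n_total=20_000_000)
result = ic_result(counts)
```

Running `python examples/01_ic_statistics.py` prints:

```
expected count E      :    44.34
IC  (bits)            :    5.264
IC_025 / IC_975 (bits):    5.195 /    5.331
significant (IC_025>0): True
2^IC (reporting ratio):     38.4
```

The pair is reported ~38 times more often than independence predicts, and
even the lower credibility bound is far above 0 — a strong signal.

`python examples/03_selection_cascade.py` builds the packaged calibration
database (30 000 reports, 642 drugs with at least one hyperammonaemia
case) and runs the cascade:

```
drugs with >= 1 event case : 642
  excluded not_significant : 555
  excluded single_country  : 11
  excluded protopathic     : 5
  retained for analysis    : 71
```

The other examples simulate a database with a planted signal and recover it
(`02_simulate_and_screen.py`) and run the full pipeline with per-drug
summaries and cohort descriptives (`04_full_pipeline.py`).

A thin CLI wraps the same library calls:

```bash
pvscreen simulate --config generator.yaml --seed 1 --out db/
pvscreen screen --db db/ --out run/
pvscreen summarize --db db/ --out run/
```

## Layout

- `src/pvscreen/icsr_model.py` — ICSR domain types and the two on-disk
  dialects (three-table relational CSV, JSONL)
- `src/pvscreen/synthetic_data.py` — report generator and calibration fixture
- `src/pvscreen/case_selection.py` — event definition, case selection,
  exclusion cascade
- `src/pvscreen/disproportionality.py` — IC statistics and drug screening
- `src/pvscreen/scoring.py` — NI/B causality grades, presentation categories,
  seriousness
- `src/pvscreen/summaries.py` — per-drug tables, cohort descriptives,
  pipeline orchestration
- `docs/methods.md` — model, assumptions, parameter choices, limitations
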