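# Methods

## The case/non-case design

A spontaneous-reporting database is a collection of individual case safety
reports (ICSRs). For a target adverse event defined by an explicit set of
MedDRA preferred terms, *cases* are the reports carrying at least one event
PT and *non-cases* are all other reports. For each drug reported as
**suspect** or **interacting** in at least one case (concomitant mentions
are never analysed), the four case-level counts `N_observed`, `N_drug`,
`N_effect`, `N_total` form the contingency of the drug–event pair; all
counts deduplicate at case level, so a drug mentioned twice in a report
counts once. `N_drug` counts only suspect/interacting occurrences, matching
the eligibility rule of the numerator; whether real-world IC denominators
include concomitant mentions varies by implementation, so this convention
is stated explicitly and kept fixed.

## Information component and credibility bounds

The disproportionality statistic is the information component

    IC = log2( (N_observed + 0.5) / (E + 0.5) ),   E = N_drug·N_effect/N_total.

The +0.5 terms are the shrinkage of an empirical-Bayes Gamma model: the
posterior of the shrunk observed-to-expected ratio is Gamma with shape
`N_observed + 0.5` and rate `E + 0.5`, and the credibility bounds are log2
quantiles of that posterior (`IC_025` at 2.5%, `IC_975` at 97.5%),
evaluated with `scipy.stats.gamma.ppf`. The point-estimate formula is the
mean-ratio form of the same posterior, so point estimate and interval are
mutually consistent; `IC_025 > 0` is the signal threshold. Two useful
consequences, both exploited by the test suite and the calibration fixture:

* a drug with a single observed case can never be significant
  (at shape 1.5 the 2.5% posterior quantile is below the shrunk ratio for
  every expected count), and
* for large counts at fixed ratio R, `IC_025 → log2 R`.

An older normal-approximation interval (IC ± z·sd, with the posterior
log-scale sd `sqrt(trigamma(N_observed + 0.5)) / ln 2`) is available behind
`method="normal"` for sensitivity analysis only. No other
disproportionality measures (ROR, PRR, EBGM) are implemented, and no
multiplicity adjustment is applied across drugs: the IC with its
conservative shrinkage is the chosen screen.

The credibility bounds are validated against an independent Monte-Carlo
oracle (empirical quantiles of raw Gamma draws). The oracle's own quantile
noise at shape 0.5 is ~0.02 bits per 10^6 draws on the log scale — above
the 0.01-bit comparison tolerance — so the oracle scales its draw count up
(to 4×10^7 at the smallest shapes) until its sampling error is below the
tolerance; this strengthens the check rather than loosening it.

## Exclusion cascade

Screened drugs pass three ordered stages, each drug tagged with the first
applicable reason:

1. `not_significant` — `IC_025 ≤ 0`;
2. `single_country` — all of the drug's *event* cases (not all its reports)
   share one country; a drug with exactly one event case satisfies this
   vacuously but is always caught by stage 1 first;
3. `protopathic` — normalised drug name on the configured list of drugs
   used to treat the event (default: lactulose, rifaximin, sodium
   phenylbutyrate, benzoic acid, carglumic acid). Reverse causation: these
   drugs are given *because of* hyperammonaemia.

The order is fixed because the stage tallies depend on it. Drug-name and PT
matching is whitespace-normalised and case-insensitive throughout, since
capitalisation varies across reporting sources.

## Causality and clinical annotation

* **Informativity** of a (case, drug) pair: NI2 when both the time to onset
  and the discontinuation of the drug are described, NI1 when exactly one
  is, NI0 when neither. "Discontinuation described" is operationalised as
  `action_taken == withdrawn`; dose reduction deliberately does not qualify
  (conservative reading), and dechallenge outcomes are not modelled
  separately from the action-taken field.
* **Extrinsic imputability** of a drug: B4 if the effect is in the product
  label, else B3 if widely published in reference works, else B2 if case
  reports exist, else B1. The evidence flags are a user-supplied table; the
  packaged default for hyperammonaemia encodes label/literature status as
  of 2021-02-01 (10 B4, 6 B3, 45 B2, 10 B1 drugs).
* **Presentation** is classified by intersecting a case's co-reported PTs
  (excluding the event-defining PTs themselves) with a configurable
  vocabulary of seven categories: coma/altered consciousness, brain oedema,
  seizures, neuropsychiatric, miscellaneous neurological, liver
  dysfunction, kidney dysfunction. The packaged vocabulary is a documented
  working set, not a licensed MedDRA hierarchy; the classification logic is
  the reproducible content and any vocabulary can be supplied as
  `category,pt` CSV.
* **Seriousness** is carrying at least one of the six regulatory outcome
  categories (death, life-threatening, hospitalisation, disabling,
  congenital, other medically important).

## Summaries and missing data

All per-drug statistics are computed over the drug's event cases with
available-case denominators: a percentage's denominator is the number of
cases in which the field is observed, reported alongside the value
(`n_*` columns), and an all-missing field yields a missing summary, never
zero. The interruption percentage treats `action_taken == unknown` as
missing. Per-case cohort time to onset is the smallest observed delay among
the case's suspect/interacting drugs. Continent shares come from a packaged
country→continent table. Outputs are written with fixed column order,
canonical rounding (one decimal for presentation percentages, full
precision kept in the machine columns) and sorted JSON keys, so a rerun on
identical inputs is byte-identical.

## The synthetic-report generator

The generator emulates the statistical structure of a real reporting
database; every draw comes from one seeded `numpy` generator, so a seed
fixes every downstream number.

| parameter | default | meaning |
|---|---|---|
| `p0` | 0.005 | baseline event probability per drug exposure |
| `rr_event` | 1 per drug | planted relative reporting rate (1 = null) |
| `mean_extra_drugs` | 0.8 | Poisson mean of drugs beyond the first |
| `co_class_prob` | 0.2 | chance a report's drugs all share one class |
| `popularity_weight` | per drug | skewed reporting frequency |
| `tto_log_mean/sd` | ln 13 / 1.0 | per-drug log-normal onset delay (days) |
| `missingness` | 15% age, 5% sex, 35% TTO, 20% action | MCAR field masks |

Ages are Normal(42.7, 23.5) clipped to [0, 93] years, sex is 54.5% male,
report years uniform 1981–2020, and country weights approximate global
continent shares (~40% Americas, 34% Europe, 22.5% Asia) — the demographic
profile typical of international hyperammonaemia reporting. The event
occurs with probability `1 − Π_d (1 − clamp(p0·rr_d, 0, 1))` over the
report's drugs: per-drug hazards combine independently, which keeps the
marginal relative reporting rate of a planted drug approximately equal to
its `rr_event` when `p0` is small and reports are mostly single-drug.
Death is drawn from the maximum `death_prob` among the report's drugs;
other outcome categories have small fixed probabilities. Each report has a
guaranteed suspect drug; remaining drugs are suspect/interacting/
concomitant at 0.5/0.1/0.4 so the concomitant stream exercises the role
filter.

What the generator does **not** model: reporting trends over time (years
are uniform), informative missingness (masks are MCAR, matching the
available-case analysis assumption), within-class correlation of event
risk, duplicate reports, or country-specific reporting cultures. Passing
tests therefore demonstrate correctness of the statistical machinery under
a clean MCAR regime, not robustness to the reporting biases of real
databases.

### Signal-recovery study conditions

The planted-signal validation uses 20 replicate databases of 50 000 cases:
one drug at `rr_event = 8` with ~2% of reports, 30 null drugs sized so
their expected counts exceed 5, `p0 = 0.005`, single-drug reports. Under
these conditions the mean of `2^IC` for the planted drug is expected near
6.5–7 rather than 8: the planted drug's own cases inflate `N_effect` (and
hence E), and the +0.5 shrinkage bites at O ≈ 35. The acceptance band
[6, 10] reflects exactly this bias; null drugs are expected significant at
the nominal ~2.5% rate.

### Calibration fixture

The packaged calibration database (30 000 reports) reproduces fixed
selection-cascade tallies — 642 event-associated drugs, of which 555
excluded as non-significant, 11 as single-country, 5 as protopathic and 71
retained — by *construction* rather than stochastic tuning: null drugs get
exactly one event case each (never significant, see above), single-country
and protopathic drugs get 4–14 event cases with small expected counts
(always significant), and the 71 signal drugs get 4–300 event cases spread
over several countries. Background reports (including mentions of the
frequent drugs in non-event cases) dilute the event rate to ~7% so that
even the smallest signal count (4 cases) clears the threshold with margin.
The seed only drives nuisance fields; the tallies hold for every seed and
are re-verified at build time by running the actual screening pipeline.

## Numerical and design choices

* Screening order is descending observed count with drug-id tie-break, so
  outputs are reproducible across runs and platforms.
* `ContingencyCounts` validates `N_observed ≤ min(N_drug, N_effect) ≤
  N_total` and derives E on demand; it is never stored separately.
* Missing values are `None` in memory, empty CSV fields and absent JSONL
  keys on disk — never sentinel numbers.
* The generator raises a configuration error if a report draws more drugs
  than the catalog holds, rather than silently truncating.
* `summarize_drug` accepts any screen row (it does not re-check that the
  drug survived the cascade); the pipeline only calls it for retained
  drugs.
* Problem sizes in the test suite (10 000-case binomial checks, 20×50 000
  replicate screens, a 30 000-case fixture) were chosen as the smallest
  scales at which the targeted statistical properties are stable.

## Limitations

Synthetic validation cannot establish external validity against a real
pharmacovigilance database: reporting biases (under-reporting, awareness
bias, channelling) are absent by design. The IC measures reporting
disproportionality, not incidence or risk — without exposure denominators
no rate can be estimated. Label knowledge drifts over time; the packaged
table is a frozen snapshot and should be replaced for any new analysis.
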