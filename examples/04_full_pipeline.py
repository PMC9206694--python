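"""End-to-end pipeline run: simulate, screen, score and summarise.

Writes screen.csv / retained.csv / excluded.csv / drug_summaries.csv /
cohort.json to an output directory and prints the per-drug clinical summary
of the planted drug and the cohort descriptives.
"""

import json
from pathlib import Path

from pvscreen import DrugSpec, GeneratorConfig, PipelineConfig, run_pipeline

catalog = tuple(
    [DrugSpec("VPA", drug_name="Valproic acid", popularity_weight=4.0,
              rr_event=20.0, class_label="antiepileptic", death_prob=0.03)]
    + [DrugSpec(f"D{i:02d}", popularity_weight=2.0, class_label="misc")
       for i in range(12)]
)
out = run_pipeline(
    PipelineConfig(
        out_dir=Path("scratch/example_run"),
        generator=GeneratorConfig(n_cases=10_000, drug_catalog=catalog, p0=0.01, seed=4),
    )
)
print(f"outputs in {out}: {sorted(p.name for p in out.iterdir())}\n")

header, *rows = (out / "drug_summaries.csv").read_text().strip().splitlines()
vpa = dict(zip(header.split(","), next(r for r in rows if r.startswith("VPA")).split(",")))
for key in ("n_cases", "ic025", "age_mean", "median_tto_days", "pct_female",
            "pct_death", "pct_single_suspect", "pct_interruption", "imputability"):
    print(f"  {key:20}: {vpa[key]}")
# n_cases = the drug's event cases; percentages use available-case
# denominators; imputability B4 = the association is in the product label.

cohort = json.loads((out / "cohort.json").read_text())
print(f"\ncohort: {cohort['n_cases']} cases, "
      f"mean age {cohort['age']['mean']:.1f}, "
      f"median TTO {cohort['time_to_onset_days']['median']:.0f} d, "
      f"continents {cohort['continent_pct']}")
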