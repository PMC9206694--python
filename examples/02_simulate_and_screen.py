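"""Simulate a reporting database with one planted signal and screen it.

Draws 20 000 synthetic case safety reports in which one drug ("hotdrug")
carries a planted relative reporting rate of 8 for hyperammonaemia against
15 null drugs, then screens every drug.  The planted drug should surface
with 2^IC near 8 and IC_025 > 0; null drugs should not.
"""

from pvscreen import (
    DrugSpec,
    GeneratorConfig,
    HYPERAMMONAEMIA_EVENT,
    generate_database,
    screen_all_drugs,
)

catalog = tuple(
    [DrugSpec("HOT", drug_name="hotdrug", popularity_weight=3.0, rr_event=8.0)]
    + [DrugSpec(f"N{i:02d}", popularity_weight=97.0 / 15) for i in range(15)]
)
config = GeneratorConfig(
    n_cases=20_000, drug_catalog=catalog, p0=0.01,
    mean_extra_drugs=0.3, seed=11,
)
db, truth = generate_database(config)
print(f"simulated {db.n_total} cases; ground truth:")
print(truth.head(3).to_string(index=False))

rows = screen_all_drugs(db, HYPERAMMONAEMIA_EVENT)
print("\ndrug       O     E      IC   IC025  signal")
for r in rows[:5]:
    print(
        f"{r.drug_name:8} {r.counts.n_observed:3d} {r.counts.expected:6.1f} "
        f"{r.ic.ic:6.2f} {r.ic.ic025:6.2f}   {r.ic.significant}"
    )
# O is the observed drug+event case count, E the count expected under
# independent reporting; only the planted drug should exceed its E by far.
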