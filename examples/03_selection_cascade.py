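"""The three-stage drug exclusion cascade on the calibration database.

Builds the packaged calibration fixture (30 000 reports, 642 drugs with at
least one hyperammonaemia case) and runs significance -> single-country ->
protopathic exclusion, printing the tally of each stage.
"""

from pvscreen import (
    ExclusionConfig,
    HYPERAMMONAEMIA_EVENT,
    apply_exclusions,
    calibration_fixture,
    screen_all_drugs,
)

db, _ = calibration_fixture(seed=1)
screen = screen_all_drugs(db, HYPERAMMONAEMIA_EVENT)
retained, excluded = apply_exclusions(screen, db, HYPERAMMONAEMIA_EVENT, ExclusionConfig())

reasons = [r.exclusion_reason for r in excluded]
print(f"drugs with >= 1 event case : {len(screen)}")
print(f"  excluded not_significant : {reasons.count('not_significant')}")
print(f"  excluded single_country  : {reasons.count('single_country')}")
print(f"  excluded protopathic     : {reasons.count('protopathic')}")
print(f"  retained for analysis    : {len(retained)}")

print("\nprotopathic exclusions (drugs that treat the event, reverse causation):")
for r in excluded:
    if r.exclusion_reason == "protopathic":
        print(f"  {r.drug_name}  (IC_025 = {r.ic.ic025:.2f})")
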