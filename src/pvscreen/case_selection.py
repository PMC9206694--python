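"""Target-event definition, case selection and the drug exclusion cascade.

The target adverse event is defined by an explicit set of MedDRA preferred
terms (no hierarchy expansion); the default is the hyperammonaemia PT set.
A *case* is any report carrying at least one event PT; every other report is
a non-case.  Only drugs reported as suspect or interacting enter the
analysis — concomitant mentions are never counted.

After screening, drugs are excluded in three ordered stages, each drug
tagged with the first applicable reason:

1. ``not_significant`` — IC_025 <= 0;
2. ``single_country`` — all of the drug's event cases share one country
   (a drug with exactly one event case is single-country by construction);
3. ``protopathic`` — the drug name is on the configured list of drugs used
   to treat the event itself (reverse-causation bias), matched by
   normalised name.

The stage order matters for the stage tallies and is fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .icsr_model import (
    CaseReport,
    ReportDatabase,
    Role,
    normalize_drug_name,
    normalize_pt,
)

__all__ = [
    "EventDefinition",
    "ExclusionConfig",
    "HYPERAMMONAEMIA_EVENT",
    "DEFAULT_PROTOPATHIC_DRUGS",
    "select_cases",
    "eligible_drugs",
    "drugs_with_event",
    "apply_exclusions",
]


@dataclass(frozen=True)
class EventDefinition:
    """A named adverse event as an explicit PT set (normalisation-insensitive)."""

    name: str
    pts: frozenset[str]

    def __post_init__(self) -> None:
        if not self.pts:
            raise ValueError("event definition needs a non-empty PT set")

    @property
    def normalized_pts(self) -> frozenset[str]:
        return frozenset(normalize_pt(p) for p in self.pts)

    def matches(self, case: CaseReport) -> bool:
        return bool(self.normalized_pts & case.normalized_pts)


#: Default target event: the three hyperammonaemia preferred terms.
HYPERAMMONAEMIA_EVENT = EventDefinition(
    name="hyperammonaemia",
    pts=frozenset(
        ["Hyperammonaemia", "Hyperammonaemic encephalopathy", "Hyperammonaemic crisis"]
    ),
)

#: Drugs used to treat hyperammonaemia (or its precursors): reporting them
#: with the event reflects treatment, not causation, so they are excluded
#: as protopathic by default.
DEFAULT_PROTOPATHIC_DRUGS = frozenset(
    [
        "lactulose",
        "rifaximin",
        "sodium phenylbutyrate",
        "benzoic acid",
        "carglumic acid",
    ]
)


@dataclass(frozen=True)
class ExclusionConfig:
    """Knobs for the exclusion cascade (significance is never optional)."""

    protopathic_drugs: frozenset[str] = DEFAULT_PROTOPATHIC_DRUGS
    single_country_rule: bool = True

    @property
    def normalized_protopathic(self) -> frozenset[str]:
        return frozenset(normalize_drug_name(d) for d in self.protopathic_drugs)


def select_cases(db: ReportDatabase, event: EventDefinition) -> frozenset[str]:
    """Case ids of reports carrying at least one event PT (each counted once)."""
    return frozenset(c.case_id for c in db.cases if event.matches(c))


def eligible_drugs(case: CaseReport) -> frozenset[str]:
    """Drug ids analysed in this case: suspect or interacting roles only."""
    return frozenset(
        d.drug_id for d in case.drugs if d.role in (Role.SUSPECT, Role.INTERACTING)
    )


def drugs_with_event(
    db: ReportDatabase, event: EventDefinition
) -> dict[str, frozenset[str]]:
    """Map of drug id -> event case ids where the drug is suspect/interacting.

    Keys are exactly the drugs eligible in at least one selected case.
    """
    selected = select_cases(db, event)
    out: dict[str, set[str]] = {}
    for case in db.cases:
        if case.case_id not in selected:
            continue
        for drug_id in eligible_drugs(case):
            out.setdefault(drug_id, set()).add(case.case_id)
    return {d: frozenset(s) for d, s in out.items()}


def apply_exclusions(
    screen: list,
    db: ReportDatabase,
    event: EventDefinition,
    config: ExclusionConfig = ExclusionConfig(),
) -> tuple[list, list]:
    """Partition screened drugs into (retained, excluded-with-reason).

    Stages run in the fixed order significance -> single-country ->
    protopathic; each excluded drug carries the first applicable reason in
    its ``exclusion_reason`` field.  ``retained + excluded`` is always a
    partition of the input.
    """
    from dataclasses import replace

    case_country = {c.case_id: c.country for c in db.cases}
    proto = config.normalized_protopathic

    retained = []
    excluded = []
    for row in screen:
        reason = None
        if not row.ic.significant:
            reason = "not_significant"
        elif config.single_country_rule and len(
            {case_country[cid] for cid in row.event_case_ids}
        ) == 1:
            reason = "single_country"
        elif normalize_drug_name(row.drug_name) in proto:
            reason = "protopathic"
        if reason is None:
            retained.append(row)
        else:
            excluded.append(replace(row, exclusion_reason=reason))
    return retained, excluded
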