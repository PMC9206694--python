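"""Case-level causality and clinical annotation.

Two gradings from the French pharmacovigilance method are implemented:

* **Informativity (NI0–NI2)** of a (case, drug) pair: NI2 when both the
  time to onset and the discontinuation of the drug are described, NI1 when
  exactly one is, NI0 when neither.  "Discontinuation described" is
  operationalised as ``action_taken == withdrawn`` (dose reduction does not
  qualify).

* **Extrinsic imputability (B1–B4)** of a drug: B4 when the effect is in
  the product label (summary of product characteristics), else B3 when
  widely published in reference databases/books, else B2 when case reports
  exist in the literature, else B1.  The underlying label knowledge is a
  user-supplied table; a curated default for hyperammonaemia (EMA/FDA
  labels as of 2021-02-01) ships with the package.

Clinical presentation is annotated by matching the case's co-reported PTs
against a configurable phenotype vocabulary (five neurological presentation
categories plus liver- and kidney-dysfunction flags); the event-definition
PTs themselves never count as presentation.  A case is *serious* when it
carries at least one of the six regulatory outcome categories.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

from .case_selection import EventDefinition
from .icsr_model import (
    ActionTaken,
    CaseReport,
    normalize_drug_name,
    normalize_pt,
)

__all__ = [
    "Informativity",
    "Imputability",
    "PhenotypeMap",
    "LabelKnowledge",
    "PRESENTATION_CATEGORIES",
    "default_phenotype_map",
    "default_label_knowledge",
    "load_phenotype_map",
    "load_label_knowledge",
    "informativity",
    "extrinsic_imputability",
    "classify_presentation",
    "is_serious",
]


class Informativity(str, enum.Enum):
    NI0 = "NI0"
    NI1 = "NI1"
    NI2 = "NI2"


class Imputability(str, enum.Enum):
    B1 = "B1"
    B2 = "B2"
    B3 = "B3"
    B4 = "B4"


#: The five main presentation categories plus the two organ-dysfunction flags.
PRESENTATION_CATEGORIES = (
    "coma_altered_consciousness",
    "brain_oedema",
    "seizures",
    "neuropsychiatric",
    "misc_neurological",
    "liver_dysfunction",
    "kidney_dysfunction",
)


@dataclass(frozen=True)
class PhenotypeMap:
    """Category -> PT vocabulary used to classify clinical presentation."""

    category_pts: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        unknown = set(self.category_pts) - set(PRESENTATION_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown presentation categories: {sorted(unknown)}")
        object.__setattr__(
            self,
            "_normalized",
            {
                cat: frozenset(normalize_pt(p) for p in pts)
                for cat, pts in self.category_pts.items()
            },
        )

    def normalized(self) -> dict[str, frozenset[str]]:
        return self._normalized  # type: ignore[attr-defined]


@dataclass(frozen=True)
class LabelKnowledge:
    """Per-drug published-evidence flags, keyed by normalised drug name.

    An absent drug means all flags false (never published -> B1).
    """

    entries: dict[str, tuple[bool, bool, bool]]  # (in_label, widely_published, case_reports)

    def flags(self, drug_name: str) -> tuple[bool, bool, bool]:
        return self.entries.get(normalize_drug_name(drug_name), (False, False, False))


def _data_path(name: str):
    return resources.files("pvscreen").joinpath("data", name)


def load_phenotype_map(path) -> PhenotypeMap:
    """Read a two-column ``category,pt`` CSV into a :class:`PhenotypeMap`."""
    cats: dict[str, set[str]] = {}
    with open(path, newline="") as f:
        reader = csv.DictReader(f)
        if reader.fieldnames != ["category", "pt"]:
            raise ValueError(
                f"phenotype map must have header category,pt; got {reader.fieldnames}"
            )
        for row in reader:
            cats.setdefault(row["category"], set()).add(row["pt"])
    return PhenotypeMap({c: frozenset(p) for c, p in cats.items()})


def load_label_knowledge(path) -> LabelKnowledge:
    """Read ``drug_name,in_label,widely_published,case_reports_published`` CSV."""

    def as_bool(tok: str) -> bool:
        return tok.strip().lower() in ("1", "true", "yes")

    entries = {}
    with open(path, newline="") as f:
        for row in csv.DictReader(f):
            entries[normalize_drug_name(row["drug_name"])] = (
                as_bool(row["in_label"]),
                as_bool(row["widely_published"]),
                as_bool(row["case_reports_published"]),
            )
    return LabelKnowledge(entries)


def default_phenotype_map() -> PhenotypeMap:
    """Packaged presentation vocabulary (config-overridable, not a licensed
    MedDRA subset — a documented working vocabulary for the seven categories)."""
    with resources.as_file(_data_path("phenotype_map.csv")) as p:
        return load_phenotype_map(p)


def default_label_knowledge() -> LabelKnowledge:
    """Packaged label-knowledge table for hyperammonaemia."""
    with resources.as_file(_data_path("label_knowledge.csv")) as p:
        return load_label_knowledge(p)


def informativity(case: CaseReport, drug_id: str) -> Informativity:
    """NI level of one (case, drug) pair.

    Raises ``KeyError`` when the drug is not mentioned in the case.
    """
    entry = next((d for d in case.drugs if d.drug_id == drug_id), None)
    if entry is None:
        raise KeyError(f"drug {drug_id!r} not in case {case.case_id!r}")
    has_tto = entry.time_to_onset_days is not None
    has_discontinuation = entry.action_taken == ActionTaken.WITHDRAWN
    n = int(has_tto) + int(has_discontinuation)
    return (Informativity.NI0, Informativity.NI1, Informativity.NI2)[n]


def extrinsic_imputability(drug_name: str, knowledge: LabelKnowledge) -> Imputability:
    """B level of a drug under the precedence B4 > B3 > B2 > B1."""
    in_label, widely, case_reports = knowledge.flags(drug_name)
    if in_label:
        return Imputability.B4
    if widely:
        return Imputability.B3
    if case_reports:
        return Imputability.B2
    return Imputability.B1


def classify_presentation(
    case: CaseReport,
    phenotype_map: PhenotypeMap,
    event: Optional[EventDefinition] = None,
) -> frozenset[str]:
    """Presentation categories whose vocabulary intersects the case's PTs.

    Event-definition PTs are excluded from matching so the defining event
    never counts as its own presentation.
    """
    pts = case.normalized_pts
    if event is not None:
        pts = pts - event.normalized_pts
    return frozenset(
        cat for cat, vocab in phenotype_map.normalized().items() if vocab & pts
    )


def is_serious(case: CaseReport) -> bool:
    """Serious = at least one regulatory outcome category reported."""
    return bool(case.outcomes)
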