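"""Per-drug analytical tables, cohort descriptives and pipeline orchestration.

All statistics follow the available-case convention: the denominator of
every percentage is the number of the drug's event cases in which the field
is actually observed (missing ages do not count as zero; an unknown action
is missing for the interruption percentage).  Denominators are reported
alongside so missing-data accounting is explicit.

:func:`run_pipeline` chains generation/loading -> case selection -> IC
screening -> exclusion cascade -> scoring -> summaries, and writes a fixed
set of machine-readable outputs (``screen.csv``, ``retained.csv``,
``excluded.csv``, ``drug_summaries.csv``, ``cohort.json``, ``run_log.json``)
that are byte-identical across reruns on the same inputs.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
import statistics
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import __version__
from .case_selection import (
    EventDefinition,
    ExclusionConfig,
    HYPERAMMONAEMIA_EVENT,
    apply_exclusions,
    eligible_drugs,
    select_cases,
)
from .disproportionality import DrugScreenRow, screen_all_drugs
from .icsr_model import (
    ActionTaken,
    CaseReport,
    ReportDatabase,
    Role,
    Sex,
    read_database,
)
from .scoring import (
    Imputability,
    Informativity,
    LabelKnowledge,
    PhenotypeMap,
    classify_presentation,
    default_label_knowledge,
    default_phenotype_map,
    extrinsic_imputability,
    informativity,
    load_label_knowledge,
    load_phenotype_map,
)
from .synthetic_data import GeneratorConfig, generate_database

__all__ = [
    "DrugSummaryRow",
    "EmptyCohortError",
    "PipelineConfig",
    "summarize_drug",
    "cohort_summary",
    "run_pipeline",
    "continent_of",
]

#: Main presentation categories reported in the per-drug profile.
_MAIN_CATEGORIES = (
    "coma_altered_consciousness",
    "brain_oedema",
    "seizures",
    "neuropsychiatric",
    "misc_neurological",
)


class EmptyCohortError(ValueError):
    """Cohort statistics were requested for an empty case set."""


def _load_continents() -> dict[str, str]:
    with resources.as_file(
        resources.files("pvscreen").joinpath("data", "continents.csv")
    ) as p:
        with open(p, newline="") as f:
            return {r["country"]: r["continent"] for r in csv.DictReader(f)}


_CONTINENTS: Optional[dict[str, str]] = None


def continent_of(country: str) -> str:
    """Continent for a two-letter country code (``"unknown"`` if unmapped)."""
    global _CONTINENTS
    if _CONTINENTS is None:
        _CONTINENTS = _load_continents()
    return _CONTINENTS.get(country.upper(), "unknown")


@dataclass(frozen=True)
class DrugSummaryRow:
    """Per-drug clinical summary over the drug's event cases.

    Percentages are on available cases; each map in ``denominators`` gives
    the case count actually used for the matching statistic.
    """

    drug_id: str
    drug_name: str
    n_cases: int
    ic025: float
    age_mean: Optional[float]
    age_min: Optional[float]
    age_max: Optional[float]
    median_tto_days: Optional[float]
    pct_female: Optional[float]
    pct_death: float
    pct_single_suspect: float
    mean_n_suspect: float
    pct_interruption: Optional[float]
    pct_liver: float
    pct_kidney: float
    pct_ni0: float
    imputability: Imputability
    presentation_profile: dict[str, float]
    missingness: dict[str, float]
    denominators: dict[str, int]

    def __post_init__(self) -> None:
        for name in ("pct_female", "pct_death", "pct_single_suspect",
                     "pct_interruption", "pct_liver", "pct_kidney", "pct_ni0"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} outside [0, 100]: {v}")
        if self.age_mean is not None:
            assert self.age_min is not None and self.age_max is not None
            if not self.age_min <= self.age_mean <= self.age_max:
                raise ValueError("age_min <= age_mean <= age_max violated")


def _pct(numer: int, denom: int) -> Optional[float]:
    return None if denom == 0 else 100.0 * numer / denom


def _drug_tto(case: CaseReport, drug_id: str) -> Optional[int]:
    for d in case.drugs:
        if d.drug_id == drug_id and d.time_to_onset_days is not None:
            return d.time_to_onset_days
    return None


def _drug_action(case: CaseReport, drug_id: str) -> ActionTaken:
    withdrawn = False
    known = None
    for d in case.drugs:
        if d.drug_id != drug_id:
            continue
        if d.action_taken == ActionTaken.WITHDRAWN:
            withdrawn = True
        if d.action_taken != ActionTaken.UNKNOWN:
            known = d.action_taken
    if withdrawn:
        return ActionTaken.WITHDRAWN
    return known if known is not None else ActionTaken.UNKNOWN


def summarize_drug(
    db: ReportDatabase,
    event: EventDefinition,
    row: DrugScreenRow,
    knowledge: Optional[LabelKnowledge] = None,
    phenotype_map: Optional[PhenotypeMap] = None,
) -> DrugSummaryRow:
    """Clinical summary of one retained drug over its event cases."""
    if knowledge is None:
        knowledge = default_label_knowledge()
    if phenotype_map is None:
        phenotype_map = default_phenotype_map()
    case_map = db.case_map()
    try:
        cases = sorted(
            (case_map[cid] for cid in row.event_case_ids), key=lambda c: c.case_id
        )
    except KeyError as e:
        raise KeyError(f"screen row references unknown case {e}") from None
    if not cases:
        raise KeyError(f"drug {row.drug_id!r} has no event cases to summarise")

    n = len(cases)
    ages = [c.age_years for c in cases if c.age_years is not None]
    sexes = [c.sex for c in cases if c.sex != Sex.UNKNOWN]
    ttos = [t for c in cases if (t := _drug_tto(c, row.drug_id)) is not None]
    actions = [
        a for c in cases if (a := _drug_action(c, row.drug_id)) != ActionTaken.UNKNOWN
    ]
    n_withdrawn = sum(1 for a in actions if a == ActionTaken.WITHDRAWN)
    n_death = sum(1 for c in cases if "death" in c.outcomes)
    n_single = sum(1 for c in cases if eligible_drugs(c) == {row.drug_id})
    mean_n_suspect = sum(len(eligible_drugs(c)) for c in cases) / n
    presentations = [classify_presentation(c, phenotype_map, event) for c in cases]
    n_liver = sum(1 for p in presentations if "liver_dysfunction" in p)
    n_kidney = sum(1 for p in presentations if "kidney_dysfunction" in p)
    n_ni0 = sum(
        1 for c in cases if informativity(c, row.drug_id) == Informativity.NI0
    )

    return DrugSummaryRow(
        drug_id=row.drug_id,
        drug_name=row.drug_name,
        n_cases=n,
        ic025=row.ic.ic025,
        age_mean=statistics.fmean(ages) if ages else None,
        age_min=min(ages) if ages else None,
        age_max=max(ages) if ages else None,
        median_tto_days=float(statistics.median(ttos)) if ttos else None,
        pct_female=_pct(sum(1 for s in sexes if s == Sex.FEMALE), len(sexes)),
        pct_death=100.0 * n_death / n,
        pct_single_suspect=100.0 * n_single / n,
        mean_n_suspect=mean_n_suspect,
        pct_interruption=_pct(n_withdrawn, len(actions)),
        pct_liver=100.0 * n_liver / n,
        pct_kidney=100.0 * n_kidney / n,
        pct_ni0=100.0 * n_ni0 / n,
        imputability=extrinsic_imputability(row.drug_name, knowledge),
        presentation_profile={
            cat: 100.0 * sum(1 for p in presentations if cat in p) / n
            for cat in _MAIN_CATEGORIES
        },
        missingness={
            "age_years": 100.0 * (n - len(ages)) / n,
            "sex": 100.0 * (n - len(sexes)) / n,
            "time_to_onset_days": 100.0 * (n - len(ttos)) / n,
            "action_taken": 100.0 * (n - len(actions)) / n,
        },
        denominators={
            "age_years": len(ages),
            "sex": len(sexes),
            "time_to_onset_days": len(ttos),
            "action_taken": len(actions),
            "cases": n,
        },
    )


def cohort_summary(db: ReportDatabase, case_ids) -> dict:
    """Cohort-level descriptives over a set of case ids.

    Per-case time to onset is the smallest observed delay among the case's
    suspect/interacting drugs (the earliest implicated exposure).
    """
    case_map = db.case_map()
    cases = sorted((case_map[cid] for cid in case_ids), key=lambda c: c.case_id)
    if not cases:
        raise EmptyCohortError("cohort_summary needs a non-empty case set")

    ages = [c.age_years for c in cases if c.age_years is not None]
    sexes = [c.sex for c in cases if c.sex != Sex.UNKNOWN]

    ttos = []
    for c in cases:
        vals = [
            d.time_to_onset_days
            for d in c.drugs
            if d.role in (Role.SUSPECT, Role.INTERACTING)
            and d.time_to_onset_days is not None
        ]
        if vals:
            ttos.append(min(vals))

    countries: dict[str, int] = {}
    continents: dict[str, int] = {}
    decades: dict[str, int] = {}
    for c in cases:
        countries[c.country] = countries.get(c.country, 0) + 1
        cont = continent_of(c.country)
        continents[cont] = continents.get(cont, 0) + 1
        decade = f"{c.report_year // 10 * 10}s"
        decades[decade] = decades.get(decade, 0) + 1

    n = len(cases)
    out: dict = {
        "n_cases": n,
        "age": {
            "n": len(ages),
            "mean": statistics.fmean(ages) if ages else None,
            "sd": statistics.stdev(ages) if len(ages) > 1 else None,
            "min": min(ages) if ages else None,
            "max": max(ages) if ages else None,
        },
        "sex": {
            "n": len(sexes),
            "pct_male": _pct(sum(1 for s in sexes if s == Sex.MALE), len(sexes)),
            "pct_female": _pct(sum(1 for s in sexes if s == Sex.FEMALE), len(sexes)),
        },
        "time_to_onset_days": {
            "n": len(ttos),
            "median": float(statistics.median(ttos)) if ttos else None,
            "iqr": (
                [float(np.percentile(ttos, 25)), float(np.percentile(ttos, 75))]
                if ttos
                else None
            ),
            "min": min(ttos) if ttos else None,
            "max": max(ttos) if ttos else None,
        },
        "pct_serious": 100.0 * sum(1 for c in cases if c.outcomes) / n,
        "countries": dict(sorted(countries.items())),
        "continent_pct": {
            k: 100.0 * v / n for k, v in sorted(continents.items())
        },
        "cases_per_decade": dict(sorted(decades.items())),
    }
    return out


# ---------------------------------------------------------------------------
# pipeline

@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end run configuration.

    Exactly one of ``db_path`` (load an existing database) or ``generator``
    (simulate one) must be set.
    """

    out_dir: Union[str, Path]
    db_path: Optional[Union[str, Path]] = None
    dialect: str = "csv_relational"
    generator: Optional[GeneratorConfig] = None
    event: EventDefinition = HYPERAMMONAEMIA_EVENT
    exclusions: ExclusionConfig = ExclusionConfig()
    knowledge_path: Optional[Union[str, Path]] = None
    phenotype_path: Optional[Union[str, Path]] = None

    def validate(self) -> None:
        if (self.db_path is None) == (self.generator is None):
            raise ValueError("set exactly one of db_path or generator")
        if not self.event.pts:
            raise ValueError("event definition has an empty PT list")


def _round(v, nd: int = 4):
    return None if v is None else round(float(v), nd)


def _screen_csv_rows(rows: list[DrugScreenRow]) -> list[dict]:
    out = []
    for r in rows:
        out.append(
            {
                "drug_id": r.drug_id,
                "drug_name": r.drug_name,
                "n_observed": r.counts.n_observed,
                "n_drug": r.counts.n_drug,
                "n_effect": r.counts.n_effect,
                "n_total": r.counts.n_total,
                "expected": _round(r.counts.expected, 6),
                "ic": _round(r.ic.ic, 6),
                "ic025": _round(r.ic.ic025, 6),
                "ic975": _round(r.ic.ic975, 6),
                "significant": r.ic.significant,
                "exclusion_reason": r.exclusion_reason or "",
            }
        )
    return out


def _write_csv(path: Path, rows: list[dict]) -> None:
    if not rows:
        path.write_text("")
        return
    with open(path, "w", newline="") as f:
        w = csv.DictWriter(f, fieldnames=list(rows[0]))
        w.writeheader()
        w.writerows(rows)


def _summary_csv_row(s: DrugSummaryRow) -> dict:
    row = {
        "drug_id": s.drug_id,
        "drug_name": s.drug_name,
        "n_cases": s.n_cases,
        "ic025": _round(s.ic025, 6),
        "age_mean": _round(s.age_mean, 1),
        "age_min": _round(s.age_min, 1),
        "age_max": _round(s.age_max, 1),
        "median_tto_days": _round(s.median_tto_days, 1),
        "pct_female": _round(s.pct_female, 1),
        "pct_death": _round(s.pct_death, 1),
        "pct_single_suspect": _round(s.pct_single_suspect, 1),
        "mean_n_suspect": _round(s.mean_n_suspect, 2),
        "pct_interruption": _round(s.pct_interruption, 1),
        "pct_liver": _round(s.pct_liver, 1),
        "pct_kidney": _round(s.pct_kidney, 1),
        "pct_ni0": _round(s.pct_ni0, 1),
        "imputability": s.imputability.value,
    }
    for cat in _MAIN_CATEGORIES:
        row[f"pct_{cat}"] = _round(s.presentation_profile[cat], 1)
    for fld, v in sorted(s.missingness.items()):
        row[f"pct_missing_{fld}"] = _round(v, 1)
    for fld, v in sorted(s.denominators.items()):
        row[f"n_{fld}"] = v
    return row


def run_pipeline(config: PipelineConfig) -> Path:
    """Run select -> screen -> exclude -> score -> summarise and write outputs.

    Returns the output directory.  Outputs are deterministic for fixed
    inputs, so a rerun produces byte-identical files.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.generator is not None:
        db, truth = generate_database(config.generator)
        truth.to_csv(out / "ground_truth.csv", index=False)
        seed: Optional[int] = config.generator.seed
    else:
        db = read_database(config.db_path, config.dialect)
        seed = None

    knowledge = (
        load_label_knowledge(config.knowledge_path)
        if config.knowledge_path
        else default_label_knowledge()
    )
    phenotype_map = (
        load_phenotype_map(config.phenotype_path)
        if config.phenotype_path
        else default_phenotype_map()
    )

    screen = screen_all_drugs(db, config.event)
    retained, excluded = apply_exclusions(screen, db, config.event, config.exclusions)

    _write_csv(out / "screen.csv", _screen_csv_rows(retained + excluded))
    _write_csv(out / "retained.csv", _screen_csv_rows(retained))
    _write_csv(out / "excluded.csv", _screen_csv_rows(excluded))

    summaries = [
        summarize_drug(db, config.event, r, knowledge, phenotype_map)
        for r in retained
    ]
    _write_csv(out / "drug_summaries.csv", [_summary_csv_row(s) for s in summaries])

    retained_case_ids = sorted(set().union(*[r.event_case_ids for r in retained])) if retained else []
    cohort = (
        cohort_summary(db, retained_case_ids) if retained_case_ids else {"n_cases": 0}
    )
    (out / "cohort.json").write_text(
        json.dumps(cohort, indent=2, sort_keys=True) + "\n"
    )

    # hash the analytical configuration only: the output location must not
    # change the recorded identity of a run
    config_repr = repr(
        dataclasses.replace(config, out_dir="")
    )
    log = {
        "package_version": __version__,
        "config_sha256": hashlib.sha256(config_repr.encode()).hexdigest(),
        "seed": seed,
        "n_total_cases": db.n_total,
        "n_event_cases": len(select_cases(db, config.event)),
        "n_screened_drugs": len(screen),
        "n_retained": len(retained),
        "n_excluded": {
            reason: sum(1 for r in excluded if r.exclusion_reason == reason)
            for reason in ("not_significant", "single_country", "protopathic")
        },
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    return out
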