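"""Synthetic spontaneous-report databases with known ground truth.

Real pharmacovigilance databases are proprietary, so the pipeline is
exercised on simulated ones that emulate their statistical structure: many
drugs with heavily skewed reporting frequencies, multi-drug reports with
co-prescription clustering, rare event preferred terms against a background
of common reactions, per-drug *relative reporting rates* for the target
event (the quantity the information component estimates), demographics,
drug roles, right-skewed times to onset, seriousness outcomes and
missing-completely-at-random field masks.

Generative procedure (fixed; every draw comes from one seeded generator):

1. Each case carries ``k = 1 + Poisson(mean_extra_drugs)`` drugs; with
   probability ``co_class_prob`` all ``k`` are drawn from a single
   therapeutic class (co-prescription clustering), otherwise by popularity
   weight without replacement.
2. The target event occurs with probability
   ``1 - prod_d(1 - clamp(p0 * rr_event_d, 0, 1))`` over the case's drugs —
   per-drug hazards combine independently, which keeps marginal relative
   reporting rates approximately multiplicative at small ``p0``.
3. Event cases receive one event PT (weighted) plus co-reported phenotype
   PTs per ``phenotype_conditional``; non-event cases receive 1–3
   background PTs.
4. Roles: the first drug is always suspect; the rest are
   suspect/interacting/concomitant with probabilities 0.5/0.1/0.4.
5. Demographics, country, report year, per-drug log-normal time to onset
   (rounded to days), action taken, and outcomes (death by the maximum
   ``death_prob`` over the case's drugs) are drawn, then MCAR missingness
   masks are applied.

:func:`calibration_fixture` builds a deterministic database whose drug
catalog is sized so the three-stage exclusion cascade lands on fixed stage
tallies (642 event-associated drugs -> 555 non-significant, 11
single-country, 5 protopathic, 71 retained); the tallies are verified at
build time by running the actual screening pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .icsr_model import (
    ActionTaken,
    CaseReport,
    DrugEntry,
    ReportDatabase,
    Role,
    Sex,
)

__all__ = [
    "DrugSpec",
    "GeneratorConfig",
    "GeneratorConfigError",
    "CalibrationError",
    "default_countries",
    "default_event_pts",
    "default_background_pts",
    "default_phenotype_conditional",
    "default_missingness",
    "generate_database",
    "write_ground_truth",
    "calibration_fixture",
    "CALIBRATION_TALLIES",
]


class GeneratorConfigError(ValueError):
    """Invalid or unsatisfiable generator configuration."""


class CalibrationError(AssertionError):
    """A calibration-fixture stage tally deviated from its target."""


@dataclass(frozen=True)
class DrugSpec:
    """One catalog drug.

    ``rr_event`` is the planted relative reporting rate for the target
    event (1 = null drug); ``popularity_weight`` sets how often the drug is
    reported at all.  ``single_country_override`` forces all of the drug's
    event cases into one country, to exercise the single-country exclusion.
    """

    drug_id: str
    drug_name: Optional[str] = None
    class_label: str = "misc"
    popularity_weight: float = 1.0
    rr_event: float = 1.0
    death_prob: float = 0.05
    tto_log_mean: float = math.log(13.0)
    tto_log_sd: float = 1.0
    single_country_override: Optional[str] = None

    @property
    def name(self) -> str:
        return self.drug_name if self.drug_name is not None else self.drug_id


def default_countries() -> dict[str, float]:
    """Reporting-country weights approximating global continent shares
    (~40% Americas, 34% Europe, 22.5% Asia, small Oceania/Middle East/Africa)."""
    return {
        "US": 0.30, "CA": 0.05, "BR": 0.05,
        "FR": 0.10, "DE": 0.10, "GB": 0.08, "IT": 0.06,
        "JP": 0.12, "CN": 0.06, "KR": 0.045,
        "AU": 0.02, "IL": 0.01, "ZA": 0.005,
    }


def default_event_pts() -> dict[str, float]:
    return {
        "Hyperammonaemia": 0.80,
        "Hyperammonaemic encephalopathy": 0.15,
        "Hyperammonaemic crisis": 0.05,
    }


def default_background_pts() -> dict[str, float]:
    return {
        "Nausea": 3.0, "Vomiting": 2.0, "Rash": 2.0, "Headache": 2.0,
        "Diarrhoea": 1.5, "Pyrexia": 1.5, "Fatigue": 1.5, "Dizziness": 1.0,
        "Pruritus": 1.0, "Dyspnoea": 0.8, "Anaemia": 0.6, "Neutropenia": 0.5,
    }


def default_phenotype_conditional() -> dict[str, float]:
    """Probability of co-reporting a PT of each presentation category,
    given the target event occurred."""
    return {
        "coma_altered_consciousness": 0.40,
        "brain_oedema": 0.05,
        "seizures": 0.15,
        "neuropsychiatric": 0.15,
        "misc_neurological": 0.10,
        "liver_dysfunction": 0.07,
        "kidney_dysfunction": 0.03,
    }


def default_phenotype_pts() -> dict[str, tuple[str, ...]]:
    from .scoring import default_phenotype_map

    return {
        cat: tuple(sorted(pts))
        for cat, pts in default_phenotype_map().category_pts.items()
    }


def default_missingness() -> dict[str, float]:
    return {
        "age_years": 0.15,
        "sex": 0.05,
        "time_to_onset_days": 0.35,
        "action_taken": 0.20,
    }


_ROLE_PROBS = ((Role.SUSPECT, 0.5), (Role.INTERACTING, 0.1), (Role.CONCOMITANT, 0.4))
_ACTION_PROBS = (
    (ActionTaken.WITHDRAWN, 0.45),
    (ActionTaken.DOSE_REDUCED, 0.10),
    (ActionTaken.CONTINUED, 0.25),
    (ActionTaken.UNKNOWN, 0.20),
)
# independent per-outcome probabilities other than death
_OUTCOME_PROBS = (
    ("hospitalisation", 0.25),
    ("life_threatening", 0.08),
    ("other_important", 0.20),
    ("disabling", 0.02),
    ("congenital", 0.001),
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of one synthetic database draw."""

    n_cases: int
    drug_catalog: tuple[DrugSpec, ...]
    event_pts: dict[str, float] = field(default_factory=default_event_pts)
    background_pts: dict[str, float] = field(default_factory=default_background_pts)
    p0: float = 0.005
    mean_extra_drugs: float = 0.8
    co_class_prob: float = 0.2
    phenotype_conditional: dict[str, float] = field(
        default_factory=default_phenotype_conditional
    )
    phenotype_pts: dict[str, tuple[str, ...]] = field(
        default_factory=default_phenotype_pts
    )
    missingness: dict[str, float] = field(default_factory=default_missingness)
    countries: dict[str, float] = field(default_factory=default_countries)
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases < 1:
            raise GeneratorConfigError("n_cases must be >= 1")
        if not self.drug_catalog:
            raise GeneratorConfigError("drug_catalog must be non-empty")
        if not 0.0 < self.p0 < 1.0:
            raise GeneratorConfigError("p0 must be in (0, 1)")
        if self.mean_extra_drugs < 0:
            raise GeneratorConfigError("mean_extra_drugs must be >= 0")
        if not 0.0 <= self.co_class_prob <= 1.0:
            raise GeneratorConfigError("co_class_prob must be in [0, 1]")
        for d in self.drug_catalog:
            if d.popularity_weight <= 0:
                raise GeneratorConfigError(f"{d.drug_id}: popularity_weight <= 0")
            if d.rr_event <= 0:
                raise GeneratorConfigError(f"{d.drug_id}: rr_event <= 0")
            if not 0.0 <= d.death_prob <= 1.0:
                raise GeneratorConfigError(f"{d.drug_id}: death_prob outside [0, 1]")
            if d.tto_log_sd <= 0:
                raise GeneratorConfigError(f"{d.drug_id}: tto_log_sd <= 0")
        ids = [d.drug_id for d in self.drug_catalog]
        if len(ids) != len(set(ids)):
            raise GeneratorConfigError("duplicate drug_id in catalog")
        for m, p in self.missingness.items():
            if not 0.0 <= p <= 1.0:
                raise GeneratorConfigError(f"missingness[{m}] outside [0, 1]")
        for pm, p in self.phenotype_conditional.items():
            if not 0.0 <= p <= 1.0:
                raise GeneratorConfigError(
                    f"phenotype_conditional[{pm}] outside [0, 1]"
                )
        if not self.event_pts or not self.background_pts or not self.countries:
            raise GeneratorConfigError("event_pts/background_pts/countries empty")


def _weighted_items(d: dict[str, float]) -> tuple[list[str], np.ndarray]:
    keys = list(d)
    w = np.asarray([d[k] for k in keys], dtype=float)
    if np.any(w <= 0):
        raise GeneratorConfigError("weights must be positive")
    return keys, w / w.sum()


def _pick(rng: np.random.Generator, probs) -> object:
    u = rng.random()
    acc = 0.0
    for value, p in probs:
        acc += p
        if u < acc:
            return value
    return probs[-1][0]


def generate_database(
    config: GeneratorConfig,
) -> tuple[ReportDatabase, pd.DataFrame]:
    """Draw one database plus its ground-truth table.

    Returns ``(db, ground_truth)`` where ``ground_truth`` has columns
    ``drug_id, rr_event, n_event_cases`` (the realised count of event cases
    in which the drug is suspect or interacting).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    catalog = config.drug_catalog
    n_drugs = len(catalog)
    pop = np.asarray([d.popularity_weight for d in catalog], dtype=float)
    pop = pop / pop.sum()
    hazard = np.clip(config.p0 * np.asarray([d.rr_event for d in catalog]), 0.0, 1.0)

    classes: dict[str, list[int]] = {}
    for i, d in enumerate(catalog):
        classes.setdefault(d.class_label, []).append(i)
    class_labels = sorted(classes)
    class_w = np.asarray(
        [sum(pop[i] for i in classes[c]) for c in class_labels], dtype=float
    )
    class_w = class_w / class_w.sum()

    country_keys, country_w = _weighted_items(config.countries)
    event_keys, event_w = _weighted_items(config.event_pts)
    bg_keys, bg_w = _weighted_items(config.background_pts)
    miss = config.missingness

    # bulk nuisance draws
    n = config.n_cases
    k_extra = rng.poisson(config.mean_extra_drugs, size=n)
    if np.any(1 + k_extra > n_drugs):
        raise GeneratorConfigError(
            f"a case drew {int(1 + k_extra.max())} drugs but the catalog has "
            f"only {n_drugs}; enlarge the catalog or lower mean_extra_drugs"
        )
    co_flags = rng.random(n) < config.co_class_prob
    ages = np.clip(rng.normal(42.7, 23.5, size=n), 0.0, 93.0)
    sex_u = rng.random(n)
    years = rng.integers(1981, 2021, size=n)
    country_idx = rng.choice(len(country_keys), size=n, p=country_w)
    event_u = rng.random(n)
    event_pt_idx = rng.choice(len(event_keys), size=n, p=event_w)

    cases: list[CaseReport] = []
    n_event_cases = np.zeros(n_drugs, dtype=int)
    pheno_cats = sorted(config.phenotype_conditional)

    for i in range(n):
        k = 1 + int(k_extra[i])
        if co_flags[i] and k > 1:
            # co-prescription cluster: all drugs from one class big enough
            eligible_classes = [c for c in class_labels if len(classes[c]) >= k]
            if eligible_classes:
                cw = np.asarray(
                    [class_w[class_labels.index(c)] for c in eligible_classes]
                )
                label = eligible_classes[
                    int(rng.choice(len(eligible_classes), p=cw / cw.sum()))
                ]
                members = classes[label]
                mw = pop[members] / pop[members].sum()
                drug_idx = [
                    members[j]
                    for j in rng.choice(len(members), size=k, replace=False, p=mw)
                ]
            else:
                drug_idx = list(rng.choice(n_drugs, size=k, replace=False, p=pop))
        elif k == 1:
            drug_idx = [int(rng.choice(n_drugs, p=pop))]
        else:
            drug_idx = list(rng.choice(n_drugs, size=k, replace=False, p=pop))

        p_event = 1.0 - float(np.prod(1.0 - hazard[drug_idx]))
        is_event = event_u[i] < p_event

        # reactions
        pts: set[str] = set()
        if is_event:
            pts.add(event_keys[int(event_pt_idx[i])])
            for cat in pheno_cats:
                if rng.random() < config.phenotype_conditional[cat]:
                    vocab = config.phenotype_pts.get(cat)
                    if vocab:
                        pts.add(vocab[int(rng.integers(len(vocab)))])
        else:
            n_bg = int(rng.integers(1, 4))
            for j in rng.choice(len(bg_keys), size=n_bg, replace=False, p=bg_w):
                pts.add(bg_keys[int(j)])

        # drug entries: first always suspect
        entries = []
        for pos, di in enumerate(drug_idx):
            spec = catalog[di]
            role = Role.SUSPECT if pos == 0 else _pick(rng, _ROLE_PROBS)
            tto: Optional[int] = int(
                round(
                    math.exp(spec.tto_log_mean + spec.tto_log_sd * rng.standard_normal())
                )
            )
            if rng.random() < miss.get("time_to_onset_days", 0.0):
                tto = None
            action = _pick(rng, _ACTION_PROBS)
            if rng.random() < miss.get("action_taken", 0.0):
                action = ActionTaken.UNKNOWN
            entries.append(
                DrugEntry(
                    drug_id=spec.drug_id,
                    drug_name=spec.name,
                    role=role,
                    time_to_onset_days=tto,
                    action_taken=action,
                )
            )

        # outcomes
        outcomes: set[str] = set()
        death_p = max(catalog[di].death_prob for di in drug_idx)
        if is_event and rng.random() < death_p:
            outcomes.add("death")
        for name, p in _OUTCOME_PROBS:
            if rng.random() < p:
                outcomes.add(name)

        age: Optional[float] = round(float(ages[i]), 1)
        if rng.random() < miss.get("age_years", 0.0):
            age = None
        sex = Sex.MALE if sex_u[i] < 0.545 else Sex.FEMALE
        if rng.random() < miss.get("sex", 0.0):
            sex = Sex.UNKNOWN

        country = country_keys[int(country_idx[i])]
        if is_event:
            for pos, di in enumerate(drug_idx):
                if (
                    catalog[di].single_country_override is not None
                    and entries[pos].role in (Role.SUSPECT, Role.INTERACTING)
                ):
                    country = catalog[di].single_country_override
                    break
            for pos, di in enumerate(drug_idx):
                if entries[pos].role in (Role.SUSPECT, Role.INTERACTING):
                    n_event_cases[di] += 1

        cases.append(
            CaseReport(
                case_id=f"C{i + 1:07d}",
                country=country,
                report_year=int(years[i]),
                age_years=age,
                sex=sex,
                drugs=tuple(entries),
                reaction_pts=frozenset(pts),
                outcomes=frozenset(outcomes),
            )
        )

    db = ReportDatabase(
        cases=tuple(cases), provenance=f"synthetic:seed={config.seed}"
    )
    truth = pd.DataFrame(
        {
            "drug_id": [d.drug_id for d in catalog],
            "rr_event": [d.rr_event for d in catalog],
            "n_event_cases": n_event_cases,
        }
    )
    return db, truth


def write_ground_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# calibration fixture

#: Stage tallies the packaged fixture is calibrated to reproduce.
CALIBRATION_TALLIES = {
    "event_drugs": 642,
    "not_significant": 555,
    "single_country": 11,
    "protopathic": 5,
    "retained": 71,
}

_FIXTURE_COUNTRIES = (
    "US", "FR", "JP", "DE", "GB", "CA", "IT", "BR", "CN", "KR", "AU", "IL",
)

_PROTOPATHIC_NAMES = (
    "Lactulose",
    "Rifaximin",
    "Sodium phenylbutyrate",
    "Benzoic acid",
    "Carglumic acid",
)


def _signal_case_counts() -> list[int]:
    """Skewed per-drug event-case counts for the 71 retained drugs."""
    big = [300, 150, 100, 80, 60, 50, 45, 40, 36, 33, 30, 28, 26, 24, 22,
           20, 19, 18, 17, 16, 15, 14, 13, 12, 11, 10]
    small_cycle = [9, 8, 7, 6, 5, 4]
    small = [small_cycle[i % 6] for i in range(71 - len(big))]
    return big + small


def calibration_fixture(
    seed: int = 0,
) -> tuple[ReportDatabase, dict[str, int]]:
    """Deterministic database whose exclusion cascade hits fixed tallies.

    The drug catalog is constructed, not tuned: 555 null drugs carry exactly
    one event case each (a single observed case can never clear the IC_025
    threshold under the gamma bound), 11 drugs carry 4 event cases all from
    one country, 5 drugs carry the protopathic names with multi-country
    positive signals, and 71 drugs carry 4–300 multi-country event cases
    with expected counts kept small (each therefore IC_025 > 0).  The seed
    only drives nuisance fields (demographics, times to onset, outcomes);
    the tallies hold for any seed and are verified here by running the
    screening-and-exclusion pipeline before returning.

    Returns ``(db, expected_tallies)``.
    """
    rng = np.random.default_rng(seed)
    countries = _FIXTURE_COUNTRIES
    event_keys = list(default_event_pts())
    pheno_pts = default_phenotype_pts()
    pheno_cond = default_phenotype_conditional()
    bg_keys = list(default_background_pts())

    cases: list[CaseReport] = []
    counter = [0]

    def next_case_id() -> str:
        counter[0] += 1
        return f"F{counter[0]:07d}"

    def demographics() -> tuple[Optional[float], Sex, int]:
        age: Optional[float] = round(float(np.clip(rng.normal(42.7, 23.5), 0, 93)), 1)
        if rng.random() < 0.15:
            age = None
        sex = Sex.MALE if rng.random() < 0.545 else Sex.FEMALE
        if rng.random() < 0.05:
            sex = Sex.UNKNOWN
        return age, sex, int(rng.integers(1981, 2021))

    def drug_entry(drug_id: str, drug_name: str, role: Role) -> DrugEntry:
        tto: Optional[int] = int(round(math.exp(math.log(13) + rng.standard_normal())))
        if rng.random() < 0.35:
            tto = None
        action = _pick(rng, _ACTION_PROBS)
        return DrugEntry(
            drug_id=drug_id,
            drug_name=drug_name,
            role=role,
            time_to_onset_days=tto,
            action_taken=action,
        )

    def event_case(drug_id: str, drug_name: str, country: str, j: int) -> CaseReport:
        age, sex, year = demographics()
        pts = {event_keys[j % len(event_keys)]}
        for cat in sorted(pheno_cond):
            if rng.random() < pheno_cond[cat]:
                vocab = pheno_pts[cat]
                pts.add(vocab[int(rng.integers(len(vocab)))])
        entries = [drug_entry(drug_id, drug_name, Role.SUSPECT)]
        if rng.random() < 0.3:  # concomitant co-medication never enters counts
            entries.append(
                drug_entry(f"BG{int(rng.integers(160)) + 1:03d}", "comed", Role.CONCOMITANT)
            )
        outcomes: set[str] = set()
        if rng.random() < 0.12:
            outcomes.add("death")
        if rng.random() < 0.30:
            outcomes.add("hospitalisation")
        if rng.random() < 0.20:
            outcomes.add("other_important")
        return CaseReport(
            case_id=next_case_id(),
            country=country,
            report_year=year,
            age_years=age,
            sex=sex,
            drugs=tuple(entries),
            reaction_pts=frozenset(pts),
            outcomes=frozenset(outcomes),
        )

    def background_case(drug_id: str, drug_name: str) -> CaseReport:
        age, sex, year = demographics()
        pts = {bg_keys[int(j)] for j in rng.choice(len(bg_keys), size=int(rng.integers(1, 4)), replace=False)}
        return CaseReport(
            case_id=next_case_id(),
            country=countries[int(rng.integers(len(countries)))],
            report_year=year,
            age_years=age,
            sex=sex,
            drugs=(drug_entry(drug_id, drug_name, Role.SUSPECT),),
            reaction_pts=frozenset(pts),
            outcomes=frozenset(
                o for o, p in _OUTCOME_PROBS if rng.random() < p
            ),
        )

    background_jobs: list[tuple[str, str, int]] = []  # (drug_id, name, n mentions)

    # 555 null drugs: one event case each -> always below the signal threshold
    for i in range(555):
        did = f"N{i + 1:03d}"
        name = f"drug-{did}"
        cases.append(event_case(did, name, countries[i % len(countries)], i))
        background_jobs.append((did, name, 8))

    # 11 significant drugs whose event cases all share one country
    for i in range(11):
        did = f"SC{i + 1:02d}"
        name = f"drug-{did}"
        for j in range(4):
            cases.append(event_case(did, name, countries[i], j))

    # 5 protopathic drugs: significant, multi-country, on the exclusion list
    for i, (pname, n_obs) in enumerate(zip(_PROTOPATHIC_NAMES, (14, 10, 8, 6, 6))):
        did = f"P{i + 1:02d}"
        for j in range(n_obs):
            cases.append(event_case(did, pname, countries[(i + j) % len(countries)], j))

    # 71 genuine signals: multi-country, small expected counts
    for i, n_obs in enumerate(_signal_case_counts()):
        did = f"SIG{i + 1:02d}"
        name = f"drug-{did}"
        for j in range(n_obs):
            cases.append(event_case(did, name, countries[(i + j) % len(countries)], j))
        if n_obs >= 10:  # the frequent drugs also show up in non-event reports
            background_jobs.append((did, name, n_obs))

    for did, name, n_mentions in background_jobs:
        for _ in range(n_mentions):
            cases.append(background_case(did, name))

    # pad with background-only drugs to dilute the event rate
    n_total_target = 30_000
    n_pool = n_total_target - len(cases)
    for j in range(n_pool):
        did = f"BG{j % 160 + 1:03d}"
        cases.append(background_case(did, f"drug-{did}"))

    db = ReportDatabase(
        cases=tuple(cases), provenance=f"calibration_fixture:seed={seed}"
    )

    _verify_calibration(db)
    return db, dict(CALIBRATION_TALLIES)


def _verify_calibration(db: ReportDatabase) -> None:
    """Run the real pipeline and assert each stage tally."""
    from .case_selection import ExclusionConfig, HYPERAMMONAEMIA_EVENT, apply_exclusions
    from .disproportionality import screen_all_drugs

    screen = screen_all_drugs(db, HYPERAMMONAEMIA_EVENT)
    retained, excluded = apply_exclusions(
        screen, db, HYPERAMMONAEMIA_EVENT, ExclusionConfig()
    )
    tallies = {
        "event_drugs": len(screen),
        "not_significant": sum(
            1 for r in excluded if r.exclusion_reason == "not_significant"
        ),
        "single_country": sum(
            1 for r in excluded if r.exclusion_reason == "single_country"
        ),
        "protopathic": sum(1 for r in excluded if r.exclusion_reason == "protopathic"),
        "retained": len(retained),
    }
    for stage, target in CALIBRATION_TALLIES.items():
        if tallies[stage] != target:
            raise CalibrationError(
                f"calibration stage {stage!r}: got {tallies[stage]}, expected {target}"
            )
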