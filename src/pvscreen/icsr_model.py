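"""Domain model and file I/O for individual case safety reports (ICSRs).

A spontaneous reporting database is modelled as a flat collection of
:class:`CaseReport` objects — one per report — each carrying demographics,
one or more drugs with reporter-assigned roles (suspect / interacting /
concomitant), the reported adverse-reaction preferred terms (PTs), and the
regulatory seriousness outcomes.

Two on-disk dialects are supported and round-trip losslessly:

``csv_relational``
    Three tables in one directory — ``reports.csv`` (one row per case),
    ``report_drugs.csv`` (one row per drug mention) and
    ``report_reactions.csv`` (one row per reported PT).  Missing values are
    empty fields, never sentinel numbers.

``jsonl``
    One JSON object per line with nested ``drugs`` / ``reactions`` arrays;
    missing values are absent keys.

PT and drug-name matching throughout the package is case-insensitive after
whitespace normalisation (see :func:`normalize_pt`), because capitalisation
of MedDRA terms and ingredient names varies across reporting sources.
"""

from __future__ import annotations

import csv
import enum
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

__all__ = [
    "Role",
    "ActionTaken",
    "Sex",
    "OUTCOME_CATEGORIES",
    "DrugEntry",
    "CaseReport",
    "ReportDatabase",
    "SchemaError",
    "ValidationError",
    "normalize_pt",
    "normalize_drug_name",
    "read_database",
    "write_database",
]


class SchemaError(ValueError):
    """A file violates the relational schema (orphan rows, missing tables)."""


class ValidationError(ValueError):
    """A field value is outside its domain (bad role/outcome token, bad range)."""


class Role(str, enum.Enum):
    """Reporter-assigned involvement of a drug in a case."""

    SUSPECT = "suspect"
    INTERACTING = "interacting"
    CONCOMITANT = "concomitant"


class ActionTaken(str, enum.Enum):
    """What was done with the drug after the event."""

    WITHDRAWN = "withdrawn"
    DOSE_REDUCED = "dose_reduced"
    CONTINUED = "continued"
    UNKNOWN = "unknown"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


#: The six regulatory seriousness categories a report may carry.
OUTCOME_CATEGORIES = (
    "death",
    "life_threatening",
    "hospitalisation",
    "disabling",
    "congenital",
    "other_important",
)

_WS = re.compile(r"\s+")


def normalize_pt(pt: str) -> str:
    """Canonical form of a preferred term: collapsed whitespace, lower case."""
    return _WS.sub(" ", pt.strip()).lower()


def normalize_drug_name(name: str) -> str:
    """Canonical form of a drug name (same rule as PTs)."""
    return _WS.sub(" ", name.strip()).lower()


@dataclass(frozen=True)
class DrugEntry:
    """One drug mention inside a case report.

    ``time_to_onset_days`` is the delay from first administration of this
    drug to the onset of the reported event; ``None`` means not reported.
    """

    drug_id: str
    drug_name: str
    role: Role
    time_to_onset_days: Optional[int] = None
    action_taken: ActionTaken = ActionTaken.UNKNOWN

    def __post_init__(self) -> None:
        if not self.drug_id:
            raise ValidationError("drug_id must be non-empty")
        if not isinstance(self.role, Role):
            raise ValidationError(f"invalid drug role: {self.role!r}")
        if not isinstance(self.action_taken, ActionTaken):
            raise ValidationError(f"invalid action_taken: {self.action_taken!r}")
        if self.time_to_onset_days is not None and self.time_to_onset_days < 0:
            raise ValidationError(
                f"time_to_onset_days must be >= 0, got {self.time_to_onset_days}"
            )


@dataclass(frozen=True)
class CaseReport:
    """One individual case safety report."""

    case_id: str
    country: str
    report_year: int
    age_years: Optional[float]
    sex: Sex
    drugs: tuple[DrugEntry, ...]
    reaction_pts: frozenset[str]
    outcomes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.case_id:
            raise ValidationError("case_id must be non-empty")
        if not self.drugs:
            raise ValidationError(f"case {self.case_id}: drugs must be non-empty")
        if not self.reaction_pts:
            raise ValidationError(
                f"case {self.case_id}: reaction_pts must be non-empty"
            )
        if self.age_years is not None and not (0 <= self.age_years <= 130):
            raise ValidationError(
                f"case {self.case_id}: age_years outside [0, 130]: {self.age_years}"
            )
        if not isinstance(self.sex, Sex):
            raise ValidationError(f"case {self.case_id}: invalid sex {self.sex!r}")
        bad = set(self.outcomes) - set(OUTCOME_CATEGORIES)
        if bad:
            raise ValidationError(
                f"case {self.case_id}: unknown outcome tokens {sorted(bad)}"
            )

    @property
    def normalized_pts(self) -> frozenset[str]:
        return frozenset(normalize_pt(p) for p in self.reaction_pts)


@dataclass(frozen=True)
class ReportDatabase:
    """An in-memory reporting database: a sequence of validated cases.

    ``provenance`` is free-text metadata (generator seed, file paths); it is
    excluded from equality so a round-tripped database compares equal to the
    original.
    """

    cases: tuple[CaseReport, ...]
    provenance: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        ids = [c.case_id for c in self.cases]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise ValidationError(f"duplicate case_id {dup!r} in database")

    @property
    def n_total(self) -> int:
        return len(self.cases)

    def case_map(self) -> dict[str, CaseReport]:
        return {c.case_id: c for c in self.cases}


# ---------------------------------------------------------------------------
# serialisation helpers

_REPORT_COLS = ["case_id", "country", "report_year", "age_years", "sex", "outcomes"]
_DRUG_COLS = [
    "case_id",
    "drug_id",
    "drug_name",
    "role",
    "time_to_onset_days",
    "action_taken",
]
_REACTION_COLS = ["case_id", "pt"]


def _fmt_age(age: Optional[float]) -> str:
    if age is None:
        return ""
    return repr(float(age))


def _parse_age(tok: str, where: str) -> Optional[float]:
    if tok == "":
        return None
    try:
        return float(tok)
    except ValueError:
        raise ValidationError(f"{where}: invalid age_years {tok!r}") from None


def _parse_enum(cls, tok: str, where: str):
    try:
        return cls(tok)
    except ValueError:
        raise ValidationError(
            f"{where}: invalid {cls.__name__.lower()} token {tok!r}"
        ) from None


def _write_csv(db: ReportDatabase, directory: Path) -> list[Path]:
    directory.mkdir(parents=True, exist_ok=True)
    p_reports = directory / "reports.csv"
    p_drugs = directory / "report_drugs.csv"
    p_reactions = directory / "report_reactions.csv"
    with open(p_reports, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(_REPORT_COLS)
        for c in db.cases:
            w.writerow(
                [
                    c.case_id,
                    c.country,
                    c.report_year,
                    _fmt_age(c.age_years),
                    c.sex.value,
                    "|".join(sorted(c.outcomes)),
                ]
            )
    with open(p_drugs, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(_DRUG_COLS)
        for c in db.cases:
            for d in c.drugs:
                w.writerow(
                    [
                        c.case_id,
                        d.drug_id,
                        d.drug_name,
                        d.role.value,
                        "" if d.time_to_onset_days is None else d.time_to_onset_days,
                        d.action_taken.value,
                    ]
                )
    with open(p_reactions, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(_REACTION_COLS)
        for c in db.cases:
            for pt in sorted(c.reaction_pts):
                w.writerow([c.case_id, pt])
    return [p_reports, p_drugs, p_reactions]


def _read_csv(directory: Path) -> ReportDatabase:
    p_reports = directory / "reports.csv"
    p_drugs = directory / "report_drugs.csv"
    p_reactions = directory / "report_reactions.csv"
    for p in (p_reports, p_drugs, p_reactions):
        if not p.exists():
            raise SchemaError(f"missing table: {p}")

    def rows_of(path: Path, cols: list[str]):
        with open(path, newline="") as f:
            reader = csv.reader(f)
            header = next(reader, None)
            if header != cols:
                raise SchemaError(
                    f"{path.name}: expected header {cols}, got {header}"
                )
            for i, row in enumerate(reader, start=2):
                if len(row) != len(cols):
                    raise SchemaError(f"{path.name} row {i}: wrong column count")
                yield i, dict(zip(cols, row))

    # pass 1: case skeletons, in file order
    order: list[str] = []
    meta: dict[str, dict] = {}
    for i, r in rows_of(p_reports, _REPORT_COLS):
        cid = r["case_id"]
        where = f"reports.csv row {i}"
        if cid in meta:
            raise SchemaError(f"{where}: duplicate case_id {cid!r}")
        try:
            year = int(r["report_year"])
        except ValueError:
            raise ValidationError(f"{where}: invalid report_year {r['report_year']!r}")
        outcomes = frozenset(t for t in r["outcomes"].split("|") if t)
        bad = set(outcomes) - set(OUTCOME_CATEGORIES)
        if bad:
            raise ValidationError(f"{where}: invalid outcome tokens {sorted(bad)}")
        meta[cid] = dict(
            country=r["country"],
            report_year=year,
            age_years=_parse_age(r["age_years"], where),
            sex=_parse_enum(Sex, r["sex"], where),
            outcomes=outcomes,
            drugs=[],
            pts=set(),
        )
        order.append(cid)

    for i, r in rows_of(p_drugs, _DRUG_COLS):
        cid = r["case_id"]
        where = f"report_drugs.csv row {i}"
        if cid not in meta:
            raise SchemaError(f"{where}: drug row for unknown case_id {cid!r}")
        tto = r["time_to_onset_days"]
        if tto == "":
            tto_val: Optional[int] = None
        else:
            try:
                tto_val = int(tto)
            except ValueError:
                raise ValidationError(f"{where}: invalid time_to_onset_days {tto!r}")
        meta[cid]["drugs"].append(
            DrugEntry(
                drug_id=r["drug_id"],
                drug_name=r["drug_name"],
                role=_parse_enum(Role, r["role"], where),
                time_to_onset_days=tto_val,
                action_taken=_parse_enum(ActionTaken, r["action_taken"], where),
            )
        )

    for i, r in rows_of(p_reactions, _REACTION_COLS):
        cid = r["case_id"]
        if cid not in meta:
            raise SchemaError(
                f"report_reactions.csv row {i}: reaction row for unknown case_id {cid!r}"
            )
        meta[cid]["pts"].add(r["pt"])

    cases = []
    for cid in order:
        m = meta[cid]
        if not m["drugs"]:
            raise SchemaError(f"case {cid!r} has no drug rows")
        if not m["pts"]:
            raise SchemaError(f"case {cid!r} has no reaction rows")
        cases.append(
            CaseReport(
                case_id=cid,
                country=m["country"],
                report_year=m["report_year"],
                age_years=m["age_years"],
                sex=m["sex"],
                drugs=tuple(m["drugs"]),
                reaction_pts=frozenset(m["pts"]),
                outcomes=m["outcomes"],
            )
        )
    return ReportDatabase(cases=tuple(cases), provenance=f"csv_relational:{directory}")


def _case_to_json(c: CaseReport) -> dict:
    obj: dict = {
        "case_id": c.case_id,
        "country": c.country,
        "report_year": c.report_year,
        "sex": c.sex.value,
        "outcomes": sorted(c.outcomes),
        "reactions": sorted(c.reaction_pts),
        "drugs": [],
    }
    if c.age_years is not None:
        obj["age_years"] = float(c.age_years)
    for d in c.drugs:
        dd: dict = {
            "drug_id": d.drug_id,
            "drug_name": d.drug_name,
            "role": d.role.value,
            "action_taken": d.action_taken.value,
        }
        if d.time_to_onset_days is not None:
            dd["time_to_onset_days"] = int(d.time_to_onset_days)
        obj["drugs"].append(dd)
    return obj


def _case_from_json(obj: dict, where: str) -> CaseReport:
    try:
        drugs = tuple(
            DrugEntry(
                drug_id=d["drug_id"],
                drug_name=d["drug_name"],
                role=_parse_enum(Role, d["role"], where),
                time_to_onset_days=d.get("time_to_onset_days"),
                action_taken=_parse_enum(
                    ActionTaken, d.get("action_taken", "unknown"), where
                ),
            )
            for d in obj["drugs"]
        )
        return CaseReport(
            case_id=obj["case_id"],
            country=obj["country"],
            report_year=int(obj["report_year"]),
            age_years=obj.get("age_years"),
            sex=_parse_enum(Sex, obj["sex"], where),
            drugs=drugs,
            reaction_pts=frozenset(obj["reactions"]),
            outcomes=frozenset(obj.get("outcomes", [])),
        )
    except KeyError as e:
        raise SchemaError(f"{where}: missing key {e}") from None


def _write_jsonl(db: ReportDatabase, path: Path) -> list[Path]:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as f:
        for c in db.cases:
            f.write(json.dumps(_case_to_json(c), sort_keys=True))
            f.write("\n")
    return [path]


def _read_jsonl(path: Path) -> ReportDatabase:
    if not path.exists():
        raise SchemaError(f"missing file: {path}")
    cases = []
    with open(path) as f:
        for i, line in enumerate(f, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as e:
                raise SchemaError(f"{path.name} line {i}: invalid JSON ({e})") from None
            cases.append(_case_from_json(obj, f"{path.name} line {i}"))
    return ReportDatabase(cases=tuple(cases), provenance=f"jsonl:{path}")


def read_database(path: Union[str, Path], dialect: str = "csv_relational") -> ReportDatabase:
    """Read a reporting database from disk.

    Parameters
    ----------
    path
        For ``csv_relational``, the directory holding the three tables; for
        ``jsonl``, the ``.jsonl`` file.
    dialect
        ``"csv_relational"`` or ``"jsonl"``.

    Raises
    ------
    SchemaError
        Orphan drug/reaction rows, missing tables, cases without drugs or
        reactions.
    ValidationError
        A field token outside its domain (named with its row number).
    """
    path = Path(path)
    if dialect == "csv_relational":
        return _read_csv(path)
    if dialect == "jsonl":
        return _read_jsonl(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_database(
    db: ReportDatabase, path: Union[str, Path], dialect: str = "csv_relational"
) -> list[Path]:
    """Write ``db`` to disk; output is canonical (sorted sets, fixed headers)
    so identical databases produce byte-identical files."""
    path = Path(path)
    if dialect == "csv_relational":
        return _write_csv(db, path)
    if dialect == "jsonl":
        return _write_jsonl(db, path)
    raise ValueError(f"unknown dialect {dialect!r}")
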