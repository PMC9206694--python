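"""Information-component disproportionality statistics and drug screening.

The case/non-case contrast for one drug–event pair is summarised by four
case-level counts:

* ``n_observed`` — cases reporting both the drug (as suspect or interacting)
  and the event,
* ``n_drug`` — cases reporting the drug (suspect/interacting), any reaction,
* ``n_effect`` — cases reporting the event, any drug,
* ``n_total`` — all cases in the database.

Under independent reporting the expected count is
``E = n_drug * n_effect / n_total``.  The information component is the
shrunk log2 observed-to-expected ratio

    IC = log2( (n_observed + 0.5) / (E + 0.5) )

and its credibility bounds come from the Gamma posterior of the shrunk
ratio, with shape ``n_observed + 0.5`` and rate ``E + 0.5``: IC_q is log2 of
the q-quantile of that posterior.  ``IC_025 > 0`` (the lower end of the 95%
credibility interval above zero) is the signal-detection threshold.  The
+0.5 terms act as a prior pulling small-count pairs toward IC = 0, which
makes the statistic deliberately conservative for rare events.

An older normal-approximation interval (IC ± z·sd with the posterior
log-scale standard deviation via the trigamma function) is available through
``method="normal"`` for sensitivity analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from scipy import special, stats

from .case_selection import EventDefinition, drugs_with_event, eligible_drugs, select_cases
from .icsr_model import CaseReport, ReportDatabase, Role

__all__ = [
    "ContingencyCounts",
    "ICResult",
    "DrugScreenRow",
    "information_component",
    "ic_credibility_bound",
    "ic_result",
    "contingency_for",
    "screen_all_drugs",
]

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class ContingencyCounts:
    """Case-level counts for one drug–event pair.

    The expected count is derived (:attr:`expected`), never stored, so the
    four counts stay the single source of truth.
    """

    n_observed: int
    n_drug: int
    n_effect: int
    n_total: int

    def __post_init__(self) -> None:
        if self.n_total < 1:
            raise ValueError("n_total must be >= 1")
        if min(self.n_observed, self.n_drug, self.n_effect) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_observed > min(self.n_drug, self.n_effect):
            raise ValueError(
                f"n_observed ({self.n_observed}) exceeds "
                f"min(n_drug={self.n_drug}, n_effect={self.n_effect})"
            )
        if max(self.n_drug, self.n_effect) > self.n_total:
            raise ValueError("n_drug and n_effect cannot exceed n_total")

    @property
    def expected(self) -> float:
        """E = n_drug * n_effect / n_total."""
        return self.n_drug * self.n_effect / self.n_total


@dataclass(frozen=True)
class ICResult:
    """IC point estimate with 95% credibility bounds (bits)."""

    ic: float
    ic025: float
    ic975: float

    @property
    def significant(self) -> bool:
        """Signal threshold: the credibility interval lies above zero."""
        return self.ic025 > 0.0

    def __post_init__(self) -> None:
        if not (self.ic025 < self.ic < self.ic975):
            raise ValueError(
                f"credibility bounds must bracket the point estimate: "
                f"{self.ic025} < {self.ic} < {self.ic975} violated"
            )


@dataclass(frozen=True)
class DrugScreenRow:
    """One drug's screening record against the target event."""

    drug_id: str
    drug_name: str
    counts: ContingencyCounts
    ic: ICResult
    event_case_ids: frozenset[str]
    exclusion_reason: Optional[str] = None


def information_component(c: ContingencyCounts) -> float:
    """IC point estimate in bits; finite for every valid count vector."""
    return math.log2((c.n_observed + 0.5) / (c.expected + 0.5))


def ic_credibility_bound(
    c: ContingencyCounts, tail: float, method: str = "gamma"
) -> float:
    """Tail-quantile of the IC posterior, in bits.

    ``tail=0.025`` gives IC_025, ``tail=0.975`` gives IC_975.

    ``method="gamma"`` (default) uses the exact Gamma posterior quantile;
    ``method="normal"`` the normal approximation on the log2 scale with
    sd = sqrt(trigamma(n_observed + 0.5)) / ln 2.
    """
    if not 0.0 < tail < 1.0:
        raise ValueError(f"tail must be in (0, 1), got {tail}")
    shape = c.n_observed + 0.5
    rate = c.expected + 0.5
    if method == "gamma":
        q = stats.gamma.ppf(tail, a=shape, scale=1.0 / rate)
        return math.log2(q)
    if method == "normal":
        ic = information_component(c)
        sd = math.sqrt(special.polygamma(1, shape)) / _LN2
        return ic + stats.norm.ppf(tail) * sd
    raise ValueError(f"unknown method {method!r}")


def ic_result(c: ContingencyCounts, method: str = "gamma") -> ICResult:
    """Point estimate plus 95% credibility bounds for one count vector."""
    return ICResult(
        ic=information_component(c),
        ic025=ic_credibility_bound(c, 0.025, method=method),
        ic975=ic_credibility_bound(c, 0.975, method=method),
    )


def contingency_for(
    db: ReportDatabase, event: EventDefinition, drug_id: str
) -> ContingencyCounts:
    """Count the case/non-case contingency for one drug.

    A drug absent from the database (or present only as concomitant) yields
    ``n_observed = n_drug = 0``.
    """
    event_cases = select_cases(db, event)
    n_drug = 0
    n_observed = 0
    for case in db.cases:
        if drug_id in eligible_drugs(case):
            n_drug += 1
            if case.case_id in event_cases:
                n_observed += 1
    return ContingencyCounts(
        n_observed=n_observed,
        n_drug=n_drug,
        n_effect=len(event_cases),
        n_total=db.n_total,
    )


def screen_all_drugs(
    db: ReportDatabase, event: EventDefinition, method: str = "gamma"
) -> list[DrugScreenRow]:
    """Case/non-case screen of every drug with at least one event case.

    Returns one row per drug appearing as suspect or interacting in at least
    one event case, ordered by descending ``n_observed`` then ``drug_id``
    (deterministic).
    """
    event_cases = select_cases(db, event)
    n_total = db.n_total
    n_effect = len(event_cases)

    drug_cases: dict[str, set[str]] = {}
    drug_names: dict[str, str] = {}
    for case in db.cases:
        for d in case.drugs:
            if d.role in (Role.SUSPECT, Role.INTERACTING):
                drug_cases.setdefault(d.drug_id, set()).add(case.case_id)
                drug_names.setdefault(d.drug_id, d.drug_name)

    rows: list[DrugScreenRow] = []
    for drug_id, cset in drug_cases.items():
        ecases = cset & event_cases
        if not ecases:
            continue
        counts = ContingencyCounts(
            n_observed=len(ecases),
            n_drug=len(cset),
            n_effect=n_effect,
            n_total=n_total,
        )
        rows.append(
            DrugScreenRow(
                drug_id=drug_id,
                drug_name=drug_names[drug_id],
                counts=counts,
                ic=ic_result(counts, method=method),
                event_case_ids=frozenset(ecases),
            )
        )
    rows.sort(key=lambda r: (-r.counts.n_observed, r.drug_id))
    return rows
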