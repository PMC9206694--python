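import pytest

from pvscreen import (
    ActionTaken,
    CaseReport,
    DrugEntry,
    ReportDatabase,
    Role,
    Sex,
)


def make_case(
    case_id,
    pts,
    drugs=None,
    country="US",
    year=2015,
    age=40.0,
    sex=Sex.MALE,
    outcomes=(),
):
    if drugs is None:
        drugs = [("D1", "drug one", Role.SUSPECT, 9, ActionTaken.WITHDRAWN)]
    entries = tuple(
        DrugEntry(
            drug_id=d[0],
            drug_name=d[1],
            role=d[2],
            time_to_onset_days=d[3] if len(d) > 3 else None,
            action_taken=d[4] if len(d) > 4 else ActionTaken.UNKNOWN,
        )
        for d in drugs
    )
    return CaseReport(
        case_id=case_id,
        country=country,
        report_year=year,
        age_years=age,
        sex=sex,
        drugs=entries,
        reaction_pts=frozenset(pts),
        outcomes=frozenset(outcomes),
    )


@pytest.fixture
def tiny_db():
    """Four cases: two hyperammonaemia cases, two background reports."""
    cases = (
        make_case(
            "c1",
            ["Hyperammonaemia", "Coma"],
            drugs=[
                ("A", "alphadrug", Role.SUSPECT, 9, ActionTaken.WITHDRAWN),
                ("B", "betadrug", Role.CONCOMITANT, None, ActionTaken.UNKNOWN),
            ],
            outcomes=["death"],
            country="FR",
        ),
        make_case(
            "c2",
            ["Hyperammonaemic crisis"],
            drugs=[
                ("A", "alphadrug", Role.INTERACTING, None, ActionTaken.CONTINUED),
                ("C", "gammadrug", Role.SUSPECT, 3, ActionTaken.WITHDRAWN),
            ],
            country="JP",
        ),
        make_case("c3", ["Nausea"], drugs=[("A", "alphadrug", Role.SUSPECT)]),
        make_case("c4", ["Rash"], drugs=[("B", "betadrug", Role.SUSPECT)]),
    )
    return ReportDatabase(cases=cases)


@pytest.fixture(scope="session")
def fixture_run():
    """Calibration fixture screened once for the whole session."""
    import pvscreen as pv

    db, tallies = pv.calibration_fixture(seed=20)
    screen = pv.screen_all_drugs(db, pv.HYPERAMMONAEMIA_EVENT)
    retained, excluded = pv.apply_exclusions(
        screen, db, pv.HYPERAMMONAEMIA_EVENT, pv.ExclusionConfig()
    )
    return db, tallies, screen, retained, excluded
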