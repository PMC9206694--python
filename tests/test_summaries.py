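"""Per-drug summary rows, cohort descriptives and the end-to-end pipeline."""

import json
import statistics

import pytest

import pvscreen as pv
from pvscreen import (
    ActionTaken,
    DrugSpec,
    GeneratorConfig,
    HYPERAMMONAEMIA_EVENT,
    PipelineConfig,
    ReportDatabase,
    Role,
    cohort_summary,
    run_pipeline,
    screen_all_drugs,
    summarize_drug,
)
from pvscreen.summaries import EmptyCohortError, continent_of

from conftest import make_case


def _event_case(i, **kw):
    kw.setdefault("drugs", [("A", "alphadrug", Role.SUSPECT, 10, ActionTaken.WITHDRAWN)])
    return make_case(f"e{i}", ["Hyperammonaemia"], **kw)


def _db_and_row(cases):
    filler = [
        make_case(f"b{i}", ["Nausea"], drugs=[("BG", "filler", Role.SUSPECT)])
        for i in range(300)
    ]
    db = ReportDatabase(cases=tuple(cases) + tuple(filler))
    row = next(
        r for r in screen_all_drugs(db, HYPERAMMONAEMIA_EVENT) if r.drug_id == "A"
    )
    return db, row


class TestSummarizeDrug:
    def test_death_percentage_direct_ratio(self):
        cases = [
            _event_case(0, outcomes=["death"]),
            _event_case(1),
            _event_case(2),
            _event_case(3),
        ]
        db, row = _db_and_row(cases)
        s = summarize_drug(db, HYPERAMMONAEMIA_EVENT, row)
        assert s.pct_death == 25.0
        assert s.n_cases == 4

    def test_all_tto_missing_propagates_as_missing(self):
        cases = [
            _event_case(i, drugs=[("A", "alphadrug", Role.SUSPECT, None, ActionTaken.WITHDRAWN)])
            for i in range(3)
        ]
        db, row = _db_and_row(cases)
        s = summarize_drug(db, HYPERAMMONAEMIA_EVENT, row)
        assert s.median_tto_days is None
        assert s.missingness["time_to_onset_days"] == 100.0

    def test_available_case_denominators(self):
        cases = [
            _event_case(0, age=30.0, sex=pv.Sex.FEMALE),
            _event_case(1, age=None, sex=pv.Sex.UNKNOWN),
            _event_case(2, age=50.0, sex=pv.Sex.MALE),
        ]
        db, row = _db_and_row(cases)
        s = summarize_drug(db, HYPERAMMONAEMIA_EVENT, row)
        assert s.denominators["age_years"] == 2
        assert s.age_mean == 40.0
        assert s.pct_female == 50.0  # of the two known-sex cases
        assert s.missingness["age_years"] == pytest.approx(100 / 3)

    def test_single_suspect_share_and_mean_suspects(self):
        cases = [
            _event_case(0),
            _event_case(
                1,
                drugs=[
                    ("A", "alphadrug", Role.SUSPECT, 5, ActionTaken.CONTINUED),
                    ("X", "other", Role.INTERACTING, None, ActionTaken.UNKNOWN),
                ],
            ),
        ]
        db, row = _db_and_row(cases)
        s = summarize_drug(db, HYPERAMMONAEMIA_EVENT, row)
        assert s.pct_single_suspect == 50.0
        assert s.mean_n_suspect == 1.5

    def test_interruption_uses_known_actions_only(self):
        cases = [
            _event_case(0),  # withdrawn
            _event_case(1, drugs=[("A", "alphadrug", Role.SUSPECT, 5, ActionTaken.CONTINUED)]),
            _event_case(2, drugs=[("A", "alphadrugs", Role.SUSPECT, 5, ActionTaken.UNKNOWN)]),
        ]
        db, row = _db_and_row(cases)
        s = summarize_drug(db, HYPERAMMONAEMIA_EVENT, row)
        assert s.pct_interruption == 50.0
        assert s.denominators["action_taken"] == 2

    def test_planted_tto_median_matches_order_statistic_oracle(self):
        """A log-normal onset distribution centred on 13 days sampled at
        n≈500 has a sample median inside [9, 18] days (the 0.001–0.999
        order-statistic envelope of the true median)."""
        cfg = GeneratorConfig(
            n_cases=500,
            drug_catalog=(DrugSpec("A", drug_name="alphadrug", rr_event=1.0),),
            p0=0.9999,
            mean_extra_drugs=0.0,
            missingness={"time_to_onset_days": 0.0},
            seed=5,
        )
        db, _ = pv.generate_database(cfg)
        row = next(
            r for r in screen_all_drugs(db, HYPERAMMONAEMIA_EVENT) if r.drug_id == "A"
        )
        s = summarize_drug(db, HYPERAMMONAEMIA_EVENT, row)
        assert s.n_cases > 400
        assert 9 <= s.median_tto_days <= 18


class TestCohortSummary:
    def test_mean_and_range(self):
        cases = [_event_case(0, age=40.0), _event_case(1, age=60.0)]
        db = ReportDatabase(cases=tuple(cases))
        c = cohort_summary(db, {"e0", "e1"})
        assert c["age"]["mean"] == 50.0
        assert (c["age"]["min"], c["age"]["max"]) == (40.0, 60.0)

    def test_tto_median(self):
        cases = [
            _event_case(i, drugs=[("A", "a", Role.SUSPECT, t, ActionTaken.UNKNOWN)])
            for i, t in enumerate([2, 13, 59])
        ]
        db = ReportDatabase(cases=tuple(cases))
        c = cohort_summary(db, {"e0", "e1", "e2"})
        assert c["time_to_onset_days"]["median"] == 13.0

    def test_continent_shares_sum_to_100(self):
        cases = [
            _event_case(i, country=cc)
            for i, cc in enumerate(["US", "FR", "JP", "AU", "BR", "DE"])
        ]
        db = ReportDatabase(cases=tuple(cases))
        c = cohort_summary(db, {f"e{i}" for i in range(6)})
        assert sum(c["continent_pct"].values()) == pytest.approx(100.0)

    def test_age_mean_recomputed_from_raw_cases(self):
        db, _ = pv.generate_database(
            GeneratorConfig(
                n_cases=400,
                drug_catalog=(DrugSpec("A"),),
                p0=0.5,
                mean_extra_drugs=0.0,
                seed=9,
            )
        )
        ids = pv.select_cases(db, HYPERAMMONAEMIA_EVENT)
        c = cohort_summary(db, ids)
        raw = [
            case.age_years
            for case in db.cases
            if case.case_id in ids and case.age_years is not None
        ]
        assert c["age"]["mean"] == pytest.approx(statistics.fmean(raw), abs=1e-9)

    def test_empty_cohort_is_an_error(self, tiny_db):
        with pytest.raises(EmptyCohortError):
            cohort_summary(tiny_db, set())

    def test_continent_lookup(self):
        assert continent_of("us") == "americas"
        assert continent_of("XX") == "unknown"


def _pipeline_generator_config(seed=3):
    catalog = tuple(
        [DrugSpec("HOT", drug_name="Valproic acid", popularity_weight=3, rr_event=15.0)]
        + [DrugSpec(f"D{i:02d}", popularity_weight=2) for i in range(10)]
    )
    return GeneratorConfig(n_cases=4000, drug_catalog=catalog, p0=0.01, seed=seed)


class TestRunPipeline:
    def test_outputs_and_one_summary_row_per_retained_drug(self, tmp_path):
        cfg = PipelineConfig(out_dir=tmp_path, generator=_pipeline_generator_config())
        out = run_pipeline(cfg)
        log = json.loads((out / "run_log.json").read_text())
        n_summary_rows = len(
            (out / "drug_summaries.csv").read_text().strip().splitlines()
        ) - 1
        assert n_summary_rows == log["n_retained"]
        n_screen = len((out / "screen.csv").read_text().strip().splitlines()) - 1
        assert n_screen == log["n_screened_drugs"]
        assert (out / "cohort.json").exists()

    def test_planted_drug_retained_with_b4_imputability(self, tmp_path):
        cfg = PipelineConfig(out_dir=tmp_path, generator=_pipeline_generator_config())
        out = run_pipeline(cfg)
        rows = (out / "drug_summaries.csv").read_text().strip().splitlines()
        hot = next(r for r in rows if r.startswith("HOT,"))
        assert "Valproic acid" in hot
        assert ",B4" in hot

    def test_rerun_is_byte_identical(self, tmp_path):
        a = run_pipeline(
            PipelineConfig(out_dir=tmp_path / "a", generator=_pipeline_generator_config())
        )
        b = run_pipeline(
            PipelineConfig(out_dir=tmp_path / "b", generator=_pipeline_generator_config())
        )
        for f in sorted(p.name for p in a.iterdir()):
            assert (a / f).read_bytes() == (b / f).read_bytes(), f

    def test_config_must_choose_one_source(self, tmp_path):
        with pytest.raises(ValueError):
            PipelineConfig(out_dir=tmp_path).validate()
        with pytest.raises(ValueError):
            PipelineConfig(
                out_dir=tmp_path,
                db_path="somewhere",
                generator=_pipeline_generator_config(),
            ).validate()

    def test_pipeline_reads_database_from_disk(self, tmp_path):
        db, _ = pv.generate_database(_pipeline_generator_config())
        pv.write_database(db, tmp_path / "db", "csv_relational")
        out = run_pipeline(
            PipelineConfig(out_dir=tmp_path / "run", db_path=tmp_path / "db")
        )
        log = json.loads((out / "run_log.json").read_text())
        assert log["n_total_cases"] == 4000
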