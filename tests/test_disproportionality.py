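"""Information-component statistic, credibility bounds and drug screening."""

import math

import numpy as np
import pytest
import sympy

import pvscreen as pv
from pvscreen import (
    ContingencyCounts,
    HYPERAMMONAEMIA_EVENT,
    ICResult,
    ReportDatabase,
    Role,
    contingency_for,
    ic_credibility_bound,
    ic_result,
    information_component,
    screen_all_drugs,
)

from conftest import make_case

# (n_observed, n_drug, n_effect, n_total) grid spanning rare to frequent pairs
GRID = [
    (0, 10, 50, 1000),
    (0, 1500, 500, 100000),
    (1, 100, 100, 10000),
    (1, 10, 10, 100),
    (2, 50, 40, 5000),
    (3, 3, 3, 3),
    (5, 200, 100, 20000),
    (5, 1000, 50, 10000),
    (8, 80, 800, 100000),
    (10, 400, 400, 40000),
    (20, 1000, 200, 100000),
    (25, 50, 100, 1000),
    (50, 5000, 100, 100000),
    (60, 2000, 3000, 1000000),
    (100, 10000, 1000, 500000),
    (150, 200, 1000, 10000),
    (300, 600, 2115, 30000),
    (500, 100000, 5000, 1000000),
    (1000, 2000, 5000, 100000),
    (1722, 2500, 3547, 2000000),
]


class TestInformationComponent:
    def test_zero_when_observed_equals_expected(self):
        c = ContingencyCounts(1, 100, 100, 10000)  # E = 1
        assert information_component(c) == 0.0

    def test_exact_power_of_two(self):
        c = ContingencyCounts(0, 1500, 500, 100000)  # E = 7.5, ratio 0.5/8
        assert information_component(c) == -4.0

    @pytest.mark.parametrize("counts", GRID)
    def test_matches_high_precision_formula(self, counts):
        """The statistic agrees with an exact-rational evaluation of
        log2((O + 1/2) / (Ndrug*Neffect/Ntotal + 1/2))."""
        o, nd, ne, nt = counts
        c = ContingencyCounts(o, nd, ne, nt)
        ratio = sympy.Rational(2 * o + 1, 2) / (
            sympy.Rational(nd, 1) * ne / nt + sympy.Rational(1, 2)
        )
        expected = float(sympy.log(ratio, 2).evalf(30))
        assert information_component(c) == pytest.approx(expected, abs=1e-12)

    def test_increasing_in_observed_at_fixed_margins(self):
        a = ContingencyCounts(10, 1000, 200, 100000)
        b = ContingencyCounts(11, 1000, 200, 100000)
        assert information_component(b) > information_component(a)

    def test_decreasing_in_effect_count(self):
        a = ContingencyCounts(10, 1000, 200, 100000)
        b = ContingencyCounts(10, 1000, 400, 100000)
        assert information_component(b) < information_component(a)


def _mc_bound(counts, tail, n_draws=400_000, seed=11):
    """Independent Monte-Carlo oracle: empirical quantile of the Gamma
    posterior of the shrunk observed/expected ratio, on the log2 scale."""
    rng = np.random.default_rng(seed)
    c = ContingencyCounts(*counts)
    draws = rng.gamma(shape=c.n_observed + 0.5, scale=1.0 / (c.expected + 0.5), size=n_draws)
    return math.log2(np.quantile(draws, tail))


class TestCredibilityBound:
    # grid rows with O >= 2: at smaller shapes the oracle's own quantile
    # noise exceeds the tolerance at this draw count (the acceptance suite
    # covers O in {0, 1} with a proportionally larger oracle)
    @pytest.mark.parametrize("counts", GRID[4:10])
    @pytest.mark.parametrize("tail", [0.025, 0.975])
    def test_gamma_quantile_matches_monte_carlo(self, counts, tail):
        got = ic_credibility_bound(ContingencyCounts(*counts), tail)
        assert got == pytest.approx(_mc_bound(counts, tail), abs=0.02)

    @pytest.mark.parametrize("counts", GRID)
    def test_bounds_bracket_point_estimate(self, counts):
        c = ContingencyCounts(*counts)
        r = ic_result(c)
        assert r.ic025 < r.ic < r.ic975

    def test_doubling_observed_raises_lower_bound(self):
        # same expected count E = 2 in both
        lo1 = ic_credibility_bound(ContingencyCounts(10, 1000, 200, 100000), 0.025)
        lo2 = ic_credibility_bound(ContingencyCounts(20, 1000, 200, 100000), 0.025)
        assert lo2 > lo1

    def test_zero_observed_never_significant(self):
        for nd, ne, nt in [(10, 50, 1000), (1500, 500, 100000), (1, 1000, 10000)]:
            r = ic_result(ContingencyCounts(0, nd, ne, nt))
            assert not r.significant

    def test_large_sample_bound_approaches_log2_rate_ratio(self):
        """At O = 10000 with O/E = 8 the lower bound converges to ~log2(8)."""
        c = ContingencyCounts(10000, 100000, 12500, 1000000)  # E = 1250
        lo = ic_credibility_bound(c, 0.025)
        assert 2.9 <= lo <= 3.0

    def test_invalid_tail_rejected(self):
        with pytest.raises(ValueError):
            ic_credibility_bound(ContingencyCounts(1, 1, 1, 1), 0.0)

    def test_normal_approximation_brackets_point_estimate(self):
        c = ContingencyCounts(20, 1000, 200, 100000)
        r = ic_result(c, method="normal")
        assert r.ic025 < r.ic < r.ic975
        # close to the gamma bound once counts are moderate
        assert r.ic025 == pytest.approx(ic_result(c).ic025, abs=0.15)


class TestCountsValidation:
    def test_observed_cannot_exceed_margins(self):
        with pytest.raises(ValueError):
            ContingencyCounts(5, 4, 10, 100)

    def test_margins_cannot_exceed_total(self):
        with pytest.raises(ValueError):
            ContingencyCounts(1, 200, 10, 100)

    def test_expected_is_derived(self):
        assert ContingencyCounts(20, 1000, 200, 100000).expected == 2.0

    def test_result_invariant_enforced(self):
        with pytest.raises(ValueError):
            ICResult(ic=0.0, ic025=0.5, ic975=1.0)


class TestContingencyFor:
    def test_single_case_database(self):
        db = ReportDatabase(cases=(make_case("c1", ["Hyperammonaemia"]),))
        c = contingency_for(db, HYPERAMMONAEMIA_EVENT, "D1")
        assert (c.n_observed, c.n_drug, c.n_effect, c.n_total) == (1, 1, 1, 1)

    def test_concomitant_mentions_never_counted(self, tiny_db):
        c = contingency_for(tiny_db, HYPERAMMONAEMIA_EVENT, "B")
        assert c.n_observed == 0
        assert c.n_drug == 1  # suspect in the non-event case c4 only

    def test_absent_drug_gives_zero_counts(self, tiny_db):
        c = contingency_for(tiny_db, HYPERAMMONAEMIA_EVENT, "nope")
        assert c.n_observed == 0 and c.n_drug == 0

    def test_counts_satisfy_ordering_invariant(self, tiny_db):
        for drug in ("A", "B", "C"):
            c = contingency_for(tiny_db, HYPERAMMONAEMIA_EVENT, drug)
            assert c.n_observed <= min(c.n_drug, c.n_effect) <= c.n_total


class TestScreenAllDrugs:
    def test_one_row_per_event_drug(self, tiny_db):
        rows = screen_all_drugs(tiny_db, HYPERAMMONAEMIA_EVENT)
        assert {r.drug_id for r in rows} == set(
            pv.drugs_with_event(tiny_db, HYPERAMMONAEMIA_EVENT)
        )

    def test_rows_match_contingency_for(self, tiny_db):
        for row in screen_all_drugs(tiny_db, HYPERAMMONAEMIA_EVENT):
            assert row.counts == contingency_for(
                tiny_db, HYPERAMMONAEMIA_EVENT, row.drug_id
            )

    def test_ordering_descending_observed_then_id(self, tiny_db):
        rows = screen_all_drugs(tiny_db, HYPERAMMONAEMIA_EVENT)
        keys = [(-r.counts.n_observed, r.drug_id) for r in rows]
        assert keys == sorted(keys)

    def test_null_drug_with_o_equal_e_not_significant(self):
        # one event case among many, drug in every case: O == E == 1
        cases = [make_case("e", ["Hyperammonaemia"], drugs=[("A", "a", Role.SUSPECT)])]
        cases += [
            make_case(f"b{i}", ["Nausea"], drugs=[("A", "a", Role.SUSPECT)])
            for i in range(99)
        ]
        db = ReportDatabase(cases=tuple(cases))
        (row,) = screen_all_drugs(db, HYPERAMMONAEMIA_EVENT)
        assert row.ic.ic == 0.0
        assert not row.ic.significant
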