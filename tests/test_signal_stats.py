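"""ROR / IC disproportionality statistics against independent formula oracles."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from faers_signal.signal_stats import (
    ContingencyTable,
    SignalCriteria,
    SignalResult,
    build_contingency,
    compute_ic,
    compute_ror,
    detect_signals,
    event_index,
    flag_unexpected,
    rank_top,
    result_from_table,
    wald_width_feasible,
)
from conftest import make_report


def oracle_ror(a, b, c, d):
    """Wald ROR oracle: plain math-module evaluation of the defining formulas."""
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = 1.959963984540054
    return ror, ror * math.exp(-z * se), ror * math.exp(z * se)


def oracle_ic(a, b, c, d):
    n = a + b + c + d
    e = (a + b) * (a + c) / n
    ic = math.log2((a + 0.5) / (e + 0.5))
    return ic, ic - 3.3 * (a + 0.5) ** -0.5 - 2.0 * (a + 0.5) ** -1.5


class TestROR:
    def test_symmetric_table(self):
        ror, lo, hi, reason = compute_ror(ContingencyTable(5, 5, 5, 5))
        assert ror == pytest.approx(1.0)
        assert lo == pytest.approx(0.173246, rel=1e-4)
        assert hi == pytest.approx(5.772153, rel=1e-4)
        assert reason is None

    def test_strong_signal_table(self):
        ror, lo, hi, _ = compute_ror(ContingencyTable(10, 90, 100, 9900))
        assert ror == pytest.approx(11.0)
        assert lo == pytest.approx(5.559585, rel=1e-5)
        assert hi == pytest.approx(21.764216, rel=1e-5)

    def test_zero_cell_undefined_with_reason(self):
        ror, lo, hi, reason = compute_ror(ContingencyTable(4, 6, 0, 90))
        assert ror is None and lo is None and hi is None
        assert "c" in reason

    def test_continuity_correction_defines_zero_cell(self):
        ror, lo, hi, reason = compute_ror(
            ContingencyTable(4, 6, 0, 90), continuity_correction=True)
        assert reason is None
        assert ror == pytest.approx((4.5 * 90.5) / (6.5 * 0.5))


class TestIC:
    def test_independence_gives_zero(self):
        # a == E exactly: (a+b)(a+c)/N == a
        ic, _ = compute_ic(ContingencyTable(10, 90, 90, 810))
        assert ic == pytest.approx(0.0, abs=1e-12)

    def test_strong_signal_table(self):
        ic, ic025 = compute_ic(ContingencyTable(10, 90, 100, 9900))
        assert ic == pytest.approx(2.7240, rel=1e-4)
        assert ic025 == pytest.approx(1.6469, rel=1e-4)

    def test_defined_at_zero_cases(self):
        # a=0 with E=5: the shrinkage keeps the IC finite and negative
        ic, ic025 = compute_ic(ContingencyTable(0, 100, 524, 9876))
        e = 100 * 524 / 10500
        assert e == pytest.approx(4.99, abs=0.01)
        assert ic == pytest.approx(math.log2(0.5 / (e + 0.5)), abs=1e-12)
        assert ic == pytest.approx(-3.459, abs=0.01)
        assert ic025 < ic

    @given(st.integers(0, 200), st.integers(1, 500), st.integers(0, 500),
           st.integers(1, 5000))
    @settings(max_examples=100, deadline=None)
    def test_matches_oracle_everywhere(self, a, b, c, d):
        t = ContingencyTable(a, b, c, d)
        ic, ic025 = compute_ic(t)
        oic, oic025 = oracle_ic(a, b, c, d)
        assert ic == pytest.approx(oic, rel=1e-12, abs=1e-12)
        assert ic025 == pytest.approx(oic025, rel=1e-12, abs=1e-12)

    def test_monotone_in_a(self):
        """More target-drug cases with everything else fixed: stronger signal."""
        prev_ror, prev_ic = 0.0, -99.0
        for a in (1, 5, 20, 80):
            t = ContingencyTable(a, 100, 50, 5000)
            ror, _, _, _ = compute_ror(t)
            ic, _ = compute_ic(t)
            assert ror > prev_ror and ic > prev_ic
            prev_ror, prev_ic = ror, ic


class TestContingency:
    def make_universe(self):
        # 100 reports, 10 on the target drug, event on 4 of them and 6 others
        reports = []
        for i in range(100):
            on_drug = i < 10
            has_event = i < 4 or 10 <= i < 16
            reports.append(make_report(
                str(i),
                drugs=(("TARGET" if on_drug else "OTHER", "PS"),),
                reactions=("EVENT",) if has_event else ("FILLER",),
            ))
        return reports

    def test_counts_match_exhaustive_enumeration(self):
        universe = self.make_universe()
        cohort = [r for r in universe if r.drugs[0].drug_name_raw == "TARGET"]
        t = build_contingency(universe, cohort, "EVENT")
        # oracle: double loop
        a = sum(1 for r in universe if r in cohort and "EVENT" in r.reactions)
        c = sum(1 for r in universe if r not in cohort and "EVENT" in r.reactions)
        assert (t.a, t.b, t.c, t.d) == (a, len(cohort) - a, c, 100 - len(cohort) - c)
        assert (t.a, t.b, t.c, t.d) == (4, 6, 6, 84)

    def test_event_only_on_target_drug(self):
        universe = self.make_universe()
        cohort = universe[:10]
        universe = [r for r in universe if "EVENT" not in r.reactions or r in cohort]
        t = build_contingency(universe, cohort, "EVENT")
        assert t.c == 0
        res = result_from_table(t)
        assert res.ror is None and res.ror_undefined_reason
        assert math.isfinite(res.ic)

    def test_soc_level_counts_once_per_distinct_soc(self):
        r = make_report("1", reactions=("PT_A", "PT_B"))
        r.socs = {"PT_A": "SOC_X", "PT_B": "SOC_X"}
        idx = event_index([r], level="SOC")
        assert idx == {"SOC_X": {"1"}}

    def test_marginal_conservation(self):
        """Sum of a over PTs equals the cohort's (report, PT) pair count."""
        universe = [make_report(str(i), drugs=(("T" if i % 3 == 0 else "O", "PS"),),
                                reactions=tuple(f"PT_{j}" for j in range(i % 4)))
                    for i in range(60)]
        cohort = [r for r in universe if r.drugs[0].drug_name_raw == "T"]
        idx = event_index(universe)
        total_a = sum(
            build_contingency(universe, cohort, e, universe_index=idx).a for e in idx)
        assert total_a == sum(len(set(r.reactions)) for r in cohort)


class TestFlags:
    def make(self, n, lo, ic025=1.0):
        return SignalResult("PT_X", n, 2.0, lo, 99.0, 1.0, ic025)

    def test_default_criteria(self):
        results = detect_signals([
            self.make(12, 39.12),        # printed-style strong row
            self.make(2, 5.0),           # below the case minimum
            self.make(5, 0.99),          # CI crosses 1
            self.make(5, 2.0, ic025=-0.1),
        ])
        assert [r.ror_signal for r in results] == [True, False, False, True]
        assert [r.ic_signal for r in results] == [True, True, True, False]

    def test_rank_top_orders_and_breaks_ties(self):
        rs = detect_signals([
            SignalResult("A", 5, 5.0, 2.0, 9.0, 1, 1),
            SignalResult("B", 5, 500.0, 2.0, 9.0, 1, 1),
            SignalResult("C", 5, 50.0, 2.0, 9.0, 1, 1),
            SignalResult("D", 10, 50.0, 2.0, 9.0, 1, 1),
        ])
        top2 = rank_top(rs, 2)
        assert [r.event for r in top2] == ["B", "D"]  # ror desc, ties by n
        assert [r.event for r in rank_top(rs, 99)] == ["B", "D", "C", "A"]

    def test_flag_unexpected_only_flags_signals(self):
        rs = detect_signals([
            self.make(10, 2.0),              # signal, unlabeled -> unexpected
            SignalResult("Fatigue", 10, 2.0, 1.5, 3.0, 1, 1),  # signal, labeled
            SignalResult("PT_Z", 1, 1.0, 0.5, 2.0, 0, -1),     # not a signal
        ])
        out = flag_unexpected(rs, ["fatigue"])
        assert [r.unexpected for r in out] == [True, False, False]

    def test_printed_row_is_wald_consistent(self):
        # a published row must satisfy ln(hi/lo)/(2*1.96) >= sqrt(1/n)
        assert wald_width_feasible(12, 39.12, 122.03)
        assert not wald_width_feasible(12, 100.0, 101.0)
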