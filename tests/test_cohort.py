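"""Cohort engine: transitions, conservation, closed-form decay, accumulation."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from seqcea.cohort import (
    AdverseEvent,
    BSCSpec,
    CohortTrace,
    LifeTable,
    LineSpec,
    ModelSettings,
    StrategyDefinition,
    accumulate,
    cycle_transition,
    monthly_mortality,
    run_cohort,
)
from seqcea.survival import ParametricSurvival


def _exp(rate):
    return ParametricSurvival("exponential", {"rate": rate})


def _toy_strategy(pfs_rate=0.1, utility=1.0, cost=0.0, bsc_rate=0.5, ae=()):
    lines = tuple(
        LineSpec(
            f"l{i}",
            _exp(pfs_rate),
            utility if i == 0 else 0.0,
            cost if i == 0 else 0.0,
            ae if i == 0 else (),
        )
        for i in range(4)
    )
    return StrategyDefinition("toy", lines, BSCSpec(_exp(bsc_rate), 0.0, 0.0))


def _const_life_table(q=0.0):
    return LifeTable(np.arange(40, 101), np.full(61, q))


class TestMortality:
    def test_monthly_conversion_closed_form(self):
        lt = _const_life_table(0.012)
        assert monthly_mortality(lt, 58.0) == pytest.approx(
            1.0 - (1.0 - 0.012) ** (1 / 12), rel=1e-12
        )
        assert monthly_mortality(lt, 58.0) == pytest.approx(0.0010055, abs=1e-7)

    def test_extreme_probabilities(self):
        assert monthly_mortality(_const_life_table(0.0), 50.0) == 0.0
        assert monthly_mortality(_const_life_table(1.0), 50.0) == 1.0

    def test_age_below_table_rejected(self):
        with pytest.raises(ValueError, match="below the life-table start"):
            monthly_mortality(_const_life_table(0.01), 20.0)

    def test_beyond_table_end_is_certain_death(self):
        assert _const_life_table(0.01).annual_at(104.0) == 1.0


class TestCycleTransition:
    def test_stated_competing_risk_arithmetic(self):
        # monthly death 0.05, raw progression 0.2 -> (0.76, 0.19, 0.05)
        lt = _const_life_table(1.0 - 0.95**12)
        line = LineSpec("x", _exp(-np.log(0.8)), 0.5, 0.0)
        stay, prog, die = cycle_transition(line, 3, lt, 58.0)
        assert die == pytest.approx(0.05, rel=1e-12)
        assert prog == pytest.approx(0.19, rel=1e-12)
        assert stay == pytest.approx(0.76, rel=1e-12)

    def test_degenerate_case_stays_put(self):
        lt = _const_life_table(0.0)
        line = LineSpec("x", _exp(1e-12), 0.5, 0.0)
        stay, prog, die = cycle_transition(line, 0, lt, 58.0)
        assert die == 0.0
        assert prog == pytest.approx(0.0, abs=1e-10)
        assert stay == pytest.approx(1.0, abs=1e-10)

    @given(
        q=st.floats(0.0, 0.5),
        rate=st.floats(1e-6, 1.0),
        shape=st.floats(0.5, 2.0),
        k=st.integers(0, 200),
    )
    def test_probabilities_sum_to_one(self, q, rate, shape, k):
        lt = _const_life_table(q)
        line = LineSpec(
            "x", ParametricSurvival("weibull", {"rate": rate, "shape": shape}), 0.5, 0.0
        )
        stay, prog, die = cycle_transition(line, k, lt, 58.0)
        assert stay + prog + die == pytest.approx(1.0, abs=1e-12)
        assert min(stay, prog, die) >= -1e-12


class TestRunCohort:
    def test_exponential_line_decays_geometrically(self, zero_life_table):
        strat = _toy_strategy(pfs_rate=0.1)
        settings = ModelSettings(
            annual_discount_rate=0.0, horizon_months=600, death_tol=1e-15
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            trace = run_cohort(strat, settings, zero_life_table)
        k = np.arange(trace.n_cycles)
        np.testing.assert_allclose(
            trace.occupancy["line1"].to_numpy(), np.exp(-0.1 * k), atol=1e-9
        )

    def test_occupancy_conserved_and_death_monotone(self, base_config):
        from seqcea.config import build_model

        strategies, settings, lt = build_model(base_config)
        for strat in strategies:
            trace = run_cohort(strat, settings, lt)
            sums = trace.occupancy.sum(axis=1).to_numpy()
            assert np.max(np.abs(sums - 1.0)) < 1e-10
            assert np.all(np.diff(trace.occupancy["death"].to_numpy()) >= -1e-12)

    def test_cohort_starts_fully_in_line1(self, zero_life_table):
        strat = _toy_strategy()
        settings = ModelSettings(annual_discount_rate=0.0, horizon_months=24)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            trace = run_cohort(strat, settings, zero_life_table)
        assert trace.occupancy.loc[0, "line1"] == 1.0
        assert trace.entries.loc[0, "line1"] == 1.0
        assert trace.occupancy.loc[0, ["line2", "line3", "line4", "bsc", "death"]].sum() == 0.0

    def test_truncated_horizon_warns(self, zero_life_table):
        strat = _toy_strategy(pfs_rate=0.001, bsc_rate=0.001)
        settings = ModelSettings(horizon_months=12)
        with pytest.warns(RuntimeWarning, match="still alive"):
            run_cohort(strat, settings, zero_life_table)


class TestAccumulate:
    def _single_state_trace(self, n_cycles, state="line1", value=1.0):
        occ = pd.DataFrame(
            0.0,
            index=range(n_cycles),
            columns=["line1", "line2", "line3", "line4", "bsc", "death"],
        )
        occ[state] = value
        ent = occ * 0.0
        return CohortTrace(occupancy=occ, entries=ent)

    def test_one_year_at_utility(self):
        # 12 undiscounted cycles at utility 0.46 accrue 0.46 QALYs
        trace = self._single_state_trace(12)
        strat = _toy_strategy(utility=0.46, cost=0.0)
        settings = ModelSettings(annual_discount_rate=0.0)
        cost, qalys = accumulate(trace, strat, settings)
        assert cost == 0.0
        assert qalys == pytest.approx(0.46, rel=1e-12)

    def test_cost_at_model_start_undiscounted(self):
        trace = self._single_state_trace(1)
        strat = _toy_strategy(cost=1000.0)
        settings = ModelSettings(annual_discount_rate=0.03)
        cost, _ = accumulate(trace, strat, settings)
        assert cost == pytest.approx(1000.0, rel=1e-12)

    def test_discounting_one_year_out(self):
        occ = self._single_state_trace(13).occupancy * 0.0
        occ.loc[12, "line1"] = 1.0
        trace = CohortTrace(occupancy=occ, entries=occ * 0.0)
        strat = _toy_strategy(cost=1000.0)
        settings = ModelSettings(annual_discount_rate=0.03)
        cost, _ = accumulate(trace, strat, settings)
        assert cost == pytest.approx(1000.0 / 1.03, rel=1e-12)  # 970.87

    def test_mean_exponential_sojourn_recovers_qalys(self, zero_life_table):
        # with utility 1, no discounting and a slow exponential line the
        # cumulative line-1 QALYs approach (1/rate)/12 years
        rate = 0.01
        strat = _toy_strategy(pfs_rate=rate)
        settings = ModelSettings(
            annual_discount_rate=0.0, start_age=40.0, death_tol=1e-15
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            trace = run_cohort(strat, settings, zero_life_table)
        _, qalys = accumulate(trace, strat, settings)
        assert qalys == pytest.approx((1.0 / rate) / 12.0, rel=0.01)

    def test_adverse_events_charged_once_at_entry(self, zero_life_table):
        ae = (AdverseEvent("anemia", incidence=0.5, cost=1000.0, disutility=0.1),)
        settings = ModelSettings(annual_discount_rate=0.0, horizon_months=60)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            base_c, base_q = accumulate(
                run_cohort(_toy_strategy(), settings, zero_life_table),
                _toy_strategy(),
                settings,
            )
            ae_strat = _toy_strategy(ae=ae)
            ae_c, ae_q = accumulate(
                run_cohort(ae_strat, settings, zero_life_table), ae_strat, settings
            )
        # full cohort enters line 1 exactly once: expected charge 0.5*1000
        assert ae_c - base_c == pytest.approx(500.0, rel=1e-9)
        assert base_q - ae_q == pytest.approx(0.05, rel=1e-9)

    def test_utility_and_cost_monotonicity(self, base_config):
        from seqcea.config import copy_config, evaluate

        base = evaluate(base_config)
        up = copy_config(base_config)
        up["utilities"]["line2"] = 0.80
        up["drugs"]["brigatinib"]["cycle_cost"] = 25_000.0
        bumped = evaluate(up)
        for label in base:
            assert bumped[label][1] >= base[label][1]  # QALYs rise with utility
            assert bumped[label][0] >= base[label][0]  # cost rises with price

    def test_equal_strategies_produce_identical_totals(self, zero_life_table):
        settings = ModelSettings(annual_discount_rate=0.03, horizon_months=240)
        a = _toy_strategy(pfs_rate=0.1, utility=0.7, cost=100.0)
        b = _toy_strategy(pfs_rate=0.1, utility=0.7, cost=100.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            ca = accumulate(run_cohort(a, settings, zero_life_table), a, settings)
            cb = accumulate(run_cohort(b, settings, zero_life_table), b, settings)
        assert ca == cb
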