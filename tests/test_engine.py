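"""Trajectory engine: DDD redistribution, refill chains, window truncation.

The independent oracles here are a day-stepping FIFO supply simulation (for
the 1 DDD/day queueing of scenarios 1-2) and the closed form of an
equally-spaced refill chain (plateau N/D, weaning tail N/(2D) for 2D days).
"""

import math
from collections import deque

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dddtraj as dt

from conftest import make_trajectory


def rec(day, n_packs=1, ddd=7.0, atc="N05BA06", pid="P1"):
    return dt.DispensationRecord(pid, atc, day, n_packs, ddd)


def fifo_oracle(items):
    """Day-stepping FIFO supply queue consuming 1 DDD/day.

    Independent of the engine: walks calendar days one at a time, drawing
    from the supply dispensed earliest; a finished supply hands over to the
    next one on the following day.
    """
    out = {}
    queue = deque(sorted(items))
    current = None
    day = None
    while queue or current is not None:
        if current is None:
            arrival, current = queue.popleft()
            day = arrival if day is None else max(arrival, day)
        take = min(1.0, current)
        out[day] = out.get(day, 0.0) + take
        current -= take
        day += 1
        if current <= 1e-12:
            current = None
    return out


class TestTotalDDD:
    @pytest.mark.parametrize(
        "n_packs,ddd,scenario,expected",
        [
            (2, 7.0, 2, 14.0),   # pack count used: 14 DDDs dispensed
            (2, 7.0, 1, 7.0),    # pack count unavailable, forced to 1
            (3, 7.5, 3, 22.5),
        ],
    )
    def test_scenario_rule(self, n_packs, ddd, scenario, expected):
        config = dt.ScenarioConfig(scenario=scenario)
        assert dt.total_ddd(rec(0, n_packs, ddd), config) == expected


class TestClassifyRuns:
    def test_chain_split_at_large_gap(self, config3):
        records = [rec(d) for d in (0, 30, 60, 160, 180)]
        runs = dt.classify_runs(records, config3)
        assert [(r.kind, r.days) for r in runs] == [
            ("regular", [0, 30, 60]),
            ("regular", [160, 180]),
        ]

    def test_single_dispensation_is_occasional(self, config3):
        (run,) = dt.classify_runs([rec(12)], config3)
        assert run.kind == "occasional"
        assert run.n_bar is None and run.rate_f is None

    def test_gap_beyond_window_means_two_occasional(self, config3):
        runs = dt.classify_runs([rec(0), rec(50)], config3)
        assert [r.kind for r in runs] == ["occasional", "occasional"]

    def test_regular_statistics(self, config3):
        records = [rec(0, 2, 14.0), rec(30, 2, 14.0)]
        (run,) = dt.classify_runs(records, config3)
        assert run.kind == "regular"
        assert run.n_bar == 28.0 and run.d_bar == 30.0
        assert run.rate_f == pytest.approx(28.0 / 30.0)

    def test_same_day_dispensations_merged_before_gaps(self, config3):
        records = [rec(0), rec(0), rec(30)]
        (run,) = dt.classify_runs(records, config3)
        assert run.days == [0, 30] and run.totals == [14.0, 7.0]

    def test_empty_input(self, config3):
        assert dt.classify_runs([], config3) == []

    def test_mixed_atc_rejected(self, config3):
        with pytest.raises(dt.ValidationError):
            dt.classify_runs([rec(0), rec(30, atc="N06AB03")], config3)


class TestDistributeOccasional:
    def test_seven_ddd_is_seven_days_at_one(self):
        run = dt.DispensingRun("A", [0], [7.0], "occasional")
        frag, pending = dt.distribute_occasional(run)
        assert frag == {d: 1.0 for d in range(7)}
        assert pending == 7

    def test_same_substance_periods_queue_one_after_the_other(self):
        run = dt.DispensingRun("A", [0, 3], [7.0, 7.0], "regular")  # kind unused here
        frag, pending = dt.distribute_occasional(run)
        assert frag == {d: 1.0 for d in range(14)}
        assert pending == 14

    def test_fractional_residual_on_final_day(self):
        run = dt.DispensingRun("A", [0], [7.5], "occasional")
        frag, pending = dt.distribute_occasional(run)
        assert frag[6] == 1.0 and frag[7] == 0.5
        assert pending == 8
        assert sum(frag.values()) == pytest.approx(7.5, abs=1e-12)

    def test_pending_pointer_defers_start(self):
        run = dt.DispensingRun("A", [2], [3.0], "occasional")
        frag, pending = dt.distribute_occasional(run, pending_until=10)
        assert min(frag) == 10 and pending == 13


class TestDistributeRegular:
    def test_monthly_refills_worked_example(self, config3):
        """28 DDD at days 0 and 30: F=28/30 on days 0-29, F/2 on days 30-89."""
        (run,) = dt.classify_runs([rec(0, 2, 14.0), rec(30, 2, 14.0)], config3)
        frag = dt.distribute_regular(run, config3)
        f = 28.0 / 30.0
        for d in range(0, 30):
            assert frag[d] == pytest.approx(f)
        for d in range(30, 90):
            assert frag[d] == pytest.approx(f / 2)
        assert max(frag) == 89
        assert sum(frag.values()) == pytest.approx(56.0, abs=1e-9)

    def test_unequal_totals_and_gaps(self, config3):
        """N=20, D=25 -> F=0.8 on days 0-49, 0.4 tail on days 50-99."""
        records = [rec(0, 1, 10.0), rec(20, 2, 10.0), rec(50, 3, 10.0)]
        (run,) = dt.classify_runs(records, config3)
        assert run.n_bar == 20.0 and run.d_bar == 25.0 and run.rate_f == pytest.approx(0.8)
        frag = dt.distribute_regular(run, config3)
        plateau = {d: v for d, v in frag.items() if d < 50}
        tail = {d: v for d, v in frag.items() if d >= 50}
        assert all(v == pytest.approx(0.8) for v in plateau.values())
        assert all(v == pytest.approx(0.4) for v in tail.values())
        assert sum(plateau.values()) == pytest.approx(40.0)
        assert sum(tail.values()) == pytest.approx(20.0)
        assert max(frag) == 99

    def test_occasional_run_rejected(self, config3):
        run = dt.DispensingRun("A", [0], [7.0], "occasional")
        with pytest.raises(dt.ValidationError):
            dt.distribute_regular(run, config3)

    @given(
        n=st.integers(1, 40),
        d=st.integers(1, 44),
        k=st.integers(2, 8),
    )
    @settings(max_examples=60, derandomize=True)
    def test_equal_spacing_closed_form(self, n, d, k):
        """Equal totals N and gaps D: plateau N/D of (k-1)D days then N/(2D) for 2D days."""
        config = dt.ScenarioConfig(scenario=3, regularity_window_days=44)
        days = [i * d for i in range(k)]
        totals = [float(n)] * k
        run = dt.DispensingRun(
            "A", days, totals, "regular", float(n), float(d), n / d
        )
        frag = dt.distribute_regular(run, config)
        expected = {}
        for day in range(0, (k - 1) * d):
            expected[day] = n / d
        for day in range((k - 1) * d, (k + 1) * d):
            expected[day] = n / (2 * d)
        assert set(frag) == set(expected)
        for day, v in expected.items():
            assert frag[day] == pytest.approx(v, abs=1e-9)


class TestBuildDaily:
    def test_two_substances_cumulate_daywise(self, config2):
        records = [rec(5, 1, 1.0, atc="N05BA06"), rec(5, 1, 1.0, atc="N06AB03")]
        preg = dt.PregnancyRecord("P1", 39)
        daily = dt.build_daily(records, preg, config2)
        assert daily.values[5] == 2.0

    def test_lookback_discards_early_dispensations_entirely(self, config2):
        # day -92 is before week -13 (day -91): dropped even though its
        # supply would reach the exposure window
        records = [rec(-92, 3, 28.0)]
        preg = dt.PregnancyRecord("P1", 39)
        daily = dt.build_daily(records, preg, config2)
        assert daily.values == {}

    def test_scenario3_all_gaps_beyond_window_equals_scenario2(self, config2, config3):
        records = [rec(0), rec(50), rec(101, atc="N06AB03"), rec(150, 2, 3.0)]
        preg = dt.PregnancyRecord("P1", 39)
        d2 = dt.build_daily(records, preg, config2)
        d3 = dt.build_daily(records, preg, config3)
        assert d2.values.keys() == d3.values.keys()
        for day in d2.values:
            assert d2.values[day] == pytest.approx(d3.values[day], abs=1e-12)

    def test_scenario2_all_single_packs_equals_scenario1(self, config1, config2):
        records = [rec(0), rec(10, 1, 3.5), rec(30, 1, 14.0, atc="N06AB03")]
        preg = dt.PregnancyRecord("P1", 39)
        d1 = dt.build_daily(records, preg, config1)
        d2 = dt.build_daily(records, preg, config2)
        assert d1.values == d2.values

    def test_no_dispensations_gives_empty_exposure(self, config3):
        daily = dt.build_daily([], dt.PregnancyRecord("P1", 39), config3)
        assert daily.values == {} and daily.total() == 0.0


@st.composite
def dispensation_lists(draw):
    n = draw(st.integers(1, 12))
    atcs = ("N05BA06", "N06AB03", "N05AH04")
    return [
        dt.DispensationRecord(
            "P1",
            draw(st.sampled_from(atcs)),
            draw(st.integers(-91, 260)),
            draw(st.integers(1, 3)),
            draw(
                st.floats(0.25, 40.0, allow_nan=False, allow_infinity=False)
            ),
        )
        for _ in range(n)
    ]


class TestMassConservation:
    @pytest.mark.parametrize("scenario", [1, 2, 3])
    @given(records=dispensation_lists())
    @settings(max_examples=50, derandomize=True)
    def test_untruncated_daily_mass_equals_dispensed_total(self, scenario, records):
        config = dt.ScenarioConfig(scenario=scenario)
        preg = dt.PregnancyRecord("P1", 39)
        daily = dt.build_daily(records, preg, config)
        dispensed = sum(dt.total_ddd(r, config) for r in records)
        assert daily.total() == pytest.approx(dispensed, abs=1e-9)
        assert all(v >= 0 for v in daily.values.values())


class TestQueueingOracle:
    @given(records=dispensation_lists())
    @settings(max_examples=60, derandomize=True)
    def test_per_substance_series_matches_fifo_simulation(self, records):
        """Scenario-2 daily series equals a day-stepping FIFO supply queue."""
        config = dt.ScenarioConfig(scenario=2)
        by_atc = {}
        for r in records:
            by_atc.setdefault(r.atc, []).append(r)
        preg = dt.PregnancyRecord("P1", 39)
        for atc, recs in by_atc.items():
            daily = dt.build_daily(recs, preg, config)
            merged = {}
            for r in recs:
                merged[r.day] = merged.get(r.day, 0.0) + dt.total_ddd(r, config)
            expected = fifo_oracle(sorted(merged.items()))
            assert set(daily.values) == {d for d, v in expected.items() if v > 0}
            for day, v in expected.items():
                if v > 0:
                    assert daily.values[day] == pytest.approx(v, abs=1e-9)


class TestTruncateAndWeekly:
    def test_week_zero_aggregation(self, config2):
        daily = dt.DailyExposure("P1", 2, {d: 1.0 for d in range(7)})
        traj = dt.truncate_and_weekly(daily, dt.PregnancyRecord("P1", 38), config2)
        assert traj.start_week == -4 and len(traj.values) == 43
        assert traj.values[4] == 7.0  # week 0 sits at index 4
        assert traj.total() == 7.0

    def test_window_start_cuts_supply_before_week_minus4(self, config2):
        daily = dt.DailyExposure("P1", 2, {d: 1.0 for d in range(-35, -24)})
        traj = dt.truncate_and_weekly(daily, dt.PregnancyRecord("P1", 38), config2)
        # only days -28..-25 survive, all in week -4
        assert traj.values[0] == 4.0
        assert traj.total() == 4.0

    def test_mass_shifted_past_birth_is_excluded(self, config2):
        end_week = 30
        last_day = 7 * end_week + 6
        daily = dt.DailyExposure("P1", 2, {last_day - 1: 1.0, last_day: 1.0, last_day + 1: 1.0})
        traj = dt.truncate_and_weekly(daily, dt.PregnancyRecord("P1", end_week), config2)
        assert len(traj.values) == end_week + 5
        assert traj.total() == 2.0

    def test_delivery_past_week_38_is_clipped(self, config2):
        daily = dt.DailyExposure("P1", 2, {7 * 40: 5.0})
        traj = dt.truncate_and_weekly(daily, dt.PregnancyRecord("P1", 42), config2)
        assert traj.end_week == 38
        assert traj.total() == 0.0

    def test_weekly_sum_equals_surviving_daily_sum(self, config3, small_cohort):
        _, pregnancies, dispensations, _ = small_cohort
        by_pid = {}
        for r in dispensations:
            by_pid.setdefault(r.pregnancy_id, []).append(r)
        for preg in pregnancies[:40]:
            daily = dt.build_daily(by_pid.get(preg.pregnancy_id, []), preg, config3)
            traj = dt.truncate_and_weekly(daily, preg, config3)
            lo = 7 * config3.window_start_week
            hi = 7 * min(preg.end_week, 38) + 6
            surviving = sum(v for d, v in daily.values.items() if lo <= d <= hi)
            assert traj.total() == pytest.approx(surviving, abs=1e-9)


class TestIsExposed:
    def test_threshold_contract(self, config2):
        eps = config2.exposure_epsilon
        assert not dt.is_exposed(make_trajectory("P1", [0.0, 0.0]), config2)
        assert dt.is_exposed(make_trajectory("P1", [0.0, 0.5]), config2)
        assert not dt.is_exposed(make_trajectory("P1", [eps / 2, eps / 2]), config2)


class TestPooledRegularOption:
    def test_pooled_f_shared_across_chains(self):
        config = dt.ScenarioConfig(scenario=3, pool_regular=True)
        records = [rec(0, 1, 10.0), rec(30, 1, 10.0), rec(160, 1, 40.0), rec(180, 1, 40.0)]
        runs = dt.classify_runs(records, config)
        assert [r.kind for r in runs] == ["regular", "regular"]
        # pooled: N = mean(10,10,40,40) = 25, D = mean(30,20) = 25, F = 1
        assert all(r.rate_f == pytest.approx(1.0) for r in runs)
        # conservation still holds per chain
        for r in runs:
            frag = dt.distribute_regular(r, config)
            assert sum(frag.values()) == pytest.approx(r.total, abs=1e-9)
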