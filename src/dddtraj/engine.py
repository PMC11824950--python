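"""Daily and weekly medication-exposure trajectories under three scenarios.

The exposure of a pregnancy to a medication is measured in Defined Daily
Doses (DDD) and redistributed over calendar days in one of three ways:

* **Scenario 1** — the pack count is unavailable (forced to 1): each
  dispensation supplies ``ddd_per_pack`` DDDs, consumed at 1 DDD/day,
  with same-substance supply periods queued one after the other.
* **Scenario 2** — the pack count is used (``n_packs * ddd_per_pack``
  DDDs per dispensation), same 1 DDD/day queueing.
* **Scenario 3** — pack count plus periodicity adjustment: dispensations of
  one substance renewed within 45 days form *regular* refill chains.  A
  chain with average dispensed quantity N̄ and average refill gap D̄ is
  redistributed at the constant rate F = N̄/D̄ DDD/day between its first and
  last dispensation, then at F/2 (a weaning tail) until the remaining
  supply is exhausted.  Dispensations not renewed within 45 days remain
  *occasional* and are queued at 1 DDD/day as in scenarios 1-2.

Every redistribution conserves mass: before window truncation the daily
series of a pregnancy sums exactly to its dispensed DDD total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .data import (
    DispensationRecord,
    PregnancyRecord,
    ScenarioConfig,
    ValidationError,
    WeeklyTrajectory,
)

__all__ = [
    "DispensingRun",
    "DailyExposure",
    "total_ddd",
    "classify_runs",
    "distribute_occasional",
    "distribute_regular",
    "build_daily",
    "truncate_and_weekly",
    "is_exposed",
    "build_trajectory",
    "build_cohort_trajectories",
]

_MASS_TOL = 1e-12


@dataclass
class DispensingRun:
    """A maximal chain of same-substance dispensations for one pregnancy.

    ``kind`` is "regular" when the chain has >= 2 dispensations with every
    consecutive gap within the regularity window, else "occasional".
    For regular runs, ``n_bar`` is the mean dispensed DDD quantity, ``d_bar``
    the mean gap in days between consecutive dispensations and ``rate_f``
    their ratio N̄/D̄ (the daily redistribution rate); all three are None for
    occasional runs.
    """

    atc: str
    days: list[int]
    totals: list[float]
    kind: str  # "occasional" | "regular"
    n_bar: float | None = None
    d_bar: float | None = None
    rate_f: float | None = None

    @property
    def first_day(self) -> int:
        return self.days[0]

    @property
    def last_day(self) -> int:
        return self.days[-1]

    @property
    def total(self) -> float:
        return float(sum(self.totals))


@dataclass
class DailyExposure:
    """Sparse day -> DDD map for one pregnancy under one scenario."""

    pregnancy_id: str
    scenario: int
    values: dict[int, float] = field(default_factory=dict)

    def add(self, day: int, ddd: float) -> None:
        if ddd > 0:
            self.values[day] = self.values.get(day, 0.0) + ddd

    def total(self) -> float:
        return float(sum(self.values.values()))


def total_ddd(record: DispensationRecord, config: ScenarioConfig) -> float:
    """Dispensed DDD quantity of one dispensation under the scenario.

    Scenario 1 ignores the pack count (forced to 1); scenarios 2 and 3 use
    ``n_packs * ddd_per_pack``.
    """
    if config.scenario == 1:
        return float(record.ddd_per_pack)
    return float(record.n_packs * record.ddd_per_pack)


def _merge_same_day(
    records: Sequence[DispensationRecord], config: ScenarioConfig
) -> list[tuple[int, float]]:
    """Sorted (day, total DDD) pairs with same-day dispensations summed."""
    merged: dict[int, float] = {}
    for r in records:
        merged[r.day] = merged.get(r.day, 0.0) + total_ddd(r, config)
    return sorted(merged.items())


def classify_runs(
    records: Sequence[DispensationRecord], config: ScenarioConfig
) -> list[DispensingRun]:
    """Partition one pregnancy x ATC's dispensations into maximal chains.

    Consecutive dispensations at most ``regularity_window_days`` apart chain
    together; chains of length >= 2 are regular (renewed within the window),
    singletons occasional.  Same-day dispensations are merged (quantities
    summed) before gaps are computed, so gaps are strictly positive.

    With ``config.pool_regular`` the rate F is computed from all regular
    dispensations of the pregnancy x ATC pooled, instead of per chain.
    """
    if not records:
        return []
    atcs = {r.atc for r in records}
    pids = {r.pregnancy_id for r in records}
    if len(atcs) != 1 or len(pids) != 1:
        raise ValidationError("classify_runs expects one pregnancy x one ATC")
    atc = atcs.pop()

    items = _merge_same_day(records, config)
    chains: list[list[tuple[int, float]]] = [[items[0]]]
    for day, tot in items[1:]:
        if day - chains[-1][-1][0] <= config.regularity_window_days:
            chains[-1].append((day, tot))
        else:
            chains.append([(day, tot)])

    runs: list[DispensingRun] = []
    for chain in chains:
        days = [d for d, _ in chain]
        totals = [t for _, t in chain]
        if len(chain) >= 2:
            gaps = [b - a for a, b in zip(days, days[1:])]
            n_bar = float(np.mean(totals))
            d_bar = float(np.mean(gaps))
            runs.append(
                DispensingRun(atc, days, totals, "regular", n_bar, d_bar, n_bar / d_bar)
            )
        else:
            runs.append(DispensingRun(atc, days, totals, "occasional"))

    if config.pool_regular:
        reg = [r for r in runs if r.kind == "regular"]
        if reg:
            all_totals = [t for r in reg for t in r.totals]
            all_gaps = [b - a for r in reg for a, b in zip(r.days, r.days[1:])]
            n_bar = float(np.mean(all_totals))
            d_bar = float(np.mean(all_gaps))
            for r in reg:
                r.n_bar, r.d_bar, r.rate_f = n_bar, d_bar, n_bar / d_bar
    return runs


def _queue_items(
    items: Iterable[tuple[int, float]], pending_until: int | None = None
) -> tuple[dict[int, float], int | None]:
    """Queue supply periods at 1 DDD/day, one after the other.

    Each (day, total) supply starts at max(its day, the day after the
    previous same-substance supply is exhausted), runs at 1 DDD/day for
    ceil(total) days with any fractional residue on its final day.
    Returns the day->DDD fragment and the new exhaustion pointer.
    """
    frag: dict[int, float] = {}
    for day, total in items:
        start = day if pending_until is None else max(day, pending_until)
        n_full = math.floor(total)
        residual = total - n_full
        for d in range(start, start + n_full):
            frag[d] = frag.get(d, 0.0) + 1.0
        if residual > _MASS_TOL:
            d = start + n_full
            frag[d] = frag.get(d, 0.0) + residual
        pending_until = start + math.ceil(total)
    return frag, pending_until


def distribute_occasional(
    run: DispensingRun, pending_until: int | None = None
) -> tuple[dict[int, float], int | None]:
    """Distribute a run at 1 DDD/day with same-substance queueing.

    Used for occasional runs under scenario 3 and for every run under
    scenarios 1-2.  ``pending_until`` carries the exhaustion day of the
    previous supply of the same substance; the updated pointer is returned
    with the day->DDD fragment.
    """
    return _queue_items(zip(run.days, run.totals), pending_until)


def distribute_regular(run: DispensingRun, config: ScenarioConfig) -> dict[int, float]:
    """Redistribute a regular refill chain at rate F with an F/2 tail.

    The rate F = N̄/D̄ covers every day from the first dispensation up to
    (excluding) the last; from the last dispensation day the remaining
    supply drains at ``weaning_factor * F`` per day until exhausted, the
    final tail day carrying any fractional residue.  Total mass equals the
    chain's dispensed total exactly.
    """
    if run.kind != "regular":
        raise ValidationError("distribute_regular requires a regular run")
    f = run.rate_f
    assert f is not None and f > 0
    tol = _MASS_TOL * max(1.0, run.total)
    frag: dict[int, float] = {}
    remaining = run.total
    # plateau [first, last); with per-chain F its mass is exactly N̄(k-1),
    # but a pooled F may exceed the chain's own supply, so cap at the mass
    # actually dispensed
    for d in range(run.first_day, run.last_day):
        x = min(f, remaining)
        if x <= tol:
            break
        frag[d] = frag.get(d, 0.0) + x
        remaining -= x
    tail_rate = config.weaning_factor * f
    d = run.last_day
    while remaining > tol:
        x = min(tail_rate, remaining)
        frag[d] = frag.get(d, 0.0) + x
        remaining -= x
        d += 1
    return frag


def build_daily(
    records: Sequence[DispensationRecord],
    pregnancy: PregnancyRecord,
    config: ScenarioConfig,
) -> DailyExposure:
    """Untruncated daily exposure of one pregnancy across all substances.

    Dispensations before the lookback week are discarded outright.  Per
    substance, scenarios 1-2 queue all dispensations at 1 DDD/day; scenario
    3 classifies refill chains and redistributes regular ones at rate F.
    Occasional supplies queue among themselves (in day order) but not behind
    regular-chain tails: the two dispensing regimes are independent
    mechanisms whose fragments are summed.  Substances are then summed
    day-wise.
    """
    exposure = DailyExposure(pregnancy.pregnancy_id, config.scenario)
    cutoff = 7 * config.lookback_week
    kept = [r for r in records if r.day >= cutoff]
    by_atc: dict[str, list[DispensationRecord]] = {}
    for r in kept:
        if r.pregnancy_id != pregnancy.pregnancy_id:
            raise ValidationError(
                f"dispensation for {r.pregnancy_id!r} passed to pregnancy "
                f"{pregnancy.pregnancy_id!r}"
            )
        by_atc.setdefault(r.atc, []).append(r)

    for atc in sorted(by_atc):
        recs = by_atc[atc]
        if config.scenario in (1, 2):
            frag, _ = _queue_items(_merge_same_day(recs, config))
            for d, v in frag.items():
                exposure.add(d, v)
        else:
            runs = classify_runs(recs, config)
            pending: int | None = None
            for run in sorted(runs, key=lambda r: r.first_day):
                if run.kind == "occasional":
                    frag, pending = distribute_occasional(run, pending)
                else:
                    frag = distribute_regular(run, config)
                for d, v in frag.items():
                    exposure.add(d, v)
    return exposure


def truncate_and_weekly(
    daily: DailyExposure, pregnancy: PregnancyRecord, config: ScenarioConfig
) -> WeeklyTrajectory:
    """Clip the daily series to the pregnancy window and sum by week.

    Days before ``window_start_week`` or after the last day of
    ``min(end_week, 38)`` are dropped (DDDs shifted past birth are not
    counted); surviving days are summed into gestational weeks, giving a
    vector over weeks ``window_start_week .. min(end_week, 38)``.
    """
    end_week = min(pregnancy.end_week, config.max_week)
    start_week = config.window_start_week
    lo = 7 * start_week
    hi = 7 * end_week + 6
    values = np.zeros(end_week - start_week + 1)
    for day, v in daily.values.items():
        if lo <= day <= hi:
            values[day // 7 - start_week] += v
    return WeeklyTrajectory(
        pregnancy_id=daily.pregnancy_id,
        scenario=daily.scenario,
        start_week=start_week,
        values=values,
    )


def is_exposed(trajectory: WeeklyTrajectory, config: ScenarioConfig) -> bool:
    """True iff any weekly DDD value exceeds the exposure threshold."""
    return bool(np.any(trajectory.values > config.exposure_epsilon))


def build_trajectory(
    records: Sequence[DispensationRecord],
    pregnancy: PregnancyRecord,
    config: ScenarioConfig,
) -> WeeklyTrajectory:
    """Daily redistribution followed by window truncation and weekly sums."""
    return truncate_and_weekly(build_daily(records, pregnancy, config), pregnancy, config)


def build_cohort_trajectories(
    dispensations: Sequence[DispensationRecord],
    pregnancies: Sequence[PregnancyRecord],
    config: ScenarioConfig,
) -> dict[str, WeeklyTrajectory]:
    """Trajectories for a whole cohort, keyed by pregnancy_id.

    Every pregnancy gets a trajectory (possibly all-zero); dispensations
    whose pregnancy_id has no pregnancy record raise an error.
    """
    by_pid: dict[str, list[DispensationRecord]] = {}
    for r in dispensations:
        by_pid.setdefault(r.pregnancy_id, []).append(r)
    known = {p.pregnancy_id for p in pregnancies}
    orphans = set(by_pid) - known
    if orphans:
        raise ValidationError(
            f"dispensations reference unknown pregnancies: {sorted(orphans)[:5]}"
        )
    return {
        p.pregnancy_id: build_trajectory(by_pid.get(p.pregnancy_id, []), p, config)
        for p in pregnancies
    }
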