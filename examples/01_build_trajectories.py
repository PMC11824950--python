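"""Build weekly exposure trajectories for one pregnancy under all scenarios.

A woman delivers at week 39 and receives the same antidepressant (2 packs of
14 DDD) at days 0 and 30 — a monthly refill pattern — plus a one-off
anxiolytic (1 pack of 7.5 DDD) at day 100.  The three scenarios redistribute
these dispensations differently: scenario 1 ignores the pack count,
scenario 2 queues the full 28 DDD per dispensation at 1 DDD/day, and
scenario 3 recognizes the refill chain and spreads it at the refill rate
F = 28/30 DDD/day with an F/2 weaning tail.
"""

import dddtraj as dt

records = [
    dt.DispensationRecord("P1", "N06AB03", day=0, n_packs=2, ddd_per_pack=14.0),
    dt.DispensationRecord("P1", "N06AB03", day=30, n_packs=2, ddd_per_pack=14.0),
    dt.DispensationRecord("P1", "N05BA06", day=100, n_packs=1, ddd_per_pack=7.5),
]
pregnancy = dt.PregnancyRecord("P1", end_week=39)

for scenario in (1, 2, 3):
    config = dt.ScenarioConfig(scenario=scenario)
    trajectory = dt.build_trajectory(records, pregnancy, config)
    weeks = {int(w): float(v) for w, v in zip(trajectory.weeks, trajectory.values) if v > 0}
    print(f"scenario {scenario}: total {trajectory.total():.1f} DDD over weeks "
          f"{min(weeks)}..{max(weeks)}")
    shown = {w: round(v, 2) for w, v in list(weeks.items())[:6]}
    print(f"  first nonzero weeks: {shown}")

# Scenario 3 places more DDDs inside the pregnancy window than scenario 2
# (the weaning tail ends at day 89 instead of a queue running to day 56 at
# 1 DDD/day) and smooths the weekly profile at the refill rate ~6.5 DDD/week.
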