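"""Seeded synthetic pregnancy cohorts with realistic dispensing structure.

The generator stands in for access-restricted claims data.  It plants, for
each exposed pregnancy, one of four exposure strata (target mean weekly DDD
levels spanning low to very high exposure) and realizes that level through a
mixture of regular refill chains (inter-dispensation gaps kept under the
45-day regularity window, around a monthly refill habit) and occasional
dispensations (isolated, or renewed only after more than 45 days).  Pack
counts follow a discrete law with most dispensations being a single pack.
Planted stratum labels are emitted alongside the records so that clustering
recovery can be measured without circularity; they are never an input to
the trajectory pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data import DispensationRecord, PregnancyRecord, ValidationError

__all__ = ["CohortSpec", "generate", "DEFAULT_ATC_POOL"]

#: Synthetic psychotropic-like ATC codes with the DDD content of one pack.
#: The range of pack sizes (2 to 50 DDDs) lets the generator hit low and
#: high weekly exposure levels with small integer pack counts.
DEFAULT_ATC_POOL: tuple[tuple[str, float], ...] = (
    ("N05BB01", 0.5),
    ("N05BA04", 0.8),
    ("N05CD07", 1.2),
    ("N05BA01", 2.0),
    ("N05BA06", 3.3),
    ("N05BA12", 5.0),
    ("N06AB03", 7.0),
    ("N06AB04", 7.5),
    ("N05AH04", 10.0),
    ("N06AB06", 14.0),
    ("N06AX11", 15.0),
    ("N05AN01", 20.0),
    ("N05AX08", 25.0),
    ("N06AB05", 28.0),
    ("N05AH03", 30.0),
    ("N03AX16", 40.0),
    ("N05AX12", 50.0),
)


@dataclass
class CohortSpec:
    """Parameters of one synthetic cohort draw.

    stratum_levels
        Target mean weekly DDD of the four planted exposure strata, lowest
        to highest.
    stratum_weights
        Mixture weights of the strata among exposed pregnancies (defaults
        follow the skewed sizes typical of psychotropic exposure, with
        roughly three quarters of exposed pregnancies in the lowest
        stratum).
    regular_fraction
        Probability that a treated substance episode is a regular refill
        chain rather than occasional dispensing.
    gap_mean, gap_jitter
        Refill-gap law (days) for regular chains, truncated below the
        45-day regularity window; defaults emulate a monthly refill habit.
    pack_probs
        Distribution of the pack count 1, 2, 3 per dispensation.
    level_jitter_sd
        Log-normal sd of the per-pregnancy exposure level around its
        stratum's target.
    outcome_probs
        Per-stratum probability of the neonatal-pathology flag (None
        disables outcome simulation); premature birth uses a flat rate.
    """

    n_pregnancies: int = 1000
    exposure_fraction: float = 0.8
    stratum_weights: tuple[float, float, float, float] = (0.767, 0.129, 0.084, 0.020)
    stratum_levels: tuple[float, float, float, float] = (0.55, 2.6, 7.0, 16.0)
    regular_fraction: float = 0.7
    gap_mean: float = 30.0
    gap_jitter: float = 5.0
    pack_probs: tuple[float, float, float] = (0.68, 0.22, 0.10)
    atc_pool: tuple[tuple[str, float], ...] = DEFAULT_ATC_POOL
    end_week_mean: float = 39.0
    end_week_sd: float = 2.0
    end_week_range: tuple[int, int] = (25, 43)
    level_jitter_sd: float = 0.15
    outcome_probs: tuple[float, float, float, float] | None = (0.11, 0.11, 0.16, 0.25)
    premature_prob: float = 0.09
    lookback_week: int = -13
    window_start_week: int = -4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pregnancies < 0:
            raise ValidationError("n_pregnancies must be >= 0")
        if not (0 <= self.exposure_fraction <= 1):
            raise ValidationError("exposure_fraction must be in [0, 1]")
        if abs(sum(self.stratum_weights) - 1.0) > 1e-9:
            raise ValidationError("stratum_weights must sum to 1")
        if any(w < 0 for w in self.stratum_weights):
            raise ValidationError("stratum_weights must be nonnegative")
        if any(level <= 0 for level in self.stratum_levels):
            raise ValidationError("stratum_levels must be positive")
        if self.gap_mean <= 0:
            raise ValidationError("gap_mean must be > 0")
        if abs(sum(self.pack_probs) - 1.0) > 1e-9:
            raise ValidationError("pack_probs must sum to 1")
        if not self.atc_pool:
            raise ValidationError("atc_pool must be non-empty")


def _pick_atc(
    pool: Sequence[tuple[str, float]],
    target_per_disp: float,
    expected_packs: float,
) -> tuple[str, float]:
    """Pool entry whose pack content best matches the target quantity."""
    want = max(target_per_disp / expected_packs, min(d for _, d in pool))
    return min(pool, key=lambda item: abs(np.log(item[1] / want)))


def generate(
    spec: CohortSpec,
) -> tuple[list[PregnancyRecord], list[DispensationRecord], dict[str, int]]:
    """Draw a cohort: pregnancies, dispensations and planted stratum labels.

    Planted labels map pregnancy_id -> stratum index 0..3 for exposed
    pregnancies (unexposed pregnancies are absent from the map).
    Reproducible: the same spec (including seed) yields identical output.
    """
    rng = np.random.default_rng(spec.seed)
    pregnancies: list[PregnancyRecord] = []
    dispensations: list[DispensationRecord] = []
    planted: dict[str, int] = {}

    lo_day = 7 * spec.lookback_week
    strata = np.arange(4)

    for i in range(spec.n_pregnancies):
        pid = f"P{i + 1:06d}"
        end_week = int(
            np.clip(
                round(rng.normal(spec.end_week_mean, spec.end_week_sd)),
                *spec.end_week_range,
            )
        )
        exposed = rng.random() < spec.exposure_fraction
        stratum: int | None = None
        if exposed:
            stratum = int(rng.choice(strata, p=spec.stratum_weights))
            planted[pid] = stratum
            level = spec.stratum_levels[stratum] * float(
                np.exp(rng.normal(0.0, spec.level_jitter_sd))
            )
            n_weeks = min(end_week, 38) - spec.window_start_week + 1
            total_target = level * n_weeks
            delivery_day = 7 * end_week

            n_episodes = int(rng.choice([1, 2, 3, 4], p=[0.45, 0.30, 0.17, 0.08]))
            n_episodes = min(n_episodes, len(spec.atc_pool))
            regular_flags = [rng.random() < spec.regular_fraction for _ in range(n_episodes)]
            # an occasional supply is consumed at 1 DDD/day, so it cannot
            # express a sustained high level: targets beyond a small one-off
            # supply require at least one refill chain (unless regular
            # dispensing is disabled altogether)
            if spec.regular_fraction > 0 and not any(regular_flags) and total_target > 45:
                regular_flags[0] = True
            n_regular = sum(regular_flags)

            # The planted stratum is expressed as a sustained exposure level:
            # regular refill chains span the pregnancy window and carry the
            # bulk of the target mass; occasional dispensations are small
            # one-off supplies on top.  Without any regular episode the
            # whole target goes to occasional supplies (whose 1 DDD/day
            # mechanism then caps the realized weekly level).
            occ_totals = []
            for flag in regular_flags:
                if not flag:
                    cap = 0.3 * total_target / max(n_episodes - n_regular, 1)
                    occ_totals.append(
                        min(float(rng.uniform(2.0, 30.0)), cap)
                        if n_regular
                        else float("nan")
                    )
            if n_regular == 0:
                shares = rng.dirichlet(np.full(n_episodes, 2.0))
                occ_totals = [total_target * float(s) for s in shares]
                reg_totals: list[float] = []
            else:
                remaining = max(total_target - sum(occ_totals), 0.1 * total_target)
                shares = rng.dirichlet(np.full(n_regular, 4.0))
                reg_totals = [remaining * float(s) for s in shares]

            expected_packs = float(np.dot(spec.pack_probs, [1, 2, 3]))
            available = list(spec.atc_pool)
            occ_iter = iter(occ_totals)
            reg_iter = iter(reg_totals)
            for flag in regular_flags:
                if flag:
                    episode_total = next(reg_iter)
                    # refill chain covering the window start to delivery
                    start = int(rng.integers(7 * spec.window_start_week - 7, 0))
                    days = [start]
                    while True:
                        gap = int(
                            np.clip(round(rng.normal(spec.gap_mean, spec.gap_jitter)), 7, 44)
                        )
                        nxt = days[-1] + gap
                        if nxt > delivery_day:
                            break
                        days.append(nxt)
                    # the episode target is the *in-window* mass; inflate the
                    # dispensed total by the fraction redistributed before the
                    # window or past its end (weaning tail, post-term weeks)
                    duration = days[-1] - days[0]
                    d_bar = duration / max(len(days) - 1, 1)
                    win_end = 7 * min(end_week, 38) + 6
                    win_start = 7 * spec.window_start_week
                    in_window = max(win_end - max(days[0], win_start), 1)
                    coverage = min(1.0, in_window / (duration + d_bar))
                    episode_total /= coverage
                else:
                    episode_total = next(occ_iter)
                    n_disp = 1 if rng.random() < 0.8 else 2
                    first = int(rng.integers(lo_day, delivery_day - 60))
                    days = [first]
                    if n_disp == 2:
                        second = first + int(rng.integers(46, 121))
                        if second <= delivery_day:
                            days.append(second)
                per_disp_target = episode_total / len(days)
                atc, ddd = _pick_atc(available, per_disp_target, expected_packs)
                available.remove((atc, ddd))
                for day in days:
                    n_packs = int(rng.choice([1, 2, 3], p=spec.pack_probs))
                    dispensations.append(
                        DispensationRecord(
                            pregnancy_id=pid,
                            atc=atc,
                            day=int(day),
                            n_packs=n_packs,
                            ddd_per_pack=ddd,
                        )
                    )

        pathology = premature = None
        if spec.outcome_probs is not None:
            p_path = spec.outcome_probs[stratum] if stratum is not None else 0.10
            pathology = bool(rng.random() < p_path)
            premature = bool(rng.random() < spec.premature_prob)
        pregnancies.append(
            PregnancyRecord(
                pregnancy_id=pid,
                end_week=end_week,
                neonatal_pathology=pathology,
                premature=premature,
            )
        )
    return pregnancies, dispensations, planted
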