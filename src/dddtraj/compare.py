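"""Three-step comparison of trajectory-calculation scenarios.

Step 1 pools all weekly DDD values of the exposed pregnancies of a scenario
into global indicators (sum of DDDs, mean, sd, 90/95 percentiles, max).
Step 2 contrasts each pregnancy's trajectory between two scenarios
(unchanged / increased / decreased / compensated).  Step 3 cross-tabulates
two cluster partitions (letters A-D plus "Non-exposed") into a 5x5
concordance table and summarizes each cluster's per-pregnancy average
weekly DDD and outcome proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import PregnancyRecord, ScenarioConfig, ValidationError, WeeklyTrajectory
from .engine import is_exposed
from .clustering import ClusterModel, LETTERS

__all__ = [
    "GlobalIndicators",
    "TrajectoryDelta",
    "ConcordanceTable",
    "ClusterSummary",
    "global_indicators",
    "trajectory_delta",
    "concordance",
    "cluster_summary",
    "NON_EXPOSED",
]

NON_EXPOSED = "Non-exposed"


@dataclass
class GlobalIndicators:
    """Pooled weekly-DDD statistics over the exposed pregnancies of a scenario.

    Percentiles are empirical quantiles with linear interpolation between
    order statistics; ``sd`` is the sample standard deviation (ddof=1).
    Statistics are None when no pregnancy is exposed.
    """

    scenario: int
    n_exposed: int
    sum_ddd: float
    weekly_mean: float | None = None
    weekly_sd: float | None = None
    weekly_p90: float | None = None
    weekly_p95: float | None = None
    weekly_max: float | None = None

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


@dataclass
class TrajectoryDelta:
    """Change of one pregnancy's trajectory between two scenarios.

    ``unchanged`` means every weekly value agrees to tolerance;
    ``compensated`` means some weeks changed yet the DDD total did not
    (a compensation effect between weeks).  ``total_diff`` is sum(b) -
    sum(a).
    """

    pregnancy_id: str
    unchanged: bool
    total_diff: float
    mean_weekly_diff: float
    compensated: bool


@dataclass
class ConcordanceTable:
    """5x5 cross-classification of two partitions over {A..D, Non-exposed}.

    The grand total equals the size of the cohort universe; margins equal
    the per-scenario category counts.  Change metrics count pregnancies that
    switched exposure status, switched cluster, and jumped at least two
    cluster levels (with A < B < C < D).
    """

    categories: tuple[str, ...]
    table: np.ndarray  # (5, 5) ints; rows = first partition
    n_status_changes: int = 0
    n_cluster_switches: int = 0
    n_big_switches: int = 0

    @property
    def grand_total(self) -> int:
        return int(self.table.sum())

    @property
    def row_margins(self) -> np.ndarray:
        return self.table.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.table.sum(axis=0)

    def as_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.table, index=self.categories, columns=self.categories)
        df["Sum"] = df.sum(axis=1)
        df.loc["Sum"] = df.sum(axis=0)
        return df


@dataclass
class ClusterSummary:
    """Per-cluster statistics of per-pregnancy average weekly DDD.

    Each pregnancy is first reduced to its own average weekly DDD
    (trajectory sum / trajectory length); the cluster mean of those
    averages differs from the pooled weekly mean when trajectory lengths
    vary — the two are distinct summaries.  Boolean outcomes are reported
    as proportions among pregnancies with a non-missing value.
    """

    clusters: list[str]
    n: dict[str, int]
    mean: dict[str, float]
    sd: dict[str, float]
    median: dict[str, float]
    min: dict[str, float]
    max: dict[str, float]
    outcome_proportions: dict[str, dict[str, float]] = field(default_factory=dict)
    outcome_n: dict[str, dict[str, int]] = field(default_factory=dict)

    def as_dataframe(self) -> pd.DataFrame:
        rows = []
        for c in self.clusters:
            row = {
                "cluster": c,
                "n": self.n[c],
                "mean": self.mean[c],
                "sd": self.sd[c],
                "median": self.median[c],
                "min": self.min[c],
                "max": self.max[c],
            }
            for outcome, per_cluster in self.outcome_proportions.items():
                row[outcome] = per_cluster.get(c, float("nan"))
            rows.append(row)
        return pd.DataFrame(rows)


def global_indicators(
    trajectories: Sequence[WeeklyTrajectory], config: ScenarioConfig
) -> GlobalIndicators:
    """Pool all weekly values of the exposed trajectories of one scenario."""
    exposed = [t for t in trajectories if is_exposed(t, config)]
    if not exposed:
        return GlobalIndicators(scenario=config.scenario, n_exposed=0, sum_ddd=0.0)
    pooled = np.concatenate([t.values for t in exposed])
    return GlobalIndicators(
        scenario=config.scenario,
        n_exposed=len(exposed),
        sum_ddd=float(pooled.sum()),
        weekly_mean=float(pooled.mean()),
        weekly_sd=float(pooled.std(ddof=1)) if len(pooled) > 1 else 0.0,
        weekly_p90=float(np.percentile(pooled, 90)),
        weekly_p95=float(np.percentile(pooled, 95)),
        weekly_max=float(pooled.max()),
    )


def trajectory_delta(
    a: WeeklyTrajectory, b: WeeklyTrajectory, tol: float = 1e-9
) -> TrajectoryDelta:
    """Compare one pregnancy's trajectories under two scenarios."""
    if a.pregnancy_id != b.pregnancy_id:
        raise ValidationError("trajectory_delta requires the same pregnancy")
    if a.start_week != b.start_week or len(a.values) != len(b.values):
        raise ValidationError(
            f"grid mismatch for {a.pregnancy_id!r}: "
            f"({a.start_week}, n={len(a.values)}) vs ({b.start_week}, n={len(b.values)})"
        )
    unchanged = bool(np.max(np.abs(b.values - a.values), initial=0.0) <= tol)
    total_diff = 0.0 if unchanged else float(b.values.sum() - a.values.sum())
    compensated = (not unchanged) and abs(total_diff) <= tol
    return TrajectoryDelta(
        pregnancy_id=a.pregnancy_id,
        unchanged=unchanged,
        total_diff=total_diff,
        mean_weekly_diff=total_diff / len(a.values),
        compensated=compensated,
    )


def concordance(
    labels_a: Mapping[str, str],
    labels_b: Mapping[str, str],
    universe: Sequence[str],
    k: int = 4,
) -> ConcordanceTable:
    """Cross-tabulate two cluster partitions over a cohort universe.

    Pregnancies absent from a label map count as Non-exposed under that
    scenario.  A pregnancy labelled in either map but missing from the
    universe is an error.
    """
    categories = tuple(LETTERS[:k]) + (NON_EXPOSED,)
    index = {c: i for i, c in enumerate(categories)}
    uni = set(universe)
    if len(uni) != len(universe):
        raise ValidationError("universe contains duplicate pregnancy ids")
    for name, lab in (("first", labels_a), ("second", labels_b)):
        stray = set(lab) - uni
        if stray:
            raise ValidationError(
                f"{name} partition labels pregnancies outside the universe: "
                f"{sorted(stray)[:5]}"
            )
        bad = set(lab.values()) - set(categories)
        if bad:
            raise ValidationError(f"unknown cluster letters: {sorted(bad)}")

    table = np.zeros((k + 1, k + 1), dtype=int)
    n_status = n_switch = n_big = 0
    for pid in universe:
        ca = labels_a.get(pid, NON_EXPOSED)
        cb = labels_b.get(pid, NON_EXPOSED)
        table[index[ca], index[cb]] += 1
        a_exp, b_exp = ca != NON_EXPOSED, cb != NON_EXPOSED
        if a_exp != b_exp:
            n_status += 1
        elif a_exp and ca != cb:
            n_switch += 1
            if abs(index[ca] - index[cb]) >= 2:
                n_big += 1
    return ConcordanceTable(
        categories=categories,
        table=table,
        n_status_changes=n_status,
        n_cluster_switches=n_switch,
        n_big_switches=n_big,
    )


def cluster_summary(
    model: ClusterModel,
    trajectories: Mapping[str, WeeklyTrajectory],
    pregnancies: Sequence[PregnancyRecord] = (),
    outcome_columns: Sequence[str] | None = None,
) -> ClusterSummary:
    """Summarize per-pregnancy average weekly DDD and outcomes by cluster.

    ``outcome_columns`` selects boolean outcome/covariate columns to report
    as per-cluster proportions; by default every boolean field present on
    the pregnancy records is used.
    """
    missing = [pid for pid in model.labels if pid not in trajectories]
    if missing:
        raise ValidationError(
            f"labelled pregnancies without a trajectory: {missing[:5]}"
        )
    clusters = sorted(set(model.labels.values()))
    averages: dict[str, list[float]] = {c: [] for c in clusters}
    for pid, letter in model.labels.items():
        averages[letter].append(trajectories[pid].mean_weekly())

    summary = ClusterSummary(
        clusters=clusters,
        n={c: len(v) for c, v in averages.items()},
        mean={c: float(np.mean(v)) for c, v in averages.items()},
        sd={c: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0 for c, v in averages.items()},
        median={c: float(np.median(v)) for c, v in averages.items()},
        min={c: float(np.min(v)) for c, v in averages.items()},
        max={c: float(np.max(v)) for c, v in averages.items()},
    )

    if pregnancies:
        by_pid = {p.pregnancy_id: p for p in pregnancies}

        def bool_value(p: PregnancyRecord, col: str):
            if col == "neonatal_pathology":
                return p.neonatal_pathology
            if col == "premature":
                return p.premature
            v = p.covariates.get(col)
            return v if isinstance(v, bool) else None

        if outcome_columns is None:
            cols: list[str] = []
            for p in by_pid.values():
                if p.neonatal_pathology is not None and "neonatal_pathology" not in cols:
                    cols.append("neonatal_pathology")
                if p.premature is not None and "premature" not in cols:
                    cols.append("premature")
                for c, v in p.covariates.items():
                    if isinstance(v, bool) and c not in cols:
                        cols.append(c)
            outcome_columns = cols
        for col in outcome_columns:
            props: dict[str, float] = {}
            counts: dict[str, int] = {}
            for c in clusters:
                vals = [
                    bool_value(by_pid[pid], col)
                    for pid, letter in model.labels.items()
                    if letter == c and pid in by_pid
                ]
                known = [v for v in vals if v is not None]
                counts[c] = sum(known)
                props[c] = (sum(known) / len(known)) if known else float("nan")
            summary.outcome_proportions[col] = props
            summary.outcome_n[col] = counts
    return summary
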