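"""Domain types and delimited-file I/O for dispensation and pregnancy records.

Conventions
-----------
Days are integers relative to conception: day 0 is the first day of
gestation, negative days precede it.  Gestational week ``w`` spans days
``[7w, 7w + 6]``, so week -4 is days -28..-22 and the -13-week dispensation
lookback means "day >= -91".

All files are delimited text (comma by default, tab accepted), UTF-8, with a
header row.  Dispensations need columns ``pregnancy_id, atc, day, n_packs,
ddd_per_pack``; pregnancies need ``pregnancy_id, end_week`` plus any number
of optional covariate/outcome columns (boolean-like columns are parsed to
booleans, everything else kept as strings).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DispensationRecord",
    "PregnancyRecord",
    "ScenarioConfig",
    "WeeklyTrajectory",
    "SchemaError",
    "ValidationError",
    "read_dispensations",
    "write_dispensations",
    "read_pregnancies",
    "write_pregnancies",
    "read_trajectories",
    "write_trajectories",
    "read_labels",
    "write_labels",
    "write_table",
]

#: Week past which trajectories are clipped ("between -4 and 38").
MAX_TRAJECTORY_WEEK = 38


class SchemaError(ValueError):
    """A required column is missing from an input file."""


class ValidationError(ValueError):
    """A row violates a type invariant (reported with its 1-based row number)."""


@dataclass(frozen=True)
class DispensationRecord:
    """One pharmacy dispensation event.

    ``day`` is relative to conception; ``n_packs`` is the number of packs
    handed over and ``ddd_per_pack`` the number of Defined Daily Doses one
    pack contains, so the dispensed quantity is ``n_packs * ddd_per_pack``
    DDDs (unless a scenario ignores the pack count).
    """

    pregnancy_id: str
    atc: str
    day: int
    n_packs: int
    ddd_per_pack: float

    def __post_init__(self) -> None:
        if not self.atc:
            raise ValidationError("atc must be non-empty")
        if self.n_packs < 1:
            raise ValidationError(f"n_packs must be >= 1, got {self.n_packs}")
        if not (self.ddd_per_pack > 0):
            raise ValidationError(
                f"ddd_per_pack must be > 0, got {self.ddd_per_pack}"
            )


@dataclass(frozen=True)
class PregnancyRecord:
    """A pregnancy and its outcome.

    ``end_week`` is the gestational week of delivery.  ``covariates`` holds
    arbitrary maternal covariates (e.g. diabetes, preeclampsia flags);
    ``neonatal_pathology`` and ``premature`` are the outcome flags reported
    per exposure cluster.
    """

    pregnancy_id: str
    end_week: int
    covariates: Mapping[str, object] = field(default_factory=dict)
    neonatal_pathology: bool | None = None
    premature: bool | None = None

    def __post_init__(self) -> None:
        if self.end_week < 1:
            raise ValidationError(f"end_week must be >= 1, got {self.end_week}")


@dataclass(frozen=True)
class ScenarioConfig:
    """Settings for one trajectory-calculation scenario.

    scenario
        1: pack count ignored (forced to 1), no periodicity adjustment;
        2: pack count used, no periodicity adjustment;
        3: pack count used plus periodicity adjustment of regular refills.
    regularity_window_days
        A dispensation renewed within this many days belongs to a regular
        refill chain (default 45: one month of treatment plus 15 days of
        flexibility).
    lookback_week
        Dispensations before this gestational week are discarded outright
        (default -13, so that supplies active at week -4 are captured).
    window_start_week
        First week of the exposure window (default -4).
    weaning_factor
        Fraction of the refill rate F kept after the last regular
        dispensation until the remaining supply is exhausted (default 0.5).
    exposure_epsilon
        A pregnancy is "exposed" iff some weekly DDD exceeds this.
    pool_regular
        If True, F is computed from all regular dispensations of a
        pregnancy x ATC pooled across chains instead of per maximal chain.
    """

    scenario: int
    regularity_window_days: int = 45
    lookback_week: int = -13
    window_start_week: int = -4
    weaning_factor: float = 0.5
    exposure_epsilon: float = 1e-9
    pool_regular: bool = False
    max_week: int = MAX_TRAJECTORY_WEEK

    def __post_init__(self) -> None:
        if self.scenario not in (1, 2, 3):
            raise ValidationError(f"scenario must be 1, 2 or 3, got {self.scenario}")
        if self.regularity_window_days <= 0:
            raise ValidationError("regularity_window_days must be > 0")
        if not (self.lookback_week <= self.window_start_week < 0):
            raise ValidationError(
                "require lookback_week <= window_start_week < 0, got "
                f"{self.lookback_week}, {self.window_start_week}"
            )
        if not (0 < self.weaning_factor <= 1):
            raise ValidationError("weaning_factor must be in (0, 1]")
        if not (self.exposure_epsilon > 0):
            raise ValidationError("exposure_epsilon must be > 0")


@dataclass
class WeeklyTrajectory:
    """Weekly DDD exposure vector for one pregnancy under one scenario.

    ``values[i]`` is the DDD total of gestational week ``start_week + i``;
    the vector spans ``start_week`` through ``min(end_week, 38)``.
    """

    pregnancy_id: str
    scenario: int
    start_week: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValidationError("trajectory values must be a 1-D vector")
        if np.any(self.values < 0):
            raise ValidationError("trajectory values must be nonnegative")

    @property
    def weeks(self) -> np.ndarray:
        return np.arange(self.start_week, self.start_week + len(self.values))

    @property
    def end_week(self) -> int:
        return self.start_week + len(self.values) - 1

    def total(self) -> float:
        return float(self.values.sum())

    def mean_weekly(self) -> float:
        return float(self.values.mean())


# ---------------------------------------------------------------------------
# I/O helpers


def _read_delimited(path: str | Path, sep: str | None) -> pd.DataFrame:
    path = Path(path)
    if sep is None:
        with open(path, "r", encoding="utf-8") as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column '{col}'")


_TRUE = {"1", "true", "yes", "t", "y"}
_FALSE = {"0", "false", "no", "f", "n"}


def _parse_bool(text: str) -> bool | None:
    s = text.strip().lower()
    if s == "" or s == "na" or s == "nan":
        return None
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValueError(f"not a boolean: {text!r}")


def read_dispensations(path: str | Path, sep: str | None = None) -> list[DispensationRecord]:
    """Read dispensation records, preserving row order and duplicates.

    Raises :class:`SchemaError` for a missing column and
    :class:`ValidationError` (citing the 1-based data row) for bad values.
    """
    df = _read_delimited(path, sep)
    _require_columns(df, ["pregnancy_id", "atc", "day", "n_packs", "ddd_per_pack"], path)
    records: list[DispensationRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            records.append(
                DispensationRecord(
                    pregnancy_id=str(row.pregnancy_id),
                    atc=str(row.atc).strip(),
                    day=int(row.day),
                    n_packs=int(row.n_packs),
                    ddd_per_pack=float(row.ddd_per_pack),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from exc
    return records


def write_dispensations(records: Iterable[DispensationRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "pregnancy_id": r.pregnancy_id,
                "atc": r.atc,
                "day": r.day,
                "n_packs": r.n_packs,
                "ddd_per_pack": _fmt(r.ddd_per_pack),
            }
            for r in records
        ],
        columns=["pregnancy_id", "atc", "day", "n_packs", "ddd_per_pack"],
    )
    df.to_csv(path, index=False)


_CORE_PREGNANCY_COLS = ("pregnancy_id", "end_week")
_OUTCOME_COLS = ("neonatal_pathology", "premature")


def read_pregnancies(path: str | Path, sep: str | None = None) -> list[PregnancyRecord]:
    """Read pregnancy records; extra columns become covariates/outcome flags."""
    df = _read_delimited(path, sep)
    _require_columns(df, _CORE_PREGNANCY_COLS, path)
    extra = [c for c in df.columns if c not in _CORE_PREGNANCY_COLS]
    records: list[PregnancyRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        d = row._asdict()
        try:
            pid = str(d["pregnancy_id"])
            if pid in seen:
                raise ValidationError(f"duplicate pregnancy_id {pid!r}")
            seen.add(pid)
            covs: dict[str, object] = {}
            outcomes: dict[str, bool | None] = {}
            for col in extra:
                raw = str(d[col])
                if col in _OUTCOME_COLS:
                    outcomes[col] = _parse_bool(raw)
                else:
                    try:
                        covs[col] = _parse_bool(raw)
                    except ValueError:
                        covs[col] = raw
            records.append(
                PregnancyRecord(
                    pregnancy_id=pid,
                    end_week=int(d["end_week"]),
                    covariates=covs,
                    neonatal_pathology=outcomes.get("neonatal_pathology"),
                    premature=outcomes.get("premature"),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from exc
    return records


def write_pregnancies(records: Sequence[PregnancyRecord], path: str | Path) -> None:
    cov_cols: list[str] = []
    for r in records:
        for c in r.covariates:
            if c not in cov_cols:
                cov_cols.append(c)
    has_np = any(r.neonatal_pathology is not None for r in records)
    has_pm = any(r.premature is not None for r in records)
    rows = []
    for r in records:
        row: dict[str, object] = {"pregnancy_id": r.pregnancy_id, "end_week": r.end_week}
        if has_np:
            row["neonatal_pathology"] = _fmt_opt_bool(r.neonatal_pathology)
        if has_pm:
            row["premature"] = _fmt_opt_bool(r.premature)
        for c in cov_cols:
            v = r.covariates.get(c, "")
            row[c] = _fmt_opt_bool(v) if isinstance(v, bool) else v
        rows.append(row)
    cols = ["pregnancy_id", "end_week"]
    cols += ["neonatal_pathology"] if has_np else []
    cols += ["premature"] if has_pm else []
    cols += cov_cols
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def _fmt(x: float) -> str:
    """Fixed 6-significant-digit formatting so outputs are diffable."""
    if x == math.floor(x) and abs(x) < 1e15:
        return str(int(x))
    return f"{x:.6g}"


def _fmt_opt_bool(v: bool | None) -> str:
    return "" if v is None else ("1" if v else "0")


def write_trajectories(trajectories: Iterable[WeeklyTrajectory], path: str | Path) -> None:
    """Write trajectories in long format: pregnancy_id, scenario, week, ddd."""
    rows = []
    for t in trajectories:
        for w, v in zip(t.weeks, t.values):
            rows.append((t.pregnancy_id, t.scenario, int(w), _fmt(float(v))))
    pd.DataFrame(rows, columns=["pregnancy_id", "scenario", "week", "ddd"]).to_csv(
        path, index=False
    )


def read_trajectories(path: str | Path, sep: str | None = None) -> list[WeeklyTrajectory]:
    df = _read_delimited(path, sep)
    _require_columns(df, ["pregnancy_id", "scenario", "week", "ddd"], path)
    out: list[WeeklyTrajectory] = []
    for (pid, scen), grp in df.groupby(["pregnancy_id", "scenario"], sort=False):
        weeks = grp["week"].astype(int).to_numpy()
        vals = grp["ddd"].astype(float).to_numpy()
        order = np.argsort(weeks)
        weeks, vals = weeks[order], vals[order]
        if not np.array_equal(weeks, np.arange(weeks[0], weeks[0] + len(weeks))):
            raise ValidationError(
                f"{path}: non-contiguous week axis for pregnancy {pid!r}"
            )
        out.append(
            WeeklyTrajectory(
                pregnancy_id=str(pid), scenario=int(scen), start_week=int(weeks[0]), values=vals
            )
        )
    return out


def write_labels(labels: Mapping[str, str], scenario: int, path: str | Path) -> None:
    """Write cluster labels as (pregnancy_id, scenario, cluster_letter)."""
    rows = [(pid, scenario, letter) for pid, letter in labels.items()]
    pd.DataFrame(rows, columns=["pregnancy_id", "scenario", "cluster"]).to_csv(
        path, index=False
    )


def read_labels(path: str | Path, sep: str | None = None) -> dict[str, str]:
    df = _read_delimited(path, sep)
    _require_columns(df, ["pregnancy_id", "cluster"], path)
    return {str(r.pregnancy_id): str(r.cluster) for r in df.itertuples(index=False)}


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a result table with fixed formatting (6 significant digits)."""
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(lambda x: "" if pd.isna(x) else _fmt(float(x)))
    out.to_csv(path, index=False)
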