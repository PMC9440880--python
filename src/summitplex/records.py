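"""Domain records for climber-expedition cohorts and their flat-table IO.

Two tables describe a cohort: one row per climber participation (demographics,
oxygen use, outcome, failure cause) and one row per expedition (peak, strict
temporal order, roster, logistics counts). Files are plain CSV or TSV with a
header row; the delimiter is sniffed (comma or tab only), encoding UTF-8.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd


class Outcome(str, Enum):
    """Result of one climber's participation in one expedition."""

    SUMMIT_SUCCESS = "summit_success"
    NO_SUMMIT = "no_summit"
    DEATH = "death"


class FailureCause(str, Enum):
    """Failure taxonomy: altitude sickness / cold, logistics and planning,
    exhaustion and motivation, accident or injury; ``NONE`` for successes."""

    ALTITUDE = "altitude"
    LOGISTICS = "logistics"
    FATIGUE = "fatigue"
    ACCIDENT = "accident"
    NONE = "none"


FAILURE_CATEGORIES = (
    FailureCause.ALTITUDE,
    FailureCause.LOGISTICS,
    FailureCause.FATIGUE,
    FailureCause.ACCIDENT,
)


class RecordsError(Exception):
    """Base class for cohort-table errors."""


class SchemaError(RecordsError):
    """A required column is missing from an input table."""


class RowError(RecordsError):
    """A row-level parse or validation failure; carries the 1-based data
    row number (header excluded)."""

    def __init__(self, row: int, message: str):
        super().__init__(f"row {row}: {message}")
        self.row = row


class ReferentialError(RecordsError):
    """Cross-reference between the two tables failed to resolve."""


@dataclass(frozen=True)
class ClimberExpeditionRecord:
    climber_id: str
    expedition_id: str
    age: int
    sex: str  # "male" | "female"
    nationality: str
    is_hired: bool
    oxygen_ascent: bool
    oxygen_descent: bool
    experience_8000m: int
    outcome: Outcome
    failure_cause: FailureCause

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError(f"age must be >= 0, got {self.age}")
        if self.sex not in ("male", "female"):
            raise ValueError(f"unknown sex token {self.sex!r}")
        if self.experience_8000m < 0:
            raise ValueError("experience_8000m must be >= 0")
        success = self.outcome is Outcome.SUMMIT_SUCCESS
        if success != (self.failure_cause is FailureCause.NONE):
            raise ValueError(
                "failure_cause must be 'none' exactly when outcome is summit_success"
            )


@dataclass(frozen=True)
class Expedition:
    expedition_id: str
    peak_id: str
    peak_height: float
    time_index: int
    roster: frozenset[str]
    days_to_summit: int
    n_camps: int
    n_members: int
    n_hired: int

    def __post_init__(self) -> None:
        if not self.roster:
            raise ValueError("roster must be nonempty")
        for field in ("days_to_summit", "n_camps", "n_members", "n_hired"):
            if getattr(self, field) < 0:
                raise ValueError(f"{field} must be >= 0")


@dataclass(frozen=True)
class ExpeditionOutcomeSummary:
    expedition_id: str
    success_rate: float


CLIMBER_COLUMNS = (
    "climber_id",
    "expedition_id",
    "age",
    "sex",
    "nationality",
    "is_hired",
    "oxygen_ascent",
    "oxygen_descent",
    "experience_8000m",
    "outcome",
    "failure_cause",
)

EXPEDITION_COLUMNS = (
    "expedition_id",
    "peak_id",
    "peak_height",
    "time_index",
    "roster",
    "days_to_summit",
    "n_camps",
    "n_members",
    "n_hired",
)

_TRUE_TOKENS = {"true", "1", "yes"}
_FALSE_TOKENS = {"false", "0", "no"}


def _parse_bool(token: str, row: int, column: str) -> bool:
    low = token.strip().lower()
    if low in _TRUE_TOKENS:
        return True
    if low in _FALSE_TOKENS:
        return False
    raise RowError(row, f"unknown boolean token {token!r} in column {column}")


def _parse_int(token: str, row: int, column: str) -> int:
    try:
        return int(token)
    except ValueError:
        raise RowError(row, f"non-integer token {token!r} in column {column}") from None


def _sniff_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") > header.count(",") else ","


def _read_table(path: Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {', '.join(missing)}")
    return df


def read_records(
    path_climbers: str | Path, path_expeditions: str | Path
) -> tuple[list[ClimberExpeditionRecord], list[Expedition]]:
    """Read and validate the climber and expedition tables.

    Returns typed records plus expeditions sorted by ``time_index``. Raises
    :class:`SchemaError` for missing columns, :class:`RowError` for bad
    tokens, :class:`ReferentialError` when cross-references fail.
    """
    edf = _read_table(Path(path_expeditions), EXPEDITION_COLUMNS)
    expeditions: dict[str, Expedition] = {}
    seen_time: dict[int, str] = {}
    for i, row in enumerate(edf.itertuples(index=False), start=1):
        eid = row.expedition_id
        if eid in expeditions:
            raise RowError(i, f"duplicate expedition_id {eid!r}")
        t = _parse_int(row.time_index, i, "time_index")
        if t in seen_time:
            raise RowError(i, f"time_index {t} already used by {seen_time[t]!r}")
        seen_time[t] = eid
        roster = frozenset(v for v in row.roster.split("|") if v)
        try:
            expeditions[eid] = Expedition(
                expedition_id=eid,
                peak_id=row.peak_id,
                peak_height=float(row.peak_height),
                time_index=t,
                roster=roster,
                days_to_summit=_parse_int(row.days_to_summit, i, "days_to_summit"),
                n_camps=_parse_int(row.n_camps, i, "n_camps"),
                n_members=_parse_int(row.n_members, i, "n_members"),
                n_hired=_parse_int(row.n_hired, i, "n_hired"),
            )
        except ValueError as exc:
            raise RowError(i, str(exc)) from None

    cdf = _read_table(Path(path_climbers), CLIMBER_COLUMNS)
    records: list[ClimberExpeditionRecord] = []
    seen_pairs: set[tuple[str, str]] = set()
    for i, row in enumerate(cdf.itertuples(index=False), start=1):
        try:
            outcome = Outcome(row.outcome)
        except ValueError:
            raise RowError(i, f"unknown outcome token {row.outcome!r}") from None
        try:
            cause = FailureCause(row.failure_cause)
        except ValueError:
            raise RowError(
                i, f"unknown failure_cause token {row.failure_cause!r}"
            ) from None
        if row.sex not in ("male", "female"):
            raise RowError(i, f"unknown sex token {row.sex!r}")
        key = (row.climber_id, row.expedition_id)
        if key in seen_pairs:
            raise RowError(i, f"duplicate (climber_id, expedition_id) pair {key}")
        seen_pairs.add(key)
        try:
            rec = ClimberExpeditionRecord(
                climber_id=row.climber_id,
                expedition_id=row.expedition_id,
                age=_parse_int(row.age, i, "age"),
                sex=row.sex,
                nationality=row.nationality,
                is_hired=_parse_bool(row.is_hired, i, "is_hired"),
                oxygen_ascent=_parse_bool(row.oxygen_ascent, i, "oxygen_ascent"),
                oxygen_descent=_parse_bool(row.oxygen_descent, i, "oxygen_descent"),
                experience_8000m=_parse_int(row.experience_8000m, i, "experience_8000m"),
                outcome=outcome,
                failure_cause=cause,
            )
        except ValueError as exc:
            raise RowError(i, str(exc)) from None
        exp = expeditions.get(rec.expedition_id)
        if exp is None:
            raise ReferentialError(
                f"record ({rec.climber_id}, {rec.expedition_id}) references an "
                "expedition_id absent from the expedition table"
            )
        if rec.climber_id not in exp.roster:
            raise ReferentialError(
                f"climber {rec.climber_id!r} is not on the roster of "
                f"expedition {rec.expedition_id!r}"
            )
        records.append(rec)

    ordered = sorted(expeditions.values(), key=lambda e: e.time_index)
    return records, ordered


def write_records(
    records: Iterable[ClimberExpeditionRecord],
    expeditions: Iterable[Expedition],
    path_climbers: str | Path,
    path_expeditions: str | Path,
) -> None:
    """Write the two tables as deterministic, round-trippable CSV."""
    exps = sorted(expeditions, key=lambda e: e.time_index)
    order = {e.expedition_id: e.time_index for e in exps}
    erows = [
        {
            "expedition_id": e.expedition_id,
            "peak_id": e.peak_id,
            "peak_height": e.peak_height,
            "time_index": e.time_index,
            "roster": "|".join(sorted(e.roster)),
            "days_to_summit": e.days_to_summit,
            "n_camps": e.n_camps,
            "n_members": e.n_members,
            "n_hired": e.n_hired,
        }
        for e in exps
    ]
    pd.DataFrame(erows, columns=list(EXPEDITION_COLUMNS)).to_csv(
        path_expeditions, index=False
    )
    recs = sorted(records, key=lambda r: (order.get(r.expedition_id, -1), r.climber_id))
    crows = [
        {
            "climber_id": r.climber_id,
            "expedition_id": r.expedition_id,
            "age": r.age,
            "sex": r.sex,
            "nationality": r.nationality,
            "is_hired": str(r.is_hired).lower(),
            "oxygen_ascent": str(r.oxygen_ascent).lower(),
            "oxygen_descent": str(r.oxygen_descent).lower(),
            "experience_8000m": r.experience_8000m,
            "outcome": r.outcome.value,
            "failure_cause": r.failure_cause.value,
        }
        for r in recs
    ]
    pd.DataFrame(crows, columns=list(CLIMBER_COLUMNS)).to_csv(path_climbers, index=False)


def records_by_expedition(
    records: Iterable[ClimberExpeditionRecord],
) -> dict[str, list[ClimberExpeditionRecord]]:
    out: dict[str, list[ClimberExpeditionRecord]] = defaultdict(list)
    for rec in records:
        out[rec.expedition_id].append(rec)
    return dict(out)


def expedition_success_rates(
    records: Iterable[ClimberExpeditionRecord],
    expeditions: Iterable[Expedition],
) -> list[ExpeditionOutcomeSummary]:
    """Fraction of each roster that summited, one summary per expedition."""
    by_exp = records_by_expedition(records)
    out = []
    for exp in sorted(expeditions, key=lambda e: e.time_index):
        recs = by_exp.get(exp.expedition_id, [])
        have = {r.climber_id for r in recs}
        if have != exp.roster:
            missing = sorted(exp.roster - have) + sorted(have - exp.roster)
            raise ReferentialError(
                f"expedition {exp.expedition_id!r}: records do not cover the "
                f"roster exactly (mismatch: {missing[:5]})"
            )
        n_success = sum(r.outcome is Outcome.SUMMIT_SUCCESS for r in recs)
        out.append(
            ExpeditionOutcomeSummary(exp.expedition_id, n_success / len(exp.roster))
        )
    return out


def prior_climb_counts(
    records: Iterable[ClimberExpeditionRecord],
    expeditions: Iterable[Expedition],
) -> dict[tuple[str, str], int]:
    """Number of the climber's logged expeditions strictly before each record.

    "Strictly before" means a smaller ``time_index``; expeditions sharing a
    time index (disallowed by validation anyway) would never count.
    """
    import bisect

    records = list(records)
    order = {e.expedition_id: e.time_index for e in expeditions}
    seen: dict[str, set[int]] = defaultdict(set)
    for rec in records:
        seen[rec.climber_id].add(order[rec.expedition_id])
    per_climber = {c: sorted(ts) for c, ts in seen.items()}  # distinct expeditions
    out: dict[tuple[str, str], int] = {}
    for rec in records:
        t = order[rec.expedition_id]
        out[(rec.climber_id, rec.expedition_id)] = bisect.bisect_left(
            per_climber[rec.climber_id], t
        )
    return out


def experience_8000m_counts(
    records: Iterable[ClimberExpeditionRecord],
    expeditions: Iterable[Expedition],
    height_threshold: float = 8000.0,
) -> dict[tuple[str, str], int]:
    """Recompute per-record experience above ``height_threshold`` meters.

    The count equals the climber's strictly earlier in-cohort expeditions on
    peaks at or above the threshold, plus a per-climber baseline taken from
    the climber's earliest record (ascents predating the cohort cannot be
    reconstructed from its history).
    """
    exps = {e.expedition_id: e for e in expeditions}
    recs = sorted(records, key=lambda r: exps[r.expedition_id].time_index)
    baseline: dict[str, int] = {}
    high_count: dict[str, int] = defaultdict(int)
    out: dict[tuple[str, str], int] = {}
    for rec in recs:
        c = rec.climber_id
        if c not in baseline:
            baseline[c] = rec.experience_8000m
        out[(c, rec.expedition_id)] = baseline[c] + high_count[c]
        if exps[rec.expedition_id].peak_height >= height_threshold:
            high_count[c] += 1
    return out


def validate_experience(
    records: Iterable[ClimberExpeditionRecord],
    expeditions: Iterable[Expedition],
) -> None:
    """Check that emitted experience_8000m columns are internally consistent
    with the recomputation in :func:`experience_8000m_counts`."""
    records = list(records)
    expected = experience_8000m_counts(records, expeditions)
    for rec in records:
        want = expected[(rec.climber_id, rec.expedition_id)]
        if rec.experience_8000m != want:
            raise ReferentialError(
                f"experience_8000m for ({rec.climber_id}, {rec.expedition_id}) "
                f"is {rec.experience_8000m}, history implies {want}"
            )
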