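"""Clinical outcome scoring and group aggregation.

Covers the 15-task upper-extremity function test (per-task completion
time capped at 120 s and a 0-5 movement-quality grade, summed to a
total time and a functional ability score with maximum 75), pre/post
change scores, minimal-clinically-important-difference (MCID) flags,
the per-object game-based assessment summaries, and the group
"mean (SD)" statistics rendered in the bundled report tables.

Conventions frozen against the bundled fixtures: sample standard
deviation (n-1 denominator) and half-away-from-zero rounding for
report rendering; an improvement "surpasses" an MCID only when it
strictly exceeds the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from ._rounding import round_half_away

__all__ = [
    "WMFTTask",
    "WMFTRecord",
    "WMFTSummary",
    "MCIDThresholds",
    "GroupSummary",
    "wmft_totals",
    "change_scores",
    "mcid_flags",
    "mcid_counts",
    "group_summary",
    "load_wmft_fixture",
    "load_object_fixture",
    "load_participants",
    "load_game_catalog",
    "wmft_change_table",
    "wmft_group_summaries",
    "object_change_table",
    "assessment_table",
    "object_group_summaries",
    "abstract_numbers",
]

N_TASKS = 15
TASK_TIME_LIMIT_S = 120.0
FAS_MAX_GRADE = 5
ASSESSMENT_OBJECTS = ("coffee_mug", "wine_glass", "tennis_ball")


@dataclass(frozen=True)
class WMFTTask:
    time_s: float
    fas_grade: int

    def __post_init__(self):
        if not 0 <= self.time_s <= TASK_TIME_LIMIT_S:
            raise ValueError(f"task time {self.time_s} outside [0, {TASK_TIME_LIMIT_S}]")
        if self.fas_grade not in range(FAS_MAX_GRADE + 1):
            raise ValueError(f"FAS grade {self.fas_grade} outside 0..{FAS_MAX_GRADE}")


@dataclass(frozen=True)
class WMFTRecord:
    participant_id: int
    phase: str  # 'pre' | 'post'
    tasks: tuple[WMFTTask, ...]

    def __post_init__(self):
        if self.phase not in ("pre", "post"):
            raise ValueError(f"phase must be 'pre' or 'post', got {self.phase!r}")
        if len(self.tasks) != N_TASKS:
            raise ValueError(f"expected {N_TASKS} tasks, got {len(self.tasks)}")


@dataclass(frozen=True)
class WMFTSummary:
    """Participant-level totals (the fixture stores these directly)."""

    participant_id: int
    phase: str
    fas_total: float
    total_time_s: float


def wmft_totals(record: WMFTRecord) -> WMFTSummary:
    """Sum the 15 task grades and times."""
    return WMFTSummary(
        participant_id=record.participant_id,
        phase=record.phase,
        fas_total=float(sum(t.fas_grade for t in record.tasks)),
        total_time_s=float(sum(t.time_s for t in record.tasks)),
    )


def change_scores(pre: WMFTSummary, post: WMFTSummary) -> tuple[float, float]:
    """(FAS improvement, time reduction); positive means better."""
    if pre.participant_id != post.participant_id:
        raise ValueError(
            f"participant mismatch: {pre.participant_id} vs {post.participant_id}"
        )
    return post.fas_total - pre.fas_total, pre.total_time_s - post.total_time_s


class MCIDThresholds(BaseModel):
    """Published MCIDs: 3-6 FAS points (conservative default 6), 22 s time."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    fas_points: float = 6.0
    total_time_seconds: float = 22.0

    @model_validator(mode="after")
    def _check(self) -> "MCIDThresholds":
        if self.fas_points <= 0 or self.total_time_seconds <= 0:
            raise ValueError("MCID thresholds must be positive")
        return self


def mcid_flags(
    change: tuple[float, float], thresholds: Optional[MCIDThresholds] = None
) -> tuple[bool, bool]:
    """(fas_exceeds, time_exceeds) under strict inequality."""
    thresholds = thresholds or MCIDThresholds()
    d_fas, d_time = change
    return d_fas > thresholds.fas_points, d_time > thresholds.total_time_seconds


@dataclass(frozen=True)
class GroupSummary:
    mean: float
    sd: Optional[float]  # None when n < 2

    @property
    def rounded(self) -> tuple[int, Optional[int]]:
        return (
            round_half_away(self.mean),
            None if self.sd is None else round_half_away(self.sd),
        )

    def __str__(self) -> str:
        m, s = self.rounded
        return f"{m}" if s is None else f"{m} ({s})"


def group_summary(values: Sequence[float]) -> GroupSummary:
    """Mean and sample SD (n-1) of a group of values."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("group_summary requires at least one value")
    sd = float(np.std(arr, ddof=1)) if arr.size >= 2 else None
    return GroupSummary(mean=float(np.mean(arr)), sd=sd)


# -- bundled fixtures ----------------------------------------------------


def _read_fixture(name: str) -> pd.DataFrame:
    with resources.files("rehabgame.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_wmft_fixture() -> pd.DataFrame:
    return _read_fixture("wmft_scores.csv")


def load_object_fixture() -> pd.DataFrame:
    return _read_fixture("object_assessments.csv")


def load_participants() -> pd.DataFrame:
    return _read_fixture("participants.csv")


def load_game_catalog() -> pd.DataFrame:
    return _read_fixture("game_catalog.csv")


def load_expected_wmft_summary() -> pd.DataFrame:
    return _read_fixture("wmft_expected_summary.csv")


def load_expected_object_summary() -> pd.DataFrame:
    return _read_fixture("object_expected_summary.csv")


def load_expected_group_summary() -> pd.DataFrame:
    return _read_fixture("group_expected_summary.csv")


# -- aggregation ---------------------------------------------------------


def wmft_change_table(df: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Per-participant totals with change columns appended."""
    df = (load_wmft_fixture() if df is None else df).copy()
    df["fas_change"] = df["fas_post"] - df["fas_pre"]
    df["time_change"] = df["time_pre_s"] - df["time_post_s"]
    return df


def wmft_group_summaries(table: Optional[pd.DataFrame] = None) -> dict[str, GroupSummary]:
    """Group mean (SD) for every column of the function-test table."""
    table = wmft_change_table() if table is None else table
    cols = {
        "fas_pre": "fas_pre",
        "fas_post": "fas_post",
        "fas_change": "fas_change",
        "time_pre": "time_pre_s",
        "time_post": "time_post_s",
        "time_change": "time_change",
    }
    return {key: group_summary(table[col]) for key, col in cols.items()}


def mcid_counts(
    table: Optional[pd.DataFrame] = None, thresholds: Optional[MCIDThresholds] = None
) -> tuple[int, int]:
    """(n exceeding FAS MCID, n exceeding time MCID) over participants."""
    table = wmft_change_table() if table is None else table
    thresholds = thresholds or MCIDThresholds()
    flags = [
        mcid_flags((row.fas_change, row.time_change), thresholds)
        for row in table.itertuples()
    ]
    return sum(f for f, _ in flags), sum(t for _, t in flags)


def object_change_table(df: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Per-object rows with SR improvement and response-time decrease."""
    df = (load_object_fixture() if df is None else df).copy()
    df["sr_change"] = df["sr_post_pct"] - df["sr_pre_pct"]
    df["rt_change"] = df["rt_pre_ms"] - df["rt_post_ms"]
    return df


_OBJECT_COLUMNS = {
    ("sr", "pre"): "sr_pre_pct",
    ("sr", "post"): "sr_post_pct",
    ("sr", "change"): "sr_change",
    ("rt", "pre"): "rt_pre_ms",
    ("rt", "post"): "rt_post_ms",
    ("rt", "change"): "rt_change",
}


def assessment_table(df: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Participant-level mean (SD) across the three objects.

    One row per (participant, measure, column) where measure is ``sr``
    or ``rt`` and column is pre/post/change.  Raises if any participant
    is missing an object cell.
    """
    df = object_change_table(df)
    rows = []
    for pid, sub in df.groupby("participant"):
        missing = set(ASSESSMENT_OBJECTS) - set(sub["object"])
        if missing:
            raise ValueError(f"participant {pid}: missing objects {sorted(missing)}")
        for (measure, column), col in _OBJECT_COLUMNS.items():
            gs = group_summary(sub[col])
            rows.append(
                {
                    "participant": pid,
                    "measure": measure,
                    "column": column,
                    "mean": gs.mean,
                    "sd": gs.sd,
                }
            )
    return pd.DataFrame(rows)


def object_group_summaries(df: Optional[pd.DataFrame] = None) -> dict[str, GroupSummary]:
    """Group mean (SD) of the per-participant mean changes."""
    df = object_change_table(df)
    per_participant = df.groupby("participant")[["sr_change", "rt_change"]].mean()
    return {
        "sr_change": group_summary(per_participant["sr_change"]),
        "rt_change": group_summary(per_participant["rt_change"]),
    }


def abstract_numbers() -> dict[str, GroupSummary]:
    """The four headline group statistics, recomputed from the fixtures."""
    wmft = wmft_group_summaries()
    objects = object_group_summaries()
    return {
        "fas_change": wmft["fas_change"],
        "time_change": wmft["time_change"],
        "sr_change": objects["sr_change"],
        "rt_change": objects["rt_change"],
    }
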