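"""Rendering and verification of the bundled clinical report tables."""

from __future__ import annotations

from typing import Optional

import pandas as pd

from ._rounding import round_half_away
from . import clinical

__all__ = [
    "render_wmft_markdown",
    "render_assessment_markdown",
    "verify_tables",
]


def render_wmft_markdown(table: Optional[pd.DataFrame] = None) -> str:
    """Markdown table of function-test scores with the group summary row."""
    table = clinical.wmft_change_table() if table is None else table
    lines = [
        "| Participant | FAS pre | FAS post | FAS change | Time pre (s) | Time post (s) | Time change (s) |",
        "|---|---|---|---|---|---|---|",
    ]
    for row in table.itertuples():
        lines.append(
            f"| {row.participant} | {row.fas_pre:g} | {row.fas_post:g} | "
            f"{row.fas_change:g} | {row.time_pre_s:g} | {row.time_post_s:g} | "
            f"{row.time_change:g} |"
        )
    gs = clinical.wmft_group_summaries(table)
    lines.append(
        "| Average (SD) | "
        + " | ".join(
            str(gs[k])
            for k in ("fas_pre", "fas_post", "fas_change", "time_pre", "time_post", "time_change")
        )
        + " |"
    )
    return "\n".join(lines)


def render_assessment_markdown(df: Optional[pd.DataFrame] = None) -> str:
    """Markdown table of per-object scores with per-participant summaries."""
    df = clinical.object_change_table(df)
    summary = clinical.assessment_table(df)
    lines = [
        "| Participant / object | SR pre (%) | SR post (%) | SR change | RT pre (ms) | RT post (ms) | RT change |",
        "|---|---|---|---|---|---|---|",
    ]
    for pid, sub in df.groupby("participant"):
        for row in sub.itertuples():
            lines.append(
                f"| {pid} / {row.object} | {row.sr_pre_pct:g} | {row.sr_post_pct:g} | "
                f"{row.sr_change:g} | {row.rt_pre_ms:g} | {row.rt_post_ms:g} | "
                f"{row.rt_change:g} |"
            )
        cells = []
        for measure in ("sr", "rt"):
            for column in ("pre", "post", "change"):
                row = summary[
                    (summary.participant == pid)
                    & (summary.measure == measure)
                    & (summary.column == column)
                ].iloc[0]
                cells.append(f"{round_half_away(row['mean'])} ({round_half_away(row.sd)})")
        lines.append(f"| {pid} / Average (SD) | " + " | ".join(cells) + " |")
    gs = clinical.object_group_summaries(df)
    lines.append(
        f"| Group change, Average (SD) | — | — | {gs['sr_change']} | — | — | {gs['rt_change']} |"
    )
    return "\n".join(lines)


def verify_tables(
    wmft_df: Optional[pd.DataFrame] = None,
    object_df: Optional[pd.DataFrame] = None,
    rounding=round_half_away,
) -> list[str]:
    """Diff every recomputed "Average (SD)" cell against the transcription.

    Returns a list of human-readable mismatch descriptions (empty when
    everything reproduces).  ``rounding`` may be swapped out to
    demonstrate that the reporting convention matters.
    """
    mismatches: list[str] = []

    def check(label: str, got_mean: float, got_sd: float, want_mean: int, want_sd: int):
        got = (rounding(got_mean), rounding(got_sd))
        want = (int(want_mean), int(want_sd))
        if got != want:
            mismatches.append(f"{label}: computed {got[0]} ({got[1]}), printed {want[0]} ({want[1]})")

    wmft = clinical.wmft_group_summaries(
        clinical.wmft_change_table(wmft_df) if wmft_df is not None else None
    )
    for row in clinical.load_expected_wmft_summary().itertuples():
        gs = wmft[row.column]
        check(f"function-test {row.column}", gs.mean, gs.sd, row.mean, row.sd)

    summary = clinical.assessment_table(object_df)
    for row in clinical.load_expected_object_summary().itertuples():
        got = summary[
            (summary.participant == row.participant)
            & (summary.measure == row.measure)
            & (summary.column == row.column)
        ].iloc[0]
        check(
            f"assessment P{row.participant} {row.measure} {row.column}",
            got["mean"],
            got["sd"],
            row.mean,
            row.sd,
        )

    group = clinical.object_group_summaries(object_df)
    wmft_keys = {"fas_change", "time_change"}
    for row in clinical.load_expected_group_summary().itertuples():
        gs = wmft[row.column] if row.column in wmft_keys else group[row.column]
        check(f"headline {row.column}", gs.mean, gs.sd, row.mean, row.sd)
    return mismatches
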