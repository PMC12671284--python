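"""Kinematic assessment of logged game sessions.

A session log is segmented into one response trace per target event,
re-referenced to the paddle position at target appearance and signed so
that leftward movement plots positive.  From the traces we compute the
session outcome measures: success rate (SR, percent caught, averaged
over the two movement directions), movement onset time (MOT; expressed
in milliseconds it is the "response time"), movement duration, peak
amplitude, overshoot count, and across-trace variability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from .engine import Direction, GameEvent, ObjectKind, SessionLog

__all__ = [
    "MetricsConfig",
    "ResponseTrace",
    "TraceKinematics",
    "SessionMetrics",
    "segment_responses",
    "detect_onset",
    "success_rate",
    "trace_kinematics",
    "variability",
    "session_summary",
    "overlay_frame",
]


#: percent of screen; amplitudes below this are not used to rescale
_MIN_STANDARDISATION_AMPLITUDE_PCT = 5.0


class MetricsConfig(BaseModel):
    """Operational thresholds of the metric pipeline.

    The onset rule (displacement threshold held for a minimum time) and
    the stop/overshoot criteria are artifact choices; the outcome
    definitions themselves (SR, MOT averaged per direction) are fixed.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    onset_threshold_pct: float = 2.0
    min_hold_s: float = 0.05
    stop_speed_pct_per_s: float = 5.0
    overshoot_tol_pct: float = 1.0
    resample_points: int = 100


@dataclass(frozen=True)
class ResponseTrace:
    """One segmented, direction-signed per-event paddle trajectory."""

    event_id: int
    direction: Direction
    t: np.ndarray  # seconds, relative to target appearance
    displacement: np.ndarray  # percent of screen, leftward positive
    caught: bool
    required_amplitude: float  # percent of screen


@dataclass(frozen=True)
class TraceKinematics:
    movement_duration_s: float
    peak_amplitude_pct: float
    primary_amplitude_pct: float
    overshoot_count: int
    final_error_pct: float


@dataclass
class SessionMetrics:
    """Summary outcome measures for one game session."""

    sr_left: Optional[float] = None
    sr_right: Optional[float] = None
    sr_avg: Optional[float] = None
    mot_left_mean_s: Optional[float] = None
    mot_right_mean_s: Optional[float] = None
    mot_avg_s: Optional[float] = None
    response_time_ms: Optional[float] = None
    movement_duration_mean_s: Optional[float] = None
    peak_amplitude_mean_pct: Optional[float] = None
    amplitude_ratio_mean: Optional[float] = None
    overshoot_count_mean: Optional[float] = None
    variability_pct: Optional[float] = None
    n_events_left: int = 0
    n_events_right: int = 0
    n_onsets: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def segment_responses(log: SessionLog) -> list[ResponseTrace]:
    """One trace per target event, windowed [t_appear, t_disappear].

    Distractor events never produce traces.  Raises if frames are
    missing inside an event window.
    """
    traces: list[ResponseTrace] = []
    t = np.asarray(log.t)
    dt = 1.0 / log.game_config.frame_rate_hz
    for event in sorted(log.target_events, key=lambda e: e.t_appear):
        i0 = int(np.searchsorted(t, event.t_appear - dt / 2))
        n = int(round(event.duration * log.game_config.frame_rate_hz)) + 1
        if i0 + n > len(t):
            raise ValueError(f"event {event.event_id}: log ends inside event window")
        window = t[i0 : i0 + n]
        expected = event.t_appear + np.arange(n) * dt
        if not np.allclose(window, expected, atol=dt / 4):
            raise ValueError(f"event {event.event_id}: missing frames inside event window")
        x = log.paddle_x[i0 : i0 + n]
        sign = -1.0 if event.required_direction is Direction.leftward else 1.0
        disp = (x - x[0]) * sign
        traces.append(
            ResponseTrace(
                event_id=event.event_id,
                direction=event.required_direction,
                t=window - event.t_appear,
                displacement=disp,
                caught=bool(log.catches.get(event.event_id, False)),
                required_amplitude=abs(event.x_spawn - x[0]),
            )
        )
    return traces


def detect_onset(
    trace: ResponseTrace,
    displacement_threshold: float = 2.0,
    min_hold: float = 0.05,
) -> Optional[float]:
    """Movement onset time for one trace, or None if never moved.

    Onset is the earliest time at which the absolute displacement
    reaches the threshold and stays at or above it for ``min_hold``
    seconds (the hold window must fit inside the trace).
    """
    if displacement_threshold <= 0 or min_hold <= 0:
        raise ValueError("thresholds must be positive")
    if len(trace.t) < 2:
        return None
    dt = float(trace.t[1] - trace.t[0])
    above = np.abs(trace.displacement) >= displacement_threshold
    h = int(np.floor(min_hold / dt + 1e-9)) + 1
    if h > len(above):
        return None
    runs = np.convolve(above.astype(int), np.ones(h, dtype=int), mode="valid")
    hits = np.nonzero(runs == h)[0]
    if len(hits) == 0:
        return None
    return float(trace.t[hits[0]])


def success_rate(
    traces: Sequence[ResponseTrace],
) -> tuple[Optional[float], Optional[float], Optional[float]]:
    """(SR_left, SR_right, SR_avg), percent caught per direction.

    SR_avg is the unweighted mean of the two directions; if one
    direction has no events it falls back to the other with a warning.
    """
    out = {}
    for direction in (Direction.leftward, Direction.rightward):
        sub = [tr for tr in traces if tr.direction is direction]
        out[direction] = (
            100.0 * sum(tr.caught for tr in sub) / len(sub) if sub else None
        )
    left, right = out[Direction.leftward], out[Direction.rightward]
    if left is None and right is None:
        return None, None, None
    if left is None or right is None:
        warnings.warn(
            "one direction has no events; SR_avg uses the other direction only",
            stacklevel=2,
        )
        return left, right, left if right is None else right
    return left, right, (left + right) / 2.0


def _smoothed_speed(trace: ResponseTrace, width_s: float = 0.04) -> np.ndarray:
    dt = float(trace.t[1] - trace.t[0])
    vel = np.gradient(trace.displacement, trace.t)
    w = max(1, int(round(width_s / dt)) | 1)  # odd window
    kernel = np.ones(w) / w
    return np.abs(np.convolve(vel, kernel, mode="same"))


def trace_kinematics(
    trace: ResponseTrace,
    onset: Optional[float] = None,
    config: Optional[MetricsConfig] = None,
) -> Optional[TraceKinematics]:
    """Per-trace kinematics; None when no onset was detected.

    ``primary_amplitude`` is the displacement at the end of the first
    sub-movement (first drop of smoothed speed below the stop
    criterion after onset) and estimates the primary reach extent
    before any corrections.
    """
    config = config or MetricsConfig()
    if onset is None:
        onset = detect_onset(trace, config.onset_threshold_pct, config.min_hold_s)
    if onset is None:
        return None
    speed = _smoothed_speed(trace)
    io = int(np.searchsorted(trace.t, onset - 1e-9))
    below = speed < config.stop_speed_pct_per_s

    # movement end: last downward crossing of the stop criterion
    after = below[io + 1 :]
    crossings = np.nonzero(after & ~np.concatenate(([below[io]], after[:-1])))[0]
    t_stop = float(trace.t[io + 1 + crossings[-1]]) if len(crossings) else float(trace.t[-1])

    # primary sub-movement end: first drop below the stop criterion
    # once the movement is underway
    moving = np.nonzero(~below[io:])[0]
    if len(moving):
        j0 = io + moving[0]
        stops = np.nonzero(below[j0:])[0]
        j_primary = j0 + stops[0] if len(stops) else len(trace.t) - 1
    else:
        j_primary = len(trace.t) - 1
    primary_amplitude = float(abs(trace.displacement[j_primary]))

    disp = trace.displacement
    a = trace.required_amplitude
    over = disp > a + config.overshoot_tol_pct
    # count maximal excursions above the required amplitude
    starts = np.nonzero(over & ~np.concatenate(([False], over[:-1])))[0]
    return TraceKinematics(
        movement_duration_s=max(0.0, t_stop - onset),
        peak_amplitude_pct=float(np.max(np.abs(disp))),
        primary_amplitude_pct=primary_amplitude,
        overshoot_count=int(len(starts)),
        final_error_pct=float(abs(disp[-1] - a)),
    )


def variability(
    traces: Sequence[ResponseTrace],
    direction: Direction,
    n_points: int = 100,
) -> Optional[float]:
    """Across-trace dispersion for one direction, percent of screen.

    Traces are linearly resampled onto a common normalised time base
    and amplitude-standardised (each trace divided by its required
    amplitude, then rescaled by the direction's mean required
    amplitude) so that the statistic reflects response consistency
    rather than the randomised spread of target amplitudes.  The
    result is the mean over time points of the across-trace sample
    standard deviation.  None with fewer than 2 traces.
    """
    sub = [tr for tr in traces if tr.direction is direction]
    if len(sub) < 2:
        return None
    grid = np.linspace(0.0, 1.0, n_points)
    amplitudes = np.array([tr.required_amplitude for tr in sub])
    # floor the per-trace scale so near-degenerate (tiny-amplitude)
    # events cannot dominate the standardised statistic
    scale = np.maximum(amplitudes, _MIN_STANDARDISATION_AMPLITUDE_PCT)
    mean_amplitude = float(np.mean(scale))
    resampled = np.vstack(
        [
            np.interp(grid, tr.t / tr.t[-1], tr.displacement) / s * mean_amplitude
            for tr, s in zip(sub, scale)
        ]
    )
    return float(np.mean(np.std(resampled, axis=0, ddof=1)))


def session_summary(
    log: SessionLog, config: Optional[MetricsConfig] = None
) -> SessionMetrics:
    """Compose all outcome measures for one session."""
    config = config or MetricsConfig()
    traces = segment_responses(log)
    metrics = SessionMetrics()
    metrics.n_events_left = sum(tr.direction is Direction.leftward for tr in traces)
    metrics.n_events_right = sum(tr.direction is Direction.rightward for tr in traces)
    if not traces:
        return metrics

    metrics.sr_left, metrics.sr_right, metrics.sr_avg = success_rate(traces)

    onsets = {
        tr.event_id: detect_onset(tr, config.onset_threshold_pct, config.min_hold_s)
        for tr in traces
    }
    mot_by_dir: dict[Direction, list[float]] = {
        Direction.leftward: [],
        Direction.rightward: [],
    }
    kinematics: list[TraceKinematics] = []
    ratios: list[float] = []
    for tr in traces:
        onset = onsets[tr.event_id]
        if onset is None:
            continue
        mot_by_dir[tr.direction].append(onset)
        kin = trace_kinematics(tr, onset, config)
        if kin is not None:
            kinematics.append(kin)
            if tr.required_amplitude > 0:
                ratios.append(kin.primary_amplitude_pct / tr.required_amplitude)
    metrics.n_onsets = sum(len(v) for v in mot_by_dir.values())

    left = mot_by_dir[Direction.leftward]
    right = mot_by_dir[Direction.rightward]
    metrics.mot_left_mean_s = float(np.mean(left)) if left else None
    metrics.mot_right_mean_s = float(np.mean(right)) if right else None
    dir_means = [m for m in (metrics.mot_left_mean_s, metrics.mot_right_mean_s) if m is not None]
    if dir_means:
        metrics.mot_avg_s = float(np.mean(dir_means))
        metrics.response_time_ms = metrics.mot_avg_s * 1000.0
    if kinematics:
        metrics.movement_duration_mean_s = float(
            np.mean([k.movement_duration_s for k in kinematics])
        )
        metrics.peak_amplitude_mean_pct = float(
            np.mean([k.peak_amplitude_pct for k in kinematics])
        )
        metrics.overshoot_count_mean = float(
            np.mean([k.overshoot_count for k in kinematics])
        )
    if ratios:
        metrics.amplitude_ratio_mean = float(np.mean(ratios))
    var = [
        v
        for v in (
            variability(traces, Direction.leftward, config.resample_points),
            variability(traces, Direction.rightward, config.resample_points),
        )
        if v is not None
    ]
    if var:
        metrics.variability_pct = float(np.mean(var))
    return metrics


def overlay_frame(traces: Sequence[ResponseTrace]) -> pd.DataFrame:
    """Long-format overlay-plot data (one row per trace sample)."""
    rows = []
    for tr in traces:
        rows.append(
            pd.DataFrame(
                {
                    "event_id": tr.event_id,
                    "direction": tr.direction.value,
                    "caught": tr.caught,
                    "t_s": tr.t,
                    "displacement_pct": tr.displacement,
                }
            )
        )
    if not rows:
        return pd.DataFrame(
            columns=["event_id", "direction", "caught", "t_s", "displacement_pct"]
        )
    return pd.concat(rows, ignore_index=True)
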