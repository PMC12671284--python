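"""Parameterised virtual players.

These generative movement models stand in for human participants so the
whole pipeline can be exercised and validated without patient data.
An able-bodied response is a prompt, smooth, accurate reach; impaired
responses show delayed onset, reduced (hypometric) amplitude, tremor,
and corrective sub-movements that overshoot the target.  All parameter
values are artifact constructs chosen to produce the qualitative
phenotypes, not measurements.

Players command paddle *positions* (kinematic mode); this keeps metric
validation independent of the simulated handle dynamics.  For
force-field experiments a player trajectory can instead be tracked in
torque mode through :func:`rehabgame.device.step_dynamics`.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator
from scipy import signal, stats

from .engine import Direction, GameEvent, ObjectKind

__all__ = ["PlayerModel", "minimum_jerk", "preset", "PRESET_NAMES"]

#: tremor low-pass corner, Hz (physiological tremor band)
_TREMOR_CUTOFF_HZ = 8.0
#: residuals smaller than this (percent screen) are not corrected
_CORRECTION_DEADBAND_PCT = 0.75
_MAX_CORRECTIONS = 3


def minimum_jerk(x0: float, x1: float, T: float, t):
    """Minimum-jerk position along a reach from ``x0`` to ``x1``.

    ``x(t) = x0 + (x1 - x0) * (10 s^3 - 15 s^4 + 6 s^5)`` with
    ``s = t / T``.  ``t`` may be a scalar or array in ``[0, T]``.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(t > T):
        raise ValueError("t must lie in [0, T]")
    s = t / T
    shape = s**3 * (10.0 - 15.0 * s + 6.0 * s**2)
    out = x0 + (x1 - x0) * shape
    return float(out) if out.ndim == 0 else out


class _Segment:
    """One min-jerk sub-movement in event-relative time."""

    __slots__ = ("t0", "t1", "x0", "x1")

    def __init__(self, t0: float, t1: float, x0: float, x1: float):
        self.t0, self.t1, self.x0, self.x1 = t0, t1, x0, x1


class PlayerModel(BaseModel):
    """Generative parameters of one virtual player."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    onset_latency_mean_s: float = 0.25
    onset_latency_sd_s: float = 0.03
    amplitude_gain: float = 1.0
    movement_time_per_amplitude_s_per_pct: float = 0.006
    tremor_sd_pct: float = 0.0
    submovement_prob: float = 0.0
    overshoot_gain: float = 0.0
    correction_delay_s: float = 0.1
    min_movement_time_s: float = 0.08
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "PlayerModel":
        if self.onset_latency_mean_s < 0 or self.onset_latency_sd_s < 0:
            raise ValueError("latency parameters must be >= 0")
        if not 0 < self.amplitude_gain <= 1.5:
            raise ValueError("amplitude_gain must be in (0, 1.5]")
        if not self.movement_time_per_amplitude_s_per_pct > 0:
            raise ValueError("movement_time_per_amplitude_s_per_pct must be > 0")
        if self.tremor_sd_pct < 0:
            raise ValueError("tremor_sd_pct must be >= 0")
        if not 0 <= self.submovement_prob <= 1:
            raise ValueError("submovement_prob must be in [0, 1]")
        if self.overshoot_gain < 0:
            raise ValueError("overshoot_gain must be >= 0")
        if self.correction_delay_s < 0:
            raise ValueError("correction_delay_s must be >= 0")
        if self.min_movement_time_s <= 0:
            raise ValueError("min_movement_time_s must be > 0")
        return self

    def snapshot(self) -> dict:
        return self.model_dump()

    # -- generative model ------------------------------------------------

    def _sample_latency(self, rng: np.random.Generator) -> float:
        mu, sd = self.onset_latency_mean_s, self.onset_latency_sd_s
        if sd == 0:
            return mu
        a = -mu / sd  # truncate at zero
        return float(stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sd, random_state=rng))

    def _plan(
        self, event: GameEvent, current_x: float, rng: np.random.Generator
    ) -> list[_Segment]:
        """Plan the sub-movement sequence for one event (relative time)."""
        latency = self._sample_latency(rng)
        amplitude = event.x_spawn - current_x
        segments: list[_Segment] = []
        x_now = current_x
        t_now = latency
        # primary movement toward the gained amplitude
        x_goal = current_x + self.amplitude_gain * amplitude
        move_t = max(
            self.min_movement_time_s,
            self.movement_time_per_amplitude_s_per_pct * abs(x_goal - x_now),
        )
        segments.append(_Segment(t_now, t_now + move_t, x_now, x_goal))
        t_now += move_t
        x_now = x_goal

        # corrective sub-movements toward the residual, with overshoot
        if rng.uniform() < self.submovement_prob:
            for _ in range(_MAX_CORRECTIONS):
                residual = event.x_spawn - x_now
                if abs(residual) < _CORRECTION_DEADBAND_PCT:
                    break
                t_now += self.correction_delay_s
                x_goal = x_now + residual * (1.0 + self.overshoot_gain)
                move_t = max(
                    self.min_movement_time_s,
                    self.movement_time_per_amplitude_s_per_pct * abs(x_goal - x_now),
                )
                segments.append(_Segment(t_now, t_now + move_t, x_now, x_goal))
                t_now += move_t
                x_now = x_goal
                if self.overshoot_gain == 0:
                    break
        return segments

    @staticmethod
    def _evaluate(segments: list[_Segment], x_start: float, rel_t: np.ndarray) -> np.ndarray:
        """Evaluate the piecewise plan (holds between sub-movements)."""
        out = np.full(rel_t.shape, x_start, dtype=float)
        for seg in segments:
            after = rel_t >= seg.t1
            out[after] = seg.x1
            inside = (rel_t >= seg.t0) & ~after
            if np.any(inside):
                s = (rel_t[inside] - seg.t0) / (seg.t1 - seg.t0)
                out[inside] = seg.x0 + (seg.x1 - seg.x0) * s**3 * (
                    10.0 - 15.0 * s + 6.0 * s**2
                )
        return out

    def respond(
        self,
        event: GameEvent,
        current_x: float,
        frame_rate_hz: float = 120.0,
        rng: Optional[np.random.Generator] = None,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Intended paddle positions for one event.

        Returns ``(t_rel, x)`` sampled at the frame rate over the event
        window.  Tremor noise is not included here; it is added at the
        session level by :meth:`trajectory`.
        """
        if rng is None:
            rng = np.random.default_rng(self.seed)
        n = int(round(event.duration * frame_rate_hz))
        rel_t = np.arange(n + 1) / frame_rate_hz
        segments = self._plan(event, current_x, rng)
        return rel_t, self._evaluate(segments, current_x, rel_t)

    def trajectory(
        self,
        events: Sequence[GameEvent],
        frame_times: np.ndarray,
        initial_x: float,
        rng: Optional[np.random.Generator] = None,
    ) -> np.ndarray:
        """Paddle position at every frame of a session.

        The player pursues each target event in turn, starting each
        response from wherever the previous one left the paddle;
        distractor events are ignored.  Low-pass-filtered tremor noise
        is added over the whole session.
        """
        if rng is None:
            rng = np.random.default_rng(self.seed)
        frame_times = np.asarray(frame_times, dtype=float)
        out = np.full(frame_times.shape, float(initial_x), dtype=float)
        x_carry = float(initial_x)
        targets = [e for e in events if e.kind is ObjectKind.target]
        for event in targets:
            i0 = int(np.searchsorted(frame_times, event.t_appear - 1e-9))
            i1 = int(np.searchsorted(frame_times, event.t_disappear - 1e-9))
            segments = self._plan(event, x_carry, rng)
            rel = frame_times[i0:i1] - event.t_appear
            out[i0:i1] = self._evaluate(segments, x_carry, rel)
            x_carry = self._evaluate(
                segments, x_carry, np.asarray([event.duration])
            )[0]
        if targets:
            i_end = int(np.searchsorted(frame_times, targets[-1].t_disappear - 1e-9))
            out[i_end:] = x_carry
        if self.tremor_sd_pct > 0 and len(frame_times) > 1:
            out = out + self._tremor(len(frame_times), frame_times, rng)
        return out

    def _tremor(self, n: int, frame_times: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        fs = 1.0 / float(np.median(np.diff(frame_times)))
        white = rng.standard_normal(n)
        if fs > 2.0 * _TREMOR_CUTOFF_HZ and n > 18:
            b, a = signal.butter(2, _TREMOR_CUTOFF_HZ / (fs / 2.0), btype="low")
            filtered = signal.lfilter(b, a, white)
        else:
            filtered = white
        sd = float(np.std(filtered))
        if sd == 0:
            return np.zeros(n)
        return filtered * (self.tremor_sd_pct / sd)


#: tuned once against the default game configuration, then frozen
_PRESETS: dict[str, dict] = {
    "able_bodied": dict(
        onset_latency_mean_s=0.25,
        onset_latency_sd_s=0.02,
        amplitude_gain=1.0,
        movement_time_per_amplitude_s_per_pct=0.006,
        tremor_sd_pct=0.1,
        submovement_prob=0.1,
        overshoot_gain=0.05,
    ),
    "stroke_mild": dict(
        onset_latency_mean_s=0.50,
        onset_latency_sd_s=0.06,
        amplitude_gain=0.73,
        movement_time_per_amplitude_s_per_pct=0.018,
        tremor_sd_pct=0.7,
        submovement_prob=0.45,
        overshoot_gain=0.30,
    ),
    "stroke_moderate": dict(
        onset_latency_mean_s=0.60,
        onset_latency_sd_s=0.09,
        amplitude_gain=0.68,
        movement_time_per_amplitude_s_per_pct=0.020,
        tremor_sd_pct=1.0,
        submovement_prob=0.45,
        overshoot_gain=0.40,
    ),
    "stroke_severe": dict(
        onset_latency_mean_s=0.80,
        onset_latency_sd_s=0.12,
        amplitude_gain=0.58,
        movement_time_per_amplitude_s_per_pct=0.024,
        tremor_sd_pct=1.5,
        submovement_prob=0.45,
        overshoot_gain=0.55,
    ),
}

PRESET_NAMES = tuple(_PRESETS)


def preset(profile: str, seed: int = 0) -> PlayerModel:
    """Documented parameter bundle for a named phenotype."""
    try:
        params = _PRESETS[profile]
    except KeyError:
        raise ValueError(
            f"unknown profile {profile!r}; choose from {', '.join(_PRESETS)}"
        ) from None
    return PlayerModel(seed=seed, **params)
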