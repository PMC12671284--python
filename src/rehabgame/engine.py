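"""Catch-the-falling-target game engine.

Targets (and optional distractors) spawn at the top of the screen at
randomised horizontal positions and descend linearly to the bottom over
one event duration.  The player-controlled paddle sits on the bottom
line; a target is caught when it reaches the paddle line overlapping the
paddle.  Every frame of a session is logged, together with the event
schedule, catch flags, and the configuration snapshot, so the session
can be re-analysed offline.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from .device import DeviceConfig

__all__ = [
    "Direction",
    "ObjectKind",
    "GameConfig",
    "GameEvent",
    "SessionLog",
    "GameSession",
    "schedule_events",
    "catch_test",
    "run_session",
]


class Direction(str, enum.Enum):
    leftward = "leftward"
    rightward = "rightward"


class ObjectKind(str, enum.Enum):
    target = "target"
    distractor = "distractor"


class GameConfig(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    session_duration_s: float = 60.0
    event_duration_s: float = 2.0
    paddle_width_pct: float = 10.0
    target_width_pct: float = 5.0
    distractors_enabled: bool = False
    distractors_per_event: int = 1
    duration_jitter_fraction: float = 0.0
    min_amplitude_pct: float = 5.0
    frame_rate_hz: float = 120.0
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "GameConfig":
        if not self.event_duration_s > 0:
            raise ValueError("event_duration_s must be positive")
        if self.session_duration_s < 0:
            raise ValueError("session_duration_s must be >= 0")
        for name in ("paddle_width_pct", "target_width_pct"):
            w = getattr(self, name)
            if not 0 < w < 100:
                raise ValueError(f"{name} must be in (0, 100)")
        if not self.frame_rate_hz > 0:
            raise ValueError("frame_rate_hz must be positive")
        if not 0 <= self.duration_jitter_fraction < 1:
            raise ValueError("duration_jitter_fraction must be in [0, 1)")
        if self.distractors_per_event < 0:
            raise ValueError("distractors_per_event must be >= 0")
        if self.min_amplitude_pct < 0:
            raise ValueError("min_amplitude_pct must be >= 0")
        return self


@dataclass(frozen=True)
class GameEvent:
    """One falling object's lifetime from appearance to disappearance."""

    event_id: int
    kind: ObjectKind
    t_appear: float
    t_disappear: float
    x_spawn: float
    required_direction: Optional[Direction] = None

    @property
    def duration(self) -> float:
        return self.t_disappear - self.t_appear

    def y_at(self, t: float) -> float:
        """Vertical position (100 at appearance, 0 at disappearance)."""
        return 100.0 * (1.0 - (t - self.t_appear) / self.duration)


@dataclass
class SessionLog:
    """Frame-level record of one game session."""

    t: np.ndarray
    paddle_x: np.ndarray
    events: list[GameEvent]
    catches: dict[int, bool]
    distractor_contacts: dict[int, bool]
    game_config: GameConfig
    device_config: Optional[DeviceConfig] = None
    player_config: Optional[dict] = None
    seed: int = 0
    schema_version: str = "1"

    @property
    def target_events(self) -> list[GameEvent]:
        return [e for e in self.events if e.kind is ObjectKind.target]

    @property
    def n_frames(self) -> int:
        return len(self.t)


def schedule_events(
    config: GameConfig, initial_paddle_x: float = 50.0, rng: np.random.Generator | None = None
) -> list[GameEvent]:
    """Build the randomised, back-to-back event schedule for a session.

    The number of target events is ``floor(session_duration /
    event_duration)``.  Required directions are balanced to within one
    of an even split by shuffling an exactly balanced sequence; spawn
    positions are drawn uniformly on the required side of the expected
    paddle position (the previous target's spawn, since the player is
    assumed to pursue each target).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_events = int(math.floor(config.session_duration_s / config.event_duration_s))
    if n_events == 0:
        warnings.warn("session shorter than one event: empty schedule", stacklevel=2)
        return []

    directions = [Direction.leftward] * (n_events // 2) + [
        Direction.rightward
    ] * (n_events - n_events // 2)
    rng.shuffle(directions)  # type: ignore[arg-type]

    half_w = config.target_width_pct / 2.0
    lo, hi = half_w, 100.0 - half_w
    events: list[GameEvent] = []
    event_id = 0
    t = 0.0
    ref = float(initial_paddle_x)
    for direction in directions:
        duration = config.event_duration_s
        if config.duration_jitter_fraction > 0:
            duration *= 1.0 + config.duration_jitter_fraction * rng.uniform(-1.0, 1.0)
        if direction is Direction.leftward:
            a, b = lo, max(lo, ref - config.min_amplitude_pct)
        else:
            a, b = min(hi, ref + config.min_amplitude_pct), hi
        x_spawn = float(rng.uniform(a, b))
        events.append(
            GameEvent(
                event_id=event_id,
                kind=ObjectKind.target,
                t_appear=t,
                t_disappear=t + duration,
                x_spawn=x_spawn,
                required_direction=direction,
            )
        )
        event_id += 1
        if config.distractors_enabled:
            for _ in range(config.distractors_per_event):
                events.append(
                    GameEvent(
                        event_id=event_id,
                        kind=ObjectKind.distractor,
                        t_appear=t,
                        t_disappear=t + duration,
                        x_spawn=float(rng.uniform(lo, hi)),
                    )
                )
                event_id += 1
        ref = x_spawn
        t += duration
    return events


def catch_test(
    paddle_x: float, paddle_width: float, target_x: float, target_width: float
) -> bool:
    """Overlap test at the paddle line; touching edges count as a catch."""
    if paddle_width <= 0 or target_width <= 0:
        raise ValueError("widths must be positive")
    return abs(target_x - paddle_x) <= (paddle_width + target_width) / 2.0


class GameSession:
    """Incremental game state: feed one paddle position per frame."""

    def __init__(
        self,
        game_config: GameConfig,
        events: Sequence[GameEvent],
        device_config: Optional[DeviceConfig] = None,
        player_config: Optional[dict] = None,
        seed: Optional[int] = None,
    ):
        self.config = game_config
        self.events = list(events)
        self._times: list[float] = []
        self._paddle: list[float] = []
        self._catches: dict[int, bool] = {}
        self._contacts: dict[int, bool] = {
            e.event_id: False for e in self.events if e.kind is ObjectKind.distractor
        }
        self._device_config = device_config
        self._player_config = player_config
        self._seed = game_config.seed if seed is None else seed
        self._frame = 0
        self._dt = 1.0 / game_config.frame_rate_hz
        # events awaiting resolution, ordered by disappearance time
        self._pending = sorted(self.events, key=lambda e: e.t_disappear)
        self._next = 0

    @property
    def t(self) -> float:
        return self._frame * self._dt

    def active_events(self, t: float) -> list[GameEvent]:
        return [e for e in self.events if e.t_appear <= t < e.t_disappear]

    def step(self, paddle_x: float) -> None:
        """Log one frame and resolve any object reaching the paddle line."""
        t = self.t
        self._times.append(t)
        self._paddle.append(float(paddle_x))
        eps = self._dt / 2.0
        # resolve each object at the first frame with t >= t_disappear (y <= 0)
        while self._next < len(self._pending) and t >= self._pending[self._next].t_disappear - eps:
            e = self._pending[self._next]
            hit = catch_test(
                paddle_x,
                self.config.paddle_width_pct,
                e.x_spawn,
                self.config.target_width_pct,
            )
            if e.kind is ObjectKind.target:
                self._catches[e.event_id] = hit
            else:
                self._contacts[e.event_id] = hit
            self._next += 1
        self._frame += 1

    def finalize(self) -> SessionLog:
        for e in self.events:
            if e.kind is ObjectKind.target and e.event_id not in self._catches:
                self._catches[e.event_id] = False
        return SessionLog(
            t=np.asarray(self._times),
            paddle_x=np.asarray(self._paddle),
            events=self.events,
            catches=dict(self._catches),
            distractor_contacts=dict(self._contacts),
            game_config=self.config,
            device_config=self._device_config,
            player_config=self._player_config,
            seed=self._seed,
        )


def run_session(
    game: GameConfig,
    player,
    device: Optional[DeviceConfig] = None,
    initial_paddle_x: float = 50.0,
    seed: Optional[int] = None,
) -> SessionLog:
    """Simulate one full session with a virtual player.

    ``player`` must provide ``trajectory(events, frame_times,
    initial_x, rng)`` returning the paddle position at every frame
    (see :mod:`rehabgame.players`).  Deterministic given the configs
    and seed.
    """
    if seed is None:
        seed = game.seed
    rng = np.random.default_rng(seed)
    events = schedule_events(game, initial_paddle_x=initial_paddle_x, rng=rng)
    total = events[-1].t_disappear if events else game.session_duration_s
    dt = 1.0 / game.frame_rate_hz
    n_frames = int(round(total / dt)) + 1
    frame_times = np.arange(n_frames) * dt
    paddle = player.trajectory(events, frame_times, initial_paddle_x, rng)
    paddle = np.clip(paddle, 0.0, 100.0)

    session = GameSession(
        game, events, device_config=device,
        player_config=getattr(player, "snapshot", lambda: None)(), seed=seed,
    )
    for x in paddle:
        session.step(float(x))
    return session.finalize()
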