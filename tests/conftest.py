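import numpy as np
import pytest

from rehabgame.device import DeviceConfig
from rehabgame.engine import (
    Direction,
    GameConfig,
    GameEvent,
    ObjectKind,
    SessionLog,
)
from rehabgame.players import PlayerModel


@pytest.fixture
def device_config() -> DeviceConfig:
    return DeviceConfig(theta_min_deg=0.0, theta_max_deg=30.0)


@pytest.fixture
def game_config() -> GameConfig:
    return GameConfig(seed=1)


@pytest.fixture
def ideal_player() -> PlayerModel:
    """Zero latency, exact tracking, no noise."""
    return PlayerModel(
        onset_latency_mean_s=0.0,
        onset_latency_sd_s=0.0,
        amplitude_gain=1.0,
        movement_time_per_amplitude_s_per_pct=0.003,
        tremor_sd_pct=0.0,
        submovement_prob=0.0,
        overshoot_gain=0.0,
        seed=0,
    )


def make_log(paddle_segments, events, frame_rate=120.0, catches=None):
    """Hand-build a SessionLog from per-event paddle position callables.

    ``paddle_segments`` maps absolute frame time to paddle position.
    """
    total = max(e.t_disappear for e in events)
    n = int(round(total * frame_rate)) + 1
    t = np.arange(n) / frame_rate
    paddle = np.array([paddle_segments(ti) for ti in t], dtype=float)
    targets = [e for e in events if e.kind is ObjectKind.target]
    return SessionLog(
        t=t,
        paddle_x=paddle,
        events=list(events),
        catches=catches or {e.event_id: False for e in targets},
        distractor_contacts={
            e.event_id: False for e in events if e.kind is ObjectKind.distractor
        },
        game_config=GameConfig(
            session_duration_s=total, event_duration_s=targets[0].duration, frame_rate_hz=frame_rate
        ),
        seed=0,
    )


@pytest.fixture
def three_event_log():
    """Three-event log with known piecewise-constant paddle motion."""
    events = [
        GameEvent(0, ObjectKind.target, 0.0, 2.0, 30.0, Direction.leftward),
        GameEvent(1, ObjectKind.target, 2.0, 4.0, 70.0, Direction.rightward),
        GameEvent(2, ObjectKind.target, 4.0, 6.0, 20.0, Direction.leftward),
    ]

    def paddle(ti):
        if ti < 0.5:
            return 50.0
        if ti < 2.5:
            return 30.0
        if ti < 4.5:
            return 70.0
        return 20.0

    return make_log(paddle, events)
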