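"""Session log serialization.

A log is written as a pair of plain-text files sharing a prefix:

* ``<prefix>.frames.csv`` — one row per frame per active object
  (columns: t_s, paddle_x_pct, event_id, object_kind, object_x_pct,
  object_y_pct); frames with no active object keep empty object fields.
* ``<prefix>.session.json`` — schema version, seed, config snapshots,
  the event schedule, catch flags, and distractor contacts.

The write -> read round trip is lossless for every field.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .device import DeviceConfig
from .engine import Direction, GameConfig, GameEvent, ObjectKind, SessionLog

__all__ = ["write_log", "read_log", "frames_table"]

SCHEMA_VERSION = "1"
FRAME_COLUMNS = [
    "t_s",
    "paddle_x_pct",
    "event_id",
    "object_kind",
    "object_x_pct",
    "object_y_pct",
]


def frames_table(log: SessionLog) -> pd.DataFrame:
    """Long-format frames table with per-object positions."""
    t = np.asarray(log.t)
    base = pd.DataFrame({"t_s": t, "paddle_x_pct": log.paddle_x})
    base["_frame"] = np.arange(len(t))
    rows = []
    dt = 1.0 / log.game_config.frame_rate_hz
    for e in log.events:
        i0 = int(np.searchsorted(t, e.t_appear - dt / 2))
        i1 = int(np.searchsorted(t, e.t_disappear - dt / 2))
        if i1 <= i0:
            continue
        sub = pd.DataFrame(
            {
                "_frame": np.arange(i0, i1),
                "event_id": e.event_id,
                "object_kind": e.kind.value,
                "object_x_pct": e.x_spawn,
                "object_y_pct": e.y_at(t[i0:i1]),
            }
        )
        rows.append(sub)
    objects = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(
            columns=["_frame", "event_id", "object_kind", "object_x_pct", "object_y_pct"]
        )
    )
    merged = base.merge(objects, on="_frame", how="left")
    merged = merged.sort_values(["_frame", "event_id"]).drop(columns="_frame")
    return merged[FRAME_COLUMNS].reset_index(drop=True)


def write_log(log: SessionLog, prefix: str | Path) -> tuple[Path, Path]:
    """Write the CSV frames table and JSON sidecar; returns both paths."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    frames_path = prefix.with_suffix(prefix.suffix + ".frames.csv")
    json_path = prefix.with_suffix(prefix.suffix + ".session.json")
    frames_table(log).to_csv(frames_path, index=False)
    sidecar = {
        "schema_version": log.schema_version,
        "seed": log.seed,
        "game_config": log.game_config.model_dump(),
        "device_config": log.device_config.model_dump(mode="json")
        if log.device_config
        else None,
        "player_config": log.player_config,
        "events": [
            {
                "event_id": e.event_id,
                "kind": e.kind.value,
                "t_appear": e.t_appear,
                "t_disappear": e.t_disappear,
                "x_spawn": e.x_spawn,
                "required_direction": e.required_direction.value
                if e.required_direction
                else None,
            }
            for e in log.events
        ],
        "catches": {str(k): bool(v) for k, v in log.catches.items()},
        "distractor_contacts": {
            str(k): bool(v) for k, v in log.distractor_contacts.items()
        },
    }
    json_path.write_text(json.dumps(sidecar, indent=1))
    return frames_path, json_path


def read_log(prefix: str | Path) -> SessionLog:
    """Load a log written by :func:`write_log`."""
    prefix = Path(prefix)
    frames_path = prefix.with_suffix(prefix.suffix + ".frames.csv")
    json_path = prefix.with_suffix(prefix.suffix + ".session.json")
    for p in (frames_path, json_path):
        if not p.exists():
            raise FileNotFoundError(f"log file not found: {p}")
    try:
        sidecar = json.loads(json_path.read_text())
        frames = pd.read_csv(frames_path, float_precision="round_trip")
        if list(frames.columns) != FRAME_COLUMNS:
            raise ValueError(f"unexpected frame columns: {list(frames.columns)}")
        per_frame = frames.drop_duplicates(subset="t_s", keep="first")
        events = [
            GameEvent(
                event_id=int(e["event_id"]),
                kind=ObjectKind(e["kind"]),
                t_appear=float(e["t_appear"]),
                t_disappear=float(e["t_disappear"]),
                x_spawn=float(e["x_spawn"]),
                required_direction=Direction(e["required_direction"])
                if e["required_direction"]
                else None,
            )
            for e in sidecar["events"]
        ]
        return SessionLog(
            t=per_frame["t_s"].to_numpy(),
            paddle_x=per_frame["paddle_x_pct"].to_numpy(),
            events=events,
            catches={int(k): bool(v) for k, v in sidecar["catches"].items()},
            distractor_contacts={
                int(k): bool(v) for k, v in sidecar["distractor_contacts"].items()
            },
            game_config=GameConfig(**sidecar["game_config"]),
            device_config=DeviceConfig(**sidecar["device_config"])
            if sidecar.get("device_config")
            else None,
            player_config=sidecar.get("player_config"),
            seed=int(sidecar["seed"]),
            schema_version=str(sidecar["schema_version"]),
        )
    except (KeyError, json.JSONDecodeError) as exc:
        raise ValueError(f"malformed log at {prefix}: {exc}") from exc
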