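"""Run configuration: one TOML file with device/game/player/metrics sections.

Unknown keys are rejected everywhere.  The top-level ``seed`` drives all
randomness (it is copied into the game and player sections), so a run
is fully determined by the file plus any CLI overrides.
"""

from __future__ import annotations

import tomllib
from pathlib import Path
from typing import Any, Optional

from pydantic import BaseModel, ConfigDict, ValidationError

from .device import DeviceConfig
from .engine import GameConfig
from .metrics import MetricsConfig
from .players import PlayerModel, preset

__all__ = ["RunConfig", "load_run_config", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or unreadable run configuration."""


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    seed: int = 0
    device: DeviceConfig = DeviceConfig(theta_min_deg=0.0, theta_max_deg=30.0)
    game: GameConfig = GameConfig()
    player: PlayerModel = PlayerModel()
    metrics: MetricsConfig = MetricsConfig()

    def with_seed(self, seed: int) -> "RunConfig":
        return RunConfig(
            seed=seed,
            device=self.device,
            game=self.game.model_copy(update={"seed": seed}),
            player=self.player.model_copy(update={"seed": seed}),
            metrics=self.metrics,
        )


def _build_player(section: dict[str, Any]) -> PlayerModel:
    section = dict(section)
    name = section.pop("preset", None)
    if name is not None:
        merged = preset(name).model_dump() | section
        return PlayerModel(**merged)  # re-validate overrides
    return PlayerModel(**section)


def load_run_config(
    path: str | Path, seed_override: Optional[int] = None
) -> RunConfig:
    """Parse and validate a TOML run configuration file."""
    path = Path(path)
    try:
        raw = tomllib.loads(path.read_text())
    except FileNotFoundError:
        raise ConfigError(f"config file not found: {path}") from None
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"config file {path} is not valid TOML: {exc}") from exc
    try:
        sections = dict(raw)
        player_section = sections.pop("player", {})
        cfg = RunConfig(player=_build_player(player_section), **sections)
    except (ValidationError, ValueError, TypeError) as exc:
        raise ConfigError(f"invalid configuration in {path}: {exc}") from exc
    if seed_override is not None:
        cfg = cfg.with_seed(seed_override)
    elif "seed" in raw:
        cfg = cfg.with_seed(cfg.seed)
    return cfg
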