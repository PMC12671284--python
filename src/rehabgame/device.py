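"""Simulated one-degree-of-freedom rotary handle.

The handle shaft angle is linearly mapped onto a screen coordinate
(percent of the active screen axis).  The device supports a
unidirectional constant-torque field: assistive toward its configured
direction and resistive against it, regardless of motion direction.

Units: angles in degrees, angular velocity in degrees/s, torque in
N*mm, inertia in kg*mm^2, viscous damping in N*mm*s/rad.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional

from pydantic import BaseModel, ConfigDict, model_validator

__all__ = [
    "Orientation",
    "ForceDirection",
    "DeviceConfig",
    "DeviceState",
    "angle_to_screen",
    "screen_to_angle",
    "field_torque",
    "step_dynamics",
]

#: N*mm / kg*mm^2 -> rad/s^2
_TORQUE_TO_RAD_ACCEL = 1000.0


class Orientation(str, enum.Enum):
    horizontal = "horizontal"
    vertical = "vertical"


class ForceDirection(str, enum.Enum):
    off = "off"
    toward_min = "toward_min"
    toward_max = "toward_max"


class DeviceConfig(BaseModel):
    """Device section of the run configuration.

    Exactly one of the explicit working range (``theta_min_deg`` /
    ``theta_max_deg``) or ``sensitivity_deg_per_screen`` drives the
    angle-to-screen mapping.  A sensitivity of ``s`` degrees per full
    screen is equivalent to a working range of ``s`` degrees centred on
    ``neutral_deg``.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    orientation: Orientation = Orientation.horizontal
    theta_min_deg: Optional[float] = None
    theta_max_deg: Optional[float] = None
    sensitivity_deg_per_screen: Optional[float] = None
    neutral_deg: float = 0.0
    force_direction: ForceDirection = ForceDirection.off
    force_magnitude_Nmm: float = 0.0
    inertia_kgmm2: float = 50.0
    damping_Nmm_s_per_rad: float = 5.0

    @model_validator(mode="after")
    def _check(self) -> "DeviceConfig":
        has_range = self.theta_min_deg is not None or self.theta_max_deg is not None
        has_sens = self.sensitivity_deg_per_screen is not None
        if has_range and has_sens:
            raise ValueError(
                "specify either theta_min_deg/theta_max_deg or "
                "sensitivity_deg_per_screen, not both"
            )
        if has_range:
            if self.theta_min_deg is None or self.theta_max_deg is None:
                raise ValueError("theta_min_deg and theta_max_deg must be given together")
            if not self.theta_max_deg > self.theta_min_deg:
                raise ValueError("theta_max_deg must exceed theta_min_deg")
        elif has_sens:
            if not self.sensitivity_deg_per_screen > 0:
                raise ValueError("sensitivity_deg_per_screen must be positive")
        else:
            raise ValueError(
                "one of theta_min_deg/theta_max_deg or "
                "sensitivity_deg_per_screen is required"
            )
        if self.force_magnitude_Nmm < 0:
            raise ValueError("force_magnitude_Nmm must be >= 0")
        if self.inertia_kgmm2 <= 0:
            raise ValueError("inertia_kgmm2 must be > 0")
        if self.damping_Nmm_s_per_rad < 0:
            raise ValueError("damping_Nmm_s_per_rad must be >= 0")
        return self

    @property
    def working_range(self) -> tuple[float, float]:
        """Effective (theta_min, theta_max) in degrees."""
        if self.sensitivity_deg_per_screen is not None:
            half = self.sensitivity_deg_per_screen / 2.0
            return (self.neutral_deg - half, self.neutral_deg + half)
        return (self.theta_min_deg, self.theta_max_deg)  # type: ignore[return-value]


@dataclass(frozen=True)
class DeviceState:
    """Instantaneous shaft state: angle (deg), velocity (deg/s), time (s)."""

    theta: float
    omega: float = 0.0
    t: float = 0.0


def angle_to_screen(theta: float, config: DeviceConfig) -> float:
    """Map a shaft angle to percent of screen, clamping outside the range."""
    lo, hi = config.working_range
    theta = min(max(theta, lo), hi)
    return (theta - lo) / (hi - lo) * 100.0


def screen_to_angle(screen_pos: float, config: DeviceConfig) -> float:
    """Inverse of :func:`angle_to_screen` on [0, 100]."""
    lo, hi = config.working_range
    return lo + (hi - lo) * screen_pos / 100.0


def field_torque(config: DeviceConfig) -> float:
    """Signed constant field torque in N*mm (positive is toward theta_max)."""
    if config.force_direction is ForceDirection.toward_max:
        return config.force_magnitude_Nmm
    if config.force_direction is ForceDirection.toward_min:
        return -config.force_magnitude_Nmm
    return 0.0


def step_dynamics(
    state: DeviceState,
    player_torque: float,
    config: DeviceConfig,
    dt: float = 1.0 / 120.0,
) -> DeviceState:
    """Advance the handle one time step with semi-implicit Euler.

    Integrates ``I * alpha = tau_player + tau_field - b * omega``.  The
    working-range endpoints are hard stops: the angle clamps and the
    velocity resets to zero on contact.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not math.isfinite(player_torque):
        raise ValueError("player torque must be finite")
    lo, hi = config.working_range
    omega_rad = math.radians(state.omega)
    tau = player_torque + field_torque(config) - config.damping_Nmm_s_per_rad * omega_rad
    alpha_rad = _TORQUE_TO_RAD_ACCEL * tau / config.inertia_kgmm2
    omega_rad += alpha_rad * dt
    omega = math.degrees(omega_rad)
    theta = state.theta + omega * dt
    if theta <= lo:
        theta, omega = lo, 0.0
    elif theta >= hi:
        theta, omega = hi, 0.0
    return DeviceState(theta=theta, omega=omega, t=state.t + dt)
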