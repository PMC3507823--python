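"""Geometry of looming discs, with optional wing bars.

A looming stimulus is an object of half-size ``l`` approaching the viewer at
constant speed ``|v|``.  Its full angular subtense at distance ``d`` is
``theta = 2*arctan(l/d)``, and the whole expansion time course is fully
determined by the ratio ``l/|v|`` when time is measured to projected
collision.  This module provides the subtense and expansion-rate primitives,
trajectory sampling, and the conversion of a physical approach into a
per-frame display schedule for a CRT of given refresh rate and pixel pitch.

Conventions
-----------
* ``t_to_collision`` is positive before the projected collision and measured
  in seconds; signed event times elsewhere in the package use
  ``t_rel = t_event - t_collision`` in milliseconds (negative before
  collision).
* Angles are reported in degrees; internal computation is in radians.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "WingSpec",
    "LoomingStimulus",
    "LoomingTrajectory",
    "FrameSchedule",
    "lov_ratio",
    "display_round",
    "angular_subtense",
    "subtense_rate",
    "trajectory",
    "collision_offset",
    "frame_schedule",
]


def _require_positive(name: str, value: float) -> None:
    if not np.isfinite(value) or value <= 0:
        raise ValueError(f"{name} must be positive and finite, got {value!r}")


@dataclass(frozen=True)
class WingSpec:
    """Horizontal bar added to a looming disc to give it a winged outline.

    Parameters
    ----------
    span
        Full tip-to-tip length of the bar in metres.
    bar_height
        Vertical thickness of the bar in metres.
    vertical_offset
        Height of the bar centre-line above the disc centre in metres.  The
        offset affects rendering only; wing-tip subtense is computed from the
        span alone.
    """

    span: float = 0.36
    bar_height: float = 0.02
    vertical_offset: float = 0.018

    def __post_init__(self) -> None:
        _require_positive("span", self.span)
        _require_positive("bar_height", self.bar_height)
        if self.vertical_offset < 0:
            raise ValueError(
                f"vertical_offset must be >= 0, got {self.vertical_offset!r}"
            )


@dataclass(frozen=True)
class LoomingStimulus:
    """Physical description of a disc approaching on a collision course.

    ``start_distance`` and ``end_distance`` delimit the simulated travel; the
    object stops ``end_distance`` metres short of the eye, so the projected
    collision lies ``end_distance / speed_v`` seconds beyond the end of
    visible motion (see :func:`collision_offset`).
    """

    half_size_l: float
    speed_v: float
    start_distance: float = 10.0
    end_distance: float = 0.07
    wing: Optional[WingSpec] = None
    stim_id: Optional[str] = None

    def __post_init__(self) -> None:
        _require_positive("half_size_l", self.half_size_l)
        _require_positive("speed_v", self.speed_v)
        if self.end_distance < 0:
            raise ValueError(f"end_distance must be >= 0, got {self.end_distance!r}")
        if self.start_distance < self.end_distance:
            raise ValueError(
                "start_distance must be >= end_distance, got "
                f"{self.start_distance!r} < {self.end_distance!r}"
            )
        if self.wing is not None and self.wing.span <= 2 * self.half_size_l:
            raise ValueError(
                f"wing span {self.wing.span!r} must exceed disc diameter "
                f"{2 * self.half_size_l!r}: wings must protrude"
            )

    @property
    def l_over_v_ms(self) -> float:
        """Half-size over speed ratio, in milliseconds."""
        return lov_ratio(self.half_size_l, self.speed_v)

    @property
    def label(self) -> str:
        """Display label of the ratio, rounded to one decimal place."""
        return f"{display_round(self.l_over_v_ms):.1f}"

    @property
    def approach_duration(self) -> float:
        """Duration of visible motion, seconds."""
        return (self.start_distance - self.end_distance) / self.speed_v


@dataclass(frozen=True)
class LoomingTrajectory:
    """Sampled approach: time to collision, distance and angular subtenses.

    ``t_to_collision`` is strictly decreasing along the samples;
    ``theta_disc_deg`` is strictly increasing.  ``theta_wing_deg`` is present
    only when the stimulus carries a wing bar.
    """

    t_to_collision: np.ndarray
    distance: np.ndarray
    theta_disc_deg: np.ndarray
    theta_wing_deg: Optional[np.ndarray] = None

    def __len__(self) -> int:
        return len(self.t_to_collision)


@dataclass
class FrameSchedule:
    """Per-frame display record for a looming stimulus on a raster monitor."""

    refresh_hz: float
    viewing_distance: float
    pixel_pitch: float
    frame: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    t_to_collision: np.ndarray = field(default_factory=lambda: np.empty(0))
    theta_deg: np.ndarray = field(default_factory=lambda: np.empty(0))
    radius_px: np.ndarray = field(default_factory=lambda: np.empty(0))
    wing_w_px: Optional[np.ndarray] = None
    wing_h_px: Optional[np.ndarray] = None
    clipped: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))
    warnings: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def any_clipped(self) -> bool:
        return bool(np.any(self.clipped))


def lov_ratio(half_size: float, speed: float) -> float:
    """Ratio of object half-size to approach speed, in milliseconds.

    Parameters
    ----------
    half_size
        Object half-size in metres (> 0).
    speed
        Approach speed in m/s (> 0).

    Returns
    -------
    float
        ``1000 * half_size / speed`` in ms.  Rounding for display labels is
        the caller's concern; see :func:`display_round`.
    """
    _require_positive("half_size", half_size)
    _require_positive("speed", speed)
    return 1000.0 * half_size / speed


def display_round(value: float, decimals: int = 1) -> float:
    """Round half-up to ``decimals`` places, as printed on stimulus labels.

    Python's built-in ``round`` is banker's rounding; labels such as 1.25 ms
    must round up to 1.3, so decimal half-up rounding is used instead.
    """
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP))


def angular_subtense(half_size: float, distance: float) -> float:
    """Full angular subtense of an object, ``2*arctan(l/d)``, in degrees.

    Strictly decreasing in ``distance``; invariant under joint rescaling of
    ``half_size`` and ``distance``.
    """
    _require_positive("half_size", half_size)
    if distance <= 0:
        raise ValueError(f"distance must be > 0 (object at or behind the eye), got {distance!r}")
    return math.degrees(2.0 * math.atan2(half_size, distance))


def subtense_rate(
    half_size: float, speed: float, t_to_collision: float, degrees: bool = True
) -> float:
    """Angular expansion rate of a looming object at time ``t_to_collision``.

    Closed form ``theta'(t) = 2*l*v / (v^2 t^2 + l^2)`` (the magnitude of the
    time derivative of the subtense with ``d = v*t``), returned in deg/s by
    default, rad/s with ``degrees=False``.  Positive, and strictly increasing
    as ``t_to_collision`` decreases.
    """
    _require_positive("half_size", half_size)
    _require_positive("speed", speed)
    if t_to_collision <= 0:
        raise ValueError(
            f"t_to_collision must be > 0 before collision, got {t_to_collision!r}"
        )
    rate = 2.0 * half_size * speed / (speed**2 * t_to_collision**2 + half_size**2)
    return math.degrees(rate) if degrees else rate


def trajectory(stim: LoomingStimulus, dt: float) -> LoomingTrajectory:
    """Sample an approach every ``dt`` seconds, from onset down to motion end.

    Samples span ``t_to_collision`` from ``start_distance/speed_v`` down to
    ``end_distance/speed_v`` (both endpoints included).  Wing-tip subtense is
    computed as ``2*arctan((span/2)/d)`` when a wing is present.
    """
    _require_positive("dt", dt)
    t_start = stim.start_distance / stim.speed_v
    t_end = stim.end_distance / stim.speed_v
    if dt > t_start - t_end:
        raise ValueError(
            f"dt={dt!r} exceeds the approach duration {t_start - t_end!r} s"
        )
    t = np.arange(t_start, t_end, -dt)
    if t[-1] > t_end + 1e-12:
        t = np.append(t, t_end)
    if t_end == 0.0:
        # the subtense diverges at the eye; stop one step short
        t = t[t > 0]
    d = stim.speed_v * t
    theta = np.degrees(2.0 * np.arctan2(stim.half_size_l, d))
    theta_wing = None
    if stim.wing is not None:
        theta_wing = np.degrees(2.0 * np.arctan2(stim.wing.span / 2.0, d))
    return LoomingTrajectory(
        t_to_collision=t, distance=d, theta_disc_deg=theta, theta_wing_deg=theta_wing
    )


def collision_offset(stim: LoomingStimulus) -> float:
    """Gap (s) between the end of visible motion and projected collision.

    The displayed approach stops ``end_distance`` short of the eye, so
    events timed "at motion end" precede projected collision by
    ``end_distance / speed_v`` seconds.
    """
    return stim.end_distance / stim.speed_v


def frame_schedule(
    stim: LoomingStimulus,
    refresh_hz: float = 200.0,
    viewing_distance: float = 0.07,
    pixel_pitch: float = 0.0004,
    screen_px: Sequence[int] = (640, 480),
) -> FrameSchedule:
    """Convert a physical approach into a per-frame on-screen schedule.

    Frame ``i`` (0-based) shows the object at distance
    ``start_distance - speed_v*(i+1)/refresh_hz``; the frame count is
    ``floor(approach_duration * refresh_hz)`` and the final frame is clamped
    to ``end_distance`` so that the last displayed size equals the size at
    the end of the approach.  On-screen disc radius is the perspective
    projection ``viewing_distance * tan(theta/2) / pixel_pitch``; the wing
    bar is scaled by the same rule in both dimensions.  Projections larger
    than the configured screen are clipped and flagged.
    """
    _require_positive("refresh_hz", refresh_hz)
    _require_positive("viewing_distance", viewing_distance)
    _require_positive("pixel_pitch", pixel_pitch)
    n_frames = int(math.floor(stim.approach_duration * refresh_hz))
    sched = FrameSchedule(
        refresh_hz=refresh_hz,
        viewing_distance=viewing_distance,
        pixel_pitch=pixel_pitch,
    )
    if n_frames == 0:
        return sched
    idx = np.arange(n_frames)
    d = stim.start_distance - stim.speed_v * (idx + 1) / refresh_hz
    d = np.maximum(d, stim.end_distance)
    d[-1] = stim.end_distance
    if stim.end_distance == 0.0:
        raise ValueError("end_distance = 0 puts the final frame at the eye; cannot render")
    theta = np.degrees(2.0 * np.arctan2(stim.half_size_l, d))
    radius = viewing_distance * (stim.half_size_l / d) / pixel_pitch
    half_w, half_h = screen_px[0] / 2.0, screen_px[1] / 2.0
    r_max = min(half_w, half_h)
    clipped = radius > r_max
    wing_w = wing_h = None
    if stim.wing is not None:
        wing_w = viewing_distance * stim.wing.span / d / pixel_pitch
        wing_h = viewing_distance * stim.wing.bar_height / d / pixel_pitch
        clipped = clipped | (wing_w > screen_px[0]) | (wing_h > screen_px[1])
        wing_w = np.minimum(wing_w, screen_px[0])
        wing_h = np.minimum(wing_h, screen_px[1])
    if np.any(clipped):
        msg = (
            f"{int(np.sum(clipped))} of {n_frames} frames exceed the "
            f"{screen_px[0]}x{screen_px[1]} px screen; values clipped"
        )
        sched.warnings.append(msg)
        warnings.warn(msg, stacklevel=2)
    sched.frame = idx
    sched.t_to_collision = d / stim.speed_v
    sched.theta_deg = theta
    sched.radius_px = np.minimum(radius, r_max)
    sched.wing_w_px = wing_w
    sched.wing_h_px = wing_h
    sched.clipped = clipped
    return sched
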