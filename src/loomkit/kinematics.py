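"""Predator attack kinematics from digitized video tracks.

Per-frame speeds are estimated from pixel coordinates of a tracked feature
(e.g. the predator's beak) with a length-based pixel calibration, then
aggregated hierarchically segment -> attack -> individual so that repeated
measures of one individual never inflate the sample size.  Closing-speed
geometry and the predator-thorax ``l/|v|`` range estimate live here too.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np

from .geometry import lov_ratio

__all__ = [
    "TrackSegment",
    "SpeedSummary",
    "ClosingSpeedScenario",
    "PredatorProfile",
    "DisplaySmoothed",
    "calibration_scale",
    "frame_speeds",
    "smooth_for_display",
    "hierarchical_mean",
    "closing_speed",
    "thorax_half_size",
    "lov_range",
]


def calibration_scale(length_px: float, length_m: float) -> float:
    """Metres per pixel from a reference feature of known physical length."""
    if length_px <= 0:
        raise ValueError(f"length_px must be > 0, got {length_px!r}")
    if length_m <= 0:
        raise ValueError(f"length_m must be > 0, got {length_m!r}")
    return length_m / length_px


@dataclass(frozen=True)
class TrackSegment:
    """One analysable run of digitized (frame, x, y) coordinates.

    ``calibration`` is a ``(length_px, length_m)`` pair for the reference
    feature used to scale pixels to metres.  Frame indices may skip; elapsed
    time between samples is ``gap / fps``.
    """

    kite_id: str
    attack_id: str
    segment_id: str
    frames: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray
    fps: float = 25.0
    calibration: Tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=int)
        x = np.asarray(self.x_px, dtype=float)
        y = np.asarray(self.y_px, dtype=float)
        if not (len(frames) == len(x) == len(y)):
            raise ValueError("frames, x_px and y_px must have equal length")
        if len(frames) < 2:
            raise ValueError("a track segment needs at least 2 samples")
        gaps = np.diff(frames)
        if np.any(gaps == 0):
            raise ValueError(
                f"duplicate frame index at position {int(np.argmin(gaps != 0))} "
                f"in segment {self.segment_id!r}"
            )
        if np.any(gaps < 0):
            raise ValueError(f"frame indices must increase in segment {self.segment_id!r}")
        if self.fps <= 0:
            raise ValueError(f"fps must be > 0, got {self.fps!r}")
        calibration_scale(*self.calibration)  # validates
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "x_px", x)
        object.__setattr__(self, "y_px", y)

    @property
    def scale_m_per_px(self) -> float:
        return calibration_scale(*self.calibration)

    def trimmed(self, trim_s: float) -> "TrackSegment":
        """Keep only samples within the final ``trim_s`` seconds."""
        if trim_s <= 0:
            raise ValueError(f"trim_s must be > 0, got {trim_s!r}")
        cutoff = self.frames[-1] - trim_s * self.fps
        keep = self.frames >= cutoff
        if int(keep.sum()) < 2:
            raise ValueError(
                f"trimming to the final {trim_s} s leaves <2 samples in "
                f"segment {self.segment_id!r}"
            )
        return TrackSegment(
            self.kite_id,
            self.attack_id,
            self.segment_id,
            self.frames[keep],
            self.x_px[keep],
            self.y_px[keep],
            self.fps,
            self.calibration,
        )


class DisplaySmoothed(np.ndarray):
    """Speed array smoothed for plotting only; must not enter summaries."""

    display_only = True


def frame_speeds(segment: TrackSegment) -> np.ndarray:
    """Speed estimate (m/s) at each inter-sample step of a track segment.

    ``speed_i = ||p_{i+1} - p_i||_px * scale * fps / frame_gap_i``; the result
    has ``n_samples - 1`` entries.
    """
    dx = np.diff(segment.x_px)
    dy = np.diff(segment.y_px)
    gaps = np.diff(segment.frames).astype(float)
    dist_px = np.hypot(dx, dy)
    return dist_px * segment.scale_m_per_px * segment.fps / gaps


def smooth_for_display(speeds: Sequence[float]) -> DisplaySmoothed:
    """Centred 3-point running mean for plotting; endpoints pass through.

    The output is tagged :class:`DisplaySmoothed` so downstream summaries can
    refuse it — quoted means are never based on smoothed data.
    """
    s = np.asarray(speeds, dtype=float)
    if len(s) < 3:
        raise ValueError(f"need >= 3 values to smooth, got {len(s)}")
    out = s.copy()
    out[1:-1] = (s[:-2] + s[1:-1] + s[2:]) / 3.0
    return out.view(DisplaySmoothed)


def _reject_smoothed(values) -> None:
    if getattr(values, "display_only", False):
        raise TypeError(
            "display-smoothed speeds must not enter quantitative summaries"
        )


@dataclass(frozen=True)
class SpeedSummary:
    """Hierarchical speed means: segment -> attack -> individual -> grand."""

    per_segment_means: Dict[Tuple[str, str, str], float]
    per_attack_means: Dict[Tuple[str, str], float]
    per_kite_means: Dict[str, float]
    grand_mean: float
    grand_sd: float
    n_kites: int


def hierarchical_mean(
    segments: Iterable[TrackSegment], trim_s: Optional[float] = None
) -> SpeedSummary:
    """Three-level unweighted averaging that avoids pseudoreplication.

    Segment mean = mean of per-frame speeds; attack mean = unweighted mean of
    its segment means; individual mean = unweighted mean of its attack means.
    Grand mean and sample SD are computed across individuals only, so every
    individual counts once however many attacks were filmed.

    Parameters
    ----------
    segments
        Labelled track segments.
    trim_s
        If given, each segment is first trimmed to its final ``trim_s``
        seconds (speed sampling window at the end of the attack).
    """
    segments = list(segments)
    if not segments:
        raise ValueError("no track segments supplied")
    seg_means: Dict[Tuple[str, str, str], float] = {}
    for seg in segments:
        if trim_s is not None:
            seg = seg.trimmed(trim_s)
        speeds = frame_speeds(seg)
        _reject_smoothed(speeds)
        key = (seg.kite_id, seg.attack_id, seg.segment_id)
        if key in seg_means:
            raise ValueError(f"duplicate segment label {key!r}")
        seg_means[key] = float(np.mean(speeds))

    attack_acc: Dict[Tuple[str, str], list] = {}
    for (kite, attack, _seg), m in seg_means.items():
        attack_acc.setdefault((kite, attack), []).append(m)
    attack_means = {k: float(np.mean(v)) for k, v in attack_acc.items()}

    kite_acc: Dict[str, list] = {}
    for (kite, _attack), m in attack_means.items():
        kite_acc.setdefault(kite, []).append(m)
    kite_means = {k: float(np.mean(v)) for k, v in kite_acc.items()}

    vals = np.array(list(kite_means.values()))
    grand_sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return SpeedSummary(
        per_segment_means=seg_means,
        per_attack_means=attack_means,
        per_kite_means=kite_means,
        grand_mean=float(np.mean(vals)),
        grand_sd=grand_sd,
        n_kites=len(vals),
    )


def closing_speed(v_pred: float, v_prey: float, phi_deg: float) -> float:
    """Magnitude of the relative velocity of two movers, m/s.

    ``phi_deg`` is the angle between the heading vectors: 180 deg is a
    head-on convergence (speeds add), 0 deg a tail chase (speeds subtract).
    ``|v_rel| = sqrt(v1^2 + v2^2 - 2 v1 v2 cos(phi))``.
    """
    if v_pred < 0:
        raise ValueError(f"v_pred must be >= 0, got {v_pred!r}")
    if v_prey < 0:
        raise ValueError(f"v_prey must be >= 0, got {v_prey!r}")
    if not 0.0 <= phi_deg <= 180.0:
        raise ValueError(f"phi_deg must lie in [0, 180], got {phi_deg!r}")
    phi = math.radians(phi_deg)
    sq = v_pred**2 + v_prey**2 - 2.0 * v_pred * v_prey * math.cos(phi)
    return math.sqrt(max(sq, 0.0))


@dataclass(frozen=True)
class PredatorProfile:
    """Predator body geometry: the thorax approximates a disc head-on."""

    wingspan: float = 1.36
    thorax_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.wingspan <= 0:
            raise ValueError(f"wingspan must be > 0, got {self.wingspan!r}")
        if not 0.0 < self.thorax_fraction < 1.0:
            raise ValueError(
                f"thorax_fraction must be in (0, 1), got {self.thorax_fraction!r}"
            )

    @property
    def thorax_half_size_l(self) -> float:
        return thorax_half_size(self)


def thorax_half_size(profile: PredatorProfile) -> float:
    """Thorax half-size ``l`` (m): ``wingspan * thorax_fraction / 2``."""
    return profile.wingspan * profile.thorax_fraction / 2.0


@dataclass(frozen=True)
class ClosingSpeedScenario:
    """Mean +/- SD speed statistics for predator and prey, and who converges.

    The ``l/|v|`` range endpoints use the fastest closing geometry (fast
    predator, fast prey, head-on) and the slowest (slow predator overtaking a
    fast prey from behind).  ``predator_chase_mean`` overrides the predator
    speed in the chase geometry for species that fly slower when manoeuvring;
    it defaults to ``predator_mean``.
    """

    predator_mean: float
    predator_sd: float = 0.0
    prey_mean: float = 0.0
    prey_sd: float = 0.0
    predator_chase_mean: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("predator_mean", "predator_sd", "prey_mean", "prey_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.predator_chase_mean is not None and self.predator_chase_mean < 0:
            raise ValueError("predator_chase_mean must be >= 0")

    @property
    def chase_mean(self) -> float:
        return (
            self.predator_mean
            if self.predator_chase_mean is None
            else self.predator_chase_mean
        )

    @property
    def v_close_max(self) -> float:
        return closing_speed(
            self.predator_mean + self.predator_sd,
            self.prey_mean + self.prey_sd,
            180.0,
        )

    @property
    def v_close_min(self) -> float:
        return closing_speed(
            self.chase_mean - self.predator_sd,
            self.prey_mean + self.prey_sd,
            0.0,
        )


def lov_range(
    scenario: ClosingSpeedScenario, profile: PredatorProfile
) -> Tuple[float, float]:
    """Predator-thorax ``l/|v|`` endpoints in ms, (low, high), unrounded.

    low uses the maximum closing speed (head-on, both fast); high uses the
    minimum (slow predator minus fast prey in a chase).  Errors out if the
    slow predator cannot overtake the fast prey.
    """
    l = thorax_half_size(profile)
    v_max = scenario.v_close_max
    slow_pred = scenario.chase_mean - scenario.predator_sd
    fast_prey = scenario.prey_mean + scenario.prey_sd
    if slow_pred - fast_prey <= 0:
        raise ValueError(
            "minimum closing speed is not positive (prey as fast as the slow "
            "predator in a chase); revise the scenario speeds"
        )
    v_min = scenario.v_close_min
    return (lov_ratio(l, v_max), lov_ratio(l, v_min))
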