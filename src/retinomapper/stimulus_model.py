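"""Periodic visual stimuli and screen geometry.

Conversions between screen pixels, visual angle, stimulus time, and
response phase.

Conventions
-----------
* Azimuth is 0 at the screen center, positive toward increasing screen x
  (the right edge of the screen as drawn), and is the angle between the
  eye->point ray and the vertical plane through the screen-center normal.
* Elevation is 0 at screen center and positive upward.
* Screen tilt rotates the screen's vertical axis toward the viewer about
  the horizontal axis through the screen center ("tilted towards" the
  animal); yaw and roll are assumed zero.
* Response phase increases with time-of-response within the cycle:
  a response peaking at time ``t`` within a cycle of period ``P`` has
  phase ``2*pi*t/P`` (mod 2*pi).  See :func:`phase_to_stimulus_time`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "ScreenGeometry",
    "StimulusSpec",
    "azimuth_bar_spec",
    "elevation_bar_spec",
    "grating_patch_spec",
    "pixel_to_visual_degrees",
    "stimulus_position_at",
    "grating_velocity_at",
    "motion_onset_time",
    "phase_to_stimulus_time",
]

SCHEMA_VERSION = 1

# Active-area dimensions of a 27-inch 16:9 panel; chosen so that a screen
# 20 cm from the eye spans roughly 110 x 75 degrees of visual field.
DEFAULT_SCREEN_WIDTH_MM = 596.7
DEFAULT_SCREEN_HEIGHT_MM = 335.7


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical geometry of the stimulus monitor relative to the eye.

    Parameters
    ----------
    width_px, height_px : int
        Screen resolution.
    width_mm, height_mm : float
        Physical active-area size.
    distance_cm : float
        Perpendicular eye-to-screen distance (eye on the screen-center
        normal).
    tilt_deg : float
        Tilt of the screen toward the viewer, degrees from vertical.
    """

    width_px: int = 2560
    height_px: int = 1440
    width_mm: float = DEFAULT_SCREEN_WIDTH_MM
    height_mm: float = DEFAULT_SCREEN_HEIGHT_MM
    distance_cm: float = 20.0
    tilt_deg: float = 17.5

    def __post_init__(self) -> None:
        for name in ("width_px", "height_px", "width_mm", "height_mm", "distance_cm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"ScreenGeometry.{name} must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["schema_version"] = SCHEMA_VERSION
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScreenGeometry":
        d = {k: v for k, v in d.items() if k != "schema_version"}
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "ScreenGeometry":
        return cls.from_dict(json.loads(s))


StimulusKind = Literal["bar_azimuth", "bar_elevation", "grating_patch"]
BAR_KINDS = ("bar_azimuth", "bar_elevation")


@dataclass(frozen=True)
class StimulusSpec:
    """One periodic stimulus: a sweeping bar or a central grating patch.

    ``velocity_profile`` is a piecewise-constant drift-speed schedule for
    the grating, a sequence of ``(duration_s, deg_per_s)`` segments whose
    durations must sum to ``period_s``.
    """

    kind: StimulusKind
    period_s: float = 8.0
    n_cycles: int = 50
    sweep_range_deg: tuple[float, float] | None = None
    patch_diameter_deg: float | None = None
    spatial_freq_cpd: float | None = None
    velocity_profile: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.period_s <= 0:
            raise ValueError("period_s must be positive")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.kind in BAR_KINDS:
            if self.sweep_range_deg is None:
                raise ValueError(f"{self.kind} requires sweep_range_deg")
        elif self.kind == "grating_patch":
            if self.velocity_profile is None:
                raise ValueError("grating_patch requires velocity_profile")
            total = sum(d for d, _ in self.velocity_profile)
            if not math.isclose(total, self.period_s, rel_tol=0, abs_tol=1e-9):
                raise ValueError(
                    "velocity_profile durations must sum to period_s "
                    f"({total} != {self.period_s})"
                )
        else:
            raise ValueError(f"unknown stimulus kind {self.kind!r}")

    @property
    def f_stim_hz(self) -> float:
        return 1.0 / self.period_s

    @property
    def duration_s(self) -> float:
        return self.period_s * self.n_cycles

    def to_dict(self) -> dict:
        d = asdict(self)
        d["schema_version"] = SCHEMA_VERSION
        if self.velocity_profile is not None:
            d["velocity_profile"] = [list(seg) for seg in self.velocity_profile]
        if self.sweep_range_deg is not None:
            d["sweep_range_deg"] = list(self.sweep_range_deg)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusSpec":
        d = {k: v for k, v in d.items() if k != "schema_version"}
        if d.get("velocity_profile") is not None:
            d["velocity_profile"] = tuple(tuple(seg) for seg in d["velocity_profile"])
        if d.get("sweep_range_deg") is not None:
            d["sweep_range_deg"] = tuple(d["sweep_range_deg"])
        return cls(**d)


def azimuth_bar_spec(
    period_s: float = 8.0,
    n_cycles: int = 10,
    sweep_range_deg: tuple[float, float] = (-55.0, 55.0),
) -> StimulusSpec:
    return StimulusSpec(
        kind="bar_azimuth", period_s=period_s, n_cycles=n_cycles,
        sweep_range_deg=sweep_range_deg,
    )


def elevation_bar_spec(
    period_s: float = 8.0,
    n_cycles: int = 10,
    sweep_range_deg: tuple[float, float] = (-37.5, 37.5),
) -> StimulusSpec:
    return StimulusSpec(
        kind="bar_elevation", period_s=period_s, n_cycles=n_cycles,
        sweep_range_deg=sweep_range_deg,
    )


def grating_patch_spec(
    period_s: float = 8.0,
    n_cycles: int = 50,
    patch_diameter_deg: float = 50.0,
    spatial_freq_cpd: float = 0.04,
    velocity_profile: Sequence[tuple[float, float]] = ((6.0, 0.0), (2.0, 50.0)),
) -> StimulusSpec:
    return StimulusSpec(
        kind="grating_patch", period_s=period_s, n_cycles=n_cycles,
        patch_diameter_deg=patch_diameter_deg, spatial_freq_cpd=spatial_freq_cpd,
        velocity_profile=tuple(tuple(seg) for seg in velocity_profile),
    )


def pixel_to_visual_degrees(
    px: tuple[float, float], geom: ScreenGeometry
) -> tuple[float, float]:
    """True visual angle of a screen pixel for an eye on the center normal.

    The flat-screen (arctangent) correction is applied: equal pixel steps
    near the screen edge subtend smaller angles than near the center.

    Parameters
    ----------
    px : (x, y)
        Pixel coordinates, origin top-left, x rightward, y downward.
    geom : ScreenGeometry

    Returns
    -------
    (azimuth_deg, elevation_deg)
    """
    x, y = px
    if not (0 <= x <= geom.width_px and 0 <= y <= geom.height_px):
        raise ValueError(f"pixel {px} outside screen bounds "
                         f"({geom.width_px} x {geom.height_px})")
    # mm offsets from screen center; dy positive upward
    dx = (x - geom.width_px / 2.0) * geom.width_mm / geom.width_px
    dy = (geom.height_px / 2.0 - y) * geom.height_mm / geom.height_px
    d = geom.distance_cm * 10.0
    t = math.radians(geom.tilt_deg)
    # 3D position with eye at origin, screen-center normal along +depth;
    # tilt rotates the screen's up-vector toward the viewer.
    p_x = dx
    p_depth = d - dy * math.sin(t)
    p_up = dy * math.cos(t)
    azimuth = math.degrees(math.atan2(p_x, math.hypot(p_depth, p_up)))
    elevation = math.degrees(math.atan2(p_up, p_depth))
    return azimuth, elevation


def stimulus_position_at(t: float, spec: StimulusSpec) -> float:
    """Swept-bar position (degrees) at time ``t``, periodic in ``period_s``."""
    if spec.kind not in BAR_KINDS:
        raise ValueError(f"stimulus_position_at requires a bar stimulus, got {spec.kind}")
    lo, hi = spec.sweep_range_deg
    frac = (t % spec.period_s) / spec.period_s
    return lo + frac * (hi - lo)


def grating_velocity_at(t: float, spec: StimulusSpec) -> float:
    """Piecewise-constant grating drift speed (deg/s) at time ``t``."""
    if spec.kind != "grating_patch":
        raise ValueError(f"grating_velocity_at requires grating_patch, got {spec.kind}")
    if t < 0:
        raise ValueError("t must be non-negative")
    tau = t % spec.period_s
    edge = 0.0
    for duration, velocity in spec.velocity_profile:
        edge += duration
        if tau < edge:
            return velocity
    return spec.velocity_profile[-1][1]


def motion_onset_time(spec: StimulusSpec) -> float:
    """Time within the cycle at which the grating first moves (deg/s > 0)."""
    if spec.kind != "grating_patch":
        raise ValueError("motion_onset_time requires grating_patch")
    edge = 0.0
    for duration, velocity in spec.velocity_profile:
        if velocity > 0:
            return edge
        edge += duration
    raise ValueError("velocity profile never moves")


def phase_to_stimulus_time(
    phase_rad: float | np.ndarray, spec: StimulusSpec, delay_s: float = 0.0
):
    """Invert the phase encoding: response phase -> time within the cycle.

    ``t = ((phase / 2*pi) * period_s - delay_s) mod period_s``.  The phase
    here follows the package convention (increases with time-of-response);
    see the module docstring.
    """
    t = (np.asarray(phase_rad) / (2.0 * np.pi)) * spec.period_s - delay_s
    out = np.mod(t, spec.period_s)
    if np.isscalar(phase_rad):
        return float(out)
    return out
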