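"""Transit-time velocimetry along a calibrated vessel path.

Pulse wave velocity is estimated foot-to-foot: the time-to-trough of the
fitted pulse wave is read at two sites along the vein (proximal and distal
to the optic disc, three wall points each), converted from cycle fractions
to seconds via the cardiac cycle time, and differenced to give the pulse
transit time. Dividing the geodesic (along-vessel) distance between the
sites, calibrated against an assumed optic-disc diameter of 1.65 mm, yields
the velocity in mm/s.

All reported quantities follow the six-decimal-place convention when
``round_6dp`` report mode is enabled.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from retivel.timebase import frame_period

__all__ = [
    "SpatialCalibration", "VesselPath", "TransitSites", "PWVResult",
    "calibrate", "geodesic_length", "site_time_seconds", "transit_time",
    "pulse_wave_velocity", "resolution_limits", "event_duration",
    "wrap_cycle_difference", "unwrap_cycles", "estimate_pwv",
    "pwv_from_path_profile",
]

DEFAULT_DISC_MM = 1.65


class VelocimetryError(ValueError):
    """Invalid velocimetry configuration or input."""


def _round6(x: float, enabled: bool) -> float:
    return round(x, 6) if enabled else x


@dataclass(frozen=True)
class SpatialCalibration:
    """Pixel-to-millimetre scale from a physical reference length."""

    mm_per_pixel: float
    reference_mm: float
    reference_px: float

    def __post_init__(self):
        if not self.mm_per_pixel > 0:
            raise VelocimetryError("mm_per_pixel must be positive")


@dataclass(frozen=True)
class VesselPath:
    """Ordered pixel coordinates tracing the vessel centerline."""

    points: tuple[tuple[float, float], ...]  # (row, col), 0-based

    def __post_init__(self):
        pts = tuple((float(r), float(c)) for r, c in self.points)
        object.__setattr__(self, "points", pts)
        if len(pts) < 2:
            raise VelocimetryError("vessel path needs at least 2 points")
        for p, q in zip(pts, pts[1:]):
            if p == q:
                raise VelocimetryError("consecutive path points must be distinct")

    def arc_lengths_px(self) -> np.ndarray:
        """Cumulative arc length (pixels) at each vertex, starting at 0."""
        pts = np.asarray(self.points)
        seg = np.hypot(*(np.diff(pts, axis=0).T))
        return np.concatenate([[0.0], np.cumsum(seg)])


@dataclass(frozen=True)
class TransitSites:
    """Two measurement sites of three venous-wall points each.

    site_a is proximal to the optic disc, site_b distal; trough times are
    in cardiac-cycle fractions.
    """

    site_a: tuple[tuple[int, int], ...]
    site_b: tuple[tuple[int, int], ...]
    trough_a_cycles: tuple[float, ...]
    trough_b_cycles: tuple[float, ...]


@dataclass(frozen=True)
class PWVResult:
    """Transit-time velocimetry result."""

    t_a_s: float        # mean proximal-site trough time, seconds
    t_b_s: float        # mean distal-site trough time, seconds
    transit_s: float    # pulse transit time, t_b - t_a
    distance_mm: float  # geodesic site separation
    pwv_mm_s: float     # distance / transit time
    direction_warning: bool = False

    def to_dict(self) -> dict:
        return {
            "t_a_s": self.t_a_s, "t_b_s": self.t_b_s,
            "transit_s": self.transit_s, "distance_mm": self.distance_mm,
            "pwv_mm_s": self.pwv_mm_s,
            "direction_warning": self.direction_warning,
        }


def calibrate(reference_px: float, reference_mm: float = DEFAULT_DISC_MM) -> SpatialCalibration:
    """Spatial calibration from a reference length (optic disc by default)."""
    if not (reference_px > 0 and reference_mm > 0):
        raise VelocimetryError("reference lengths must be positive")
    return SpatialCalibration(
        mm_per_pixel=reference_mm / reference_px,
        reference_mm=reference_mm, reference_px=reference_px,
    )


def geodesic_length(path: VesselPath, calib: SpatialCalibration) -> float:
    """Along-path (geodesic) length of the vessel polyline in mm."""
    return float(path.arc_lengths_px()[-1]) * calib.mm_per_pixel


def unwrap_cycles(values: np.ndarray, reference: float | None = None) -> np.ndarray:
    """Replace cycle fractions by representatives within half a cycle of a
    reference (the first finite value unless given), so that points
    straddling the cycle boundary (0.995 vs 0.005) average sensibly."""
    vals = np.asarray(values, dtype=float)
    if reference is None:
        finite = vals[np.isfinite(vals)]
        if len(finite) == 0:
            return vals.copy()
        reference = float(finite[0])
    return reference + np.array([
        wrap_cycle_difference(v - reference) if math.isfinite(v) else v
        for v in vals
    ])


def site_time_seconds(
    trough_cycles,
    cycle_time_s: float,
    min_points: int = 3,
    round_6dp: bool = False,
) -> float:
    """Mean site trough time in seconds from per-point cycle fractions.

    Each point is converted by the cardiac cycle time and the site mean
    taken (the order is immaterial by linearity). Points are first unwrapped
    to within half a cycle of the site's first value, which leaves sites
    away from the cycle boundary untouched but keeps straddling sites
    coherent; the mean may then fall marginally below zero (a trough just
    before the cycle reference). By default all three wall points must be
    finite; with fewer finite values than ``min_points`` the result is NaN
    with a warning.
    """
    if not cycle_time_s > 0:
        raise VelocimetryError("cycle_time_s must be positive")
    vals = np.asarray(trough_cycles, dtype=float)
    finite = np.isfinite(vals)
    if finite.sum() < min_points:
        warnings.warn(
            f"site has {int(finite.sum())} finite trough values, "
            f"needs {min_points}; site time is missing",
            RuntimeWarning, stacklevel=2,
        )
        return float("nan")
    rep = unwrap_cycles(vals[finite])
    return _round6(float(np.mean(rep) * cycle_time_s), round_6dp)


def transit_time(t_a_s: float, t_b_s: float, round_6dp: bool = False) -> float:
    """Pulse transit time: distal minus proximal trough time (seconds).

    A non-positive result indicates a propagation direction opposite to the
    assumed proximal-to-distal sense; it is returned with a warning, not
    absolute-valued or dropped.
    """
    if not (math.isfinite(t_a_s) and math.isfinite(t_b_s)):
        return float("nan")
    dt = _round6(t_b_s - t_a_s, round_6dp)
    if dt <= 0:
        warnings.warn(
            f"non-positive transit time {dt}: pulse appears to travel "
            "distal-to-proximal", RuntimeWarning, stacklevel=2,
        )
    return dt


def pulse_wave_velocity(distance_mm: float, transit_s: float, round_6dp: bool = False) -> float:
    """Velocity = distance / transit time, in mm/s."""
    if distance_mm < 0:
        raise VelocimetryError("distance must be non-negative")
    if not transit_s > 0:
        raise VelocimetryError(f"velocity undefined for transit time {transit_s}")
    return _round6(distance_mm / transit_s, round_6dp)


def resolution_limits(fps: float, window_mm: float, round_6dp: bool = True):
    """Measurement limits of a video velocimeter.

    The frame period sets the minimum resolvable time scale, and the spatial
    window (maximum observable path length) divided by that period bounds the
    measurable velocity: e.g. a 1.197 mm field at 120 FPS caps the estimate
    at 1.197/0.008333 = 143.646 mm/s.
    """
    if not window_mm > 0:
        raise VelocimetryError("window_mm must be positive")
    min_time_s = frame_period(fps, round_6dp=round_6dp)
    return min_time_s, _round6(window_mm / min_time_s, round_6dp)


def event_duration(frame_start: int, frame_end: int, fps: float, round_6dp: bool = True):
    """Frame count and duration of an event between two frame indices."""
    if frame_end <= frame_start:
        raise VelocimetryError(
            f"frame_end ({frame_end}) must exceed frame_start ({frame_start})")
    count = frame_end - frame_start
    seconds = _round6(count * frame_period(fps, round_6dp=round_6dp), round_6dp)
    return count, seconds


def wrap_cycle_difference(delta_cycles: float) -> float:
    """Map a trough-time difference in cycles to its representative in
    (-0.5, 0.5], handling sites that straddle the cycle boundary."""
    wrapped = (delta_cycles + 0.5) % 1.0 - 0.5
    if wrapped == -0.5:
        wrapped = 0.5
    return wrapped


def estimate_pwv(
    trough_a_cycles,
    trough_b_cycles,
    cycle_time_s: float,
    distance_mm: float,
    min_points: int = 3,
    round_6dp: bool = False,
) -> PWVResult:
    """Full transit-time chain from site trough times to velocity.

    The site difference is taken modulo one cycle with representative in
    (-0.5, 0.5], so sites straddling the cycle boundary (e.g. 0.98 vs 0.02)
    difference correctly.
    """
    t_a = site_time_seconds(trough_a_cycles, cycle_time_s,
                            min_points=min_points, round_6dp=round_6dp)
    t_b = site_time_seconds(trough_b_cycles, cycle_time_s,
                            min_points=min_points, round_6dp=round_6dp)
    if not (math.isfinite(t_a) and math.isfinite(t_b)):
        return PWVResult(t_a_s=t_a, t_b_s=t_b, transit_s=float("nan"),
                         distance_mm=distance_mm, pwv_mm_s=float("nan"))
    delta_cycles = wrap_cycle_difference((t_b - t_a) / cycle_time_s)
    dt = _round6(delta_cycles * cycle_time_s, round_6dp)
    warning = dt <= 0
    if warning:
        warnings.warn(
            f"non-positive transit time {dt}: pulse appears to travel "
            "distal-to-proximal", RuntimeWarning, stacklevel=2,
        )
        pwv = float("nan") if dt == 0 else _round6(distance_mm / dt, round_6dp)
    else:
        pwv = pulse_wave_velocity(distance_mm, dt, round_6dp=round_6dp)
    return PWVResult(t_a_s=t_a, t_b_s=t_b, transit_s=dt,
                     distance_mm=distance_mm, pwv_mm_s=pwv,
                     direction_warning=warning)


def pwv_from_path_profile(
    arc_mm,
    trough_cycles,
    cycle_time_s: float,
    min_points: int = 8,
) -> float:
    """PWV from the trough-time profile along the whole vessel segment.

    Under constant propagation speed the trough time grows linearly with arc
    length, so the least-squares slope of trough time (seconds) against arc
    position (mm) is the inverse velocity; using every mapped vessel pixel
    rather than two sites averages the per-pixel phase noise down. Trough
    fractions are unwrapped around their median before fitting. Returns NaN
    (with a warning) for too few finite points or a non-positive slope.
    """
    if not cycle_time_s > 0:
        raise VelocimetryError("cycle_time_s must be positive")
    x = np.asarray(arc_mm, dtype=float)
    y = np.asarray(trough_cycles, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < min_points or np.ptp(x[ok]) == 0:
        warnings.warn("too few finite points for a path profile fit",
                      RuntimeWarning, stacklevel=2)
        return float("nan")
    y_rep = unwrap_cycles(y[ok], reference=float(np.median(y[ok])))
    slope = float(np.polyfit(x[ok], y_rep * cycle_time_s, 1)[0])
    if slope <= 0:
        warnings.warn(f"non-positive path-profile slope {slope}; "
                      "propagation direction opposite to the path",
                      RuntimeWarning, stacklevel=2)
        return float("nan") if slope == 0 else 1.0 / slope
    return 1.0 / slope
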