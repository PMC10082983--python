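"""Cardiac-cycle time base.

Frames are indexed within each cardiac cycle and mapped to a *nominal time*
measured in fractions of the cycle:

    t_i = i / n_c + c - 1

for frame ``i`` (1-based) of cycle ``c`` containing ``n_c`` frames, so the
grid of cycle ``c`` lies in ``(c-1, c]`` and the last frame of each cycle
lands exactly on an integer. Cycle boundaries come from an external cardiac
reference (pulse-oximetry audio in the acquisition protocol) and are supplied
as frame indices; the mean cycle duration in seconds converts cycle-fraction
times to real time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class TimebaseError(ValueError):
    """Invalid cardiac timing configuration or frame index."""


@dataclass(frozen=True)
class CardiacTiming:
    """Cardiac-cycle boundaries and duration for one analyzed video segment.

    Parameters
    ----------
    cycle_boundaries
        Ordered frame indices (0-based) marking the start of each cycle;
        length ``n_cycles + 1``. The first element is the first analyzed
        frame, the last is one past the final analyzed frame (half-open
        per cycle).
    cycle_time_s
        Mean cardiac cycle duration in seconds.
    """

    cycle_boundaries: tuple[int, ...]
    cycle_time_s: float

    def __post_init__(self) -> None:
        bounds = tuple(int(b) for b in self.cycle_boundaries)
        object.__setattr__(self, "cycle_boundaries", bounds)
        if len(bounds) < 2:
            raise TimebaseError("need at least 2 cycle boundaries (one complete cycle)")
        if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
            raise TimebaseError("cycle_boundaries must be strictly increasing")
        if not self.cycle_time_s > 0:
            raise TimebaseError(f"cycle_time_s must be positive, got {self.cycle_time_s}")

    @property
    def n_cycles(self) -> int:
        return len(self.cycle_boundaries) - 1

    @property
    def n_frames(self) -> int:
        return self.cycle_boundaries[-1] - self.cycle_boundaries[0]

    def frames_in_cycle(self, c: int) -> int:
        """Number of frames in cycle ``c`` (1-based)."""
        if not 1 <= c <= self.n_cycles:
            raise TimebaseError(f"cycle index {c} out of range 1..{self.n_cycles}")
        return self.cycle_boundaries[c] - self.cycle_boundaries[c - 1]


@dataclass(frozen=True)
class CycleTimeGrid:
    """Per-frame nominal times in cardiac-cycle fractions."""

    t: np.ndarray            # cycle-fraction time, strictly increasing
    frame_index: np.ndarray  # 1-based index i within its cycle
    cycle_index: np.ndarray  # cycle label c, 1-based

    def __len__(self) -> int:
        return len(self.t)


def nominal_frame_time(i: int, c: int, n_c: int) -> float:
    """Nominal time of within-cycle frame ``i`` (1-based) of cycle ``c``.

    Returns ``i / n_c + c - 1``, which lies in ``(c-1, c]``.
    """
    if n_c <= 0:
        raise TimebaseError(f"n_c must be positive, got {n_c}")
    if c < 1:
        raise TimebaseError(f"cycle index must be >= 1, got {c}")
    if not 1 <= i <= n_c:
        raise TimebaseError(f"frame index {i} outside 1..{n_c}")
    return i / n_c + c - 1


def build_time_grid(timing: CardiacTiming) -> CycleTimeGrid:
    """Map every analyzed frame to its cycle-fraction nominal time."""
    t, idx, cyc = [], [], []
    for c in range(1, timing.n_cycles + 1):
        n_c = timing.frames_in_cycle(c)
        for i in range(1, n_c + 1):
            t.append(nominal_frame_time(i, c, n_c))
            idx.append(i)
            cyc.append(c)
    return CycleTimeGrid(
        t=np.asarray(t, dtype=float),
        frame_index=np.asarray(idx, dtype=int),
        cycle_index=np.asarray(cyc, dtype=int),
    )


def cycles_to_seconds(t_cycles, cycle_time_s: float):
    """Convert cycle-fraction time(s) to seconds."""
    if not cycle_time_s > 0:
        raise TimebaseError(f"cycle_time_s must be positive, got {cycle_time_s}")
    return np.multiply(t_cycles, cycle_time_s)


def frame_period(fps: float, round_6dp: bool = False) -> float:
    """Duration of one frame, ``1/fps`` seconds.

    With ``round_6dp`` the result is rounded to six decimal places, the
    convention used for all reported arithmetic (e.g. 1/120 -> 0.008333 s).
    """
    if not fps > 0:
        raise TimebaseError(f"fps must be positive, got {fps}")
    period = 1.0 / fps
    return round(period, 6) if round_6dp else period
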