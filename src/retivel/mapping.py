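"""Whole-field pulse mapping.

Applies the harmonic regression independently to every pixel of a
pre-aligned frame stack and collects the two per-pixel summaries into
images: the harmonic regression wave amplitude (HRWa) map and the
time-to-trough map (cycle fractions; NaN where the trough is undefined).
Coordinates are 0-based (row, col) with row 0 at the image top.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from retivel.harmonic import FitError, PixelSeries, fit_harmonic_regression
from retivel.timebase import CardiacTiming, build_time_grid

__all__ = ["FrameStack", "PulseMaps", "extract_green_series", "fit_stack", "sample_map"]

# qc codes
QC_OK = 0
QC_DEGENERATE = 1   # constant / zero-amplitude pixel, trough undefined
QC_NOCONVERGE = 2   # rho search did not converge
QC_FAILED = 3       # fit raised
QC_SKIPPED = 4      # outside the region of interest


@dataclass(frozen=True)
class FrameStack:
    """Time-ordered single-channel (green) intensity frames.

    frames : (T, H, W) float array
    fps    : acquisition frame rate
    origin : index of the first analyzed frame in the source video
    """

    frames: np.ndarray
    fps: float
    origin: int = 0

    def __post_init__(self):
        frames = np.asarray(self.frames, dtype=float)
        object.__setattr__(self, "frames", frames)
        if frames.ndim != 3:
            raise ValueError(f"frames must be (T, H, W), got shape {frames.shape}")
        if frames.shape[0] < 8:
            raise ValueError(f"need at least 8 frames, got {frames.shape[0]}")
        if not self.fps > 0:
            raise ValueError(f"fps must be positive, got {self.fps}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape


@dataclass(frozen=True)
class PulseMaps:
    """Per-pixel HRWa, time-to-trough and QC images."""

    amplitude: np.ndarray  # H x W, intensity units, >= 0
    trough: np.ndarray     # H x W, cycle fractions in [0, 1), NaN if undefined
    qc: np.ndarray         # H x W int codes (QC_*)

    def __post_init__(self):
        if not (self.amplitude.shape == self.trough.shape == self.qc.shape):
            raise ValueError("map shapes differ")


def extract_green_series(
    stack: FrameStack,
    pixel: tuple[int, int],
    t: np.ndarray,
    neighborhood: int = 1,
) -> PixelSeries:
    """Intensity time series of one pixel (optionally a k x k neighborhood
    mean, default 1 x 1) paired with the cycle-fraction time grid."""
    row, col = pixel
    T, H, W = stack.shape
    if not (0 <= row < H and 0 <= col < W):
        raise IndexError(f"pixel {pixel} outside {H}x{W} image")
    if neighborhood < 1 or neighborhood % 2 == 0:
        raise ValueError("neighborhood must be a positive odd integer")
    if len(t) != T:
        raise ValueError(f"time grid length {len(t)} != stack length {T}")
    if neighborhood == 1:
        y = stack.frames[:, row, col]
    else:
        h = neighborhood // 2
        r0, r1 = max(row - h, 0), min(row + h + 1, H)
        c0, c1 = max(col - h, 0), min(col + h + 1, W)
        y = stack.frames[:, r0:r1, c0:c1].mean(axis=(1, 2))
    return PixelSeries(y=np.array(y, dtype=float), t=np.asarray(t, dtype=float))


def fit_stack(
    stack: FrameStack,
    timing: CardiacTiming,
    order: int = 2,
    roi: np.ndarray | None = None,
    knots: tuple[float, ...] | None = None,
    basis: str = "2pi",
    neighborhood: int = 1,
) -> PulseMaps:
    """Fit the harmonic regression to every pixel (within ``roi`` if given).

    Pixels are processed independently with no spatial smoothing. Per-pixel
    failures are recorded in the QC map instead of aborting the run; the
    output is deterministic for identical inputs and configuration.
    """
    T, H, W = stack.shape
    if timing.n_frames != T:
        raise ValueError(
            f"timing covers {timing.n_frames} frames but stack has {T}")
    grid = build_time_grid(timing)
    if roi is not None:
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != (H, W):
            raise ValueError(f"roi shape {roi.shape} != image shape {(H, W)}")

    amplitude = np.zeros((H, W), dtype=float)
    trough = np.full((H, W), np.nan)
    qc = np.full((H, W), QC_SKIPPED, dtype=int)

    for row in range(H):
        for col in range(W):
            if roi is not None and not roi[row, col]:
                continue
            series = extract_green_series(stack, (row, col), grid.t,
                                          neighborhood=neighborhood)
            try:
                fit = fit_harmonic_regression(series, order=order,
                                              knots=knots, basis=basis)
            except FitError:
                qc[row, col] = QC_FAILED
                continue
            amplitude[row, col] = fit.hrw_amplitude
            trough[row, col] = fit.time_to_trough
            if "degenerate" in fit.flags or fit.hrw_amplitude == 0.0:
                qc[row, col] = QC_DEGENERATE
            elif not fit.converged:
                qc[row, col] = QC_NOCONVERGE
            else:
                qc[row, col] = QC_OK
    return PulseMaps(amplitude=amplitude, trough=trough, qc=qc)


def sample_map(maps: PulseMaps, points: list[tuple[int, int]]):
    """Amplitude and trough values at the given (row, col) points.

    Values at pixels flagged degenerate/failed in QC are returned as NaN so
    that missingness propagates into downstream site averages.
    """
    H, W = maps.amplitude.shape
    amp, tr = [], []
    for row, col in points:
        if not (0 <= row < H and 0 <= col < W):
            raise IndexError(f"point ({row}, {col}) outside {H}x{W} map")
        ok = maps.qc[row, col] in (QC_OK, QC_NOCONVERGE)
        amp.append(maps.amplitude[row, col] if ok else float("nan"))
        tr.append(maps.trough[row, col] if ok else float("nan"))
    return np.asarray(amp), np.asarray(tr)
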