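"""Lymphatic pumping rate from NIRF image stacks.

The measurement follows the trough-counting procedure: draw a circular ROI
over the conducting vessel, plot the mean ROI intensity of each frame over
time, count the troughs T_r over F frames, and convert with

    rate [pumps/min] = T_r / (F / (fps * 60))

Baseline rates average the left and right collecting vessels imaged for at
least 3 minutes on different days.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d, median_filter
from scipy.signal import find_peaks
from skimage.draw import disk, polygon

__all__ = [
    "ImageStack",
    "ROI",
    "IntensityTrace",
    "TroughSet",
    "PumpingRateResult",
    "Measurement",
    "MeasurementSet",
    "extract_trace",
    "detrend",
    "detect_troughs",
    "compute_rate",
    "baseline_rate",
    "rate_from_trace",
]


class TraceTooShortError(ValueError):
    pass


class InvalidRoiError(ValueError):
    pass


@dataclass(frozen=True)
class ImageStack:
    """Time-ordered grayscale frames with acquisition metadata.

    frames : (T, H, W) non-negative intensities
    fps : frames per second (mandatory; a wrong fps scales every rate)
    pixel_size_um : microns per pixel, or None when uncalibrated
    """

    frames: np.ndarray
    fps: float
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        if frames.ndim != 3 or frames.shape[0] < 1:
            raise ValueError("frames must be a (T, H, W) array with T >= 1")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if np.any(frames < 0):
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "frames", frames)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass(frozen=True)
class ROI:
    """Circular or polygonal region of interest, 0-based (row, col).

    Circle: ``ROI.circle(row, col, radius)``; polygon:
    ``ROI.from_polygon([(r0, c0), ...])``.
    """

    kind: str
    params: tuple

    @classmethod
    def circle(cls, row: float, col: float, radius: float) -> "ROI":
        if radius <= 0:
            raise InvalidRoiError("radius must be > 0")
        return cls("circle", (float(row), float(col), float(radius)))

    @classmethod
    def from_polygon(cls, vertices) -> "ROI":
        verts = tuple((float(r), float(c)) for r, c in vertices)
        if len(verts) < 3:
            raise InvalidRoiError("polygon needs >= 3 vertices")
        return cls("polygon", verts)

    def footprint(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        """(rows, cols) of pixels inside the ROI; validates bounds."""
        h, w = shape
        if self.kind == "circle":
            r0, c0, rad = self.params
            if r0 - rad < -0.5 or c0 - rad < -0.5 or r0 + rad > h - 0.5 or (
                c0 + rad > w - 0.5
            ):
                raise InvalidRoiError("circle ROI extends outside the image")
            rr, cc = disk((r0, c0), rad, shape=shape)
        else:
            rows = [v[0] for v in self.params]
            cols = [v[1] for v in self.params]
            if min(rows) < 0 or min(cols) < 0 or max(rows) > h - 1 or (
                max(cols) > w - 1
            ):
                raise InvalidRoiError("polygon ROI extends outside the image")
            rr, cc = polygon(rows, cols, shape=shape)
        if rr.size == 0:
            raise InvalidRoiError("ROI has an empty pixel footprint")
        return rr, cc

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        rr, cc = self.footprint(shape)
        m[rr, cc] = True
        return m


@dataclass(frozen=True)
class IntensityTrace:
    """Per-frame mean ROI intensity at a known frame rate."""

    values: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 1:
            raise ValueError("values must be a non-empty 1-D array")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return self.values.size / self.fps


@dataclass(frozen=True)
class TroughSet:
    """Frame indices of detected troughs, strictly increasing."""

    indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        if idx.size and np.any(np.diff(idx) <= 0):
            raise ValueError("trough indices must be strictly increasing")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return self.indices.size


@dataclass(frozen=True)
class PumpingRateResult:
    n_troughs: int
    n_frames: int
    fps: float
    rate: float  # pumps per minute


@dataclass(frozen=True)
class Measurement:
    side: str  # "left" or "right"
    day: object
    result: PumpingRateResult


@dataclass(frozen=True)
class MeasurementSet:
    entries: tuple[Measurement, ...]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("MeasurementSet needs >= 1 entry")


def extract_trace(stack: ImageStack, roi: ROI) -> IntensityTrace:
    """Mean ROI intensity of every frame."""
    rr, cc = roi.footprint(stack.shape)
    values = stack.frames[:, rr, cc].mean(axis=1)
    return IntensityTrace(values=values, fps=stack.fps)


def detrend(trace: IntensityTrace, window_s: float) -> IntensityTrace:
    """Subtract a running median; ``window_s = 0`` is the identity.

    Removes slow ICG washin/washout drift without displacing troughs, for
    traces too unsteady to count raw.
    """
    if window_s < 0:
        raise ValueError("window_s must be >= 0")
    if window_s == 0:
        return trace
    size = max(3, int(round(window_s * trace.fps)) | 1)  # odd
    baseline = median_filter(trace.values, size=size, mode="nearest")
    return IntensityTrace(values=trace.values - baseline, fps=trace.fps)


def detect_troughs(
    trace: IntensityTrace,
    prominence_fraction: float = 0.15,
    min_separation_s: float = 2.0,
    smooth_s: float = 1.0,
) -> TroughSet:
    """Interior local minima deep enough to count as contractions.

    A minimum counts when its prominence is at least
    ``prominence_fraction * (max - min)`` of the analyzed trace (absolute
    NIRF intensity is arbitrary, so the threshold is relative). Candidates
    closer together than ``min_separation_s`` are thinned keeping the
    deeper (lower) one; on equal depth the earlier. ``smooth_s`` is the
    sigma (seconds) of an optional Gaussian pre-smoothing — symmetric, so
    minima of noiseless periodic traces do not move; 0 disables it.
    Endpoints are never troughs (their prominence is undefined).
    """
    if not 0.0 <= prominence_fraction <= 1.0:
        raise ValueError("prominence_fraction must be in [0, 1]")
    if min_separation_s < 0:
        raise ValueError("min_separation_s must be >= 0")
    x = trace.values
    if x.size < 3:
        raise TraceTooShortError("need >= 3 frames to define a trough")
    if smooth_s > 0:
        x = gaussian_filter1d(x, smooth_s * trace.fps, mode="nearest")
    span = x.max() - x.min()
    if span == 0:
        return TroughSet(indices=np.empty(0, dtype=int))
    cand, _ = find_peaks(-x, prominence=prominence_fraction * span)
    if cand.size == 0:
        return TroughSet(indices=cand)
    min_gap = min_separation_s * trace.fps
    # greedy thinning: deepest first, earlier wins ties
    order = sorted(range(cand.size), key=lambda i: (x[cand[i]], cand[i]))
    kept: list[int] = []
    for i in order:
        if all(abs(cand[i] - k) >= min_gap for k in kept):
            kept.append(int(cand[i]))
    return TroughSet(indices=np.sort(kept))


def compute_rate(n_troughs: int, n_frames: int, fps: float) -> float:
    """Pumps per minute: ``n_troughs / (n_frames / (fps * 60))``."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if fps <= 0:
        raise ValueError("fps must be > 0")
    if n_troughs < 0:
        raise ValueError("n_troughs must be >= 0")
    return n_troughs * fps * 60.0 / n_frames


def rate_from_trace(
    trace: IntensityTrace,
    prominence_fraction: float = 0.15,
    min_separation_s: float = 2.0,
    smooth_s: float = 1.0,
    detrend_window_s: float = 0.0,
) -> PumpingRateResult:
    """Full single-trace pipeline: (optional detrend) -> troughs -> rate."""
    work = detrend(trace, detrend_window_s)
    troughs = detect_troughs(
        work,
        prominence_fraction=prominence_fraction,
        min_separation_s=min_separation_s,
        smooth_s=smooth_s,
    )
    rate = compute_rate(len(troughs), len(trace), trace.fps)
    return PumpingRateResult(
        n_troughs=len(troughs), n_frames=len(trace), fps=trace.fps, rate=rate
    )


#: Minimum session length (s) below which baseline_rate warns.
MIN_SESSION_S = 180.0


def baseline_rate(measurements: MeasurementSet) -> float:
    """Unweighted mean rate across sides and days (the baseline estimate)."""
    rates = []
    for m in measurements.entries:
        dur = m.result.n_frames / m.result.fps
        if dur < MIN_SESSION_S:
            warnings.warn(
                f"measurement {m.side}/{m.day} lasts {dur:.0f} s "
                f"(< {MIN_SESSION_S:.0f} s baseline convention)",
                stacklevel=2,
            )
        rates.append(m.result.rate)
    return float(np.mean(rates))
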