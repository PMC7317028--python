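"""Normalization and protocol segmentation of fluorescence traces.

The raw fluorescence level carries subject-specific nuisance (pigmentation,
optical coupling), so the signal is first divided by its mean over a central
resting window; all downstream statistics are computed on this unitless
normalized trace.  Segmentation then extracts half-open analysis windows:
rest, occlusion and reperfusion.  The reperfusion window is anchored, by
default, at the fluorescence minimum reached shortly after cuff release
(maximal hyperemia), located on a lightly smoothed copy of the signal so a
single noise spike cannot move the anchor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .trace_io import ProtocolMarks, RawTrace


class SegmentationError(ValueError):
    """Raised when a requested analysis window does not fit the trace."""


@dataclass(frozen=True)
class NormalizedTrace:
    """Unitless trace: intensity divided by its mean over a resting window."""

    times: np.ndarray
    values: np.ndarray
    norm_constant: float
    source: str
    sampling_rate: float
    marks: ProtocolMarks | None = None

    def __len__(self) -> int:
        return len(self.times)

    @property
    def start_s(self) -> float:
        return float(self.times[0])

    @property
    def end_s(self) -> float:
        """Half-open end of the trace (one step past the last sample)."""
        return float(self.times[-1]) + 1.0 / self.sampling_rate

    def index_of(self, t_s: float) -> int:
        """Nearest sample index of time ``t_s`` (grid arithmetic, not search)."""
        return int(round((t_s - self.start_s) * self.sampling_rate))


@dataclass(frozen=True)
class Segment:
    """A labeled half-open window ``[start_s, end_s)`` of a normalized trace."""

    label: str
    start_s: float
    end_s: float
    values: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise SegmentationError("segment end must exceed start")
        expected = int(round((self.end_s - self.start_s) * self.sampling_rate))
        if len(self.values) != expected:
            raise SegmentationError(
                f"segment sample count {len(self.values)} != expected {expected}")

    @property
    def times(self) -> np.ndarray:
        return self.start_s + np.arange(len(self.values)) / self.sampling_rate

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def __len__(self) -> int:
        return len(self.values)


def _slice(trace: NormalizedTrace, start_s: float, end_s: float) -> np.ndarray:
    i0 = trace.index_of(start_s)
    i1 = trace.index_of(end_s)
    if i0 < 0 or i1 > len(trace) or i1 <= i0:
        raise SegmentationError(
            f"window [{start_s}, {end_s}) outside trace [{trace.start_s}, {trace.end_s})")
    return trace.values[i0:i1]


def normalize_trace(raw: RawTrace,
                    window: tuple[float, float] = (60.0, 120.0)) -> NormalizedTrace:
    """Divide intensities by their mean over ``window`` (half-open, seconds).

    The window must lie inside the trace and contain at least 2 samples; the
    mean of the normalized values over the window is exactly 1 (up to float
    rounding).
    """
    start_s, end_s = window
    t0 = float(raw.times[0])
    i0 = int(round((start_s - t0) * raw.sampling_rate))
    i1 = int(round((end_s - t0) * raw.sampling_rate))
    if i0 < 0 or i1 > len(raw) or i1 - i0 < 2:
        raise SegmentationError(
            f"normalization window [{start_s}, {end_s}) invalid for a "
            f"{len(raw)}-sample trace starting at {t0} s")
    norm = float(np.mean(raw.intensities[i0:i1]))
    return NormalizedTrace(times=raw.times, values=raw.intensities / norm,
                           norm_constant=norm, source=raw.subject_id,
                           sampling_rate=raw.sampling_rate, marks=raw.marks)


def segment_rest(trace: NormalizedTrace,
                 discard_s: float = 60.0,
                 duration_s: float = 150.0,
                 matched_interval: bool = True) -> Segment:
    """Extract the resting-phase analysis window.

    Without protocol marks the window is ``[discard_s, discard_s+duration_s)``:
    the first 30-60 s are discarded while the subject settles.  When marks are
    present and ``matched_interval`` is on (the default), the window is the
    ``duration_s`` interval ending at occlusion start, so FM and FM(R) compare
    equal-length windows.
    """
    if trace.marks is not None and matched_interval:
        start = trace.marks.occlusion_start_s - duration_s
        if start < trace.start_s:
            raise SegmentationError(
                f"matched rest interval would start at {start} s, before the trace")
        if start < discard_s:
            warnings.warn(
                "matched rest interval begins inside the discard period",
                stacklevel=2)
    else:
        start = trace.start_s + discard_s
    end = start + duration_s
    if end > trace.end_s + 1e-9:
        raise SegmentationError(
            f"trace too short for rest window [{start}, {end})")
    return Segment(label="rest", start_s=start, end_s=end,
                   values=_slice(trace, start, end),
                   sampling_rate=trace.sampling_rate)


def segment_occlusion(trace: NormalizedTrace) -> Segment:
    """The full occlusion interval ``[occlusion_start, release)`` (QC segment)."""
    if trace.marks is None:
        raise SegmentationError("occlusion segment requires protocol marks")
    m = trace.marks
    return Segment(label="occlusion", start_s=m.occlusion_start_s,
                   end_s=m.release_s,
                   values=_slice(trace, m.occlusion_start_s, m.release_s),
                   sampling_rate=trace.sampling_rate)


def locate_hyperemia_minimum(trace: NormalizedTrace,
                             marks: ProtocolMarks,
                             search_s: float = 60.0,
                             smooth_s: float = 1.0) -> float:
    """Time of maximal hyperemia: the signal minimum after cuff release.

    Fluorescence falls sharply for ~20-30 s after release as reoxygenated
    blood floods the tissue; the minimum marks maximal hyperemia and anchors
    the reperfusion window.  The minimum is located on a ``smooth_s`` moving
    average so an isolated noise spike cannot win; ties break to the earliest
    time.  Smoothing affects localization only.
    """
    if search_s <= 0:
        raise SegmentationError("search_s must be positive")
    i0 = trace.index_of(marks.release_s)
    if i0 >= len(trace) - 1 or i0 < 0:
        raise SegmentationError("no samples after cuff release")
    i1 = min(len(trace), trace.index_of(marks.release_s + search_s))
    window = trace.values[i0:i1]
    if len(window) == 0:
        raise SegmentationError("empty hyperemia search window")
    k = max(1, int(round(smooth_s * trace.sampling_rate)))
    if k > 1 and len(window) >= k:
        kernel = np.ones(k) / k
        smoothed = np.convolve(window, kernel, mode="same")
        # edges of 'same' convolution are biased low; restrict to valid core
        half = k // 2
        core = smoothed[half:len(window) - half] if len(window) > k else smoothed
        offset = half if len(window) > k else 0
    else:
        core = window
        offset = 0
    idx = int(np.argmin(core)) + offset  # argmin takes the first minimum
    return float(trace.times[i0 + idx])


def segment_reperfusion(trace: NormalizedTrace,
                        start_s: float,
                        duration_s: float = 150.0,
                        allow_truncation: bool = False) -> Segment:
    """Extract the reperfusion analysis window ``[start_s, start_s+duration_s)``.

    In strict mode (default) the full duration must fit the trace; with
    ``allow_truncation`` a shorter segment is returned and a warning recorded.
    """
    end = start_s + duration_s
    if end > trace.end_s + 1e-9:
        if not allow_truncation:
            raise SegmentationError(
                f"only {trace.end_s - start_s:.1f} s remain after {start_s:.1f} s; "
                f"{duration_s} s requested")
        end = trace.end_s
        warnings.warn(
            f"reperfusion window truncated to {end - start_s:.1f} s",
            stacklevel=2)
    return Segment(label="reperfusion", start_s=start_s, end_s=end,
                   values=_slice(trace, start_s, end),
                   sampling_rate=trace.sampling_rate)
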