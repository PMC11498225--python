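"""Calcium-reporter trace normalization, onset detection and kymographs.

Traces from genetically encoded indicators (GCaMP) or dyes (Fluo-4) are
normalized to the mean fluorescence over a baseline window, F/F0.  Response
onset is the first sustained excursion above baseline noise; spatiotemporal
dynamics along a contact line are displayed as a kymograph (position x time).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "CalciumTrace",
    "Kymograph",
    "normalize_trace",
    "onset_frame",
    "kymograph",
]


@dataclass
class CalciumTrace:
    raw: np.ndarray
    normalized: np.ndarray
    baseline_window: tuple[int, int]

    @property
    def max_fold(self) -> float:
        """Peak of the normalized trace, the maximum fold change over baseline."""
        return float(np.max(self.normalized))

    @property
    def baseline_sd(self) -> float:
        a, b = self.baseline_window
        return float(np.std(self.normalized[a:b], ddof=1))


@dataclass
class Kymograph:
    data: np.ndarray                  # (n_positions, n_frames)
    start: tuple[float, float]        # (y, x) px
    end: tuple[float, float]
    width_px: int
    frame_interval_s: float
    pixel_size_um: float

    @property
    def n_positions(self) -> int:
        return self.data.shape[0]


def normalize_trace(
    trace: np.ndarray, baseline_window: tuple[int, int] | int
) -> CalciumTrace:
    """Divide a fluorescence trace by its baseline-window mean (F/F0).

    ``baseline_window`` is a ``(start, stop)`` frame slice or a single int n
    meaning the first n frames.  The window mean must be positive and span at
    least 2 frames.
    """
    trace = np.asarray(trace, dtype=float)
    if isinstance(baseline_window, int):
        baseline_window = (0, baseline_window)
    a, b = baseline_window
    if b - a < 2:
        raise ValueError("baseline window must span at least 2 frames")
    if b > len(trace):
        raise ValueError("baseline window exceeds trace length")
    f0 = trace[a:b].mean()
    if f0 <= 0:
        raise ValueError("baseline mean must be positive")
    return CalciumTrace(
        raw=trace, normalized=trace / f0, baseline_window=(a, b)
    )


def onset_frame(
    trace: CalciumTrace, k_sd: float = 3.0, sustain_frames: int = 2
) -> int | None:
    """First frame of a sustained rise above baseline noise, or None.

    The threshold is ``1 + k_sd * SD`` of the normalized baseline; the
    excursion must hold for ``sustain_frames`` consecutive frames, which
    rejects single-frame noise spikes.
    """
    sd = trace.baseline_sd
    thr = 1.0 + k_sd * sd
    above = trace.normalized > thr
    start = trace.baseline_window[1]
    run = 0
    for t in range(start, len(above)):
        run = run + 1 if above[t] else 0
        if run >= sustain_frames:
            return t - sustain_frames + 1
    return None


def kymograph(
    stack,
    start: tuple[float, float],
    end: tuple[float, float],
    width_px: int = 1,
    channel: int | str = 0,
) -> Kymograph:
    """Sample intensity along a line in every frame and stack over time.

    The line from ``start`` to ``end`` (both ``(y, x)`` in px) is sampled at
    ~1 px spacing with bilinear interpolation and averaged over ``width_px``
    parallel offsets perpendicular to the line.
    """
    y0, x0 = start
    y1, x1 = end
    length = float(np.hypot(y1 - y0, x1 - x0))
    if length < 1:
        raise ValueError("line must be at least 1 px long")
    frames = stack.channel(channel).astype(float)
    h, w = frames.shape[1:]
    for (yy, xx) in (start, end):
        if not (0 <= yy <= h - 1 and 0 <= xx <= w - 1):
            raise ValueError("line endpoints must lie inside the field")
    n = int(np.ceil(length)) + 1
    t_par = np.linspace(0.0, 1.0, n)
    ys = y0 + t_par * (y1 - y0)
    xs = x0 + t_par * (x1 - x0)
    # unit normal for width averaging
    ny_, nx_ = -(x1 - x0) / length, (y1 - y0) / length
    offsets = np.arange(width_px) - (width_px - 1) / 2.0
    data = np.zeros((n, frames.shape[0]))
    for t in range(frames.shape[0]):
        acc = np.zeros(n)
        for off in offsets:
            coords = np.vstack([ys + off * ny_, xs + off * nx_])
            acc += ndimage.map_coordinates(
                frames[t], coords, order=1, mode="nearest"
            )
        data[:, t] = acc / len(offsets)
    return Kymograph(
        data=data,
        start=start,
        end=end,
        width_px=width_px,
        frame_interval_s=stack.frame_interval_s,
        pixel_size_um=stack.pixel_size_um,
    )
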