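"""Micropattern (FLECS) contraction kinetics.

Single cells adhere to cross-shaped adhesive micropatterns on a soft
elastomer; cell contraction pulls the pattern inward, so the pattern's area
fraction relative to the first frame reports contractile force.  Contraction
is plotted as the inverse of the area fraction, and kinetics are summarised
by the maximum contraction reached within a fixed interval after stimulation
and by the ratio of the post-stimulus to baseline contraction-curve slope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure, segmentation

__all__ = [
    "PatternTrack",
    "ContractionCurve",
    "ContractionMetrics",
    "segment_patterns",
    "gate_occupancy",
    "contraction_curves",
    "contraction_metrics",
    "classify_acceleration",
    "window_slopes",
    "analyze_flecs",
]

#: default kinetic horizon after stimulation (90 min), in seconds
T_MAX_S = 90 * 60.0


@dataclass
class PatternTrack:
    pattern_id: int
    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int]          # (min_row, min_col, max_row, max_col)
    area_px0: float
    occupied: bool = False
    merged_suspect: bool = False


@dataclass
class ContractionCurve:
    """Per-pattern area-fraction time series and its inverse."""

    pattern_id: int
    time_s: np.ndarray
    area_px: np.ndarray
    stimulus_frame: int
    lost_frame: int | None = None            # first frame below the detachment cut

    @property
    def area_fraction(self) -> np.ndarray:
        return self.area_px / self.area_px[0]

    @property
    def contraction(self) -> np.ndarray:
        """Inverse of the area fraction; 1 at the first frame."""
        return 1.0 / self.area_fraction

    @property
    def n_frames(self) -> int:
        return len(self.area_px)


@dataclass
class ContractionMetrics:
    pattern_id: int
    max_contraction: float
    baseline_slope: float
    post_slope: float
    speed_ratio: float
    speed_ratio_defined: bool
    truncated: bool = False


# ---------------------------------------------------------------------------
# segmentation and occupancy gating
# ---------------------------------------------------------------------------

def _drop_small(binary: np.ndarray, min_area_px: int) -> np.ndarray:
    labels = measure.label(binary)
    if labels.max() == 0:
        return binary
    counts = np.bincount(labels.ravel())
    keep = np.flatnonzero(counts >= min_area_px)
    keep = keep[keep > 0]
    return np.isin(labels, keep)


def _threshold(img: np.ndarray, method: str = "otsu") -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.max() == img.min():
        return np.zeros(img.shape, dtype=bool)
    if method == "otsu":
        t = filters.threshold_otsu(img)
    elif method == "mean":
        t = img.mean()
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return img > t


def segment_patterns(
    stack,
    pattern_channel: int | str = 0,
    threshold_method: str = "otsu",
    min_area_px: int = 200,
    exclude_border: bool = True,
    merged_area_factor: float = 1.8,
) -> tuple[np.ndarray, list[PatternTrack]]:
    """Segment micropatterns on the first frame of the pattern channel.

    Connected components of the binarized frame above ``min_area_px`` become
    pattern ROIs.  Patterns touching the image border are dropped (truncated
    geometry biases the area readout).  Components much larger than the median
    pattern (``merged_area_factor`` times) are kept but flagged as suspected
    merges of touching patterns.

    Returns the frame-0 label map and one :class:`PatternTrack` per pattern.
    """
    frame0 = stack.channel(pattern_channel)[0]
    binary = _threshold(frame0, threshold_method)
    binary = _drop_small(binary, min_area_px)
    if exclude_border:
        binary = segmentation.clear_border(binary)
    labels = measure.label(binary)
    props = measure.regionprops(labels)
    if not props:
        warnings.warn("no patterns found in frame 0", stacklevel=2)
        return labels, []
    median_area = float(np.median([p.area for p in props]))
    tracks = []
    for p in props:
        tracks.append(
            PatternTrack(
                pattern_id=p.label,
                centroid=p.centroid,
                bbox=p.bbox,
                area_px0=float(p.area),
                merged_suspect=p.area > merged_area_factor * median_area,
            )
        )
    return labels, tracks


def gate_occupancy(
    labels: np.ndarray,
    tracks: list[PatternTrack],
    nuclear_frame: np.ndarray,
    threshold_method: str = "otsu",
    min_overlap_px: int = 5,
) -> list[PatternTrack]:
    """Mark each pattern occupied iff a nucleus overlaps its ROI.

    The nuclear frame is binarized and a pattern counts as occupied when at
    least ``min_overlap_px`` thresholded nuclear pixels fall inside its ROI —
    patterns without a cell cannot contract and are excluded downstream.
    """
    nuc = _threshold(nuclear_frame, threshold_method)
    for tr in tracks:
        overlap = int(np.count_nonzero(nuc & (labels == tr.pattern_id)))
        tr.occupied = overlap >= min_overlap_px
    return tracks


# ---------------------------------------------------------------------------
# per-pattern kinetics
# ---------------------------------------------------------------------------

def contraction_curves(
    stack,
    labels: np.ndarray,
    tracks: list[PatternTrack],
    stimulus_frame: int,
    pattern_channel: int | str = 0,
    threshold_method: str = "otsu",
    bbox_dilation_px: int = 10,
    min_area_fraction: float = 0.25,
    occupied_only: bool = True,
    upsample_factor: int = 4,
) -> list[ContractionCurve]:
    """Per-frame re-binarized pattern area inside a dilated frame-0 box.

    For every (occupied) pattern, each frame is bilinearly upsampled by
    ``upsample_factor`` within the pattern's dilated frame-0 bounding box and
    re-thresholded; upsampling before binarization shrinks the area quantum
    of the digitized boundary so that the slow per-frame area change is not
    swamped by pixel-staircase jumps.  Areas are reported in original-pixel
    units.  A track is truncated when the area falls below
    ``min_area_fraction`` of its initial value — the detachment regime where
    the cell pulls the pattern apart — and the loss frame is recorded.
    """
    if stimulus_frame >= stack.n_frames:
        raise ValueError("stimulus_frame beyond the end of the stack")
    frames = stack.channel(pattern_channel)
    h, w = frames.shape[1:]
    curves = []
    for tr in tracks:
        if occupied_only and not tr.occupied:
            continue
        r0, c0, r1, c1 = tr.bbox
        r0 = max(0, r0 - bbox_dilation_px)
        c0 = max(0, c0 - bbox_dilation_px)
        r1 = min(h, r1 + bbox_dilation_px)
        c1 = min(w, c1 + bbox_dilation_px)
        z = max(1, int(upsample_factor))
        roi_box = labels[r0:r1, c0:c1] == tr.pattern_id
        if z > 1:
            roi_box = ndimage.zoom(roi_box.astype(np.uint8), z, order=0) > 0
        areas = []
        lost = None
        for t in range(stack.n_frames):
            box = frames[t, r0:r1, c0:c1]
            if z > 1:
                box = ndimage.zoom(box, z, order=1)
            fg = _threshold(box, threshold_method)
            # keep only components overlapping the frame-0 ROI, so that tips
            # of neighbouring patterns entering the dilated box do not count
            comp = measure.label(fg)
            hit = np.unique(comp[roi_box & fg])
            hit = hit[hit > 0]
            area = float(np.isin(comp, hit).sum()) / z ** 2 if hit.size else 0.0
            if areas and area < min_area_fraction * areas[0]:
                lost = t
                break
            areas.append(area)
        areas = np.asarray(areas, dtype=float)
        if areas[0] <= 0:
            warnings.warn(
                f"pattern {tr.pattern_id}: empty initial binarization, skipped",
                stacklevel=2,
            )
            continue
        curves.append(
            ContractionCurve(
                pattern_id=tr.pattern_id,
                time_s=np.arange(len(areas)) * stack.frame_interval_s,
                area_px=areas,
                stimulus_frame=stimulus_frame,
                lost_frame=lost,
            )
        )
    return curves


def _ols_slope(t: np.ndarray, y: np.ndarray) -> float:
    ok = np.isfinite(y)
    if ok.sum() < 2:
        return np.nan
    t, y = t[ok], y[ok]
    return float(np.polyfit(t, y, 1)[0])


def window_slopes(
    time_s: np.ndarray,
    y: np.ndarray,
    stimulus_frame: int,
    post_window_frames: int | None = None,
) -> tuple[float, float]:
    """OLS slopes of ``y`` vs time over the baseline and post-stimulus windows.

    Baseline window: frames ``[0, stimulus_frame)``.  Post window: frames
    ``(stimulus_frame, stimulus_frame + post_window_frames]`` (to the end of
    the series when unspecified).
    """
    base = slice(0, stimulus_frame)
    end = len(y) if post_window_frames is None else min(
        len(y), stimulus_frame + 1 + post_window_frames
    )
    post = slice(stimulus_frame + 1, end)
    return _ols_slope(time_s[base], y[base]), _ols_slope(time_s[post], y[post])


def contraction_metrics(
    curve: ContractionCurve,
    frame_interval_s: float | None = None,
    t_max_s: float = T_MAX_S,
) -> ContractionMetrics:
    """Maximum contraction within ``t_max_s`` of stimulation and slope ratio.

    The speed ratio (post-stimulus slope over baseline slope of the
    contraction curve) is only defined for a positive baseline slope; a flat
    or negative baseline is flagged undefined rather than producing an
    unstable ratio.
    """
    if frame_interval_s is None:
        dt = float(curve.time_s[1] - curve.time_s[0]) if curve.n_frames > 1 else 1.0
    else:
        dt = frame_interval_s
    post_frames = int(round(t_max_s / dt))
    truncated = curve.lost_frame is not None or (
        curve.n_frames < curve.stimulus_frame + 1 + post_frames
    )
    c = curve.contraction
    b_slope, p_slope = window_slopes(
        curve.time_s, c, curve.stimulus_frame, post_frames
    )
    post = c[curve.stimulus_frame + 1:
             min(curve.n_frames, curve.stimulus_frame + 1 + post_frames)]
    max_c = float(post.max()) if post.size else np.nan
    # a baseline slope at the floating-point floor is flat, not positive
    slope_floor = 1e-9 * max(abs(p_slope) if np.isfinite(p_slope) else 0.0,
                             1e-30)
    defined = (np.isfinite(b_slope) and b_slope > slope_floor
               and np.isfinite(p_slope))
    return ContractionMetrics(
        pattern_id=curve.pattern_id,
        max_contraction=max_c,
        baseline_slope=b_slope,
        post_slope=p_slope,
        speed_ratio=p_slope / b_slope if defined else np.nan,
        speed_ratio_defined=bool(defined),
        truncated=truncated,
    )


def classify_acceleration(
    metrics: list[ContractionMetrics],
    control_metrics: list[ContractionMetrics],
) -> tuple[list[bool], float]:
    """Flag cells whose contraction accelerated beyond the control average.

    A cell counts as accelerated when its speed ratio exceeds the mean speed
    ratio of the control (cell-alone) group; returns per-cell flags and the
    percentage accelerated among cells with a defined ratio.
    """
    control = [m.speed_ratio for m in control_metrics if m.speed_ratio_defined]
    if not control:
        raise ValueError("control group has no defined speed ratios")
    thr = float(np.mean(control))
    flags = [
        bool(m.speed_ratio_defined and m.speed_ratio > thr) for m in metrics
    ]
    defined = [m for m in metrics if m.speed_ratio_defined]
    if not defined:
        return flags, np.nan
    pct = 100.0 * sum(
        1 for m in defined if m.speed_ratio > thr
    ) / len(defined)
    return flags, pct


# ---------------------------------------------------------------------------
# convenience pipeline
# ---------------------------------------------------------------------------

def analyze_flecs(
    stack,
    stimulus_frame: int,
    pattern_channel: int | str = 0,
    nuclear_channel: int | str = 1,
    threshold_method: str = "otsu",
    t_max_s: float = T_MAX_S,
    min_area_px: int = 200,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """End-to-end FLECS quantification of one stack.

    Returns a per-(pattern, frame) curve table and a per-pattern metrics
    table.
    """
    labels, tracks = segment_patterns(
        stack, pattern_channel, threshold_method, min_area_px=min_area_px
    )
    nuclear0 = stack.channel(nuclear_channel)[0]
    tracks = gate_occupancy(labels, tracks, nuclear0, threshold_method)
    curves = contraction_curves(
        stack, labels, tracks, stimulus_frame,
        pattern_channel, threshold_method,
    )
    rows = []
    for cv in curves:
        af = cv.area_fraction
        con = cv.contraction
        for i in range(cv.n_frames):
            rows.append(
                dict(
                    pattern_id=cv.pattern_id,
                    frame=i,
                    time_s=cv.time_s[i],
                    area_px=cv.area_px[i],
                    area_fraction=af[i],
                    contraction=con[i],
                )
            )
    curve_df = pd.DataFrame(
        rows,
        columns=["pattern_id", "frame", "time_s", "area_px",
                 "area_fraction", "contraction"],
    )
    metric_rows = []
    for cv in curves:
        m = contraction_metrics(cv, stack.frame_interval_s, t_max_s)
        metric_rows.append(
            dict(
                pattern_id=m.pattern_id,
                max_contraction=m.max_contraction,
                baseline_slope=m.baseline_slope,
                post_slope=m.post_slope,
                speed_ratio=m.speed_ratio,
                speed_ratio_defined=m.speed_ratio_defined,
                truncated=m.truncated,
            )
        )
    metrics_df = pd.DataFrame(
        metric_rows,
        columns=["pattern_id", "max_contraction", "baseline_slope",
                 "post_slope", "speed_ratio", "speed_ratio_defined",
                 "truncated"],
    )
    return curve_df, metrics_df
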