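"""Nuclear/cytoplasmic translocation quantification.

Mechanosensitive co-transcription factors (YAP, TAZ) and calcium effectors
(NFAT1, pSmad2/3) shuttle into the nucleus on activation.  The readout is the
ratio of mean marker fluorescence inside a DAPI-derived nuclear mask to that
in the remaining cytoplasm, optionally background-subtracted; for live
reporters, the nuclear MFI time course is normalized to the first frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters, measure, morphology

__all__ = [
    "TranslocationResult",
    "nuclear_mask",
    "cell_mask_from_marker",
    "compartment_mfi",
    "nuclear_timeseries",
]


@dataclass
class TranslocationResult:
    nuclear_mfi: float
    cytoplasmic_mfi: float
    ratio: float
    ratio_defined: bool
    clipped: bool = False
    cell_id: int = 0
    frame: int = 0


def nuclear_mask(
    dapi: np.ndarray,
    method: str = "otsu",
    min_size_px: int = 50,
) -> np.ndarray:
    """Labelled nuclei from a DAPI image: threshold, fill holes, size filter."""
    dapi = np.asarray(dapi, dtype=float)
    if dapi.size == 0:
        raise ValueError("empty raster")
    if dapi.max() == dapi.min():
        warnings.warn("blank nuclear image; empty mask", stacklevel=2)
        return np.zeros(dapi.shape, dtype=int)
    if method == "otsu":
        t = filters.threshold_otsu(dapi)
    elif method == "mean":
        t = dapi.mean()
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    binary = ndimage.binary_fill_holes(dapi > t)
    labels = measure.label(binary)
    if labels.max() > 0:
        counts = np.bincount(labels.ravel())
        keep = np.flatnonzero(counts >= min_size_px)
        binary = np.isin(labels, keep[keep > 0])
    if not binary.any():
        warnings.warn("no nuclei above the size filter", stacklevel=2)
    return measure.label(binary)


def cell_mask_from_marker(marker: np.ndarray) -> np.ndarray:
    """Whole-cell mask from a cytoskeletal (e.g. F-actin) channel.

    Otsu threshold, morphological closing, hole fill; the largest component
    is returned.
    """
    marker = np.asarray(marker, dtype=float)
    if marker.max() == marker.min():
        raise ValueError("blank image; cannot derive a cell mask")
    binary = marker > filters.threshold_otsu(marker)
    binary = morphology.binary_closing(binary, morphology.disk(3))
    binary = ndimage.binary_fill_holes(binary)
    labels = measure.label(binary)
    if labels.max() == 0:
        raise ValueError("no foreground component found")
    sizes = np.bincount(labels.ravel())[1:]
    return labels == (int(np.argmax(sizes)) + 1)


def estimate_background(marker: np.ndarray, cell_mask: np.ndarray) -> float:
    """Background level as the mode of intensities outside the cell mask."""
    outside = np.asarray(marker, dtype=float)[~np.asarray(cell_mask, bool)]
    if outside.size == 0:
        return 0.0
    hist, edges = np.histogram(outside, bins=64)
    i = int(np.argmax(hist))
    return float(0.5 * (edges[i] + edges[i + 1]))


def compartment_mfi(
    marker: np.ndarray,
    cell_mask: np.ndarray,
    nuc_mask: np.ndarray,
    background: float | None = None,
    cell_id: int = 0,
    frame: int = 0,
) -> TranslocationResult:
    """Nuclear and cytoplasmic mean fluorescence and their ratio.

    The nuclear mask is intersected with the cell mask; the cytoplasm is the
    cell minus the nucleus.  When ``background`` is None it is estimated as
    the intensity mode outside the cell.  Background-subtracted means that
    come out negative are clipped to 0 and flagged.
    """
    marker = np.asarray(marker, dtype=float)
    cell = np.asarray(cell_mask, bool)
    nuc = np.asarray(nuc_mask, bool) & cell
    cyto = cell & ~nuc
    if not nuc.any():
        raise ValueError("nuclear mask does not overlap the cell mask")
    if background is None:
        background = estimate_background(marker, cell)
    clipped = False
    nuclear = float(marker[nuc].mean()) - background
    if nuclear < 0:
        nuclear, clipped = 0.0, True
    if cyto.any():
        cytoplasmic = float(marker[cyto].mean()) - background
        if cytoplasmic < 0:
            cytoplasmic, clipped = 0.0, True
    else:
        cytoplasmic = np.nan
    defined = np.isfinite(cytoplasmic) and cytoplasmic > 0
    return TranslocationResult(
        nuclear_mfi=nuclear,
        cytoplasmic_mfi=cytoplasmic,
        ratio=nuclear / cytoplasmic if defined else np.nan,
        ratio_defined=bool(defined),
        clipped=clipped,
        cell_id=cell_id,
        frame=frame,
    )


def nuclear_timeseries(
    stack,
    marker_channel: int | str = 0,
    nuclear_channel: int | str = 1,
    method: str = "otsu",
    min_size_px: int = 50,
    max_jump_px: float = 30.0,
) -> tuple[np.ndarray, bool]:
    """Frame-0-normalized nuclear marker MFI over time for one tracked nucleus.

    The nucleus is segmented per frame and linked by nearest centroid; if it
    leaves the field (or the jump exceeds ``max_jump_px``) the series is
    truncated and flagged.

    Returns ``(series, truncated)`` where ``series[t]`` is nuclear MFI at
    frame t divided by that at frame 0.
    """
    if stack.n_frames < 2:
        raise ValueError("need at least 2 frames")
    marker = stack.channel(marker_channel)
    dapi = stack.channel(nuclear_channel)
    values = []
    prev_centroid = None
    truncated = False
    for t in range(stack.n_frames):
        labels = nuclear_mask(dapi[t], method, min_size_px)
        props = measure.regionprops(labels)
        if not props:
            truncated = True
            break
        if prev_centroid is None:
            props.sort(key=lambda p: p.area, reverse=True)
            chosen = props[0]
        else:
            dists = [
                np.hypot(p.centroid[0] - prev_centroid[0],
                         p.centroid[1] - prev_centroid[1])
                for p in props
            ]
            j = int(np.argmin(dists))
            if dists[j] > max_jump_px:
                truncated = True
                break
            chosen = props[j]
        prev_centroid = chosen.centroid
        values.append(float(marker[t][labels == chosen.label].mean()))
    if truncated:
        warnings.warn(
            f"nucleus lost at frame {len(values)}; series truncated",
            stacklevel=2,
        )
    series = np.asarray(values)
    if series.size == 0 or series[0] <= 0:
        raise ValueError("no measurable nucleus at frame 0")
    return series / series[0], truncated
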