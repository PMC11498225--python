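"""Image-stack I/O, run configuration, result tables and rigid registration.

All imaging stages of the pipeline exchange data through :class:`ImageStack`,
a thin container around a 4-D ``(time, channel, y, x)`` array with physical
calibration attached.  Calibration (``pixel_size_um``, ``frame_interval_s``)
is always supplied by the caller, never read from TIFF tags, so that runs are
deterministic across TIFF dialects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy import ndimage
from skimage.registration import phase_cross_correlation

__all__ = [
    "ImageStack",
    "AnalysisConfig",
    "ResultTable",
    "read_stack",
    "write_stack",
    "register_translation",
]


@dataclass
class ImageStack:
    """Time-lapse multi-channel raster with physical calibration.

    Axis order is fixed as ``(time, channel, y, x)``; y increases downward and
    pixel indices are 0-based.

    Parameters
    ----------
    frames
        4-D intensity array, shape ``(n_frames, n_channels, height, width)``.
    pixel_size_um
        Lateral calibration in micrometres per pixel, strictly positive.
    frame_interval_s
        Acquisition interval in seconds, strictly positive.
    channel_names
        One label per channel; defaults to ``ch0..chN``.
    """

    frames: np.ndarray
    pixel_size_um: float
    frame_interval_s: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim == 2:
            self.frames = self.frames[np.newaxis, np.newaxis]
        elif self.frames.ndim == 3:
            self.frames = self.frames[:, np.newaxis]
        if self.frames.ndim != 4:
            raise ValueError(
                f"frames must be 4-D (time, channel, y, x); got {self.frames.ndim}-D"
            )
        if not (self.pixel_size_um > 0):
            raise ValueError("pixel_size_um must be strictly positive")
        if not (self.frame_interval_s > 0):
            raise ValueError("frame_interval_s must be strictly positive")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.frames.shape[1])]
        if len(self.channel_names) != self.frames.shape[1]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.frames.shape[1]} channels"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_channels(self) -> int:
        return self.frames.shape[1]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.frames.shape

    def channel_index(self, channel: int | str) -> int:
        """Resolve a channel given by index or by name."""
        if isinstance(channel, str):
            try:
                return self.channel_names.index(channel)
            except ValueError:
                raise KeyError(
                    f"channel {channel!r} not in {self.channel_names}"
                ) from None
        if not 0 <= channel < self.n_channels:
            raise IndexError(f"channel index {channel} out of range")
        return int(channel)

    def channel(self, channel: int | str) -> np.ndarray:
        """Return the ``(time, y, x)`` sub-stack of one channel."""
        return self.frames[:, self.channel_index(channel)]

    @property
    def time_s(self) -> np.ndarray:
        """Frame acquisition times in seconds, starting at 0."""
        return np.arange(self.n_frames) * self.frame_interval_s


@dataclass
class AnalysisConfig:
    """Run-level constants shared across pipeline stages.

    ``stimulus_frame`` is the frame at which the perturbing agent (macrophages,
    control medium or a compound) is added; frames before it form the baseline
    window used for slope normalisation and trace normalisation.
    """

    baseline_window_frames: int = 15
    stimulus_frame: int = 15
    threshold_method: str = "otsu"
    piv_window_px: int = 32
    piv_step_px: int = 16
    min_corr: float = 0.3
    substrate_E_pa: float = 200.0
    substrate_nu: float = 0.5
    regularization_lambda: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_window_frames < 2:
            raise ValueError("baseline_window_frames must be >= 2")
        if self.stimulus_frame < self.baseline_window_frames:
            raise ValueError("stimulus_frame must be >= baseline_window_frames")
        if not (0 < self.substrate_nu <= 0.5):
            raise ValueError("substrate_nu must be in (0, 0.5]")
        if self.regularization_lambda < 0:
            raise ValueError("regularization_lambda must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)

    def replace(self, **kwargs) -> "AnalysisConfig":
        return replace(self, **kwargs)


class ResultTable:
    """Long-format table of per-entity metric values.

    Rows carry ``(entity_id, condition, metric_name, value, units)``.  A given
    ``(entity_id, metric_name)`` pair may appear at most once per run.
    """

    COLUMNS = ["entity_id", "condition", "metric_name", "value", "units"]

    def __init__(self) -> None:
        self._rows: list[dict] = []
        self._seen: set[tuple] = set()

    def add(self, entity_id, condition, metric_name, value, units="") -> None:
        key = (entity_id, metric_name)
        if key in self._seen:
            raise ValueError(f"duplicate (entity_id, metric_name) pair {key}")
        self._seen.add(key)
        self._rows.append(
            dict(
                entity_id=entity_id,
                condition=condition,
                metric_name=metric_name,
                value=value,
                units=units,
            )
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self._rows, columns=self.COLUMNS)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self._rows)


def read_stack(path, pixel_size_um: float, frame_interval_s: float,
               channel_names: list[str] | None = None) -> ImageStack:
    """Read a multi-page TIFF into an :class:`ImageStack`.

    2-D files become a single frame, 3-D files are interpreted as
    ``(time, y, x)`` with one channel, and 4-D files as
    ``(time, channel, y, x)``.
    """
    try:
        frames = tifffile.imread(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read TIFF stack {path!r}: {exc}") from exc
    return ImageStack(
        frames=frames,
        pixel_size_um=pixel_size_um,
        frame_interval_s=frame_interval_s,
        channel_names=list(channel_names) if channel_names else [],
    )


def write_stack(stack: ImageStack, path) -> None:
    """Write the stack as a plain multi-page TIFF (no calibration tags)."""
    tifffile.imwrite(path, stack.frames)


def register_translation(
    stack: ImageStack,
    reference_frame: int = 0,
    channel: int | str = 0,
    upsample_factor: int = 20,
) -> tuple[ImageStack, np.ndarray]:
    """Align every frame to a reference frame by translation only.

    Shifts are estimated by phase correlation with sub-pixel refinement on one
    channel and applied to all channels; intensities shifted outside the field
    are filled with 0.

    Returns
    -------
    registered : ImageStack
    shifts : ndarray, shape (n_frames, 2)
        Per-frame ``(dy, dx)`` displacement of the frame content relative to
        the reference, in pixels (the applied correction is its negation).
    """
    if stack.n_frames < 2:
        raise ValueError("registration needs at least 2 frames")
    ci = stack.channel_index(channel)
    ref = stack.frames[reference_frame, ci].astype(float)
    out = np.empty_like(stack.frames, dtype=float)
    shifts = np.zeros((stack.n_frames, 2))
    for t in range(stack.n_frames):
        frame = stack.frames[t, ci].astype(float)
        if t == reference_frame or not np.any(frame != frame.flat[0]):
            if t != reference_frame:
                warnings.warn(
                    f"frame {t} is constant; registration shift set to (0, 0)",
                    stacklevel=2,
                )
            shift = np.zeros(2)
        else:
            # plain (non-whitened) correlation: robust for smooth microscopy
            # images where phase whitening amplifies noise
            shift, _, _ = phase_cross_correlation(
                ref, frame, upsample_factor=upsample_factor,
                normalization=None,
            )
        shifts[t] = -shift
        for c in range(stack.n_channels):
            out[t, c] = ndimage.shift(
                stack.frames[t, c].astype(float), shift, order=1, cval=0.0
            )
    registered = ImageStack(
        frames=out,
        pixel_size_um=stack.pixel_size_um,
        frame_interval_s=stack.frame_interval_s,
        channel_names=list(stack.channel_names),
    )
    return registered, shifts
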