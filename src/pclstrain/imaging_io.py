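"""Calibrated image-sequence loading, contrast stretching and tissue masking.

Frames are held as float arrays on a common [0, 1] intensity scale; spatial
calibration (μm per pixel) and temporal calibration (seconds per frame)
travel with the sequence.  Coordinate convention throughout the package:
0-based pixel indices, origin at the top-left, x rightward along columns,
y downward along rows, pixel centers at integer coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import tifffile
from scipy import ndimage
from skimage import filters, morphology

__all__ = ["FrameSequence", "load_sequence", "stretch_contrast", "tissue_mask"]


@dataclass
class FrameSequence:
    """A calibrated grayscale time-lapse.

    Parameters
    ----------
    frames : list of 2-D float arrays
        Intensities in [0, 1]; all frames share one shape.
    times : array of float
        Acquisition time of each frame in seconds, strictly increasing.
    pixel_size : float
        Micrometres per pixel.
    reference_index : int
        Index of the undeformed reference frame (t0).
    """

    frames: list[np.ndarray]
    times: np.ndarray
    pixel_size: float
    reference_index: int = 0

    def __post_init__(self) -> None:
        if len(self.frames) < 2:
            raise ValueError("a sequence needs at least 2 frames")
        shape = self.frames[0].shape
        for i, f in enumerate(self.frames):
            if f.ndim != 2:
                raise ValueError(f"frame {i} is not 2-D (shape {f.shape})")
            if f.shape != shape:
                raise ValueError(
                    f"frame {i} has shape {f.shape}, expected {shape}"
                )
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.frames):
            raise ValueError("times and frames must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive (um/px)")
        if not (0 <= self.reference_index < len(self.frames)):
            raise IndexError(
                f"reference_index {self.reference_index} out of range"
            )

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape

    @property
    def reference(self) -> np.ndarray:
        return self.frames[self.reference_index]


def _to_gray01(arr: np.ndarray) -> np.ndarray:
    """Convert one raw frame to float grayscale; integer dtypes are scaled
    by their full range, floats are assumed already on a [0, 1]-like scale.
    RGB(A) is reduced by channel average (luminance)."""
    arr = np.asarray(arr)
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=-1)
    if arr.ndim != 2:
        raise ValueError(f"cannot interpret frame of shape {arr.shape}")
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        return arr.astype(float) / info.max
    out = arr.astype(float)
    m = out.max()
    if m > 1.0:
        out = out / m
    return out


def load_sequence(
    source: str | Path | Sequence[str | Path],
    pixel_size: float,
    frame_interval: float,
    reference_index: int = 0,
) -> FrameSequence:
    """Load a movie from a multipage TIFF or an ordered list of image files.

    For a list of files, lexicographic order of the given paths is the
    temporal order.  Timestamps are ``frame_interval * index`` seconds.
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        if not path.exists():
            raise IOError(f"cannot read {path}: no such file")
        if path.suffix.lower() in (".tif", ".tiff"):
            raw = tifffile.imread(path)
            if raw.ndim == 2:
                raw = raw[None]
            frames = [_to_gray01(p) for p in raw]
        else:
            raw = iio.imread(path)
            if raw.ndim == 2:
                raw = raw[None]
            frames = [_to_gray01(p) for p in raw]
    else:
        paths = sorted(Path(p) for p in source)
        frames = []
        for p in paths:
            if not p.exists():
                raise IOError(f"cannot read {p}: no such file")
            frames.append(_to_gray01(iio.imread(p)))
    if len(frames) < 2:
        raise ValueError(f"need at least 2 frames, got {len(frames)}")
    times = frame_interval * np.arange(len(frames), dtype=float)
    return FrameSequence(
        frames=frames,
        times=times,
        pixel_size=pixel_size,
        reference_index=reference_index,
    )


def stretch_contrast(
    frame: np.ndarray, p_low: float = 2.0, p_high: float = 98.0
) -> np.ndarray:
    """Linearly rescale so the ``p_low`` percentile maps to 0 and ``p_high``
    to 1, clipping outside [0, 1].  Monotone in the input intensity.

    A constant frame (zero percentile span) returns all zeros with a
    warning rather than raising.
    """
    if not (0 <= p_low < p_high <= 100):
        raise ValueError(f"need 0 <= p_low < p_high <= 100, got ({p_low}, {p_high})")
    lo, hi = np.percentile(frame, [p_low, p_high])
    if hi - lo <= 0:
        warnings.warn("constant frame: contrast stretch has zero span, returning zeros")
        return np.zeros_like(np.asarray(frame, dtype=float))
    return np.clip((np.asarray(frame, dtype=float) - lo) / (hi - lo), 0.0, 1.0)


def tissue_mask(
    frame: np.ndarray,
    window: int = 7,
    smooth_sigma: float = 2.0,
    min_object_px: int = 100,
    max_hole_px: int = 50,
) -> np.ndarray:
    """Binary mask of textured tissue.

    Tissue (alveolar walls, septa) is speckle-textured while the lumen and
    agarose-filled voids are smooth, so intensity alone cannot separate
    them but local variance can.  The local variance over a ``window``-px
    neighborhood is smoothed and thresholded by Otsu's criterion; speckle
    components below ``min_object_px`` are dropped and holes below
    ``max_hole_px`` filled.  Thresholding on variance with Otsu makes the
    mask invariant to a global intensity rescaling of the frame.
    """
    f = np.asarray(frame, dtype=float)
    mean = ndimage.uniform_filter(f, window)
    var = ndimage.uniform_filter(f * f, window) - mean * mean
    var = np.maximum(ndimage.gaussian_filter(var, smooth_sigma), 0.0)

    if var.max() < 1e-7:                       # featureless frame
        return np.zeros_like(var, dtype=bool)
    # Otsu on log-variance: lumen/agarose variance sits orders of magnitude
    # below tissue speckle, while the tissue mode itself is broad enough
    # that Otsu on linear variance can split it instead.
    logvar = np.log10(var + 1e-12)
    t = filters.threshold_otsu(logvar)
    mask = logvar > t
    # Otsu always splits; if the two classes differ by less than ~4x in
    # median variance the frame is texture throughout -> full mask.
    lo_med = np.median(var[~mask]) if np.any(~mask) else 0.0
    hi_med = np.median(var[mask]) if np.any(mask) else np.inf
    if lo_med > 0.25 * hi_med:
        mask = var > 1e-7
    mask = morphology.remove_small_objects(mask, max_size=min_object_px)
    mask = morphology.remove_small_holes(mask, max_size=max_hole_px)
    return mask
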