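"""Airway lumen segmentation, ellipse fitting, and the caliber time series.

The lumen appears as a large, bright, *smooth* region enclosed by textured
tissue.  Two candidate segmentations are computed per frame — global
intensity thresholding and region growing from a seed — and the one whose
boundary sits on the sharper intensity edge wins.  Lumen area versus time
is the classic airway-caliber readout that strain mapping extends.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure, morphology, segmentation

from .imaging_io import FrameSequence

__all__ = [
    "SegmentationError",
    "LumenEllipse",
    "segment_lumen",
    "fit_ellipse",
    "lumen_area_series",
]


class SegmentationError(RuntimeError):
    """Raised when no plausible lumen region can be found."""


@dataclass
class LumenEllipse:
    """Least-squares ellipse fitted to the lumen boundary (px units)."""

    cx: float
    cy: float
    a: float            # semi-major axis
    b: float            # semi-minor axis
    theta: float        # major-axis angle, radians, CCW from +x

    @property
    def center(self) -> tuple[float, float]:
        return (self.cx, self.cy)

    @property
    def area_px(self) -> float:
        return np.pi * self.a * self.b

    def boundary_point(self, phi: float | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Point on the ellipse in the direction of polar angle ``phi``
        from the center (ray-ellipse intersection)."""
        phi = np.asarray(phi, dtype=float)
        pr = phi - self.theta
        r = (self.a * self.b) / np.sqrt(
            (self.b * np.cos(pr)) ** 2 + (self.a * np.sin(pr)) ** 2
        )
        return self.cx + r * np.cos(phi), self.cy + r * np.sin(phi)

    def outward_normal(self, phi: float | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Unit outward normal at the boundary point in direction ``phi``."""
        phi = np.asarray(phi, dtype=float)
        pr = phi - self.theta
        # ellipse param t at the ray intersection: tan t = (a/b) tan(pr)
        t = np.arctan2(self.a * np.sin(pr), self.b * np.cos(pr))
        nx_e = self.b * np.cos(t)
        ny_e = self.a * np.sin(t)
        nx = nx_e * np.cos(self.theta) - ny_e * np.sin(self.theta)
        ny = nx_e * np.sin(self.theta) + ny_e * np.cos(self.theta)
        n = np.hypot(nx, ny)
        return nx / n, ny / n


def _clean(mask: np.ndarray) -> np.ndarray:
    """Closing + hole fill + largest connected component."""
    if not mask.any():
        return mask
    mask = morphology.closing(mask, morphology.disk(3))
    mask = ndimage.binary_fill_holes(mask)
    lab = measure.label(mask)
    if lab.max() == 0:
        return np.zeros_like(mask)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    return lab == sizes.argmax()


def _candidate_threshold(smooth: np.ndarray, seed: tuple[int, int]) -> np.ndarray:
    t = filters.threshold_otsu(smooth)
    bright = smooth > t
    bright = _clean(bright)
    return bright


def _candidate_flood(smooth: np.ndarray, seed: tuple[int, int]) -> np.ndarray:
    span = float(smooth.max() - smooth.min())
    if span <= 0:
        return np.zeros_like(smooth, dtype=bool)
    grown = segmentation.flood(smooth, (seed[1], seed[0]), tolerance=0.2 * span)
    return _clean(grown)


def _refine_half_height(smooth: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Re-threshold at the half-height between the lumen interior level and
    the surrounding tissue level.  The two candidate segmentations place
    the boundary at slightly different intensities; anchoring it at the
    half-height of the edge makes the boundary consistent across frames,
    which matters when ratios of areas over time are the readout."""
    interior = morphology.erosion(mask, morphology.disk(3))
    ring = morphology.dilation(mask, morphology.disk(7)) & ~mask
    if not interior.any() or not ring.any():
        return mask
    lum = float(np.median(smooth[interior]))
    bg = float(np.median(smooth[ring]))
    if lum <= bg:
        return mask
    refined = _clean(smooth > 0.5 * (lum + bg))
    # accept only if it is recognisably the same region
    if (refined & mask).sum() < 0.5 * mask.sum():
        return mask
    return refined


def _boundary_sharpness(frame_smooth: np.ndarray, mask: np.ndarray) -> float:
    boundary = mask ^ morphology.erosion(mask)
    if not boundary.any():
        return -np.inf
    grad = filters.sobel(frame_smooth)
    return float(grad[boundary].mean())


def segment_lumen(
    frame: np.ndarray,
    seed_hint: tuple[int, int] | None = None,
    min_area_px: int = 200,
    smooth_sigma: float = 2.0,
) -> np.ndarray:
    """Binary lumen mask (single connected component).

    Two candidates are produced — Otsu thresholding of the smoothed frame,
    and flood-fill region growing from ``seed_hint`` (default: the frame
    center) — and the candidate with the sharper boundary (higher mean
    Sobel gradient along its contour) is returned; ties go to the larger
    region.  A candidate must be large enough and have a smooth interior
    (its intensity variance well below the whole-frame variance); a frame
    of pure speckle with no lumen therefore raises
    :class:`SegmentationError`.
    """
    f = np.asarray(frame, dtype=float)
    h, w = f.shape
    if seed_hint is None:
        seed_hint = (w // 2, h // 2)
    smooth = ndimage.gaussian_filter(f, smooth_sigma)
    frame_var = float(np.var(f))

    candidates = []
    for builder in (_candidate_threshold, _candidate_flood):
        m = builder(smooth, seed_hint)
        if m.sum() < min_area_px:
            continue
        interior = morphology.erosion(m, morphology.disk(3))
        if interior.sum() < min_area_px // 2:
            continue
        if frame_var > 0 and float(np.var(f[interior])) > 0.3 * frame_var:
            continue                     # textured interior: not a lumen
        candidates.append(m)
    if not candidates:
        raise SegmentationError(
            "no plausible lumen region: no large, smooth-interior bright "
            f"component found (min_area_px={min_area_px})"
        )
    scored = [(_boundary_sharpness(smooth, m), int(m.sum()), i, m)
              for i, m in enumerate(candidates)]
    scored.sort(key=lambda s: (s[0], s[1]))
    return _refine_half_height(smooth, scored[-1][3])


def fit_ellipse(mask: np.ndarray) -> LumenEllipse:
    """Least-squares ellipse through the boundary pixels of ``mask``."""
    if not np.any(mask):
        raise ValueError("cannot fit an ellipse to an empty mask")
    boundary = mask ^ morphology.erosion(mask)
    ys, xs = np.nonzero(boundary)
    if len(xs) < 5:
        raise ValueError(f"need >= 5 boundary pixels, got {len(xs)}")
    model = measure.EllipseModel.from_estimate(
        np.column_stack([xs, ys]).astype(float)
    )
    if not model:
        raise ValueError(f"ellipse fit did not converge: {model}")
    (cx, cy), (a, b), theta = model.center, model.axis_lengths, model.theta
    if b > a:                           # normalize: a = semi-major
        a, b = b, a
        theta += np.pi / 2
    theta = (theta + np.pi / 2) % np.pi - np.pi / 2
    return LumenEllipse(cx=cx, cy=cy, a=a, b=b, theta=theta)


def lumen_area_series(
    sequence: FrameSequence,
    fit_ellipses: bool = True,
    max_failure_fraction: float = 0.2,
) -> pd.DataFrame:
    """Per-frame lumen area in μm² (pixel count × pixel_size²).

    Segmentation of each frame is seeded with the previous frame's mask
    centroid (temporal coherence).  Isolated failures are interpolated
    with a warning; more than ``max_failure_fraction`` failing frames is
    an error.
    """
    ps = sequence.pixel_size
    rows = []
    seed = None
    n_fail = 0
    for i, frame in enumerate(sequence.frames):
        try:
            m = segment_lumen(frame, seed_hint=seed)
            cy, cx = ndimage.center_of_mass(m)
            seed = (int(round(cx)), int(round(cy)))
            area = float(m.sum()) * ps * ps
            ell = fit_ellipse(m) if fit_ellipses else None
        except (SegmentationError, ValueError) as exc:
            n_fail += 1
            warnings.warn(f"frame {i}: lumen segmentation failed ({exc}); interpolating")
            area, ell = np.nan, None
        rows.append({
            "time_s": sequence.times[i],
            "area_um2": area,
            "ellipse_cx_px": ell.cx if ell else np.nan,
            "ellipse_cy_px": ell.cy if ell else np.nan,
            "ellipse_a_px": ell.a if ell else np.nan,
            "ellipse_b_px": ell.b if ell else np.nan,
            "ellipse_theta_rad": ell.theta if ell else np.nan,
        })
    if n_fail > max_failure_fraction * len(sequence):
        raise SegmentationError(
            f"{n_fail}/{len(sequence)} frames failed lumen segmentation"
        )
    df = pd.DataFrame(rows)
    df["area_um2"] = df["area_um2"].interpolate(limit_direction="both")
    return df
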