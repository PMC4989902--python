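"""Spokes analysis: displacement and strain sampled along rays normal to
the lumen, averaged within angular sections.

The area around the airway is split into angular sections (default 8,
45 degrees each); within each section several rays (default 7) radiate
outward from the fitted lumen ellipse along its outward normal.  Sampling
displacement at continuous positions uses bilinear interpolation of the
four surrounding pixels; strain at a sample point is built from four
interpolated displacements at offsets of +-h px in x and y (the same
central-difference stencil as the dense strain maps).  Averaging over a
section's rays at each radial position gives a mean profile with a
variability estimate, which is what exposes directional heterogeneity —
a neighboring vessel or airway in one section bends that section's
profile away from the others.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .flow import DisplacementField
from .lumen import LumenEllipse
from .strain_core import _principal_arrays

__all__ = [
    "SpokeSet",
    "build_spokes",
    "bilinear_sample",
    "spoke_displacement_profile",
    "spoke_strain_profile",
]


@dataclass
class SpokeSet:
    """Sample geometry: points[s, j, k] is sample k of ray j in section s."""

    points: np.ndarray           # (n_sections, n_spokes, n_samples, 2) px, (x, y)
    directions: np.ndarray       # (n_sections, n_spokes, 2) unit outward ray dir
    valid: np.ndarray            # (n_sections, n_spokes, n_samples) in-frame flag
    distances: np.ndarray        # (n_samples,) um from the lumen boundary
    radial_step: float           # um
    n_sections: int
    n_spokes: int
    pixel_size: float

    @property
    def n_samples(self) -> int:
        return self.points.shape[2]


def build_spokes(
    ellipse: LumenEllipse,
    frame_shape: tuple[int, int],
    pixel_size: float,
    n_sections: int = 8,
    n_spokes: int = 7,
    radial_step: float = 8.05,       # um; 7 px at 1.15 um/px
    max_length: float = 400.0,       # um
) -> SpokeSet:
    """Rays normal to the lumen ellipse at angularly equispaced boundary
    points; the rays of a section are equispaced within its angular span.
    Sample points outside the frame are flagged invalid (truncated)."""
    if radial_step <= 0 or max_length <= 0 or n_sections < 1 or n_spokes < 1:
        raise ValueError("spoke parameters must be positive")
    H, W = frame_shape
    if not (0 <= ellipse.cx < W and 0 <= ellipse.cy < H):
        raise ValueError("lumen ellipse center outside the frame")

    span = 2 * np.pi / n_sections
    phis = np.empty((n_sections, n_spokes))
    for s in range(n_sections):
        phis[s] = s * span + (np.arange(n_spokes) + 0.5) / n_spokes * span
    bx, by = ellipse.boundary_point(phis)
    nx, ny = ellipse.outward_normal(phis)

    n_samples = int(np.floor(max_length / radial_step)) + 1
    step_px = radial_step / pixel_size
    k = np.arange(n_samples)
    px = bx[..., None] + nx[..., None] * k * step_px
    py = by[..., None] + ny[..., None] * k * step_px
    valid = (px >= 0) & (px <= W - 1) & (py >= 0) & (py <= H - 1)
    if not valid[..., 0].any():
        raise ValueError("every spoke origin lies outside the frame")
    return SpokeSet(
        points=np.stack([px, py], axis=-1),
        directions=np.stack([nx, ny], axis=-1),
        valid=valid,
        distances=k * radial_step,
        radial_step=radial_step,
        n_sections=n_sections,
        n_spokes=n_spokes,
        pixel_size=pixel_size,
    )


def bilinear_sample(
    field: DisplacementField, x: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Displacement (u, v) at continuous positions by bilinear weighting of
    the four surrounding pixels.  Positions outside the frame raise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    H, W = field.shape
    if np.any(x < 0) or np.any(x > W - 1) or np.any(y < 0) or np.any(y > H - 1):
        raise ValueError("sample point outside the displacement field domain")
    x0 = np.minimum(np.floor(x).astype(int), W - 2)
    y0 = np.minimum(np.floor(y).astype(int), H - 2)
    fx, fy = x - x0, y - y0
    w00 = (1 - fx) * (1 - fy)
    w10 = fx * (1 - fy)
    w01 = (1 - fx) * fy
    w11 = fx * fy

    def interp(a):
        return (w00 * a[y0, x0] + w10 * a[y0, x0 + 1]
                + w01 * a[y0 + 1, x0] + w11 * a[y0 + 1, x0 + 1])

    return interp(field.u), interp(field.v)


def _masked_mean_sd(values: np.ndarray, valid: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean/SD over axis 1 (rays) honoring a validity mask."""
    n = valid.sum(axis=1)
    vals = np.where(valid, values, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n > 0, vals.sum(axis=1) / np.maximum(n, 1), np.nan)
        var = np.where(
            n > 0,
            np.where(valid, (values - mean[:, None, :]) ** 2, 0.0).sum(axis=1)
            / np.maximum(n, 1),
            np.nan,
        )
    return mean, np.sqrt(var), n


def spoke_displacement_profile(
    field: DisplacementField, spokes: SpokeSet
) -> pd.DataFrame:
    """Per-section mean inward radial displacement (μm) vs. distance.

    The displacement at each sample point is projected onto the inward ray
    direction (positive = toward the lumen); mean and standard deviation
    are taken over the section's rays at each radial position.
    """
    px = spokes.points[..., 0]
    py = spokes.points[..., 1]
    u, v = bilinear_sample(field, np.clip(px, 0, field.shape[1] - 1),
                           np.clip(py, 0, field.shape[0] - 1))
    inward = -(u * spokes.directions[..., 0:1] + v * spokes.directions[..., 1:2])
    inward_um = inward * field.pixel_size
    mean, sd, n = _masked_mean_sd(inward_um, spokes.valid)
    S, K = spokes.n_sections, spokes.n_samples
    return pd.DataFrame({
        "section": np.repeat(np.arange(S), K),
        "distance_um": np.tile(spokes.distances, S),
        "mean_displacement_um": mean.ravel(),
        "sd_displacement_um": sd.ravel(),
        "n": n.ravel(),
    })


def spoke_strain_profile(
    field: DisplacementField, spokes: SpokeSet, h: int = 7
) -> pd.DataFrame:
    """Per-section mean radial (major) and circumferential (minor) strain
    vs. distance, one frame.

    At each sample point, displacements at the four surrounding offsets
    (+-h, 0) and (0, +-h) px are obtained by bilinear interpolation,
    central differences give the deformation gradient, and the principal
    strains of E = (F^T F - I)/2 are section-averaged per radial position.
    Sample points whose stencil exits the frame are dropped (count
    decrements).
    """
    H, W = field.shape
    px = spokes.points[..., 0]
    py = spokes.points[..., 1]
    ok = (spokes.valid
          & (px - h >= 0) & (px + h <= W - 1)
          & (py - h >= 0) & (py + h <= H - 1))
    cx = np.clip(px, h, W - 1 - h)
    cy = np.clip(py, h, H - 1 - h)
    u_xp, v_xp = bilinear_sample(field, cx + h, cy)
    u_xm, v_xm = bilinear_sample(field, cx - h, cy)
    u_yp, v_yp = bilinear_sample(field, cx, cy + h)
    u_ym, v_ym = bilinear_sample(field, cx, cy - h)
    F11 = 1.0 + (u_xp - u_xm) / (2.0 * h)
    F12 = (u_yp - u_ym) / (2.0 * h)
    F21 = (v_xp - v_xm) / (2.0 * h)
    F22 = 1.0 + (v_yp - v_ym) / (2.0 * h)
    E11 = (F11 * F11 + F21 * F21 - 1.0) / 2.0
    E22 = (F12 * F12 + F22 * F22 - 1.0) / 2.0
    E12 = (F11 * F12 + F21 * F22) / 2.0
    lam_p, lam_m, _, _ = _principal_arrays(E11, E12, E22)
    mean_p, sd_p, n = _masked_mean_sd(lam_p, ok)
    mean_m, sd_m, _ = _masked_mean_sd(lam_m, ok)
    S, K = spokes.n_sections, spokes.n_samples
    return pd.DataFrame({
        "section": np.repeat(np.arange(S), K),
        "distance_um": np.tile(spokes.distances, S),
        "mean_major": mean_p.ravel(),
        "sd_major": sd_p.ravel(),
        "mean_minor": mean_m.ravel(),
        "sd_minor": sd_m.ravel(),
        "n": n.ravel(),
    })


def spoke_strain_kymograph(
    fields: list[DisplacementField],
    spokes: SpokeSet,
    times: np.ndarray,
    h: int = 7,
) -> pd.DataFrame:
    """Per-section strain profiles stacked over time (long format with a
    time_s column) — one kymograph per section."""
    frames = []
    for f, t in zip(fields, times):
        df = spoke_strain_profile(f, spokes, h=h)
        df.insert(0, "time_s", t)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
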