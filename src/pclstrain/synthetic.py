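"""Synthetic lung-slice movies with analytic deformation ground truth.

Real PCLS recordings show a speckle-textured tissue slab (alveolar walls,
septa) surrounding a smooth, bright airway lumen.  This module renders such
scenes under prescribed deformation maps whose displacement and Lagrangian
strain fields are known in closed form, so every stage of the measurement
pipeline (optical flow, strain tensors, radial binning, spokes) can be
validated against exact truth.

The default contraction kinematics are area-preserving in-plane: a lumen of
reference radius ``R0`` narrows to ``r0(t)`` and every tissue annulus keeps
its area, ``r(R) = sqrt(R^2 - R0^2 + r0^2)``.  This yields radial stretch
(``E_rr > 0``) and circumferential compression (``E_tt < 0``) that decay
away from the wall — the sign structure observed around a constricting
airway.  An exponential-decay mode localises the deformation within a
tunable length scale instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

from .imaging_io import FrameSequence

__all__ = [
    "SyntheticTruth",
    "RigidTruth",
    "StretchTruth",
    "make_speckle_texture",
    "annulus_contraction",
    "logistic_contraction_trajectory",
    "render_sequence",
    "rigid_motion_sequence",
    "uniform_stretch_sequence",
]


def make_speckle_texture(
    shape: tuple[int, int],
    feature_scale: float = 3.0,
    seed: int = 0,
    contrast_percentiles: tuple[float, float] = (1.0, 99.0),
) -> np.ndarray:
    """Band-limited random speckle texture in [0, 1].

    White Gaussian noise is low-pass filtered to an autocorrelation length
    of roughly ``feature_scale`` pixels, then contrast-stretched.  The same
    seed always reproduces the same array.
    """
    if shape[0] <= 0 or shape[1] <= 0:
        raise ValueError(f"texture shape must be positive, got {shape}")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(shape)
    tex = ndimage.gaussian_filter(noise, sigma=feature_scale / 2.0)
    lo, hi = np.percentile(tex, contrast_percentiles)
    tex = np.clip((tex - lo) / (hi - lo), 0.0, 1.0)
    return tex


@dataclass
class SyntheticTruth:
    """Analytic deformation map with closed-form displacements and strains.

    All radial quantities are in micrometres; the pixel grid is converted
    through ``pixel_size``.  ``r0_t`` is the lumen radius trajectory, one
    value per frame; frame 0 must be the undeformed reference
    (``r0_t[0] == R0``).
    """

    center: tuple[float, float]          # (cx, cy) in px, reference frame
    R0: float                            # reference lumen radius, um
    r0_t: np.ndarray                     # lumen radius per frame, um
    pixel_size: float                    # um / px
    mode: Literal["area-preserving", "exponential-decay"] = "area-preserving"
    decay_length: float = 120.0          # um, exponential-decay mode only
    # optional stiff circular inclusion: (cx_px, cy_px, radius_um, blend_um)
    inclusion: tuple[float, float, float, float] | None = None

    def __post_init__(self) -> None:
        self.r0_t = np.asarray(self.r0_t, dtype=float)
        if np.any(self.r0_t <= 0) or np.any(self.r0_t > self.R0):
            raise ValueError("lumen radius trajectory must satisfy 0 < r0(t) <= R0")
        if abs(self.r0_t[0] - self.R0) > 1e-9:
            raise ValueError("frame 0 must be undeformed: r0_t[0] == R0")

    # -- radial map and its derivative (um -> um) ------------------------

    def _r_of_R(self, R: np.ndarray, r0: float) -> np.ndarray:
        R = np.asarray(R, dtype=float)
        inside = R < self.R0
        if self.mode == "area-preserving":
            out = np.sqrt(np.maximum(R * R - self.R0**2 + r0 * r0, 0.0))
        else:
            out = R + (r0 - self.R0) * np.exp(-(R - self.R0) / self.decay_length)
        return np.where(inside, R * (r0 / self.R0), out)

    def _drdR(self, R: np.ndarray, r0: float) -> np.ndarray:
        R = np.asarray(R, dtype=float)
        inside = R < self.R0
        if self.mode == "area-preserving":
            r = np.sqrt(np.maximum(R * R - self.R0**2 + r0 * r0, 1e-12))
            out = R / r
        else:
            out = 1.0 - (r0 - self.R0) / self.decay_length * np.exp(
                -(R - self.R0) / self.decay_length
            )
        return np.where(inside, r0 / self.R0, out)

    def _inclusion_weight(self, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
        """Smoothstep factor: 0 inside the stiff inclusion, 1 outside."""
        assert self.inclusion is not None
        cx, cy, rad_um, blend_um = self.inclusion
        d = np.hypot(X - cx, Y - cy) * self.pixel_size
        s = np.clip((d - rad_um) / max(blend_um, 1e-9), 0.0, 1.0)
        return s * s * (3.0 - 2.0 * s)

    # -- public truth queries --------------------------------------------

    def displacement(self, X: np.ndarray, Y: np.ndarray, frame: int) -> tuple[np.ndarray, np.ndarray]:
        """Analytic displacement (u, v) in px at reference pixel coords."""
        cx, cy = self.center
        dx, dy = np.asarray(X, float) - cx, np.asarray(Y, float) - cy
        R_um = np.hypot(dx, dy) * self.pixel_size
        r0 = float(self.r0_t[frame])
        with np.errstate(invalid="ignore", divide="ignore"):
            scale = np.where(R_um > 1e-9, self._r_of_R(R_um, r0) / R_um, r0 / self.R0)
        u = dx * (scale - 1.0)
        v = dy * (scale - 1.0)
        if self.inclusion is not None:
            w = self._inclusion_weight(np.asarray(X, float), np.asarray(Y, float))
            u, v = u * w, v * w
        return u, v

    def strain_rr(self, R_um: np.ndarray, frame: int) -> np.ndarray:
        """Closed-form radial Lagrangian strain E_rr(R) = ((dr/dR)^2 - 1)/2."""
        g = self._drdR(R_um, float(self.r0_t[frame]))
        return (g * g - 1.0) / 2.0

    def strain_tt(self, R_um: np.ndarray, frame: int) -> np.ndarray:
        """Closed-form circumferential strain E_tt(R) = ((r/R)^2 - 1)/2."""
        R = np.asarray(R_um, dtype=float)
        r = self._r_of_R(R, float(self.r0_t[frame]))
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(R > 1e-9, r / R, self.r0_t[frame] / self.R0)
        return (ratio * ratio - 1.0) / 2.0

    def lumen_mask(self, shape: tuple[int, int], frame: int) -> np.ndarray:
        """Boolean lumen mask in the *deformed* frame."""
        Y, X = np.mgrid[0 : shape[0], 0 : shape[1]]
        rho = np.hypot(X - self.center[0], Y - self.center[1]) * self.pixel_size
        return rho < float(self.r0_t[frame])

    def tissue_footprint(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean tissue mask in the reference frame (everything but lumen)."""
        return ~self.lumen_mask(shape, 0)


def annulus_contraction(
    R0: float,
    r0_t: Sequence[float] | np.ndarray,
    center: tuple[float, float],
    pixel_size: float,
    mode: Literal["area-preserving", "exponential-decay"] = "area-preserving",
    decay_length: float = 120.0,
    inclusion: tuple[float, float, float, float] | None = None,
) -> SyntheticTruth:
    """Truth object for a contracting annulus; see :class:`SyntheticTruth`."""
    return SyntheticTruth(
        center=center,
        R0=R0,
        r0_t=np.asarray(r0_t, dtype=float),
        pixel_size=pixel_size,
        mode=mode,
        decay_length=decay_length,
        inclusion=inclusion,
    )


def logistic_contraction_trajectory(
    times: np.ndarray,
    R0: float,
    r0_min: float,
    t_contract: float = 600.0,
    tau: float = 80.0,
) -> np.ndarray:
    """Lumen radius r0(t): logistic fall from R0 toward ``r0_min`` until
    ``t_contract`` (fast narrowing then asymptotic slow phase), then logistic
    recovery back toward R0 — the canonical caliber-vs-time shape of an
    agonist/relaxant experiment."""
    times = np.asarray(times, dtype=float)
    fall = 1.0 / (1.0 + np.exp(-(times - 3 * tau) / tau))
    r = R0 - (R0 - r0_min) * fall
    relax = times > t_contract
    if np.any(relax):
        rec = 1.0 / (1.0 + np.exp(-(times[relax] - t_contract - 3 * tau) / tau))
        r_at_t1 = r[~relax][-1] if np.any(~relax) else r0_min
        r[relax] = r_at_t1 + (R0 - r_at_t1) * rec
    r[0] = R0
    return np.clip(r, r0_min, R0)


def _invert_displacement(
    truth: SyntheticTruth,
    shape: tuple[int, int],
    frame: int,
    n_iter: int = 8,
) -> tuple[np.ndarray, np.ndarray]:
    """Reference coords (X, Y) for each deformed pixel (x, y) by fixed-point
    iteration X <- x - u(X).  Converges when displacement gradients are < 1
    in magnitude, which holds for the moderate strains simulated here."""
    Yd, Xd = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    Xr, Yr = Xd.copy(), Yd.copy()
    for _ in range(n_iter):
        u, v = truth.displacement(Xr, Yr, frame)
        Xr, Yr = Xd - u, Yd - v
    return Xr, Yr


def render_sequence(
    texture: np.ndarray,
    truth: SyntheticTruth,
    times: Sequence[float] | np.ndarray,
    pixel_size: float | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    lumen_intensity: float = 0.95,
    reference_index: int = 0,
) -> FrameSequence:
    """Render the movie: each frame is the texture pulled back through the
    inverse deformation map (backward warping, bilinear), with the lumen
    painted as a bright smooth disc and optional additive Gaussian noise.
    Deterministic for a given seed."""
    times = np.asarray(times, dtype=float)
    if len(times) != len(truth.r0_t):
        raise ValueError("times and truth.r0_t must have one entry per frame")
    rng = np.random.default_rng(seed)
    shape = texture.shape
    frames = []
    for k in range(len(times)):
        Xr, Yr = _invert_displacement(truth, shape, k)
        # cubic spline resampling: bilinear warping blurs the speckle
        # anisotropically, which a flow estimator misreads as deformation
        frame = ndimage.map_coordinates(texture, [Yr, Xr], order=3, mode="nearest")
        lum = truth.lumen_mask(shape, k)
        # soften the lumen edge over ~1.5 px so segmentation sees a real edge
        soft = ndimage.gaussian_filter(lum.astype(float), 1.5)
        frame = frame * (1.0 - soft) + lumen_intensity * soft
        if noise_sd > 0:
            frame = frame + rng.normal(0.0, noise_sd, shape)
        frames.append(np.clip(frame, 0.0, 1.0))
    ps = truth.pixel_size if pixel_size is None else pixel_size
    return FrameSequence(frames=frames, times=times, pixel_size=ps,
                         reference_index=reference_index)


@dataclass
class RigidTruth:
    """Rigid-motion ground truth: nonzero displacement, identically zero strain."""

    dx: float
    dy: float
    theta_deg: float
    center: tuple[float, float]

    def displacement(self, X: np.ndarray, Y: np.ndarray, frame: int = -1) -> tuple[np.ndarray, np.ndarray]:
        th = np.deg2rad(self.theta_deg)
        cx, cy = self.center
        dxc, dyc = np.asarray(X, float) - cx, np.asarray(Y, float) - cy
        u = np.cos(th) * dxc - np.sin(th) * dyc + cx + self.dx - np.asarray(X, float)
        v = np.sin(th) * dxc + np.cos(th) * dyc + cy + self.dy - np.asarray(Y, float)
        return u, v


@dataclass
class StretchTruth:
    """Homogeneous uniaxial stretch about the frame center: x = cx +
    alpha*(X - cx) along one axis.  The Lagrangian strain is constant,
    E = (alpha^2 - 1)/2 along the stretched axis and zero elsewhere."""

    alpha: float
    center: tuple[float, float]
    axis: str = "x"

    @property
    def strain(self) -> float:
        return (self.alpha**2 - 1.0) / 2.0

    def displacement(self, X: np.ndarray, Y: np.ndarray, frame: int = -1) -> tuple[np.ndarray, np.ndarray]:
        u = np.zeros_like(np.asarray(X, float))
        v = np.zeros_like(np.asarray(Y, float))
        if self.axis == "x":
            u = (self.alpha - 1.0) * (np.asarray(X, float) - self.center[0])
        else:
            v = (self.alpha - 1.0) * (np.asarray(Y, float) - self.center[1])
        return u, v


def uniform_stretch_sequence(
    texture: np.ndarray,
    alpha: float = 1.1,
    axis: str = "x",
    pixel_size: float = 1.15,
    frame_interval: float = 2.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[FrameSequence, StretchTruth]:
    """Two-frame movie under a homogeneous stretch by ``alpha`` along one
    axis, centered on the frame."""
    h, w = texture.shape
    center = ((w - 1) / 2.0, (h - 1) / 2.0)
    truth = StretchTruth(alpha=alpha, center=center, axis=axis)
    Yd, Xd = np.mgrid[0:h, 0:w].astype(float)
    Xr, Yr = Xd.copy(), Yd.copy()
    if axis == "x":
        Xr = (Xd - center[0]) / alpha + center[0]
    else:
        Yr = (Yd - center[1]) / alpha + center[1]
    moved = ndimage.map_coordinates(texture, [Yr, Xr], order=3, mode="nearest")
    moved = np.clip(moved, 0.0, 1.0)
    rng = np.random.default_rng(seed)
    frames = [texture.copy(), moved]
    if noise_sd > 0:
        frames = [np.clip(f + rng.normal(0, noise_sd, f.shape), 0, 1) for f in frames]
    seq = FrameSequence(frames=frames, times=np.array([0.0, frame_interval]),
                        pixel_size=pixel_size, reference_index=0)
    return seq, truth


def rigid_motion_sequence(
    texture: np.ndarray,
    dx: float,
    dy: float,
    theta_deg: float = 0.0,
    pixel_size: float = 1.15,
    frame_interval: float = 2.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[FrameSequence, RigidTruth]:
    """Two-frame movie under a rigid translation + rotation about the frame
    center.  The truth strain is identically zero — the classic check that
    whole-slice drift contaminates displacements but not strains."""
    h, w = texture.shape
    center = ((w - 1) / 2.0, (h - 1) / 2.0)
    truth = RigidTruth(dx=dx, dy=dy, theta_deg=theta_deg, center=center)
    Yd, Xd = np.mgrid[0:h, 0:w].astype(float)
    # inverse rigid map (exact)
    th = np.deg2rad(theta_deg)
    xs, ys = Xd - center[0] - dx, Yd - center[1] - dy
    Xr = np.cos(th) * xs + np.sin(th) * ys + center[0]
    Yr = -np.sin(th) * xs + np.cos(th) * ys + center[1]
    moved = ndimage.map_coordinates(texture, [Yr, Xr], order=3, mode="nearest")
    moved = np.clip(moved, 0.0, 1.0)
    rng = np.random.default_rng(seed)
    frames = [texture.copy(), moved]
    if noise_sd > 0:
        frames = [np.clip(f + rng.normal(0, noise_sd, f.shape), 0, 1) for f in frames]
    seq = FrameSequence(
        frames=frames,
        times=np.array([0.0, frame_interval]),
        pixel_size=pixel_size,
        reference_index=0,
    )
    return seq, truth
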