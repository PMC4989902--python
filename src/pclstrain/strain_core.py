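"""Lagrangian strain tensors and principal strains from displacement fields.

Given a dense displacement field u(X, Y), v(X, Y) on the reference pixel
grid, the local deformation gradient

    F = [[dx/dX, dx/dY], [dy/dX, dy/dY]],   (x, y) = (X + u, Y + v)

is estimated by central differences over a 4-point stencil of half-width
``h`` pixels.  The Lagrangian strain is E = (F^T F - I) / 2, a symmetric
2x2 tensor whose invariants I1 = E11 + E22 and I2 = E11*E22 - E12^2 give
the principal strains in closed form,

    lambda_pm = (I1 +- sqrt(I1^2 - 4*I2)) / 2,

with discriminant I1^2 - 4*I2 = (E11 - E22)^2 + 4*E12^2 >= 0, so both
eigenvalues are real.  Around a constricting airway the major principal
direction is essentially radial and the minor circumferential; the major
eigenvector's sign is fixed by requiring a component pointing toward the
lumen center.  Rigid motions (translation + rotation) give C = F^T F = I
and hence zero strain — the key advantage of strain maps over raw
displacement maps when the whole slice drifts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .flow import DisplacementField

__all__ = [
    "DeformationGradient",
    "StrainTensor",
    "PrincipalStrain",
    "StrainField",
    "deformation_gradient_at",
    "lagrangian_strain",
    "principal_strains",
    "orient_major_eigenvector",
    "strain_field",
]


@dataclass
class DeformationGradient:
    F11: float
    F12: float
    F21: float
    F22: float

    @property
    def matrix(self) -> np.ndarray:
        return np.array([[self.F11, self.F12], [self.F21, self.F22]])

    @property
    def det(self) -> float:
        return self.F11 * self.F22 - self.F12 * self.F21


@dataclass
class StrainTensor:
    E11: float
    E12: float
    E22: float

    @property
    def I1(self) -> float:
        return self.E11 + self.E22

    @property
    def I2(self) -> float:
        return self.E11 * self.E22 - self.E12 * self.E12

    @property
    def matrix(self) -> np.ndarray:
        return np.array([[self.E11, self.E12], [self.E12, self.E22]])


@dataclass
class PrincipalStrain:
    lambda_major: float
    lambda_minor: float
    major_eigenvector: np.ndarray          # unit 2-vector (x, y)
    position: tuple[float, float] | None = None


def deformation_gradient_at(
    field: DisplacementField, point: tuple[int, int], h: int = 7
) -> DeformationGradient:
    """Deformation gradient at one grid point from the four displacement
    samples at (X +- h, Y) and (X, Y +- h), by central differences."""
    X, Y = point
    H, W = field.shape
    if not (h <= X < W - h and h <= Y < H - h):
        raise ValueError(
            f"stencil of half-width {h} at ({X}, {Y}) exits the {W}x{H} frame"
        )
    u, v = field.u, field.v
    dudX = (u[Y, X + h] - u[Y, X - h]) / (2 * h)
    dudY = (u[Y + h, X] - u[Y - h, X]) / (2 * h)
    dvdX = (v[Y, X + h] - v[Y, X - h]) / (2 * h)
    dvdY = (v[Y + h, X] - v[Y - h, X]) / (2 * h)
    return DeformationGradient(1.0 + dudX, dudY, dvdX, 1.0 + dvdY)


def lagrangian_strain(F: DeformationGradient) -> StrainTensor:
    """E = (F^T F - I)/2, written out in components."""
    E11 = (F.F11 * F.F11 + F.F21 * F.F21 - 1.0) / 2.0
    E22 = (F.F12 * F.F12 + F.F22 * F.F22 - 1.0) / 2.0
    E12 = (F.F11 * F.F12 + F.F21 * F.F22) / 2.0
    return StrainTensor(E11, E12, E22)


def principal_strains(E: StrainTensor) -> PrincipalStrain:
    """Closed-form eigen-decomposition of a symmetric 2x2 strain tensor.

    The major eigenvector is ``(E12, lambda_major - E11)`` normalized; when
    that degenerates (E12 == 0, i.e. E already diagonal) the relevant
    coordinate axis is returned, and in the fully repeated case
    (E11 == E22, E12 == 0) the x-axis is returned as a placeholder — the
    caller re-orients it radially toward the lumen.
    """
    lam_p, lam_m, wx, wy = _principal_arrays(
        np.float64(E.E11), np.float64(E.E12), np.float64(E.E22)
    )
    return PrincipalStrain(float(lam_p), float(lam_m),
                           np.array([float(wx), float(wy)]))


def _principal_arrays(E11, E12, E22):
    """Vectorized eigenvalues/major eigenvector from invariants.

    The eigenvector follows from either row of (E - lambda I) w = 0:
    (E12, lambda - E11) or (lambda - E22, E12).  The rows are parallel in
    exact arithmetic but the one with the larger norm is far better
    conditioned when the tensor is nearly diagonal, so it is chosen
    pointwise.
    """
    I1 = E11 + E22
    disc = np.sqrt((E11 - E22) ** 2 + 4.0 * E12 * E12)
    lam_p = (I1 + disc) / 2.0
    lam_m = (I1 - disc) / 2.0
    a_x = np.asarray(E12, dtype=float)
    a_y = np.asarray(lam_p - E11, dtype=float)
    b_x = np.asarray(lam_p - E22, dtype=float)
    b_y = a_x
    norm_a = np.hypot(a_x, a_y)
    norm_b = np.hypot(b_x, b_y)
    use_b = norm_b > norm_a
    wx = np.where(use_b, b_x, a_x)
    wy = np.where(use_b, b_y, a_y)
    norm = np.where(use_b, norm_b, norm_a)
    # fully repeated eigenvalue: any direction is valid; pick the x-axis
    # (the caller re-orients radially toward the lumen)
    degen = norm < 1e-14
    wx = np.where(degen, 1.0, wx)
    wy = np.where(degen, 0.0, wy)
    norm = np.where(degen, 1.0, norm)
    return lam_p, lam_m, wx / norm, wy / norm


def orient_major_eigenvector(
    vec: np.ndarray,
    point: tuple[float, float],
    lumen_center: tuple[float, float],
) -> np.ndarray:
    """Return +-vec such that it has a non-negative component toward the
    lumen center.  Exactly tangential vectors keep their input sign; a
    point coinciding with the center is left unchanged with a warning."""
    vec = np.asarray(vec, dtype=float)
    d = np.array([lumen_center[0] - point[0], lumen_center[1] - point[1]])
    if d[0] == 0 and d[1] == 0:
        warnings.warn("point coincides with lumen center; orientation unchanged")
        return vec
    return -vec if float(vec @ d) < 0 else vec


@dataclass
class StrainField:
    """Principal strains on a regular evaluation grid in reference coords.

    ``xs``/``ys`` are 1-D grid coordinates (px); 2-D arrays are indexed
    [y, x].  Strains are zeroed where the tissue mask is false; ``valid``
    records which grid points carry tissue (and hence enter averages).
    """

    xs: np.ndarray
    ys: np.ndarray
    lambda_major: np.ndarray
    lambda_minor: np.ndarray
    evec_x: np.ndarray
    evec_y: np.ndarray
    E11: np.ndarray
    E12: np.ndarray
    E22: np.ndarray
    valid: np.ndarray
    grid_spacing: int
    h: int
    pixel_size: float

    def positions(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid (X, Y) of evaluation points, px."""
        return np.meshgrid(self.xs, self.ys)

    def to_frame(self) -> pd.DataFrame:
        X, Y = self.positions()
        return pd.DataFrame({
            "X_px": X.ravel(), "Y_px": Y.ravel(),
            "X_um": X.ravel() * self.pixel_size,
            "Y_um": Y.ravel() * self.pixel_size,
            "lambda_major": self.lambda_major.ravel(),
            "lambda_minor": self.lambda_minor.ravel(),
            "evec_x": self.evec_x.ravel(),
            "evec_y": self.evec_y.ravel(),
            "tissue": self.valid.ravel().astype(int),
        })


def strain_field(
    field: DisplacementField,
    grid_spacing: int = 7,
    h: int = 7,
    mask: np.ndarray | None = None,
    lumen_center: tuple[float, float] | None = None,
) -> StrainField:
    """Principal strains at equally spaced points across the frame.

    Evaluation points start ``h`` px from the frame edge (the stencil must
    stay inside).  Where ``mask`` is false the strains are set to zero and
    flagged invalid; eigenvectors are oriented toward ``lumen_center`` when
    given.
    """
    H, W = field.shape
    xs = np.arange(h, W - h, grid_spacing)
    ys = np.arange(h, H - h, grid_spacing)
    X, Y = np.meshgrid(xs, ys)
    u, v = field.u, field.v

    dudX = (u[Y, X + h] - u[Y, X - h]) / (2.0 * h)
    dudY = (u[Y + h, X] - u[Y - h, X]) / (2.0 * h)
    dvdX = (v[Y, X + h] - v[Y, X - h]) / (2.0 * h)
    dvdY = (v[Y + h, X] - v[Y - h, X]) / (2.0 * h)
    F11, F12, F21, F22 = 1.0 + dudX, dudY, dvdX, 1.0 + dvdY

    E11 = (F11 * F11 + F21 * F21 - 1.0) / 2.0
    E22 = (F12 * F12 + F22 * F22 - 1.0) / 2.0
    E12 = (F11 * F12 + F21 * F22) / 2.0
    lam_p, lam_m, wx, wy = _principal_arrays(E11, E12, E22)

    if lumen_center is not None:
        dx = lumen_center[0] - X
        dy = lumen_center[1] - Y
        flip = (wx * dx + wy * dy) < 0
        wx = np.where(flip, -wx, wx)
        wy = np.where(flip, -wy, wy)

    if mask is not None:
        valid = mask[Y, X].astype(bool)
        if not valid.any():
            warnings.warn("tissue mask excludes every grid point; strain field is all zero")
    else:
        valid = np.ones_like(lam_p, dtype=bool)
    lam_p = np.where(valid, lam_p, 0.0)
    lam_m = np.where(valid, lam_m, 0.0)

    return StrainField(
        xs=xs, ys=ys,
        lambda_major=lam_p, lambda_minor=lam_m,
        evec_x=wx, evec_y=wy,
        E11=np.where(valid, E11, 0.0),
        E12=np.where(valid, E12, 0.0),
        E22=np.where(valid, E22, 0.0),
        valid=valid,
        grid_spacing=grid_spacing, h=h, pixel_size=field.pixel_size,
    )
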