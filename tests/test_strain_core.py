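"""Strain tensor construction, closed-form eigen-decomposition, orientation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pclstrain import (
    DeformationGradient,
    DisplacementField,
    StrainTensor,
    deformation_gradient_at,
    lagrangian_strain,
    orient_major_eigenvector,
    principal_strains,
    strain_field,
)
from tests.conftest import PIXEL_SIZE, SIZE


def _linear_field(a_u, b_u, a_v, b_v, shape=(64, 64)):
    """u = a_u*X + b_u*Y, v = a_v*X + b_v*Y."""
    Y, X = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    return DisplacementField(a_u * X + b_u * Y, a_v * X + b_v * Y, 0, 1, PIXEL_SIZE)


class TestDeformationGradient:
    def test_zero_field_gives_identity(self):
        f = _linear_field(0, 0, 0, 0)
        F = deformation_gradient_at(f, (20, 20), h=5)
        np.testing.assert_allclose(F.matrix, np.eye(2))

    def test_linear_field_exact(self):
        # u = 0.1*X -> F = [[1.1, 0], [0, 1]] exactly (central differences
        # are exact for linear fields)
        f = _linear_field(0.1, 0, 0, 0)
        F = deformation_gradient_at(f, (30, 25), h=7)
        np.testing.assert_allclose(F.matrix, [[1.1, 0.0], [0.0, 1.0]], atol=1e-12)

    def test_rotation_field_gives_rotation_matrix(self):
        th = np.deg2rad(10.0)
        c = (32, 32)
        Y, X = np.mgrid[0:64, 0:64].astype(float)
        u = np.cos(th) * (X - c[0]) - np.sin(th) * (Y - c[1]) + c[0] - X
        v = np.sin(th) * (X - c[0]) + np.cos(th) * (Y - c[1]) + c[1] - Y
        f = DisplacementField(u, v, 0, 1, PIXEL_SIZE)
        F = deformation_gradient_at(f, (32, 32), h=7)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        np.testing.assert_allclose(F.matrix, R, atol=1e-10)

    def test_stencil_outside_frame_rejected(self):
        f = _linear_field(0, 0, 0, 0)
        with pytest.raises(ValueError, match="stencil"):
            deformation_gradient_at(f, (2, 30), h=5)


class TestLagrangianStrain:
    @pytest.mark.parametrize(
        "F, expected",
        [
            # identity -> zero strain
            ((1, 0, 0, 1), (0.0, 0.0, 0.0)),
            # uniaxial stretch 1.1: E11 = (1.1^2 - 1)/2 = 0.105
            ((1.1, 0, 0, 1.0), (0.105, 0.0, 0.0)),
            # simple shear F = [[1, 0.2], [0, 1]] -> E = [[0, .1], [.1, .02]]
            ((1, 0.2, 0, 1), (0.0, 0.1, 0.02)),
        ],
    )
    def test_closed_form_cases(self, F, expected):
        E = lagrangian_strain(DeformationGradient(*F))
        np.testing.assert_allclose([E.E11, E.E12, E.E22], expected, atol=1e-15)

    @pytest.mark.parametrize("theta", [0.0, 10.0, 45.0, 123.0])
    def test_rigid_rotation_is_strain_free(self, theta):
        th = np.deg2rad(theta)
        F = DeformationGradient(np.cos(th), -np.sin(th), np.sin(th), np.cos(th))
        E = lagrangian_strain(F)
        np.testing.assert_allclose([E.E11, E.E12, E.E22], 0.0, atol=1e-15)


class TestPrincipalStrains:
    @pytest.mark.parametrize(
        "E, lam_p, lam_m",
        [
            # frozen values cross-checked against numpy.linalg.eigvalsh
            ((0.0, 0.1, 0.02), 0.1104988, -0.0904988),
            ((0.03, 0.04, -0.09), 0.0421110, -0.1021110),
        ],
    )
    def test_against_frozen_eigensolver_values(self, E, lam_p, lam_m):
        E = StrainTensor(*E)
        p = principal_strains(E)
        ref = np.linalg.eigvalsh(E.matrix)           # independent oracle
        assert p.lambda_major == pytest.approx(lam_p, abs=1e-6)
        assert p.lambda_minor == pytest.approx(lam_m, abs=1e-6)
        assert p.lambda_major == pytest.approx(ref[1], abs=1e-14)
        assert p.lambda_minor == pytest.approx(ref[0], abs=1e-14)
        assert p.lambda_major + p.lambda_minor == pytest.approx(E.I1, abs=1e-14)

    def test_zero_tensor(self):
        p = principal_strains(StrainTensor(0.0, 0.0, 0.0))
        assert p.lambda_major == 0.0 and p.lambda_minor == 0.0
        assert np.hypot(*p.major_eigenvector) == pytest.approx(1.0)

    def test_diagonal_tensor_eigenvector_is_coordinate_axis(self):
        p = principal_strains(StrainTensor(0.2, 0.0, -0.1))
        np.testing.assert_allclose(p.major_eigenvector, [1.0, 0.0])
        p = principal_strains(StrainTensor(-0.1, 0.0, 0.2))
        np.testing.assert_allclose(p.major_eigenvector, [0.0, 1.0])

    @given(
        st.floats(-0.5, 0.5), st.floats(-0.5, 0.5), st.floats(-0.5, 0.5)
    )
    @settings(derandomize=True, max_examples=200, deadline=None)
    def test_eigen_identities_hold(self, e11, e12, e22):
        E = StrainTensor(e11, e12, e22)
        p = principal_strains(E)
        assert p.lambda_major >= p.lambda_minor
        assert p.lambda_major + p.lambda_minor == pytest.approx(E.I1, abs=1e-12)
        assert p.lambda_major * p.lambda_minor == pytest.approx(E.I2, abs=1e-12)
        # eigenvector residual ||E w - lambda w||
        w = p.major_eigenvector
        resid = E.matrix @ w - p.lambda_major * w
        assert np.hypot(*resid) <= 1e-10


class TestOrientation:
    def test_flipped_toward_lumen(self):
        v = orient_major_eigenvector(np.array([1.0, 0.0]), (200, 100), (100, 100))
        np.testing.assert_allclose(v, [-1.0, 0.0])

    def test_already_toward_lumen_unchanged(self):
        v = orient_major_eigenvector(np.array([-1.0, 0.0]), (200, 100), (100, 100))
        np.testing.assert_allclose(v, [-1.0, 0.0])

    def test_tangential_keeps_input_sign(self):
        v = orient_major_eigenvector(np.array([0.0, 1.0]), (200, 100), (100, 100))
        np.testing.assert_allclose(v, [0.0, 1.0])

    def test_point_at_center_warns(self):
        with pytest.warns(UserWarning, match="coincides"):
            v = orient_major_eigenvector(np.array([1.0, 0.0]), (100, 100), (100, 100))
        np.testing.assert_allclose(v, [1.0, 0.0])


class TestStrainField:
    def test_uniform_stretch_recovered_everywhere(self):
        f = _linear_field(0.1, 0, 0, 0, shape=(96, 96))
        sf = strain_field(f, grid_spacing=7, h=7)
        np.testing.assert_allclose(sf.lambda_major, 0.105, atol=1e-6)
        np.testing.assert_allclose(sf.lambda_minor, 0.0, atol=1e-6)

    def test_fully_false_mask_zeroes_everything(self):
        f = _linear_field(0.1, 0, 0, 0)
        with pytest.warns(UserWarning, match="mask"):
            sf = strain_field(f, mask=np.zeros((64, 64), dtype=bool))
        assert np.all(sf.lambda_major == 0.0)
        assert np.all(sf.lambda_minor == 0.0)
        assert not sf.valid.any()

    def test_translation_invariance_bitwise(self, annulus):
        """Adding a constant to (u, v) cancels in central differences, so
        every strain is bitwise unchanged."""
        f = annulus.field
        shifted = DisplacementField(f.u + 3.25, f.v - 1.5, 0, 1, f.pixel_size)
        a = strain_field(f, 7, 7)
        b = strain_field(shifted, 7, 7)
        assert np.array_equal(a.lambda_major, b.lambda_major)
        assert np.array_equal(a.lambda_minor, b.lambda_minor)

    def test_rigid_motion_nullity_analytic(self, rotation_bundle):
        """Translation + rotation displacement evaluated analytically gives
        |strain| <= 1e-8 everywhere (rigid motions are strain-free)."""
        _, truth, _ = rotation_bundle
        Y, X = np.mgrid[0:SIZE, 0:SIZE].astype(float)
        u, v = truth.displacement(X, Y)
        f = DisplacementField(u + 5.0, v - 3.0, 0, 1, PIXEL_SIZE)
        sf = strain_field(f, 7, 7)
        assert np.abs(sf.lambda_major).max() <= 1e-8
        assert np.abs(sf.lambda_minor).max() <= 1e-8

    def test_eigenvalue_lower_bound_on_analytic_fields(self, annulus):
        """lambda_minor >= -0.5 because C = F^T F is positive semidefinite."""
        sf = strain_field(annulus.analytic_field, 7, 7)
        assert sf.lambda_minor.min() >= -0.5

    def test_annulus_strains_match_closed_form(self, annulus):
        """Analytic displacement -> strain grid reproduces E_rr, E_tt."""
        sf = strain_field(annulus.analytic_field, 7, 7, mask=annulus.tissue,
                          lumen_center=annulus.ellipse.center)
        X, Y = sf.positions()
        R = annulus.radius_um(X, Y)
        sel = sf.valid & (R > 105) & (R < 190)
        err_rr = np.abs(sf.lambda_major - annulus.truth.strain_rr(R, 1))[sel]
        err_tt = np.abs(sf.lambda_minor - annulus.truth.strain_tt(R, 1))[sel]
        peak = annulus.truth.strain_rr(np.array([R0_UM := 100.0]), 1)[0]
        assert np.median(err_rr) <= 0.15 * peak
        assert np.median(err_tt) <= 0.15 * peak

    def test_major_eigenvector_points_toward_lumen(self, annulus):
        sf = strain_field(annulus.analytic_field, 7, 7, mask=annulus.tissue,
                          lumen_center=annulus.ellipse.center)
        X, Y = sf.positions()
        dx = annulus.ellipse.center[0] - X
        dy = annulus.ellipse.center[1] - Y
        dots = (sf.evec_x * dx + sf.evec_y * dy)[sf.valid]
        assert np.all(dots >= -1e-9)
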