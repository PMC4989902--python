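"""Spoke geometry, bilinear sampling, section-averaged profiles."""

import numpy as np
import pytest

from pclstrain import (
    DisplacementField,
    LumenEllipse,
    bilinear_sample,
    build_spokes,
    spoke_displacement_profile,
    spoke_strain_profile,
)
from pclstrain.synthetic import annulus_contraction
from tests.conftest import CENTER, PIXEL_SIZE, R0_UM, R1_UM, SIZE


@pytest.fixture
def circle_ellipse():
    return LumenEllipse(cx=CENTER[0], cy=CENTER[1],
                        a=R0_UM / PIXEL_SIZE, b=R0_UM / PIXEL_SIZE, theta=0.0)


class TestBuildSpokes:
    def test_default_geometry_has_56_rays_starting_on_the_circle(self, circle_ellipse):
        s = build_spokes(circle_ellipse, (SIZE, SIZE), PIXEL_SIZE)
        assert s.points.shape[:2] == (8, 7)
        origins = s.points[:, :, 0, :]
        r = np.hypot(origins[..., 0] - CENTER[0], origins[..., 1] - CENTER[1])
        np.testing.assert_allclose(r, R0_UM / PIXEL_SIZE, atol=1e-9)

    def test_constant_sample_spacing(self, circle_ellipse):
        s = build_spokes(circle_ellipse, (SIZE, SIZE), PIXEL_SIZE, radial_step=10.0)
        steps = np.linalg.norm(np.diff(s.points, axis=2), axis=-1) * PIXEL_SIZE
        np.testing.assert_allclose(steps, 10.0, atol=1e-9)

    def test_truncation_near_frame_corner(self):
        e = LumenEllipse(cx=30.0, cy=30.0, a=25.0, b=25.0, theta=0.0)
        s = build_spokes(e, (128, 128), PIXEL_SIZE, max_length=400.0)
        px = s.points[..., 0][s.valid]
        py = s.points[..., 1][s.valid]
        assert px.min() >= 0 and px.max() <= 127
        assert py.min() >= 0 and py.max() <= 127
        assert not s.valid.all()

    def test_center_outside_frame_rejected(self):
        e = LumenEllipse(cx=-50.0, cy=10.0, a=20.0, b=20.0, theta=0.0)
        with pytest.raises(ValueError):
            build_spokes(e, (64, 64), PIXEL_SIZE)


class TestBilinearSample:
    def _field(self, u, v):
        return DisplacementField(u, v, 0, 1, PIXEL_SIZE)

    def test_integer_point_returns_exact_pixel(self):
        u = np.arange(16.0).reshape(4, 4)
        f = self._field(u, -u)
        us, vs = bilinear_sample(f, np.array([2.0]), np.array([1.0]))
        assert us[0] == 6.0 and vs[0] == -6.0

    def test_cell_center_averages_corners(self):
        u = np.array([[0.0, 1.0], [1.0, 2.0]])
        f = self._field(u, u)
        us, _ = bilinear_sample(f, np.array([0.5]), np.array([0.5]))
        assert us[0] == pytest.approx(1.0)

    def test_exact_for_linear_fields(self):
        Y, X = np.mgrid[0:32, 0:32].astype(float)
        f = self._field(0.05 * X + 0.02 * Y, 0.01 * X - 0.03 * Y)
        rng = np.random.default_rng(12)
        xs = rng.uniform(1, 30, 50)
        ys = rng.uniform(1, 30, 50)
        us, vs = bilinear_sample(f, xs, ys)
        np.testing.assert_allclose(us, 0.05 * xs + 0.02 * ys, atol=1e-12)
        np.testing.assert_allclose(vs, 0.01 * xs - 0.03 * ys, atol=1e-12)

    def test_outside_domain_rejected(self):
        f = self._field(np.zeros((8, 8)), np.zeros((8, 8)))
        with pytest.raises(ValueError, match="outside"):
            bilinear_sample(f, np.array([7.5]), np.array([2.0]))


class TestDisplacementProfile:
    def test_zero_field_gives_zero_profiles(self, circle_ellipse):
        z = np.zeros((SIZE, SIZE))
        f = DisplacementField(z, z.copy(), 0, 1, PIXEL_SIZE)
        s = build_spokes(circle_ellipse, (SIZE, SIZE), PIXEL_SIZE)
        df = spoke_displacement_profile(f, s)
        # rays truncated by the frame produce missing entries, not zeros
        np.testing.assert_allclose(df["mean_displacement_um"].dropna(), 0.0)
        np.testing.assert_allclose(df["sd_displacement_um"].dropna(), 0.0)

    def test_axisymmetric_sections_agree(self, annulus, circle_ellipse):
        s = build_spokes(circle_ellipse, (SIZE, SIZE), PIXEL_SIZE,
                         max_length=120.0)
        df = spoke_displacement_profile(annulus.analytic_field, s)
        peak = df["mean_displacement_um"].abs().max()
        spread = df.groupby("distance_um")["mean_displacement_um"].agg(np.ptp)
        assert spread.max() <= 0.05 * peak

    def test_wall_displacement_matches_contraction(self, annulus, circle_ellipse):
        """At distance 0 the inward displacement is R0 - r0 = 20 um."""
        s = build_spokes(circle_ellipse, (SIZE, SIZE), PIXEL_SIZE)
        df = spoke_displacement_profile(annulus.analytic_field, s)
        at0 = df[df["distance_um"] == 0.0]["mean_displacement_um"]
        np.testing.assert_allclose(at0, R0_UM - R1_UM, rtol=0.02)

    def test_sd_scales_with_sample_noise_not_ray_count(self, circle_ellipse):
        """On a noisy field the reported per-section SD estimates the ray
        scatter (constant in n), so the SEM of the section mean shrinks as
        1/sqrt(n_spokes)."""
        rng = np.random.default_rng(13)
        noise = 0.5
        u = rng.normal(0, noise, (SIZE, SIZE))
        v = rng.normal(0, noise, (SIZE, SIZE))
        f = DisplacementField(u, v, 0, 1, PIXEL_SIZE)
        sems = []
        for n in (7, 28):
            s = build_spokes(circle_ellipse, (SIZE, SIZE), PIXEL_SIZE,
                             n_spokes=n, max_length=100.0)
            df = spoke_displacement_profile(f, s)
            assert (df["sd_displacement_um"].dropna() >= 0).all()
            sems.append((df["sd_displacement_um"] / np.sqrt(df["n"])).median())
        assert sems[1] == pytest.approx(sems[0] / 2.0, rel=0.2)


class TestStrainProfile:
    def test_zero_field_gives_zero_strain(self, circle_ellipse):
        z = np.zeros((SIZE, SIZE))
        f = DisplacementField(z, z.copy(), 0, 1, PIXEL_SIZE)
        s = build_spokes(circle_ellipse, (SIZE, SIZE), PIXEL_SIZE)
        df = spoke_strain_profile(f, s)
        np.testing.assert_allclose(df["mean_major"].dropna(), 0.0, atol=1e-14)
        np.testing.assert_allclose(df["mean_minor"].dropna(), 0.0, atol=1e-14)

    def test_uniform_stretch_section_means(self, circle_ellipse):
        Y, X = np.mgrid[0:SIZE, 0:SIZE].astype(float)
        f = DisplacementField(0.1 * X, np.zeros_like(X), 0, 1, PIXEL_SIZE)
        s = build_spokes(circle_ellipse, (SIZE, SIZE), PIXEL_SIZE,
                         max_length=100.0)
        df = spoke_strain_profile(f, s)
        np.testing.assert_allclose(df["mean_major"].dropna(), 0.105, atol=1e-3)

    def test_annulus_profiles_match_closed_forms(self, annulus, circle_ellipse):
        s = build_spokes(circle_ellipse, (SIZE, SIZE), PIXEL_SIZE,
                         max_length=100.0)
        df = spoke_strain_profile(annulus.analytic_field, s)
        R = R0_UM + df["distance_um"].to_numpy()
        truth_rr = annulus.truth.strain_rr(R, 1)
        truth_tt = annulus.truth.strain_tt(R, 1)
        peak = annulus.truth.strain_rr(np.array([R0_UM]), 1)[0]
        ok = (df["n"] > 0).to_numpy()
        # E_rr has a kink at the wall (one-sided radial gradient); samples
        # whose stencil crosses into the lumen cannot resolve it, so the
        # radial comparison starts one stencil half-width out.  E_tt is
        # continuous across the wall and is checked everywhere.
        h_um = 7 * PIXEL_SIZE
        beyond = ok & (df["distance_um"].to_numpy() >= h_um)
        assert np.nanmax(np.abs(df["mean_major"][beyond] - truth_rr[beyond])) <= 0.15 * peak
        assert np.nanmax(np.abs(df["mean_minor"][ok] - truth_tt[ok])) <= 0.15 * peak

    def test_stiff_inclusion_bends_one_section(self, texture, circle_ellipse):
        """A rigid inclusion in one section pulls that section's strain
        profile well outside the spread of the others."""
        incl_r_um = 180.0
        incl = (CENTER[0] + incl_r_um / PIXEL_SIZE * np.cos(np.deg2rad(22.5)),
                CENTER[1] + incl_r_um / PIXEL_SIZE * np.sin(np.deg2rad(22.5)),
                60.0, 30.0)
        truth = annulus_contraction(R0_UM, [R0_UM, R1_UM], CENTER, PIXEL_SIZE,
                                    inclusion=incl)
        Y, X = np.mgrid[0:SIZE, 0:SIZE].astype(float)
        u, v = truth.displacement(X, Y, 1)
        f = DisplacementField(u, v, 0, 1, PIXEL_SIZE)
        s = build_spokes(circle_ellipse, (SIZE, SIZE), PIXEL_SIZE,
                         max_length=150.0)
        df = spoke_strain_profile(f, s)
        prof = df.pivot_table(index="distance_um", columns="section",
                              values="mean_major")
        others = [c for c in prof.columns if c != 0]
        ref = prof[others].mean(axis=1)
        spread = prof[others].std(axis=1).mean()
        deviation = (prof[0] - ref).abs().mean()
        assert deviation > 3.0 * spread


def test_section_average_consistent_with_radial_binning(annulus, circle_ellipse):
    """For an axisymmetric field, the mean over all sections' spoke strain
    profiles agrees with the circumferential bin average at matching
    distances (within binning error)."""
    from pclstrain import bin_average, distance_map, strain_field
    s = build_spokes(circle_ellipse, (SIZE, SIZE), PIXEL_SIZE, max_length=90.0)
    df = spoke_strain_profile(annulus.analytic_field, s)
    spoke_mean = df.groupby("distance_um")["mean_major"].mean()

    sf = strain_field(annulus.analytic_field, 7, 7, mask=annulus.tissue,
                      lumen_center=annulus.ellipse.center)
    prof = bin_average(sf, distance_map(annulus.lumen0, PIXEL_SIZE), 15.0)
    for d, v in spoke_mean.items():
        if d < 7 * PIXEL_SIZE:        # wall-kink sample, see strain profile test
            continue
        k = min(int(d // 15.0), len(prof.mean_major) - 1)
        if prof.counts[k] > 0 and np.isfinite(v):
            assert v == pytest.approx(prof.mean_major[k], abs=0.05)
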