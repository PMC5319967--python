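"""Mesh construction, interpolation, measurement and shape variants."""

import numpy as np
import pytest
from scipy.integrate import quad

from fetallv.geometry import (
    GeometryParams,
    InfeasibleGeometryError,
    ProlateCoords,
    ShapeVariantSpec,
    assign_fiber_field,
    build_lv_mesh,
    cavity_volume,
    fiber_frames_at,
    lv_metrics,
    make_shape_variant,
    measure_echo_dimensions,
    outer_volume,
    wall_volume,
)


@pytest.fixture(scope="module")
def params():
    return GeometryParams(long_axis=18.0, short_axis=9.0, wall_thickness=3.0)


@pytest.fixture(scope="module")
def mesh(params):
    return build_lv_mesh(params)


class TestConstruction:
    def test_topology_is_30_nodes_20_elements(self, mesh):
        assert mesh.n_nodes == 30
        assert mesh.n_elements == 20

    def test_dimensions_round_trip(self, mesh, params):
        met = lv_metrics(mesh)
        assert met.long_axis == pytest.approx(params.long_axis, abs=0.1)
        assert met.short_axis == pytest.approx(params.short_axis, abs=0.1)
        assert met.wall_thickness == pytest.approx(params.wall_thickness, abs=0.1)

    def test_degenerate_wall_thickness_rejected(self):
        with pytest.raises(InfeasibleGeometryError):
            GeometryParams(long_axis=18.0, short_axis=9.0, wall_thickness=9.0)

    def test_oblate_inner_surface_rejected(self):
        with pytest.raises(InfeasibleGeometryError):
            # long semi-axis below short semi-axis cannot be prolate
            build_lv_mesh(GeometryParams(4.0, 9.0, 1.0))

    def test_jacobian_positive(self, mesh):
        assert mesh.check_jacobian() > 0


class TestVolumes:
    def test_cavity_volume_against_1d_integral_oracle(self, mesh, params):
        """Quadrature cavity volume matches an independent solid-of-revolution
        integral of the analytic truncated ellipsoid to < 0.1%."""
        d, lam = params.focal_length, params.lambda_endo
        oracle, _ = quad(
            lambda mu: np.pi
            * (d * np.sinh(lam) * np.sin(mu)) ** 2
            * (d * np.cosh(lam) * np.sin(mu)),
            0.0,
            params.base_truncation_mu,
        )
        assert cavity_volume(mesh) == pytest.approx(oracle, rel=1e-3)
        assert params.cavity_volume_closed_form() == pytest.approx(oracle, rel=1e-10)

    def test_wall_volume_consistent_with_outer_minus_cavity(self, mesh):
        assert wall_volume(mesh) == pytest.approx(
            outer_volume(mesh) - cavity_volume(mesh), rel=1e-6
        )

    def test_hemi_ellipsoid_closed_form(self):
        """A mesh truncated just past the equator approaches the hemi-
        ellipsoid volume 2/3 pi a b^2 as mu_base -> pi/2."""
        a_semi, b_semi = 10.0, 5.0
        mu_b = np.pi / 2 + 1e-4
        la = a_semi * (1 - np.cos(mu_b))
        p = GeometryParams(la, 2 * b_semi, 1.5, base_truncation_mu=mu_b)
        v = cavity_volume(build_lv_mesh(p))
        assert v == pytest.approx(2.0 / 3.0 * np.pi * a_semi * b_semi**2, rel=1e-3)

    def test_isotropic_scaling_law(self, mesh):
        big = mesh.scaled(2.0)
        assert cavity_volume(big) == pytest.approx(8 * cavity_volume(mesh), rel=1e-12)
        assert wall_volume(big) == pytest.approx(8 * wall_volume(mesh), rel=1e-12)
        m0, m1 = lv_metrics(mesh), lv_metrics(big)
        assert m1.long_axis == pytest.approx(2 * m0.long_axis, rel=1e-12)
        assert m1.short_axis == pytest.approx(2 * m0.short_axis, rel=1e-12)


class TestInterpolation:
    def test_corner_reproduces_nodal_value(self, mesh):
        # element 0 corner (0,0,0): apex endocardial node
        x = mesh.evaluate_field(0, (0.0, 0.0, 0.0))
        assert x[0] == pytest.approx(mesh.dofs[0, 0, 1, 0], abs=1e-14)  # Z value
        assert np.hypot(x[1], x[2]) == pytest.approx(mesh.dofs[0, 0, 0, 0], abs=1e-14)

    def test_c1_continuity_across_elements(self, mesh):
        """Value and first parametric derivative agree across shared edges."""
        for (ea, eb) in [(0 * 4 + 1, 1 * 4 + 1), (2 * 4 + 2, 3 * 4 + 2)]:
            for d1, d2 in [(0, 0), (1, 0), (0, 1)]:
                ra, za = mesh.meridian(ea, 1.0, 0.37, d1=d1, d2=d2)
                rb, zb = mesh.meridian(eb, 0.0, 0.37, d1=d1, d2=d2)
                assert ra[0] == pytest.approx(rb[0], rel=1e-8, abs=1e-10)
                assert za[0] == pytest.approx(zb[0], rel=1e-8, abs=1e-10)

    def test_cubic_field_reproduced_exactly(self, mesh, rng):
        """A bicubic Hermite field whose DOFs encode a separable cubic of the
        global coordinates is interpolated exactly at interior points."""

        def f(x1, x2):  # cubic in x1 times cubic in x2
            return (x1**3 - 2 * x1 + 1) * (2 * x2**3 + x2**2 - 1)

        def fd1(x1, x2):
            return (3 * x1**2 - 2) * (2 * x2**3 + x2**2 - 1)

        def fd2(x1, x2):
            return (x1**3 - 2 * x1 + 1) * (6 * x2**2 + 2 * x2)

        def fd12(x1, x2):
            return (3 * x1**2 - 2) * (6 * x2**2 + 2 * x2)

        g1 = np.linspace(0, 1, 6)[:, None]
        g2 = np.linspace(0, 1, 5)[None, :]
        nodal = np.stack(
            [f(g1, g2), fd1(g1, g2), fd2(g1, g2), fd12(g1, g2)], axis=-1
        )
        for _ in range(20):
            e = rng.integers(0, 20)
            s, t = rng.uniform(0, 1, 2)
            e1, e2 = e // 4, e % 4
            x1, x2 = (e1 + s) / 5, (e2 + t) / 4
            val = mesh.interpolate(nodal, int(e), s, t)
            assert val[0] == pytest.approx(f(x1, x2), rel=1e-12, abs=1e-12)

    def test_out_of_range_local_coordinates_rejected(self, mesh):
        with pytest.raises(ValueError):
            mesh.evaluate_field(0, (1.5, 0.0, 0.0))

    def test_axisymmetry_of_physical_points(self, mesh):
        """Radius and axial position are independent of the circumferential
        coordinate."""
        pts = [mesh.evaluate_field(5, (0.3, 0.7, u)) for u in np.linspace(0, 1, 7)]
        radii = [np.hypot(p[1], p[2]) for p in pts]
        axial = [p[0] for p in pts]
        assert np.ptp(radii) < 1e-10 * radii[0]
        assert np.ptp(axial) < 1e-10 * abs(axial[0]) + 1e-12


class TestFiberField:
    def test_midwall_angle_is_arithmetic_midpoint(self, mesh):
        ff = fiber_frames_at(mesh, 2, 1, 0.5, 1.0, 83.0, -37.0)  # depth 0.5
        assert ff.angles[0] == pytest.approx(23.0, abs=1e-10)

    def test_linear_transmural_variation(self, mesh):
        ff = assign_fiber_field(mesh, 83.0, -37.0)
        expected = 83.0 * (1 - ff.depth) + (-37.0) * ff.depth
        np.testing.assert_allclose(ff.angles, expected, atol=1e-10)

    def test_zero_angles_give_circumferential_fibers(self, mesh):
        ff = assign_fiber_field(mesh, 0.0, 0.0)
        f = ff.frames[:, :, 0]
        r = ff.frames[:, :, 2]
        np.testing.assert_allclose(np.abs(f[:, 2]), 1.0, atol=1e-12)  # e_phi
        np.testing.assert_allclose(np.einsum("ni,ni->n", f, r), 0.0, atol=1e-12)

    def test_frames_orthonormal_right_handed(self, mesh, rng):
        for endo, epi in [(83.0, -37.0), (45.0, -10.0), (70.0, 20.0)]:
            ff = assign_fiber_field(mesh, endo, epi)
            Q = ff.frames
            gram = np.einsum("nij,nik->njk", Q, Q)
            assert np.max(np.abs(gram - np.eye(3))) < 1e-12
            np.testing.assert_allclose(np.linalg.det(Q), 1.0, atol=1e-12)

    def test_angle_range_guard(self, mesh):
        with pytest.raises(ValueError):
            assign_fiber_field(mesh, 95.0, -37.0)


class TestShapeVariants:
    def test_wall_thickness_scale(self, mesh):
        v = make_shape_variant(mesh, ShapeVariantSpec("wall_thickness_scale", 0.30))
        m0, m1 = lv_metrics(mesh), lv_metrics(v)
        assert m1.wall_thickness == pytest.approx(1.30 * m0.wall_thickness, rel=0.01)
        # epicardium-only move leaves the cavity untouched
        assert m1.cavity_volume == pytest.approx(m0.cavity_volume, rel=1e-9)

    def test_zero_scale_is_identity(self, mesh):
        v = make_shape_variant(mesh, ShapeVariantSpec("wall_thickness_scale", 0.0))
        np.testing.assert_array_equal(v.dofs, mesh.dofs)

    def test_aspect_ratio_scale_preserves_cavity(self, mesh):
        v = make_shape_variant(mesh, ShapeVariantSpec("aspect_ratio_scale", 0.20))
        m0, m1 = lv_metrics(mesh), lv_metrics(v)
        ar0 = m0.long_axis / m0.short_axis
        ar1 = m1.long_axis / m1.short_axis
        assert ar1 == pytest.approx(1.20 * ar0, rel=1e-3)
        assert m1.cavity_volume == pytest.approx(m0.cavity_volume, rel=5e-3)


class TestMeasurement:
    def test_echo_dimensions_orderings(self, mesh):
        d = measure_echo_dimensions(mesh)
        assert d["outer_width_base"] > d["inner_width_base"]
        assert d["outer_width_mid"] > d["inner_width_mid"]
        assert d["outer_length"] > d["inner_length"]
        assert d["inner_width_mid"] >= d["inner_width_base"]


def test_prolate_coordinates_cartesian_map():
    p = ProlateCoords(lambda_=0.8, mu=np.pi / 2, phi=0.0, focal_length=10.0)
    x = p.to_cartesian()
    assert x[0] == pytest.approx(0.0, abs=1e-12)
    assert x[1] == pytest.approx(10.0 * np.sinh(0.8))
    with pytest.raises(ValueError):
        ProlateCoords(lambda_=-1.0, mu=0.1, phi=0.0, focal_length=10.0)
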