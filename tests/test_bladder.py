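"""Ellipse/ellipsoid quadratic forms, silhouette projection and volumes."""

import math

import numpy as np
import pytest
from skimage.draw import ellipse as draw_ellipse

from conftest import random_spd_quadric, silhouette_extent_oracle
from mirrorwell.bladder import (
    Ellipse2D,
    Ellipsoid3D,
    bladder_volume,
    canonicalize,
    dice,
    ellipse_form,
    ellipsoid_form,
    fit_ellipse,
    fit_ellipsoid,
    project_form,
    rotation_matrix,
)
from mirrorwell.bladder import _ellipse_from_form
from mirrorwell.errors import FitError, GeometryError
from mirrorwell.geometry import WorldPoint


def silhouettes(E: Ellipsoid3D) -> tuple[Ellipse2D, Ellipse2D]:
    M = ellipsoid_form(E)
    top = _ellipse_from_form(project_form(M, "z"), (E.center.x, E.center.y))
    side = _ellipse_from_form(project_form(M, "y"), (E.center.x, E.center.z))
    return top, side


class TestFitEllipse:
    def test_axis_aligned_render_roundtrip(self):
        mask = np.zeros((80, 100), np.uint8)
        rr, cc = draw_ellipse(40, 50, 10, 20, shape=mask.shape)
        mask[rr, cc] = 1
        e = fit_ellipse(mask)
        assert abs(e.j - 20) < 0.5 and abs(e.k - 10) < 0.5
        assert min(e.phi, math.pi - e.phi) < 0.05

    def test_circle_any_phi(self):
        mask = np.zeros((64, 64), np.uint8)
        rr, cc = draw_ellipse(32, 32, 15, 15, shape=mask.shape)
        mask[rr, cc] = 1
        e = fit_ellipse(mask)
        assert abs(e.j - 15) < 0.5 and abs(e.k - 15) < 0.5

    def test_pixel_size_scaling(self):
        mask = np.zeros((64, 64), np.uint8)
        rr, cc = draw_ellipse(32, 32, 8, 16, shape=mask.shape)
        mask[rr, cc] = 1
        e = fit_ellipse(mask, pixel_size=0.01)
        assert e.j == pytest.approx(0.16, abs=0.005)

    def test_tiny_mask_rejected(self):
        mask = np.zeros((10, 10), np.uint8)
        mask[5, 3:6] = 1  # 3 pixels
        with pytest.raises(FitError):
            fit_ellipse(mask)


class TestQuadraticForms:
    def test_unit_circle_is_identity(self):
        e = Ellipse2D((0, 0), 1.0, 1.0, 0.0)
        np.testing.assert_allclose(ellipse_form(e), np.eye(2), atol=1e-15)

    def test_axis_aligned_diagonal(self):
        e = Ellipse2D((0, 0), 2.0, 1.0, 0.0)
        np.testing.assert_allclose(ellipse_form(e), np.diag([0.25, 1.0]), atol=1e-15)

    def test_quarter_turn_swaps_axes(self):
        e = Ellipse2D((0, 0), 2.0, 1.0, math.pi / 2)
        np.testing.assert_allclose(ellipse_form(e), np.diag([1.0, 0.25]), atol=1e-15)

    def test_unit_sphere_is_identity(self):
        E = Ellipsoid3D(WorldPoint(0, 0, 0), 1, 1, 1)
        np.testing.assert_allclose(ellipsoid_form(E), np.eye(3), atol=1e-15)

    def test_axis_aligned_ellipsoid_diagonal(self):
        E = Ellipsoid3D(WorldPoint(0, 0, 0), 2, 1, 1)
        np.testing.assert_allclose(
            ellipsoid_form(E), np.diag([0.25, 1, 1]), atol=1e-15
        )

    def test_eigenvalues_are_inverse_square_axes(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            a, b, c = np.sort(rng.uniform(0.05, 0.5, 3))[::-1]
            E = Ellipsoid3D(
                WorldPoint(0, 0, 0), a, b, c,
                phi=rng.uniform(-3, 3), psi=rng.uniform(-3, 3), theta=rng.uniform(-3, 3),
            )
            vals = np.sort(np.linalg.eigvalsh(ellipsoid_form(E)))
            np.testing.assert_allclose(
                vals, sorted([1 / a**2, 1 / b**2, 1 / c**2]), rtol=1e-10
            )

    def test_rotation_order_is_printed_product(self):
        phi, psi, theta = 0.3, -0.8, 1.1
        cph, sph = math.cos(phi), math.sin(phi)
        cps, sps = math.cos(psi), math.sin(psi)
        cth, sth = math.cos(theta), math.sin(theta)
        Rx = np.array([[1, 0, 0], [0, cph, -sph], [0, sph, cph]])
        Rz = np.array([[cps, -sps, 0], [sps, cps, 0], [0, 0, 1]])
        Ry = np.array([[cth, 0, sth], [0, 1, 0], [-sth, 0, cth]])
        np.testing.assert_allclose(
            rotation_matrix(phi, psi, theta), Rx @ Rz @ Ry, atol=1e-15
        )
        np.testing.assert_allclose(
            rotation_matrix(phi, psi, theta, order="xyz"),
            Rx @ np.array([[cps, 0, sps], [0, 1, 0], [-sps, 0, cps]])
            @ np.array([[cth, -sth, 0], [sth, cth, 0], [0, 0, 1]]),
            atol=1e-15,
        )

    def test_canonicalize_preserves_form_and_sorts_axes(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            axes = rng.uniform(0.05, 0.5, 3)
            E = Ellipsoid3D(
                WorldPoint(0, 0, 0), *axes,
                phi=rng.uniform(-3, 3), psi=rng.uniform(-3, 3), theta=rng.uniform(-3, 3),
            )
            C = canonicalize(E)
            assert C.a >= C.b >= C.c
            np.testing.assert_allclose(
                ellipsoid_form(C), ellipsoid_form(E), atol=1e-9
            )


class TestProjectForm:
    def test_axis_aligned_drops_cleanly(self):
        M = np.diag([1 / 4.0, 1.0, 1 / 9.0])
        np.testing.assert_allclose(project_form(M, "z"), np.diag([0.25, 1.0]))

    def test_sphere_projects_to_circle(self):
        M = np.eye(3) / 0.3**2
        for axis in "xyz":
            np.testing.assert_allclose(project_form(M, axis), np.eye(2) / 0.3**2)

    def test_silhouette_matches_brute_force_fan(self):
        rng = np.random.default_rng(3)
        angles = np.arange(0.0, 360.0, 12.0)
        for _ in range(10):
            M, _ = random_spd_quadric(rng)
            for axis in ("z", "y"):
                P = project_form(M, axis)
                extents, dirs = silhouette_extent_oracle(M, axis, angles)
                on_ellipse = np.einsum(
                    "ni,ij,nj->n", dirs * extents[:, None], P, dirs * extents[:, None]
                )
                np.testing.assert_allclose(on_ellipse, 1.0, atol=1e-6)

    def test_non_spd_rejected(self):
        with pytest.raises(GeometryError):
            project_form(np.diag([1.0, -1.0, 1.0]), "z")


class TestFitEllipsoid:
    def test_two_circles_give_sphere(self):
        r = 0.25
        circle_top = Ellipse2D((0.0, 0.0), r, r, 0.0)
        circle_side = Ellipse2D((0.0, 6.0), r, r, 0.0)
        res = fit_ellipsoid(circle_top, circle_side)
        assert res.objective < 1e-8
        E = res.ellipsoid
        assert (E.a, E.b, E.c) == pytest.approx((r, r, r), rel=1e-4)

    def test_axis_aligned_roundtrip_volume(self):
        truth = Ellipsoid3D(WorldPoint(0.2, -0.1, 6.0), 0.30, 0.18, 0.15)
        res = fit_ellipsoid(*silhouettes(truth))
        assert res.objective < 1e-6
        assert res.ellipsoid.volume == pytest.approx(truth.volume, rel=0.02)

    def test_inconsistent_shared_extent_warns_but_fits(self):
        top = Ellipse2D((0.0, 0.0), 0.2, 0.1, 0.0)  # x-extent 0.4 mm
        side = Ellipse2D((0.0, 6.0), 0.15, 0.1, math.pi / 2)  # x-extent 0.2 mm
        res = fit_ellipsoid(top, side)
        assert any("shared_extent_mismatch" in w for w in res.warnings)
        assert res.ellipsoid.a > 0

    def test_center_fused_from_both_views(self):
        truth = Ellipsoid3D(WorldPoint(0.4, -0.2, 5.5), 0.3, 0.2, 0.15)
        res = fit_ellipsoid(*silhouettes(truth))
        c = res.ellipsoid.center
        assert (c.x, c.y, c.z) == pytest.approx((0.4, -0.2, 5.5), abs=1e-9)


class TestBladderVolume:
    def test_reference_height_unit_sphere(self, view_geom, well_geom):
        E = Ellipsoid3D(WorldPoint(0, 0, 6), 1.0, 1.0, 1.0)
        vol, scale = bladder_volume(E, view_geom.focal_plane_z, view_geom, well_geom)
        assert scale == 1.0
        assert vol == pytest.approx(4.18879, abs=1e-4)

    def test_height_scale_matches_thin_lens_arithmetic(self, view_geom, well_geom):
        E = Ellipsoid3D(WorldPoint(0, 0, 6), 0.3, 0.2, 0.15)
        z = view_geom.focal_plane_z + 6.0  # closer to the top camera
        vol, scale = bladder_volume(E, z, view_geom, well_geom)
        f = view_geom.focal_length
        d_ref = view_geom.nominal_object_distance
        expected = (d_ref - 6.0 - f) / (d_ref - f)
        assert scale == pytest.approx(expected, rel=1e-12)
        assert scale < 1.0  # closer objects image larger, so true size is smaller
        assert vol == pytest.approx(E.volume * expected**3, rel=1e-12)

    def test_volume_rotation_invariant(self, view_geom, well_geom):
        rng = np.random.default_rng(4)
        base = None
        for _ in range(5):
            E = Ellipsoid3D(
                WorldPoint(0, 0, 6), 0.3, 0.2, 0.15,
                phi=rng.uniform(-3, 3), psi=rng.uniform(-3, 3), theta=rng.uniform(-3, 3),
            )
            vol, _ = bladder_volume(E, 6.0, view_geom, well_geom)
            base = vol if base is None else base
            assert vol == pytest.approx(base, rel=1e-12)

    def test_height_outside_well_rejected(self, view_geom, well_geom):
        E = Ellipsoid3D(WorldPoint(0, 0, 6), 0.3, 0.2, 0.15)
        with pytest.raises(GeometryError):
            bladder_volume(E, 13.0, view_geom, well_geom)


class TestDice:
    def test_identical_masks(self):
        m = np.zeros((10, 10), bool)
        m[2:5, 2:5] = True
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((10, 10), bool)
        b = np.zeros((10, 10), bool)
        a[:2], b[5:] = True, True
        assert dice(a, b) == 0.0

    def test_half_overlap(self):
        a = np.zeros((20, 20), bool)
        b = np.zeros((20, 20), bool)
        a[:10].flat[:100] = True
        a = np.zeros((20, 20), bool); a.flat[:100] = True
        b = np.zeros((20, 20), bool); b.flat[50:150] = True
        assert dice(a, b) == pytest.approx(0.5)

    def test_both_empty_convention(self):
        z = np.zeros((5, 5), bool)
        assert dice(z, z) == 1.0

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(5)
        a = rng.random((16, 16)) > 0.5
        b = rng.random((16, 16)) > 0.5
        assert dice(a, b) == dice(b, a)
        assert 0.0 <= dice(a, b) <= 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice(np.zeros((3, 3)), np.zeros((4, 4)))
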