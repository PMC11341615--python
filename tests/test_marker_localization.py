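"""Two-view triangulation, single-view nadir localization, reprojection."""

import numpy as np
import pytest
from scipy.optimize import minimize, minimize_scalar

from fluoroacc import (
    CArmGeometry,
    DegenerateConfigurationError,
    DetectorPoint,
    Point3D,
    ProjectionLine,
    backproject,
    closest_points_between_lines,
    nadir_on_line,
    project_point,
    reprojection_error,
    triangulate_pair,
)

from conftest import random_geometry


def _random_line(rng):
    d = rng.normal(size=3)
    d /= np.linalg.norm(d)
    return ProjectionLine(Point3D.from_array(rng.uniform(-100, 100, 3)), d)


def _brute_force_closest(a, b):
    """Independent oracle: numerical minimization of the squared distance
    over the two line parameters."""

    def cost(x):
        pa = a.origin.as_array() + x[0] * a.direction
        pb = b.origin.as_array() + x[1] * b.direction
        return np.sum((pa - pb) ** 2)

    res = minimize(cost, x0=[0.0, 0.0], method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-20, "maxiter": 20000})
    return np.sqrt(res.fun)


class TestClosestPoints:
    def test_common_perpendicular(self):
        a = ProjectionLine(Point3D(0, 0, 0), np.array([1.0, 0, 0]))
        b = ProjectionLine(Point3D(0, 1, 0), np.array([0.0, 0, 1.0]))
        n = closest_points_between_lines(a, b)
        np.testing.assert_allclose(n.nadir_a.as_array(), [0, 0, 0], atol=1e-12)
        np.testing.assert_allclose(n.nadir_b.as_array(), [0, 1, 0], atol=1e-12)
        assert n.gap_mm == pytest.approx(1.0)
        np.testing.assert_allclose(n.midpoint.as_array(), [0, 0.5, 0], atol=1e-12)

    def test_intersecting_lines_gap_zero(self):
        a = ProjectionLine(Point3D(-1, -1, 0), np.array([1.0, 1.0, 0]) / np.sqrt(2))
        b = ProjectionLine(Point3D(1, -1, 0), np.array([-1.0, 1.0, 0]) / np.sqrt(2))
        n = closest_points_between_lines(a, b)
        assert n.gap_mm == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(n.nadir_a.as_array(), n.nadir_b.as_array(), atol=1e-12)

    def test_parallel_lines_rejected(self):
        d = np.array([1.0, 0, 0])
        with pytest.raises(DegenerateConfigurationError, match="deg"):
            closest_points_between_lines(
                ProjectionLine(Point3D(0, 0, 0), d), ProjectionLine(Point3D(0, 1, 0), d)
            )

    def test_matches_brute_force_on_random_pairs(self, rng):
        for _ in range(100):
            a, b = _random_line(rng), _random_line(rng)
            n = closest_points_between_lines(a, b)
            assert n.gap_mm == pytest.approx(_brute_force_closest(a, b), abs=1e-6)

    def test_segment_orthogonal_to_both_lines(self, rng):
        for _ in range(20):
            a, b = _random_line(rng), _random_line(rng)
            n = closest_points_between_lines(a, b)
            seg = n.nadir_b.as_array() - n.nadir_a.as_array()
            if n.gap_mm > 1e-9:
                seg /= n.gap_mm
                assert abs(seg @ a.direction) < 1e-9
                assert abs(seg @ b.direction) < 1e-9


class TestTriangulation:
    def test_noiseless_recovery(self, ap_geometry, lao60_geometry):
        p = Point3D(12, -7, 30)
        loc = triangulate_pair(
            ap_geometry,
            project_point(ap_geometry, p),
            lao60_geometry,
            project_point(lao60_geometry, p),
        )
        assert loc.p_pair.distance_to(p) < 1e-9
        assert loc.nadirs.gap_mm < 1e-9
        assert loc.angular_separation_deg == pytest.approx(60.0)

    def test_random_noiseless_recovery(self, rng):
        for _ in range(20):
            g1, g2 = random_geometry(rng), random_geometry(rng)
            p = Point3D.from_array(rng.uniform(-80, 80, 3))
            try:
                loc = triangulate_pair(
                    g1, project_point(g1, p), g2, project_point(g2, p),
                    warn_angle_deg=0.0,
                )
            except DegenerateConfigurationError:
                continue
            assert loc.p_pair.distance_to(p) < 1e-9

    def test_noisy_pair_matches_two_line_oracle(self, ap_geometry, lao60_geometry, rng):
        p = Point3D(12, -7, 30)
        for _ in range(10):
            d1 = project_point(ap_geometry, p)
            d2 = project_point(lao60_geometry, p)
            d1n = DetectorPoint(d1.u_mm + rng.uniform(-0.1, 0.1), d1.v_mm + rng.uniform(-0.1, 0.1))
            d2n = DetectorPoint(d2.u_mm + rng.uniform(-0.1, 0.1), d2.v_mm + rng.uniform(-0.1, 0.1))
            loc = triangulate_pair(ap_geometry, d1n, lao60_geometry, d2n)
            oracle = closest_points_between_lines(
                backproject(ap_geometry, d1n), backproject(lao60_geometry, d2n)
            )
            assert loc.p_pair.distance_to(oracle.midpoint) < 1e-6

    def test_identical_geometries_rejected(self, ap_geometry):
        with pytest.raises(DegenerateConfigurationError):
            triangulate_pair(
                ap_geometry, DetectorPoint(0, 0), ap_geometry, DetectorPoint(1, 0)
            )

    def test_small_separation_warns(self):
        g1 = CArmGeometry(1200, 800, primary_deg=0.0)
        g2 = CArmGeometry(1200, 800, primary_deg=10.0)
        p = Point3D(5, 5, 5)
        with pytest.warns(UserWarning, match="angular separation"):
            triangulate_pair(g1, project_point(g1, p), g2, project_point(g2, p))

    def test_precision_degrades_at_small_separation(self, rng):
        """Mean 3D error under fixed detector noise shrinks as the views
        move apart."""
        p = Point3D(5, -3, 10)
        mean_err = []
        for sep in (10.0, 30.0, 60.0, 90.0):
            g1 = CArmGeometry(1200, 800, primary_deg=-sep / 2)
            g2 = CArmGeometry(1200, 800, primary_deg=sep / 2)
            errs = []
            local = np.random.default_rng(1234)
            for _ in range(200):
                d1 = project_point(g1, p)
                d2 = project_point(g2, p)
                d1 = DetectorPoint(*(d1.as_array() + local.normal(0, 0.1, 2)))
                d2 = DetectorPoint(*(d2.as_array() + local.normal(0, 0.1, 2)))
                loc = triangulate_pair(g1, d1, g2, d2, warn_angle_deg=0.0)
                errs.append(loc.p_pair.distance_to(p))
            mean_err.append(np.mean(errs))
        assert all(a >= b for a, b in zip(mean_err, mean_err[1:]))


class TestReprojectionError:
    def test_consistent_point_has_zero_error(self, ap_geometry):
        p = Point3D(7, 13, -4)
        assert reprojection_error(ap_geometry, p, project_point(ap_geometry, p)) == 0.0

    def test_perpendicular_displacement_magnified(self, ap_geometry):
        d0 = project_point(ap_geometry, Point3D(0, 0, 0))
        err = reprojection_error(ap_geometry, Point3D(1, 0, 0), d0)
        assert err == pytest.approx(1.5, rel=0.01)

    def test_view_axis_displacement_nearly_invisible(self, ap_geometry, rng):
        for _ in range(10):
            p = Point3D.from_array(rng.uniform(-50, 50, 3) * [1, 0, 1])
            d0 = project_point(ap_geometry, p)
            moved = Point3D(p.x, p.y + 1.0, p.z)
            assert reprojection_error(ap_geometry, moved, d0) <= 0.2


class TestNadirOnLine:
    def test_point_on_line(self):
        line = ProjectionLine(Point3D(0, 0, 0), np.array([1.0, 0, 0]))
        nadir, dist = nadir_on_line(line, Point3D(5, 0, 0))
        assert dist == 0.0
        np.testing.assert_allclose(nadir.as_array(), [5, 0, 0])

    def test_3_4_5_triangle(self):
        line = ProjectionLine(Point3D(0, 0, 0), np.array([1.0, 0, 0]))
        nadir, dist = nadir_on_line(line, Point3D(3, 4, 0))
        np.testing.assert_allclose(nadir.as_array(), [3, 0, 0])
        assert dist == pytest.approx(4.0)

    def test_matches_1d_brute_force(self, rng):
        for _ in range(100):
            line = _random_line(rng)
            q = Point3D.from_array(rng.uniform(-100, 100, 3))

            def cost(t):
                return np.linalg.norm(q.as_array() - line.point_at(t).as_array())

            res = minimize_scalar(cost, bounds=(-1000, 1000), method="bounded",
                                  options={"xatol": 1e-12})
            _, dist = nadir_on_line(line, q)
            assert dist == pytest.approx(res.fun, abs=1e-9)

    def test_nadir_optimality(self, rng):
        line = _random_line(rng)
        q = Point3D.from_array(rng.uniform(-50, 50, 3))
        nadir, dist = nadir_on_line(line, q)
        for t in rng.uniform(-200, 200, 50):
            assert dist <= np.linalg.norm(q.as_array() - line.point_at(t).as_array()) + 1e-12

    def test_single_view_underestimates_true_error(self, ap_geometry, rng):
        """If the marker truly sits on the back-projected ray, the nadir
        distance to a reference never exceeds the true 3D distance."""
        for _ in range(50):
            m = Point3D.from_array(rng.uniform(-60, 60, 3))
            q = Point3D.from_array(rng.uniform(-60, 60, 3))
            line = backproject(ap_geometry, project_point(ap_geometry, m))
            _, dist = nadir_on_line(line, q)
            assert dist <= m.distance_to(q) + 1e-9
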