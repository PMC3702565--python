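"""Principal-curve construction: projection, binning, fitting, arc length."""

import numpy as np
import pytest

from pathpmf import (
    Conformation,
    PathNodes,
    arc_length,
    bin_and_average,
    fit_curve,
    line_project,
    reparametrize,
    tangent,
)
from pathpmf.pathway import PathCurve
from pathpmf.toysim import SyntheticEnsembleSpec, make_synthetic_ensemble


class TestLineProject:
    def test_endpoints(self, rng):
        a, b = rng.normal(size=12), rng.normal(size=12)
        assert line_project(a, a, b) == pytest.approx(0.0, abs=1e-12)
        assert line_project(b, a, b) == pytest.approx(1.0, abs=1e-12)

    def test_perpendicular_offset_ignored(self, rng):
        a, b = np.zeros(6), np.zeros(6)
        b[0] = 2.0
        x = 0.5 * (a + b)
        x[1] += 3.7  # perpendicular to the line
        assert line_project(x, a, b) == pytest.approx(0.5, abs=1e-12)

    def test_matches_grid_search(self, rng):
        a, b = rng.normal(size=12), rng.normal(size=12)
        x = rng.normal(size=12)
        lam = line_project(x, a, b)
        grid = np.arange(-3.0, 3.0, 1e-5)
        dists = np.linalg.norm(
            x[None, :] - a[None, :] - grid[:, None] * (b - a)[None, :], axis=1
        )
        assert lam == pytest.approx(grid[np.argmin(dists)], abs=2e-5)

    def test_degenerate_line(self):
        a = np.ones(6)
        with pytest.raises(ValueError, match="degenerate"):
            line_project(a, a, a)

    def test_accepts_conformations(self, asym_points):
        b = Conformation(asym_points.coords + 1.0)
        assert line_project(asym_points, asym_points, b) == pytest.approx(0.0)


class TestBinAndAverage:
    def test_one_frame_per_bin(self):
        a, b = np.zeros(6), np.zeros(6)
        b[0] = 1.0
        lam = (np.arange(100) + 0.5) / 100
        frames = a[None, :] + lam[:, None] * (b - a)[None, :]
        nodes = bin_and_average([frames], a, b, n_bins=100)
        assert len(nodes) == 100
        np.testing.assert_allclose(nodes.nodes, frames, atol=1e-12)
        assert np.all(nodes.counts == 1)

    def test_symmetric_offsets_cancel(self):
        a, b = np.zeros(4), np.zeros(4)
        b[0] = 1.0
        lam = (np.arange(10) + 0.5) / 10
        on_line = a[None, :] + lam[:, None] * (b - a)[None, :]
        off = np.zeros_like(on_line)
        off[:, 1] = 0.8
        frames = np.concatenate([on_line + off, on_line - off])
        nodes = bin_and_average([frames], a, b, n_bins=10)
        np.testing.assert_allclose(nodes.nodes, on_line, atol=1e-12)
        assert np.all(nodes.counts == 2)

    def test_recovers_generating_arc(self):
        """Bin averages track the known circular path within sampling error."""
        spec = SyntheticEnsembleSpec(
            a=np.array([-5.0, 0.0]), b=np.array([5.0, 0.0]),
            shape="arc", bulge=2.5, sigma=0.5, n_frames=5000, seed=3,
        )
        frames = make_synthetic_ensemble(spec)
        nodes = bin_and_average([frames], spec.a, spec.b, n_bins=50, min_count=5)
        dense = spec.path(np.linspace(0, 1, 3000))
        for node, count in zip(nodes.nodes, nodes.counts):
            dist = np.min(np.linalg.norm(dense - node, axis=1))
            se = 3.0 * spec.sigma / np.sqrt(count)
            assert dist < max(3.0 * se, 0.15)

    def test_zero_range_error(self):
        a, b = np.zeros(6), np.ones(6)
        frames = np.tile(a, (5, 1))
        with pytest.raises(ValueError, match="range"):
            bin_and_average([frames], a, b, n_bins=10)

    def test_empty_bins_dropped(self):
        a, b = np.zeros(3), np.array([1.0, 0.0, 0.0])
        # frames only near the two ends: middle bins are empty
        lam = np.concatenate([np.linspace(0, 0.1, 20), np.linspace(0.9, 1.0, 20)])
        frames = a[None, :] + lam[:, None] * (b - a)[None, :]
        nodes = bin_and_average([frames], a, b, n_bins=20)
        assert len(nodes) < 20
        assert np.all(nodes.counts >= 1)


class TestFitCurve:
    def test_collinear_nodes_give_straight_segment(self):
        nodes = PathNodes(np.linspace([1.0, 1, 1], [4.0, 5, 1], 25),
                          np.ones(25, dtype=int))
        curve = fit_curve(nodes, P=1)
        assert np.abs(curve.c).max() < 1e-8
        np.testing.assert_allclose(curve(0.0), [1, 1, 1], atol=1e-9)
        np.testing.assert_allclose(curve(1.0), [4, 5, 1], atol=1e-9)

    def test_exact_recovery_of_basis_curve(self, rng):
        """Nodes sampled exactly from a + b t + c sin(pi t) are reproduced."""
        d = 6
        a = rng.normal(size=d)
        b = rng.normal(size=d)
        c = rng.normal(size=d)
        t = np.linspace(0, 1, 25)
        pts = a + np.multiply.outer(t, b) + np.multiply.outer(np.sin(np.pi * t), c)
        curve, info = fit_curve(PathNodes(pts, np.ones(25, dtype=int)), P=1,
                                return_info=True)
        assert info["objective"] < 1e-10
        np.testing.assert_allclose(curve.a, a, atol=1e-6)
        np.testing.assert_allclose(curve.b, b, atol=1e-6)
        np.testing.assert_allclose(curve.c[:, 0], c, atol=1e-6)

    def test_protein_scale_configuration_converges(self, rng):
        """P = 1 with 100 nodes in a high-dimensional space fits cleanly."""
        d = 90
        a = rng.normal(size=d)
        b = rng.normal(size=d, scale=3.0)
        c = rng.normal(size=d)
        t = np.linspace(0, 1, 100)
        pts = (a + np.multiply.outer(t, b)
               + np.multiply.outer(np.sin(np.pi * t), c)
               + rng.normal(0, 0.05, (100, d)))
        curve, info = fit_curve(PathNodes(pts, np.ones(100, dtype=int)), P=1,
                                return_info=True)
        # residual consistent with the injected noise level
        assert info["objective"] < 2 * 100 * d * 0.05**2

    def test_objective_non_increasing(self, rng):
        pts = rng.normal(size=(20, 4)).cumsum(axis=0)  # a rough ordered path
        _, info = fit_curve(PathNodes(pts, np.ones(20, dtype=int)), P=2,
                            return_info=True)
        trace = info["objective_trace"]
        assert all(x >= y - 1e-12 for x, y in zip(trace[:-1], trace[1:]))

    def test_too_few_nodes(self):
        nodes = PathNodes(np.zeros((3, 3)) + np.arange(3)[:, None],
                          np.ones(3, dtype=int))
        with pytest.raises(ValueError, match="nodes"):
            fit_curve(nodes, P=5)
        with pytest.raises(ValueError, match="non-negative"):
            fit_curve(nodes, P=-1)


class TestArcLength:
    def test_straight_segment(self, straight_curve):
        assert straight_curve.length == pytest.approx(5.0, rel=1e-9)
        assert arc_length(straight_curve, 0.0) == 0.0

    def test_semicircle_length(self, semicircle_curve):
        assert semicircle_curve.length == pytest.approx(np.pi, rel=1e-5)

    def test_matches_dense_polyline(self, semicircle_curve):
        t = np.linspace(0, 1, 1_000_001)
        pts = semicircle_curve(t)
        poly = np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1))
        assert semicircle_curve.length == pytest.approx(poly, rel=1e-6)

    def test_out_of_range(self, straight_curve):
        with pytest.raises(ValueError):
            arc_length(straight_curve, 1.5)


class TestReparametrize:
    def test_straight_segment_fixed_point(self, straight_curve):
        grid = np.linspace(0, 1, 51)
        again = reparametrize(straight_curve)
        np.testing.assert_allclose(again(grid), straight_curve(grid), atol=1e-10)

    def test_stretched_segment_midpoint(self):
        """A quadratically stretched straight line regains its geometric midpoint."""
        t = np.linspace(0, 1, 40)
        pts = np.zeros((40, 3))
        pts[:, 0] = 10.0 * t**2  # uneven spacing along x
        curve = fit_curve(PathNodes(pts, np.ones(40, dtype=int)), P=3)
        uniform = reparametrize(curve)
        np.testing.assert_allclose(uniform(0.5), [5.0, 0, 0], atol=1e-3)

    def test_constant_speed(self, semicircle_curve):
        alphas = np.linspace(1e-4, 1 - 1e-4, 1001)
        h = 1e-6
        speeds = np.linalg.norm(
            (semicircle_curve(alphas + h) - semicircle_curve(alphas - h)) / (2 * h),
            axis=1,
        )
        L = semicircle_curve.length
        assert np.max(np.abs(speeds - L)) < 1e-3 * L

    def test_endpoint_consistency(self, semicircle_curve):
        np.testing.assert_allclose(semicircle_curve(0.0), [1, 0, 0], atol=1e-3)
        np.testing.assert_allclose(semicircle_curve(1.0), [-1, 0, 0], atol=1e-3)


class TestTangent:
    def test_straight_segment(self, straight_curve):
        expected = np.array([3.0, 4.0, 0.0]) / 5.0
        for alpha in (0.0, 0.3, 0.77, 1.0):
            np.testing.assert_allclose(tangent(straight_curve, alpha), expected,
                                       atol=1e-9)

    def test_semicircle_midpoint_perpendicular_to_chord(self, semicircle_curve):
        chord = np.array([-2.0, 0.0, 0.0])
        e = tangent(semicircle_curve, 0.5)
        assert abs(np.linalg.norm(e) - 1.0) < 1e-10
        # tangent at the apex is parallel to the chord for a semicircle
        cosang = abs(e @ chord) / np.linalg.norm(chord)
        assert cosang == pytest.approx(1.0, abs=1e-4)

    def test_matches_finite_difference(self, semicircle_curve, rng):
        h = 1e-6
        for alpha in rng.uniform(h, 1 - h, 100):
            e = tangent(semicircle_curve, alpha)
            fd = (semicircle_curve(alpha + h) - semicircle_curve(alpha - h)) / (2 * h)
            fd /= np.linalg.norm(fd)
            np.testing.assert_allclose(e, fd, atol=1e-5)


class TestPathCurveContainer:
    def test_parameter_range_checked(self, straight_curve):
        with pytest.raises(ValueError):
            straight_curve(1.2)

    def test_zero_mode_curve(self):
        curve = PathCurve(np.zeros(3), np.array([1.0, 0, 0]), np.zeros((3, 0)))
        assert curve.n_modes == 0
        assert curve.length == pytest.approx(1.0)
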