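"""Toy Langevin engine, test potentials, synthetic ensembles, oracles."""

import numpy as np
import pytest

from pathpmf import (
    PathNodes,
    SyntheticEnsembleSpec,
    curved_valley_potential,
    double_well_1d,
    fit_curve,
    make_synthetic_ensemble,
    reference_free_energy,
    reparametrize,
    run_langevin,
)
from pathpmf.toysim import LangevinPropagator, ToyPotential, arc_endpoints


class TestRunLangevin:
    def test_zero_temperature_fixed_point(self):
        pot = double_well_1d(barrier=0.0)  # flat potential
        traj = run_langevin(pot, np.array([0.7]), dt=0.01, gamma=1.0, kT=0.0,
                            n_steps=50, seed=0)
        np.testing.assert_array_equal(traj, np.full((50, 1), 0.7))

    def test_harmonic_equipartition(self):
        """Long harmonic sampling reproduces variance kT/k."""
        k, kT = 4.0, 1.0

        def energy(x):
            return 0.5 * k * float(np.sum(np.square(x)))

        pot = ToyPotential(1, energy, lambda x: k * np.asarray(x), {"k": k})
        traj = run_langevin(pot, np.zeros(1), dt=0.01, gamma=1.0, kT=kT,
                            n_steps=200_000, seed=3)
        var = traj[2000:].var()
        # standard error of the variance with correlation time ~ gamma/(k dt)
        tau = 1.0 / (k * 0.01)
        n_eff = len(traj) / (2 * tau)
        se = np.sqrt(2.0 / n_eff) * (kT / k)
        assert var == pytest.approx(kT / k, abs=3 * se)

    def test_deterministic_given_seed(self):
        pot = double_well_1d()
        t1 = run_langevin(pot, np.zeros(1), 0.01, 1.0, 1.0, 500, seed=11)
        t2 = run_langevin(pot, np.zeros(1), 0.01, 1.0, 1.0, 500, seed=11)
        t3 = run_langevin(pot, np.zeros(1), 0.01, 1.0, 1.0, 500, seed=12)
        np.testing.assert_array_equal(t1, t2)
        assert not np.array_equal(t1, t3)

    def test_bias_forces_added(self, straight_curve):
        from pathpmf import window_layout

        w = window_layout(straight_curve, 3, K=50.0)[1]
        pot = ToyPotential(3, lambda x: 0.0, lambda x: np.zeros(3), {})
        traj = run_langevin(pot, w.anchor + 2.0 * w.tangent, dt=0.01, gamma=1.0,
                            kT=0.0, n_steps=2000, seed=0, extra_bias=w)
        # with kT = 0 the bias drags the walker back to zero displacement
        assert abs(w.displacement(traj[-1])) < 1e-3

    def test_invalid_parameters(self):
        pot = double_well_1d()
        with pytest.raises(ValueError):
            run_langevin(pot, np.zeros(1), dt=0.0, gamma=1.0, kT=1.0,
                         n_steps=10, seed=0)


class TestCurvedValleyPotential:
    def test_floor_energy_zero_without_tilt(self):
        pot = curved_valley_potential()
        r, (th0, th1) = pot.params["radius"], pot.params["theta_range"]
        for th in np.linspace(th0, th1, 17):
            x = np.array([r * np.cos(th), r * np.sin(th)])
            assert pot.energy(x) == pytest.approx(0.0, abs=1e-12)

    def test_gradient_finite_difference(self, rng):
        pot = curved_valley_potential(tilt=3.0, well_k=5.0, dim=3)
        pts = rng.normal(0.0, 2.0, (100, 3)) + np.array([0.0, 4.0, 0.0])
        assert pot.check_gradient(pts) < 1e-5

    def test_tilt_sets_endpoint_difference(self):
        pot = curved_valley_potential(tilt=2.5)
        a, b = arc_endpoints(pot)
        assert pot.energy(b) - pot.energy(a) == pytest.approx(2.5, abs=1e-12)

    def test_extra_dimensions_confined(self):
        pot = curved_valley_potential(dim=4, confine_k=2.0)
        a, _ = arc_endpoints(pot)
        x = a.copy()
        x[2:] = [1.0, 2.0]
        assert pot.energy(x) == pytest.approx(0.5 * 2.0 * 5.0, abs=1e-12)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            curved_valley_potential(radius=-1.0)
        with pytest.raises(ValueError):
            curved_valley_potential(dim=1)


class TestSyntheticEnsemble:
    def test_noise_free_frames_on_path(self):
        spec = SyntheticEnsembleSpec(a=np.zeros(4), b=np.ones(4), shape="sine",
                                     bulge=1.5, sigma=0.0, n_frames=64, seed=0)
        frames = make_synthetic_ensemble(spec)
        expected = spec.path(np.linspace(0, 1, 64))
        np.testing.assert_allclose(frames, expected, atol=1e-14)

    def test_deterministic(self):
        spec = SyntheticEnsembleSpec(a=np.zeros(3), b=np.ones(3), shape="line",
                                     sigma=0.4, n_frames=100, seed=5)
        np.testing.assert_array_equal(
            make_synthetic_ensemble(spec), make_synthetic_ensemble(spec)
        )

    def test_arc_passes_through_endpoints_and_sagitta(self):
        a, b = np.array([-4.0, 0.0]), np.array([4.0, 0.0])
        spec = SyntheticEnsembleSpec(a=a, b=b, shape="arc", bulge=2.0,
                                     sigma=0.0, n_frames=3)
        pts = spec.path(np.array([0.0, 0.5, 1.0]))
        np.testing.assert_allclose(pts[0], a, atol=1e-12)
        np.testing.assert_allclose(pts[2], b, atol=1e-12)
        # midpoint bulges by the sagitta perpendicular to the chord
        assert np.linalg.norm(pts[1] - np.array([0.0, 2.0])) < 1e-12

    def test_pipeline_recovers_generating_arc(self):
        """bin+fit on a noisy arc ensemble lands within sampling error of
        the true path at every retained node."""
        from pathpmf import bin_and_average

        a, b = np.array([-5.0, 0.0]), np.array([5.0, 0.0])
        spec = SyntheticEnsembleSpec(a=a, b=b, shape="arc", bulge=3.0,
                                     sigma=0.5, n_frames=5000, seed=9)
        frames = make_synthetic_ensemble(spec)
        nodes = bin_and_average([frames], a, b, n_bins=40, min_count=10)
        curve = reparametrize(fit_curve(nodes, P=5))
        dense = spec.path(np.linspace(0, 1, 4000))
        pts = curve(np.linspace(0.1, 0.9, 200))
        # recovery is an interior property: the pathway extends beyond the
        # generating path, and end-bin means are biased off the tube centre
        # by the selection effect of binning a path that simply stops
        worst = 0.0
        for p in pts:
            d = np.linalg.norm(dense - p, axis=1)
            j = int(np.argmin(d))
            if len(dense) // 20 <= j <= len(dense) - len(dense) // 20:
                worst = max(worst, d[j])
        # well inside the tube width sigma; node noise plus fit bias
        assert worst < 0.3 * spec.sigma

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            SyntheticEnsembleSpec(a=np.zeros(3), b=np.zeros(2))
        with pytest.raises(ValueError):
            SyntheticEnsembleSpec(a=np.zeros(3), b=np.ones(3), sigma=-1.0)
        with pytest.raises(ValueError):
            SyntheticEnsembleSpec(a=np.zeros(3), b=np.ones(3), shape="spiral")


class TestReferenceFreeEnergy:
    def test_isotropic_harmonic_quadratic_profile(self):
        """Straight curve through an isotropic 2D harmonic well: the
        projected free energy is quadratic with the potential's curvature
        (the perpendicular integral contributes a constant)."""
        k = 2.0
        pot = ToyPotential(
            2,
            lambda x: 0.5 * k * np.sum(np.atleast_2d(x) ** 2, axis=1),
            lambda x: k * np.asarray(x),
            {"k": k},
        )
        nodes = PathNodes(np.linspace([-2.0, 0.0], [2.0, 0.0], 20),
                          np.ones(20, dtype=int))
        curve = reparametrize(fit_curve(nodes, P=1))
        grid = np.linspace(0.1, 0.9, 81)
        prof = reference_free_energy(pot, curve, grid, grid_points=900)
        x_alpha = -2.0 + 4.0 * prof.alpha  # curve coordinate
        # quadratic fit recovers the potential's curvature k/2 within 2%
        coeffs = np.polyfit(x_alpha, prof.f, 2)
        assert coeffs[0] == pytest.approx(0.5 * k, rel=0.02)

    def test_flat_potential_constant_profile(self):
        pot = ToyPotential(2, lambda x: 0.0 * np.atleast_2d(x)[:, 0],
                           lambda x: np.zeros_like(x), {})
        nodes = PathNodes(np.linspace([-1.0, 0.0], [1.0, 0.0], 10),
                          np.ones(10, dtype=int))
        curve = reparametrize(fit_curve(nodes, P=1))
        prof = reference_free_energy(pot, curve, np.linspace(0.2, 0.8, 21),
                                     grid_points=400, padding=1.0)
        assert prof.f.max() < 0.05

    def test_resolution_convergence(self):
        pot = curved_valley_potential(width_k=8.0)
        a, b = arc_endpoints(pot)
        spec = SyntheticEnsembleSpec(a=a, b=b, shape="arc", bulge=3.0,
                                     sigma=0.0, n_frames=100, seed=0)
        frames = make_synthetic_ensemble(spec)
        from pathpmf import bin_and_average

        nodes = bin_and_average([frames], a, b, n_bins=50)
        curve = reparametrize(fit_curve(nodes, P=5))
        grid = np.linspace(0.1, 0.9, 41)
        f1 = reference_free_energy(pot, curve, grid, grid_points=300).f
        f2 = reference_free_energy(pot, curve, grid, grid_points=600).f
        assert np.sqrt(np.mean((f1 - f2) ** 2)) < 0.02

    def test_high_dim_rejected(self):
        pot = curved_valley_potential(dim=4)
        with pytest.raises(ValueError, match="dim"):
            reference_free_energy(pot, None, np.linspace(0, 1, 5))


class TestLangevinPropagator:
    def test_vectorised_rows_independent_without_bias(self):
        pot = double_well_1d()
        prop = LangevinPropagator(pot, dt=0.01, kT=1.0)
        rng = np.random.default_rng(0)
        x = prop(np.array([[0.5], [-0.5]]), 100, rng)
        assert x.shape == (2, 1)
        assert np.isfinite(x).all()

    def test_nonfinite_detection(self):
        bad = ToyPotential(1, lambda x: 1e308, lambda x: np.full_like(x, 1e308), {})
        prop = LangevinPropagator(bad, dt=1.0, kT=1.0)
        with pytest.raises(FloatingPointError):
            prop(np.ones((1, 1)), 10, np.random.default_rng(0))
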