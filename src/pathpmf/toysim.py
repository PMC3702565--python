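"""Synthetic-data engine: toy potentials, Langevin sampling, and oracles.

This module stands in for a molecular-dynamics engine so that every stage
of the pipeline — pathway construction, tangent-only umbrella restraints,
replica exchange, WHAM — can be validated end to end against analytically
known ground truth:

* :func:`run_langevin` — an overdamped Euler–Maruyama sampler (only the
  equilibrium distribution matters for free-energy validation, so inertial
  dynamics buy nothing here);
* :func:`curved_valley_potential` — a harmonic valley along a circular arc
  with an optional linear tilt along the arc, i.e. a transition tube of
  known geometry, known width and known end-to-end free-energy difference;
* :func:`make_synthetic_ensemble` — frames scattered with Gaussian noise
  around a known path between two endpoints, emulating the unrestrained
  trajectory ensembles from which the principal curve is built;
* :func:`reference_free_energy` — brute-force quadrature of the projected
  free energy F(alpha), the independent oracle the sampled profile is
  compared against.

Toy states are raw coordinate vectors with no rigid-body alignment (the
potentials are not translation-invariant), and toy units set kT = 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .pathway import PathCurve
from .wham import FreeEnergyProfile

__all__ = [
    "ToyPotential",
    "SyntheticEnsembleSpec",
    "LangevinPropagator",
    "run_langevin",
    "double_well_1d",
    "curved_valley_potential",
    "arc_endpoints",
    "make_synthetic_ensemble",
    "reference_free_energy",
]


@dataclass(frozen=True)
class ToyPotential:
    """Analytic potential with matching gradient.

    ``energy`` accepts a single point (dim,) or a batch (n, dim) and
    returns a scalar / (n,) array; ``gradient`` likewise with matching
    shape.  ``params`` records the construction parameters.
    """

    dim: int
    energy: Callable[[np.ndarray], np.ndarray]
    gradient: Callable[[np.ndarray], np.ndarray]
    params: dict

    def check_gradient(self, points: np.ndarray, h: float = 1e-6) -> float:
        """Max relative finite-difference error of the gradient over points."""
        points = np.atleast_2d(points)
        worst = 0.0
        for x in points:
            g = np.asarray(self.gradient(x), dtype=float)
            fd = np.empty_like(g)
            for j in range(self.dim):
                xp, xm = x.copy(), x.copy()
                xp[j] += h
                xm[j] -= h
                fd[j] = (self.energy(xp) - self.energy(xm)) / (2 * h)
            scale = max(np.linalg.norm(fd), 1.0)
            worst = max(worst, float(np.linalg.norm(g - fd) / scale))
        return worst


@dataclass(frozen=True)
class SyntheticEnsembleSpec:
    """Recipe for a synthetic conformational ensemble around a known path.

    ``shape`` selects the ground-truth path between the two endpoints:
    ``"line"`` (straight segment), ``"sine"`` (segment plus a sinusoidal
    perpendicular bulge of amplitude ``bulge``, exactly representable in
    the curve basis with P = 1), or ``"arc"`` (circular arc bulging by
    ``bulge`` at its midpoint).  Frames are placed uniformly in the path
    parameter and perturbed with i.i.d. Gaussian noise of width ``sigma``
    per coordinate.
    """

    a: np.ndarray
    b: np.ndarray
    shape: str = "sine"
    bulge: float = 0.0
    sigma: float = 0.0
    n_frames: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "a", np.asarray(self.a, dtype=float).ravel())
        object.__setattr__(self, "b", np.asarray(self.b, dtype=float).ravel())
        if self.a.size != self.b.size:
            raise ValueError("endpoint dimension mismatch")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        if self.shape not in ("line", "sine", "arc"):
            raise ValueError(f"unknown path shape {self.shape!r}")

    def _bulge_direction(self) -> np.ndarray:
        """A fixed unit vector perpendicular to the chord."""
        chord = self.b - self.a
        chord = chord / np.linalg.norm(chord)
        # pick the coordinate axis least aligned with the chord
        trial = np.zeros_like(chord)
        trial[int(np.argmin(np.abs(chord)))] = 1.0
        perp = trial - (trial @ chord) * chord
        return perp / np.linalg.norm(perp)

    def path(self, t: np.ndarray) -> np.ndarray:
        """Ground-truth path points at parameter values t in [0, 1]."""
        t = np.asarray(t, dtype=float)
        base = self.a + np.multiply.outer(t, self.b - self.a)
        if self.shape == "line" or self.bulge == 0.0:
            return base
        perp = self._bulge_direction()
        if self.shape == "sine":
            return base + np.multiply.outer(self.bulge * np.sin(np.pi * t), perp)
        # circular arc through a, b with sagitta `bulge` at the midpoint
        half = 0.5 * np.linalg.norm(self.b - self.a)
        s = self.bulge
        radius = (half**2 + s**2) / (2 * s)
        mid = 0.5 * (self.a + self.b)
        center = mid + (s - radius) * perp
        chord_dir = (self.b - self.a) / (2 * half)
        phi_half = np.arcsin(half / radius)
        phi = (2 * t - 1.0) * phi_half  # -phi_half .. +phi_half
        return (
            center
            + np.multiply.outer(radius * np.sin(phi), chord_dir)
            + np.multiply.outer(radius * np.cos(phi), perp)
        )


def make_synthetic_ensemble(spec: SyntheticEnsembleSpec) -> np.ndarray:
    """Frames around the spec's path: (n_frames, dim) array.

    Deterministic for a given seed.  The ground-truth path stays available
    through ``spec.path`` for assertions.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.linspace(0.0, 1.0, spec.n_frames)
    pts = spec.path(t)
    if spec.sigma > 0:
        pts = pts + rng.normal(0.0, spec.sigma, size=pts.shape)
    return pts


def double_well_1d(barrier: float = 4.0, tilt: float = 0.0) -> ToyPotential:
    """Quartic double well on the real line: V(x) = barrier*(x^2-1)^2 + tilt*x/2."""

    def energy(x):
        x = np.asarray(x, dtype=float)
        v = barrier * (x**2 - 1.0) ** 2 + 0.5 * tilt * x
        return v.reshape(np.shape(x)[:-1]) if np.ndim(x) > 1 else float(np.squeeze(v))

    def gradient(x):
        x = np.asarray(x, dtype=float)
        return 4.0 * barrier * x * (x**2 - 1.0) + 0.5 * tilt

    return ToyPotential(1, energy, gradient, {"barrier": barrier, "tilt": tilt})


def curved_valley_potential(
    dim: int = 2,
    radius: float = 6.0,
    width_k: float = 4.0,
    theta_range: tuple[float, float] = (np.pi / 6, 5 * np.pi / 6),
    tilt: float = 0.0,
    end_k: float = 40.0,
    confine_k: float = 4.0,
    well_k: float = 0.0,
    well_center: float = 0.5,
) -> ToyPotential:
    """Harmonic valley along a circular arc — a transition tube of known shape.

    In the (x, y) plane the energy is ``(width_k/2)(r - radius)^2`` plus a
    linear tilt along the arc angle raising one end ``tilt`` energy units
    above the other, plus harmonic angular walls of stiffness ``end_k``
    (per radian², scaled by radius²) beyond the ends of the arc.  Extra
    dimensions are confined by ``(confine_k/2) z^2``.  Points on the
    untilted arc floor have exactly zero energy; with a tilt the energy
    difference between the two floor endpoints equals ``tilt`` exactly.

    ``well_k`` > 0 adds a harmonic term ``(well_k/2)(frac - well_center)^2``
    in the fractional arc angle ``frac = (theta - theta0)/span``, carving a
    single well along the tube (the single-minimum test landscape).
    """
    if radius <= 0 or width_k <= 0:
        raise ValueError("radius and width_k must be positive")
    if dim < 2:
        raise ValueError("dim must be at least 2")
    th0, th1 = theta_range
    if not 0 <= th0 < th1 <= np.pi:
        raise ValueError("theta_range must be an increasing range within [0, pi]")
    span = th1 - th0

    def _polar(xy):
        x, y = xy[..., 0], xy[..., 1]
        r = np.hypot(x, y)
        th = np.arctan2(y, x)
        return r, th

    def energy(x):
        x = np.asarray(x, dtype=float)
        scalar = x.ndim == 1
        x = np.atleast_2d(x)
        r, th = _polar(x[:, :2])
        v = 0.5 * width_k * (r - radius) ** 2
        frac = np.clip((th - th0) / span, 0.0, 1.0)
        v += tilt * frac
        if well_k:
            v += 0.5 * well_k * (frac - well_center) ** 2
        below = np.minimum(th - th0, 0.0)
        above = np.maximum(th - th1, 0.0)
        v += 0.5 * end_k * radius**2 * (below**2 + above**2)
        if x.shape[1] > 2:
            v += 0.5 * confine_k * np.sum(x[:, 2:] ** 2, axis=1)
        return float(v[0]) if scalar else v

    def gradient(x):
        x = np.asarray(x, dtype=float)
        scalar = x.ndim == 1
        x = np.atleast_2d(x)
        g = np.zeros_like(x)
        xx, yy = x[:, 0], x[:, 1]
        r, th = _polar(x[:, :2])
        r_safe = np.where(r > 1e-12, r, 1e-12)
        dr_dx = xx / r_safe
        dr_dy = yy / r_safe
        dth_dx = -yy / r_safe**2
        dth_dy = xx / r_safe**2
        dv_dr = width_k * (r - radius)
        inside = (th >= th0) & (th <= th1)
        frac = np.clip((th - th0) / span, 0.0, 1.0)
        dv_dth = np.where(inside, tilt / span, 0.0)
        if well_k:
            dv_dth = dv_dth + np.where(
                inside, well_k * (frac - well_center) / span, 0.0
            )
        below = np.minimum(th - th0, 0.0)
        above = np.maximum(th - th1, 0.0)
        dv_dth = dv_dth + end_k * radius**2 * (below + above)
        g[:, 0] = dv_dr * dr_dx + dv_dth * dth_dx
        g[:, 1] = dv_dr * dr_dy + dv_dth * dth_dy
        if x.shape[1] > 2:
            g[:, 2:] = confine_k * x[:, 2:]
        return g[0] if scalar else g

    params = {
        "radius": radius,
        "width_k": width_k,
        "theta_range": (th0, th1),
        "tilt": tilt,
        "end_k": end_k,
        "confine_k": confine_k,
        "well_k": well_k,
        "well_center": well_center,
    }
    return ToyPotential(dim, energy, gradient, params)


def arc_endpoints(pot: ToyPotential) -> tuple[np.ndarray, np.ndarray]:
    """The two valley-floor endpoints of a curved-valley potential."""
    p = pot.params
    th0, th1 = p["theta_range"]
    r = p["radius"]
    ends = []
    for th in (th0, th1):
        pt = np.zeros(pot.dim)
        pt[0], pt[1] = r * np.cos(th), r * np.sin(th)
        ends.append(pt)
    return ends[0], ends[1]


class LangevinPropagator:
    """Overdamped Euler–Maruyama integrator, vectorised over window rows.

    Update:  x <- x - (dt/gamma) grad(V + biases) + sqrt(2 kT dt / gamma) xi.
    When ``biases`` is given, row w of the state feels bias force
    ``-biases[w].K * d_w * e_w`` in addition to the base potential — i.e.
    each row is propagated under its own window's restraint, which is the
    contract :func:`pathpmf.hrex.run_hrex` expects.
    """

    def __init__(
        self,
        pot: ToyPotential,
        dt: float,
        gamma: float = 1.0,
        kT: float = 1.0,
        biases: Optional[Sequence] = None,
    ):
        if dt <= 0 or gamma <= 0 or kT <= 0:
            raise ValueError("dt, gamma and kT must be positive")
        self.pot = pot
        self.dt = dt
        self.gamma = gamma
        self.kT = kT
        self.noise_scale = np.sqrt(2.0 * kT * dt / gamma)
        if biases is not None:
            self._anchors = np.stack([np.asarray(b.anchor) for b in biases])
            self._tangents = np.stack([np.asarray(b.tangent) for b in biases])
            self._ks = np.array([b.K for b in biases])
        else:
            self._anchors = None

    def _force(self, x: np.ndarray) -> np.ndarray:
        f = -np.asarray(self.pot.gradient(x), dtype=float)
        if self._anchors is not None:
            d = np.sum((x - self._anchors) * self._tangents, axis=1)
            f -= (self._ks * d)[:, None] * self._tangents
        return f

    def __call__(
        self, x: np.ndarray, n_steps: int, rng: np.random.Generator
    ) -> np.ndarray:
        x = np.array(x, dtype=float)
        for _ in range(n_steps):
            f = self._force(x)
            x += (self.dt / self.gamma) * f
            x += self.noise_scale * rng.standard_normal(x.shape)
            if not np.all(np.isfinite(x)):
                raise FloatingPointError("non-finite coordinates during propagation")
        return x


def run_langevin(
    pot: ToyPotential,
    x0: np.ndarray,
    dt: float,
    gamma: float,
    kT: float,
    n_steps: int,
    seed: int,
    extra_bias=None,
) -> np.ndarray:
    """Single-walker overdamped Langevin trajectory, (n_steps, dim).

    ``extra_bias`` is any object exposing ``forces(x) -> dim-vector`` (e.g.
    an :class:`~pathpmf.restraints.UmbrellaWindow`); its forces are added
    to the base potential's.  Deterministic for a given seed.
    """
    if dt <= 0 or gamma <= 0 or kT < 0:
        raise ValueError("dt and gamma must be positive and kT non-negative")
    rng = np.random.default_rng(seed)
    x = np.asarray(x0, dtype=float).copy()
    noise_scale = np.sqrt(2.0 * kT * dt / gamma)
    out = np.empty((n_steps, x.size))
    for i in range(n_steps):
        f = -np.asarray(pot.gradient(x), dtype=float)
        if extra_bias is not None:
            f = f + np.asarray(extra_bias.forces(x), dtype=float)
        x = x + (dt / gamma) * f
        if noise_scale > 0:
            x = x + noise_scale * rng.standard_normal(x.shape)
        if not np.all(np.isfinite(x)):
            raise FloatingPointError(f"non-finite coordinates at step {i}")
        out[i] = x
    return out


def reference_free_energy(
    pot: ToyPotential,
    curve: PathCurve,
    alpha_grid: np.ndarray,
    kT: float = 1.0,
    grid_points: int = 600,
    padding: float = 4.0,
    check_convergence: bool = False,
    convergence_tol: float = 0.02,
) -> FreeEnergyProfile:
    """Brute-force projected free energy by dense spatial quadrature (dim <= 3).

    F(alpha_bin) = -kT ln of the Boltzmann weight integrated over the
    region whose closest-point projection onto the curve falls in the bin,
    minimum-shifted.  The integration box covers the curve plus ``padding``
    length units on each side; points above 40 kT are discarded (their
    weight is negligible).  With ``check_convergence`` the computation is
    repeated at half resolution and an error is raised if the RMS change
    exceeds ``convergence_tol`` (in kT).
    """
    if pot.dim > 3:
        raise ValueError("dense quadrature supported only for dim <= 3")
    alpha_grid = np.asarray(alpha_grid, dtype=float)

    def _compute(n: int) -> np.ndarray:
        dense_alpha = np.linspace(0.0, 1.0, 2001)
        cpts = np.asarray(curve(dense_alpha))
        lo = cpts.min(axis=0) - padding
        hi = cpts.max(axis=0) + padding
        axes = [np.linspace(lo[d], hi[d], n) for d in range(pot.dim)]
        mesh = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([m.ravel() for m in mesh], axis=1)
        v = np.asarray(pot.energy(pts), dtype=float)
        keep = v < 40.0 * kT
        pts, v = pts[keep], v[keep]
        # nearest curve point for every retained grid point, chunked
        alpha_star = np.empty(len(pts))
        chunk = 20000
        for s in range(0, len(pts), chunk):
            block = pts[s : s + chunk]
            d2 = (
                np.sum(block**2, axis=1)[:, None]
                - 2.0 * block @ cpts.T
                + np.sum(cpts**2, axis=1)[None, :]
            )
            alpha_star[s : s + chunk] = dense_alpha[np.argmin(d2, axis=1)]
        edges = np.concatenate(
            [
                [alpha_grid[0] - (alpha_grid[1] - alpha_grid[0]) / 2],
                0.5 * (alpha_grid[1:] + alpha_grid[:-1]),
                [alpha_grid[-1] + (alpha_grid[-1] - alpha_grid[-2]) / 2],
            ]
        )
        idx = np.digitize(alpha_star, edges) - 1
        w = np.exp(-v / kT)
        f = np.full(len(alpha_grid), np.inf)
        for b in range(len(alpha_grid)):
            sel = idx == b
            if np.any(sel):
                f[b] = -kT * np.log(np.sum(w[sel]))
        finite = np.isfinite(f)
        f -= f[finite].min()
        return f

    f = _compute(grid_points)
    if check_convergence:
        f_coarse = _compute(grid_points // 2)
        both = np.isfinite(f) & np.isfinite(f_coarse)
        rms = float(np.sqrt(np.mean((f[both] - f_coarse[both]) ** 2)))
        if rms > convergence_tol:
            raise ValueError(
                f"quadrature not converged: RMS change {rms:.3g} kT between "
                f"resolutions {grid_points // 2} and {grid_points}"
            )
    finite = np.isfinite(f)
    return FreeEnergyProfile(alpha=alpha_grid[finite], f=f[finite], kT=kT)
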