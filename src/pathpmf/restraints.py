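"""Umbrella restraints along the pathway and rigid-body-eliminating restraints.

Each umbrella window i holds a reference parameter alpha_i, the anchor
point Z_i = Z(alpha_i) on the curve and the frozen unit tangent e_i there.
Under the local linear approximation the curve near Z_i is replaced by its
tangent line, so the nonlinear closest-point projection becomes the linear
projection

    alpha_lin(x) = alpha_i + (x - Z_i) . e_i / L,

and the harmonic umbrella potential in the curve parameter,
(kappa/2)(alpha - alpha_i)^2 with kappa = K * L^2, becomes a simple
one-dimensional spring along the tangent:

    U_i(x) = (K/2) [ (x - Z_i) . e_i ]^2 .

Displacements perpendicular to the tangent cost exactly nothing — the
restraint confines motion only along the pathway, leaving all orthogonal
degrees of freedom free, which is what makes the reconstructed profile a
genuinely one-dimensional free energy.

Because this potential is a function of raw Cartesian coordinates it is not
invariant under rigid-body motion of the whole molecule; the
:class:`RigidBodyRestraint` pins the centroid and the overall orientation
to remove those six degrees of freedom in protein applications.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .geometry import Conformation, kabsch_rotation
from .pathway import PathCurve, VectorLike, _vec, tangent as curve_tangent

__all__ = [
    "UmbrellaWindow",
    "RigidBodyRestraint",
    "project",
    "window_layout",
    "umbrella_energy",
    "umbrella_forces",
    "rigid_body_energy",
]


@dataclass(frozen=True)
class UmbrellaWindow:
    """One umbrella window along the curve.

    ``K`` is the Cartesian spring constant (kcal/mol/Å² in protein paths,
    kT/length² in toy paths); the equivalent curve-parameter spring
    constant is ``kappa = K * L**2``.
    """

    index: int
    alpha_ref: float
    anchor: np.ndarray
    tangent: np.ndarray
    K: float
    L: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "anchor", np.asarray(self.anchor, dtype=float).ravel())
        object.__setattr__(
            self, "tangent", np.asarray(self.tangent, dtype=float).ravel()
        )
        if not 0.0 <= self.alpha_ref <= 1.0:
            raise ValueError("alpha_ref must lie in [0, 1]")
        if self.K <= 0 or self.L <= 0:
            raise ValueError("K and L must be positive")
        if abs(np.linalg.norm(self.tangent) - 1.0) > 1e-10:
            raise ValueError("tangent must be a unit vector")

    @property
    def kappa(self) -> float:
        """Spring constant in curve-parameter units: kappa = K L^2 (energy)."""
        return self.K * self.L**2

    def displacement(self, x: VectorLike) -> float:
        """Signed tangent displacement d = (x - Z_i) . e_i (length units)."""
        xv = _vec(x)
        if xv.size != self.anchor.size:
            raise ValueError("dimension mismatch with window anchor")
        return float((xv - self.anchor) @ self.tangent)

    def alpha_linear(self, x: VectorLike) -> float:
        """Linearised projection alpha_lin = alpha_i + d / L."""
        return self.alpha_ref + self.displacement(x) / self.L

    def energy(self, x: VectorLike) -> float:
        return umbrella_energy(self, x)

    def forces(self, x: VectorLike) -> np.ndarray:
        return umbrella_forces(self, x)


def umbrella_energy(w: UmbrellaWindow, x: VectorLike) -> float:
    """Tangent-only harmonic umbrella energy U = (K/2) d^2."""
    d = w.displacement(x)
    return 0.5 * w.K * d * d


def umbrella_forces(w: UmbrellaWindow, x: VectorLike) -> np.ndarray:
    """Restraint forces F = -K d e_i, the exact negative gradient of the energy."""
    d = w.displacement(x)
    return -w.K * d * w.tangent


def window_layout(
    curve: PathCurve, n_windows: int, K: float
) -> list[UmbrellaWindow]:
    """Uniformly spaced windows covering alpha in [0, 1].

    With n windows the spacing is 1/(n-1); anchors and tangents are
    evaluated on the (arc-length parametrised) curve.  Window indices are
    1-based.
    """
    if n_windows < 2:
        raise ValueError("need at least 2 windows")
    if not curve.uniform:
        raise ValueError("curve must be arc-length reparametrised first")
    L = curve.length
    windows = []
    for i in range(n_windows):
        alpha = i / (n_windows - 1)
        windows.append(
            UmbrellaWindow(
                index=i + 1,
                alpha_ref=alpha,
                anchor=np.asarray(curve(alpha), dtype=float).ravel(),
                tangent=curve_tangent(curve, alpha),
                K=K,
                L=L,
            )
        )
    return windows


def project(curve: PathCurve, x: VectorLike, n_grid: int = 401) -> float:
    """Nonlinear projection: the alpha in [0, 1] whose curve point is nearest x.

    Global coarse grid scan followed by bounded local refinement; boundary
    values are returned for points beyond the curve ends.  Used for
    analysis and reporting; the umbrella forces use the frozen linearised
    projection instead.
    """
    xv = _vec(x)
    if xv.size != curve.dim:
        raise ValueError("dimension mismatch between point and curve")
    grid = np.linspace(0.0, 1.0, max(n_grid, 201))
    pts = curve(grid)
    d2 = np.sum((pts - xv) ** 2, axis=1)
    k = int(np.argmin(d2))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    if lo == hi:
        return float(grid[k])

    def f(a: float) -> float:
        return float(np.sum((np.asarray(curve(a)).ravel() - xv) ** 2))

    res = minimize_scalar(f, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    # bounded minimisation never lands exactly on a bound; when the coarse
    # scan already pointed at a boundary, compare against it explicitly
    candidates = [float(np.clip(res.x, 0.0, 1.0))]
    if k == 0:
        candidates.append(0.0)
    if k == len(grid) - 1:
        candidates.append(1.0)
    return min(candidates, key=f)


@dataclass(frozen=True)
class RigidBodyRestraint:
    """Harmonic restraints pinning overall translation and rotation.

    ``k_center`` (kcal/mol/Å²) acts on the unweighted centroid displacement
    from the reference; ``k_orient`` (kcal/mol/degree²) acts on the
    orientation angle, defined as the rotation angle of the optimal
    (Kabsch) superposition rotation taking the centred conformation onto
    the centred reference — a single axis-free scalar, smooth near zero.
    """

    reference: Conformation
    k_center: float = 1000.0
    k_orient: float = 200.0

    def __post_init__(self) -> None:
        if self.k_center <= 0 or self.k_orient <= 0:
            raise ValueError("spring constants must be positive")

    def energy(self, x: VectorLike) -> float:
        return rigid_body_energy(self, x)[0]


def _orientation_angle_deg(x_at: np.ndarray, ref_at: np.ndarray) -> float:
    """Rotation angle (degrees) of the optimal superposition of x onto ref."""
    rot = kabsch_rotation(x_at - x_at.mean(axis=0), ref_at - ref_at.mean(axis=0))
    cos_theta = np.clip((np.trace(rot) - 1.0) / 2.0, -1.0, 1.0)
    return float(np.degrees(np.arccos(cos_theta)))


def rigid_body_energy(
    r: RigidBodyRestraint, x: VectorLike
) -> tuple[float, np.ndarray]:
    """Energy and gradient of the rigid-body restraint.

    energy = (k_center/2)|c(x) - c(ref)|^2 + (k_orient/2) theta(x, ref)^2
    with c the unweighted centroid and theta in degrees.  The centroid
    gradient is analytic; the orientation gradient is computed by central
    finite differences of the angle (the angle itself is obtained through
    an SVD, for which a closed-form gradient buys little here).
    """
    xv = _vec(x)
    ref = r.reference.coords
    if xv.size != ref.size:
        raise ValueError("dimension mismatch with restraint reference")
    n = xv.size // 3
    x_at = xv.reshape(-1, 3)
    ref_at = ref.reshape(-1, 3)

    dc = x_at.mean(axis=0) - ref_at.mean(axis=0)
    e_center = 0.5 * r.k_center * float(dc @ dc)
    grad_center = np.tile(r.k_center * dc / n, n)

    theta = _orientation_angle_deg(x_at, ref_at)
    e_orient = 0.5 * r.k_orient * theta * theta

    h = 1e-6
    grad_theta = np.zeros_like(xv)
    for j in range(xv.size):
        xp = xv.copy()
        xp[j] += h
        xm = xv.copy()
        xm[j] -= h
        tp = _orientation_angle_deg(xp.reshape(-1, 3), ref_at)
        tm = _orientation_angle_deg(xm.reshape(-1, 3), ref_at)
        grad_theta[j] = (tp - tm) / (2 * h)
    grad = grad_center + r.k_orient * theta * grad_theta
    return e_center + e_orient, grad
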