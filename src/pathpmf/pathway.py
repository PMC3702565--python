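"""Principal-curve construction from conformational ensembles.

The transition pathway is built in four stages, mirroring the averaged-path
construction used with unrestrained trajectory ensembles:

1. every frame is rigid-body aligned to a common reference and orthogonally
   projected onto the straight line joining the two endpoint structures;
2. the covered projection range is divided into equal segments and frames
   are averaged within each segment, giving an ordered polyline of nodes
   through the centre of the sampled tube;
3. a smooth global curve  Z_i(t) = a_i + b_i t + sum_p c_{i,p} sin(p*pi*t)
   is fitted through the nodes by alternating linear least squares (for the
   coefficients) with per-node optimisation of the curve parameters t_k;
4. the curve is reparametrised by normalised arc length, yielding the
   uniform curve parameter alpha in [0, 1] along which the free energy is
   defined.

The sinusoidal basis keeps the curve infinitely differentiable, which is
what makes the local linear (tangent) approximation used by the umbrella
restraints legitimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy.interpolate import PchipInterpolator

from .geometry import Conformation, Ensemble, kabsch_align

__all__ = [
    "PathNodes",
    "PathCurve",
    "FitConvergenceError",
    "line_project",
    "bin_and_average",
    "fit_curve",
    "arc_length",
    "reparametrize",
    "tangent",
]

VectorLike = Union[Conformation, np.ndarray, Sequence[float]]


def _vec(x: VectorLike) -> np.ndarray:
    if isinstance(x, Conformation):
        return x.coords
    return np.asarray(x, dtype=float).ravel()


class FitConvergenceError(RuntimeError):
    """Raised when the alternating curve fit fails to converge.

    Carries the last objective value in ``objective``.
    """

    def __init__(self, message: str, objective: float):
        super().__init__(message)
        self.objective = objective


@dataclass
class PathNodes:
    """Ordered bin-average nodes delineating the centre of the sampled tube."""

    nodes: np.ndarray  # (n_nodes, D)
    counts: np.ndarray  # frames contributing to each node

    def __post_init__(self) -> None:
        self.nodes = np.atleast_2d(np.asarray(self.nodes, dtype=float))
        self.counts = np.asarray(self.counts, dtype=int)
        if len(self.counts) != len(self.nodes):
            raise ValueError("counts must match number of nodes")
        if np.any(self.counts < 1):
            raise ValueError("retained nodes must have at least one frame")

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def dim(self) -> int:
        return self.nodes.shape[1]


# number of points in the tabulated arc-length map; dense enough that the
# monotone cubic inverse is accurate to ~1e-10 in t for smooth curves
_ARC_TABLE_SIZE = 2001

# 5-point Gauss-Legendre rule on [0, 1]
_GL_X, _GL_W = np.polynomial.legendre.leggauss(5)
_GL_X = 0.5 * (_GL_X + 1.0)
_GL_W = 0.5 * _GL_W


class PathCurve:
    """Smooth parametric curve in D dimensions.

    The curve is stored through its basis coefficients.  A freshly fitted
    curve is parametrised by the internal fit parameter ``t``; after
    :func:`reparametrize` the public parameter is the normalised arc length
    ``alpha``, with ``|dZ/dalpha| = L`` uniformly.  Both kinds of curve are
    evaluated with ``curve(u)``.
    """

    def __init__(
        self,
        a: np.ndarray,
        b: np.ndarray,
        c: np.ndarray,
        t_of_param: Optional[PchipInterpolator] = None,
    ):
        self.a = np.asarray(a, dtype=float)
        self.b = np.asarray(b, dtype=float)
        self.c = np.atleast_2d(np.asarray(c, dtype=float))
        if self.c.size == 0:
            self.c = np.zeros((self.a.size, 0))
        if self.c.shape[0] != self.a.size or self.b.shape != self.a.shape:
            raise ValueError("inconsistent coefficient shapes")
        self._t_of_param = t_of_param
        self._arc_table = self._build_arc_table()

    # -- basis evaluation in the internal parameter t ---------------------

    @property
    def dim(self) -> int:
        return self.a.size

    @property
    def n_modes(self) -> int:
        return self.c.shape[1]

    @property
    def uniform(self) -> bool:
        """True once the curve is parametrised by normalised arc length."""
        return self._t_of_param is not None

    def _eval_t(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        p = np.arange(1, self.n_modes + 1)
        # shape (..., P)
        sins = np.sin(np.pi * np.multiply.outer(t, p))
        out = (
            self.a
            + np.multiply.outer(t, self.b)
            + np.tensordot(sins, self.c, axes=([-1], [1]))
        )
        return out

    def _deriv_t(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        p = np.arange(1, self.n_modes + 1)
        coss = np.cos(np.pi * np.multiply.outer(t, p)) * (np.pi * p)
        return self.b + np.tensordot(coss, self.c, axes=([-1], [1]))

    def _speed_t(self, t: np.ndarray) -> np.ndarray:
        return np.linalg.norm(np.atleast_2d(self._deriv_t(t)), axis=-1)

    # -- arc length -------------------------------------------------------

    def _build_arc_table(self) -> tuple[np.ndarray, np.ndarray]:
        """Cumulative arc length s(t) on a dense grid via per-interval Gauss quadrature."""
        t_grid = np.linspace(0.0, 1.0, _ARC_TABLE_SIZE)
        h = t_grid[1] - t_grid[0]
        # quadrature nodes inside each interval, flattened
        tq = (t_grid[:-1, None] + h * _GL_X[None, :]).ravel()
        sp = self._speed_t(tq).reshape(-1, len(_GL_X))
        seg = h * sp @ _GL_W
        s = np.concatenate([[0.0], np.cumsum(seg)])
        if not np.all(np.diff(s) > 0):
            raise ValueError("arc length is not strictly increasing (degenerate curve)")
        return t_grid, s

    @property
    def length(self) -> float:
        """Total arc length L (Å)."""
        return float(self._arc_table[1][-1])

    @property
    def arc_table(self) -> tuple[np.ndarray, np.ndarray]:
        return self._arc_table

    # -- public evaluation ------------------------------------------------

    def _to_t(self, u) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        if np.any(u < -1e-12) or np.any(u > 1 + 1e-12):
            raise ValueError("curve parameter must lie in [0, 1]")
        u = np.clip(u, 0.0, 1.0)
        if self._t_of_param is None:
            return u
        return np.clip(self._t_of_param(u), 0.0, 1.0)

    def __call__(self, u) -> np.ndarray:
        """Evaluate the curve at parameter value(s) ``u`` in [0, 1]."""
        return self._eval_t(self._to_t(u))

    def derivative(self, u) -> np.ndarray:
        """dZ/du at ``u`` (chain rule through the arc-length map if uniform)."""
        t = self._to_t(u)
        d = self._deriv_t(t)
        if self._t_of_param is None:
            return d
        # alpha = s(t)/L  =>  dt/dalpha = L / |dZ/dt|
        speed = self._speed_t(t)
        if d.ndim > 1:
            return d * (self.length / speed)[..., None]
        return d * (self.length / float(np.squeeze(speed)))


def line_project(x: VectorLike, a: VectorLike, b: VectorLike) -> float:
    """Scalar coordinate of the orthogonal projection of x onto the line a->b.

    Returns lambda with a + lambda*(b - a) the closest point on the
    (infinite) line; lambda may fall outside [0, 1].
    """
    xv, av, bv = _vec(x), _vec(a), _vec(b)
    if not (xv.size == av.size == bv.size):
        raise ValueError("dimension mismatch between x, a, b")
    ab = bv - av
    denom = float(ab @ ab)
    if denom == 0.0:
        raise ValueError("degenerate line: endpoints coincide")
    return float((xv - av) @ ab / denom)


def bin_and_average(
    ensembles: Sequence[Union[Ensemble, np.ndarray]],
    a: VectorLike,
    b: VectorLike,
    n_bins: int = 100,
    reference: Optional[Conformation] = None,
    min_count: int = 1,
) -> PathNodes:
    """Project all frames onto the endpoint line, bin, and average per bin.

    The covered range ``[min(lambda), max(lambda)]`` over all frames — not
    the nominal [0, 1] between the endpoints — is divided into ``n_bins``
    equal segments, which is why the resulting pathway can extend beyond
    both endpoint structures.  When ``reference`` is given, every frame is
    Kabsch-aligned to it first (the protein use case); pass ``None`` for
    toy-coordinate ensembles where rigid-body alignment is meaningless.
    Bins with fewer than ``min_count`` frames (empty bins in particular)
    are dropped; the curve fit tolerates the uneven node spacing because
    the node parameters t_k are free.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    av, bv = _vec(a), _vec(b)

    frames: list[np.ndarray] = []
    for ens in ensembles:
        if isinstance(ens, Ensemble):
            for f in ens.frames:
                if reference is not None:
                    f = kabsch_align(f, reference)[0]
                frames.append(f.coords)
        else:
            arr = np.atleast_2d(np.asarray(ens, dtype=float))
            if reference is not None:
                arr = np.stack(
                    [kabsch_align(Conformation(r), reference)[0].coords for r in arr]
                )
            frames.extend(arr)
    if not frames:
        raise ValueError("no frames supplied")
    x = np.stack(frames)

    ab = bv - av
    lam = (x - av) @ ab / float(ab @ ab)
    lo, hi = float(lam.min()), float(lam.max())
    if hi <= lo:
        raise ValueError("zero projection range: all frames project identically")
    idx = np.minimum(((lam - lo) / (hi - lo) * n_bins).astype(int), n_bins - 1)

    nodes, counts = [], []
    for k in range(n_bins):
        sel = idx == k
        m = int(sel.sum())
        if m < max(min_count, 1):
            continue
        nodes.append(x[sel].mean(axis=0))
        counts.append(m)
    return PathNodes(np.stack(nodes), np.asarray(counts))


def _project_params(
    curve_eval, curve_deriv, curve_deriv2, nodes: np.ndarray, t: np.ndarray
) -> np.ndarray:
    """Refine per-node parameters t_k by clamped vectorised Newton iterations."""
    for _ in range(25):
        z = curve_eval(t)
        d1 = curve_deriv(t)
        d2 = curve_deriv2(t)
        r = z - nodes
        g = 2.0 * np.sum(r * d1, axis=1)
        h = 2.0 * (np.sum(d1 * d1, axis=1) + np.sum(r * d2, axis=1))
        step = np.where(h > 1e-30, g / np.where(h > 1e-30, h, 1.0), np.sign(g) * 1e-3)
        step = np.clip(step, -0.05, 0.05)
        t = np.clip(t - step, 0.0, 1.0)
        if np.max(np.abs(step)) < 1e-14:
            break
    return t


def fit_curve(
    nodes: PathNodes,
    P: int = 1,
    max_iter: int = 50,
    rtol: float = 1e-10,
    polish_budget: int = 150,
    return_info: bool = False,
):
    """Fit the smooth sinusoidal curve through ordered path nodes.

    Minimises  sum_k |Z(t_k) - node_k|^2  jointly over the basis
    coefficients and the per-node parameters t_k.  The first and last node
    parameters are pinned to 0 and 1; the interior t_k are initialised
    proportional to node index (nodes arrive ordered by the line-projection
    coordinate).

    Two stages: alternating sweeps (linear least squares for the
    coefficients given t, clamped Newton updates of each t_k given the
    coefficients — the objective is non-increasing across these sweeps),
    stopped at relative improvement ``rtol`` or after ``max_iter`` sweeps;
    then a joint sparse Gauss-Newton polish over coefficients and interior
    t_k with an evaluation budget of ``polish_budget``.  The polish exists
    because the joint problem has a nearly flat direction — nodes can
    slide tangentially along the curve almost for free — which makes
    purely alternating iterations crawl; the trust-region step handles
    that degeneracy directly.  Convergence is judged on the objective:
    a non-finite or increased objective raises :class:`FitConvergenceError`.

    With ``return_info`` the alternating objective trace and final
    objective are returned alongside the curve.
    """
    if P < 0:
        raise ValueError("P must be non-negative")
    y = nodes.nodes
    m, dim = y.shape
    if m < P + 2:
        raise ValueError(f"need at least P + 2 = {P + 2} nodes, got {m}")

    t = np.linspace(0.0, 1.0, m)
    p_arr = np.arange(1, P + 1)
    q = 2 + P

    def design(tv: np.ndarray) -> np.ndarray:
        cols = [np.ones_like(tv), tv]
        for p in p_arr:
            cols.append(np.sin(np.pi * p * tv))
        return np.stack(cols, axis=1)

    def ddesign(tv: np.ndarray) -> np.ndarray:
        cols = [np.zeros_like(tv), np.ones_like(tv)]
        for p in p_arr:
            cols.append(np.pi * p * np.cos(np.pi * p * tv))
        return np.stack(cols, axis=1)

    # --- stage 1: alternating sweeps ------------------------------------
    trace: list[float] = []
    coef = None
    for _ in range(max_iter):
        phi = design(t)
        coef, *_ = np.linalg.lstsq(phi, y, rcond=None)
        resid = phi @ coef - y
        obj = float(np.sum(resid * resid))
        trace.append(obj)
        if len(trace) > 1 and trace[-2] - obj <= rtol * max(trace[-2], 1e-300):
            break

        a_, b_, c_ = coef[0], coef[1], coef[2:].T

        def ev(tv, a_=a_, b_=b_, c_=c_):
            s = np.sin(np.pi * np.multiply.outer(tv, p_arr))
            return a_ + np.multiply.outer(tv, b_) + s @ c_.T

        def d1(tv, b_=b_, c_=c_):
            cmat = np.cos(np.pi * np.multiply.outer(tv, p_arr)) * (np.pi * p_arr)
            return b_ + cmat @ c_.T

        def d2(tv, c_=c_):
            smat = -np.sin(np.pi * np.multiply.outer(tv, p_arr)) * (np.pi * p_arr) ** 2
            return smat @ c_.T

        if m > 2:
            t_int = _project_params(ev, d1, d2, y[1:-1], t[1:-1])
            t = np.concatenate([[0.0], t_int, [1.0]])

    # --- stage 2: joint sparse Gauss-Newton polish ----------------------
    if polish_budget > 0 and m > 2:
        from scipy import sparse
        from scipy.optimize import least_squares

        def unpack(x):
            return x[: q * dim].reshape(q, dim), np.concatenate(
                [[0.0], x[q * dim:], [1.0]]
            )

        def residual(x):
            cmat, tv = unpack(x)
            return (design(tv) @ cmat - y).ravel()

        def jacobian(x):
            cmat, tv = unpack(x)
            phi = design(tv)
            dz = ddesign(tv) @ cmat  # (m, dim) curve derivative at each t_k
            rows, cols, vals = [], [], []
            rr = (np.arange(m)[:, None] * dim + np.arange(dim)[None, :]).ravel()
            for qq in range(q):
                rows.append(rr)
                cols.append((qq * dim + np.arange(dim))[None, :].repeat(m, 0).ravel())
                vals.append(np.repeat(phi[:, qq], dim))
            kk = np.arange(1, m - 1)
            rows.append((kk[:, None] * dim + np.arange(dim)[None, :]).ravel())
            cols.append((q * dim + np.arange(m - 2))[:, None].repeat(dim, 1).ravel())
            vals.append(dz[1:-1].ravel())
            return sparse.csr_matrix(
                (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
                shape=(m * dim, q * dim + m - 2),
            )

        x0 = np.concatenate([coef.ravel(), t[1:-1]])
        lb = np.full_like(x0, -np.inf)
        ub = np.full_like(x0, np.inf)
        lb[q * dim:] = 0.0
        ub[q * dim:] = 1.0
        res = least_squares(
            residual,
            x0,
            jac=jacobian,
            bounds=(lb, ub),
            method="trf",
            tr_solver="lsmr",
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
            max_nfev=polish_budget,
        )
        polished = 2.0 * float(res.cost)
        if not np.isfinite(polished) or polished > trace[-1] * (1 + 1e-9) + 1e-30:
            raise FitConvergenceError(
                f"curve fit failed to converge (objective {polished:.6g} after "
                f"polish, {trace[-1]:.6g} after alternating stage)",
                objective=polished,
            )
        coef, t = unpack(res.x)
        trace.append(polished)

    curve = PathCurve(coef[0], coef[1], coef[2:].T)
    if return_info:
        return curve, {"objective_trace": trace, "objective": trace[-1], "t": t}
    return curve


def arc_length(curve: PathCurve, t: float) -> float:
    """Arc length s(t) from the start of the curve, in the curve's internal parameter."""
    if not 0.0 <= t <= 1.0:
        raise ValueError("t must lie in [0, 1]")
    t_grid, s_grid = curve.arc_table
    return float(np.interp(t, t_grid, s_grid))


def reparametrize(curve: PathCurve) -> PathCurve:
    """Return the same geometric curve parametrised by normalised arc length.

    The new parameter alpha in [0, 1] satisfies s(t(alpha)) = alpha * L, so
    the speed |dZ/dalpha| equals the total length L uniformly.  The inverse
    map is a monotone (PCHIP) cubic through the tabulated arc lengths.
    """
    t_grid, s_grid = curve.arc_table
    if np.any(np.diff(s_grid) <= 0):
        raise ValueError("arc-length table is not monotone")
    alpha_grid = s_grid / s_grid[-1]
    t_of_alpha = PchipInterpolator(alpha_grid, t_grid)
    return PathCurve(curve.a, curve.b, curve.c, t_of_param=t_of_alpha)


def tangent(curve: PathCurve, alpha: float) -> np.ndarray:
    """Unit tangent vector of the curve at parameter alpha."""
    d = np.asarray(curve.derivative(float(alpha)), dtype=float).ravel()
    norm = np.linalg.norm(d)
    if norm == 0.0:
        raise ValueError(f"zero curve derivative at alpha={alpha}")
    return d / norm
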