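"""Weighted-histogram reconstruction of the 1D free energy along the curve.

Each umbrella window i contributes samples of the curve coordinate alpha
collected under the harmonic bias u_i(alpha) = (kappa/2)(alpha - alpha_i)^2
(kappa = K L^2).  The self-consistent WHAM equations over a common
histogram grid,

    p(b)  =  sum_i n_i(b)  /  sum_i N_i exp[(f_i - u_i(b)) / kT]
    f_i   =  -kT ln sum_b p(b) exp[-u_i(b) / kT],

are iterated until the window offsets f_i stabilise; the unbiased profile
is F(b) = -kT ln p(b), shifted so its minimum is zero.

Statistical errors follow the mean-coordinate scheme: within window i the
gradient of the free energy at alpha_i relates to the mean restraint
displacement, F'(alpha_i) ~ kappa (alpha_i - <alpha>_i), so the
uncertainty of <alpha>_i (estimated by block averaging, which absorbs
autocorrelation) propagates into the free-energy *difference* relative to
the first window, accumulating in quadrature along the chain of windows.

A compact binless multistate-reweighting (MBAR-style) estimator is also
provided purely as an independent cross-check route; the histogram WHAM
above is the primary path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "WindowSamples",
    "FreeEnergyProfile",
    "WhamConvergenceError",
    "wham_1d",
    "wham_error",
    "block_error_of_mean",
    "mbar_profile",
    "count_minima",
]


def count_minima(
    profile: "FreeEnergyProfile", prominence: float = 0.1, smooth_bins: int = 5
) -> int:
    """Number of local minima deeper than ``prominence`` (kT).

    The profile is first smoothed with a short moving average (statistical
    bin noise otherwise registers as spurious shallow minima), then minima
    are counted by peak prominence on the negated profile, so only wells
    separated from their surroundings by at least ``prominence`` count.
    Boundary minima (profile sloping up away from an edge) are included.
    """
    from scipy.signal import find_peaks

    f = np.asarray(profile.f, dtype=float)
    if smooth_bins > 1:
        kernel = np.ones(smooth_bins) / smooth_bins
        # reflect-pad so edges stay meaningful
        pad = smooth_bins // 2
        fp = np.concatenate([f[pad:0:-1], f, f[-2 : -pad - 2 : -1]])
        f = np.convolve(fp, kernel, mode="valid")[: len(f)]
    # pad low on the negated profile so boundary minima register as peaks
    cap = f.max() + 1e3 * max(prominence, 1.0)
    g = np.concatenate([[-cap], -f, [-cap]])
    peaks, _ = find_peaks(g, prominence=prominence)
    return int(len(peaks))


class WhamConvergenceError(RuntimeError):
    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


@dataclass
class WindowSamples:
    """Biased alpha samples from one umbrella window.

    ``kappa`` is the curve-parameter spring constant (energy units matching
    kT); ``cut`` is the leading fraction of samples discarded as
    equilibration.
    """

    index: int
    alpha_ref: float
    kappa: float
    samples: np.ndarray
    cut: float = 0.25

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if not 0.0 <= self.cut < 1.0:
            raise ValueError("cut must lie in [0, 1)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def retained(self) -> np.ndarray:
        start = int(np.floor(self.cut * len(self.samples)))
        return self.samples[start:]

    def bias(self, alpha: np.ndarray) -> np.ndarray:
        d = np.asarray(alpha) - self.alpha_ref
        return 0.5 * self.kappa * d * d


@dataclass
class FreeEnergyProfile:
    """Free energy on an alpha grid, minimum-shifted, with standard errors."""

    alpha: np.ndarray
    f: np.ndarray
    err: Optional[np.ndarray] = None
    kT: float = 1.0
    window_offsets: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if np.any(np.diff(self.alpha) <= 0):
            raise ValueError("alpha grid must be strictly increasing")
        if self.err is not None:
            self.err = np.asarray(self.err, dtype=float)
            if np.any(self.err < 0):
                raise ValueError("errors must be non-negative")

    def value_at(self, alpha: float) -> float:
        return float(np.interp(alpha, self.alpha, self.f))

    def minimum(self) -> tuple[float, float]:
        k = int(np.argmin(self.f))
        return float(self.alpha[k]), float(self.f[k])


def _check_overlap(windows: Sequence[WindowSamples], edges: np.ndarray) -> None:
    """Warn when adjacent windows (by alpha_ref) share no occupied histogram bins."""
    order = np.argsort([w.alpha_ref for w in windows])
    occupied = []
    for w in windows:
        h, _ = np.histogram(w.retained, bins=edges)
        occupied.append(h > 0)
    for a, b in zip(order[:-1], order[1:]):
        if not np.any(occupied[a] & occupied[b]):
            warnings.warn(
                f"windows {windows[a].index} and {windows[b].index} share no "
                "occupied histogram bins; the profile may be disconnected",
                stacklevel=3,
            )


def wham_1d(
    all_samples: Sequence[WindowSamples],
    n_bins: int = 200,
    tol: float = 1e-8,
    max_iter: int = 100_000,
    kT: float = 1.0,
    compute_errors: bool = True,
) -> FreeEnergyProfile:
    """Self-consistent WHAM over a common histogram of the sampled range.

    ``tol`` is the convergence threshold on max |Delta f_i| per iteration in
    units of kT.  Bin count defaults to 200 over the union of all sampled
    alpha values.  Raises :class:`WhamConvergenceError` on non-convergence.
    """
    windows = [w for w in all_samples if len(w.retained) > 0]
    if not windows:
        raise ValueError("no window has retained samples")

    data = [w.retained for w in windows]
    lo = min(d.min() for d in data)
    hi = max(d.max() for d in data)
    if hi <= lo:
        raise ValueError("degenerate sample range")
    edges = np.linspace(lo, hi, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    if len(windows) > 1:
        _check_overlap(windows, edges)

    counts = np.stack([np.histogram(d, bins=edges)[0] for d in data]).astype(float)
    n_tot = counts.sum(axis=0)  # per bin
    n_i = counts.sum(axis=1)  # per window
    # reduced biases at bin centers: (n_windows, n_bins)
    u = np.stack([w.bias(centers) / kT for w in windows])

    f = np.zeros(len(windows))  # reduced window offsets f_i / kT
    for _ in range(max_iter):
        # log denominator per bin: log sum_i N_i exp(f_i - u_ib)
        log_den = logsumexp(f[:, None] - u, b=n_i[:, None], axis=0)
        with np.errstate(divide="ignore"):
            log_p = np.where(n_tot > 0, np.log(n_tot) - log_den, -np.inf)
        f_new = -logsumexp(log_p[None, :] - u, axis=1)
        f_new -= f_new[0]
        resid = float(np.max(np.abs(f_new - f)))
        f = f_new
        if resid < tol:
            break
    else:
        raise WhamConvergenceError(
            f"WHAM did not converge in {max_iter} iterations "
            f"(residual {resid:.3g} kT)",
            residual=resid,
        )

    mask = np.isfinite(log_p)
    alpha = centers[mask]
    free = -kT * log_p[mask]
    free -= free.min()

    err = None
    if compute_errors and len(windows) >= 2:
        try:
            err = wham_error(windows, alpha_grid=alpha, kT=kT)
        except ValueError:
            err = None
    return FreeEnergyProfile(alpha=alpha, f=free, err=err, kT=kT,
                             window_offsets=kT * f)


def block_error_of_mean(x: np.ndarray, n_blocks: int = 10) -> float:
    """Standard error of the mean of a correlated series by block averaging.

    The series is divided into ``n_blocks`` contiguous blocks; the spread of
    block means estimates the error of the global mean including
    autocorrelation (blocks must be longer than the correlation time for
    the estimate to be unbiased).
    """
    x = np.asarray(x, dtype=float).ravel()
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    if len(x) < n_blocks:
        raise ValueError("fewer samples than blocks")
    usable = (len(x) // n_blocks) * n_blocks
    means = x[:usable].reshape(n_blocks, -1).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(n_blocks))


def wham_error(
    all_samples: Sequence[WindowSamples],
    alpha_grid: Optional[np.ndarray] = None,
    n_blocks: int = 10,
    kT: float = 1.0,
) -> np.ndarray:
    """Free-energy-difference errors relative to the first window.

    The mean-force estimate carried by window i is kappa (alpha_i -
    <alpha>_i); its uncertainty is kappa * sigma(<alpha>_i) with sigma from
    block averaging.  Integrating the mean force over the link lengths
    assigned to each window (trapezoidal: half the spacing to each
    neighbour) gives per-window free-energy differences whose errors
    accumulate in quadrature along the chain, starting at zero for the
    first window.
    """
    windows = sorted(all_samples, key=lambda w: w.alpha_ref)
    if len(windows) < 2:
        raise ValueError("need at least 2 windows for chained errors")
    centers = np.array([w.alpha_ref for w in windows])
    sig = np.array(
        [block_error_of_mean(w.retained, n_blocks=n_blocks) for w in windows]
    )
    # link length attributed to each window (trapezoidal weights)
    dalpha = np.empty_like(centers)
    dalpha[0] = (centers[1] - centers[0]) / 2
    dalpha[-1] = (centers[-1] - centers[-2]) / 2
    dalpha[1:-1] = (centers[2:] - centers[:-2]) / 2
    contrib = np.array([w.kappa for w in windows]) * sig * dalpha
    cumulative = np.sqrt(np.cumsum(contrib**2))
    if alpha_grid is None:
        return cumulative
    return np.interp(np.asarray(alpha_grid), centers, cumulative)


def mbar_profile(
    all_samples: Sequence[WindowSamples],
    n_bins: int = 200,
    tol: float = 1e-10,
    max_iter: int = 50_000,
    kT: float = 1.0,
) -> FreeEnergyProfile:
    """Binless multistate reweighting, histogrammed only for presentation.

    Solves the self-consistent equations for the window offsets over the
    pooled samples (no histogram discretisation enters the estimation),
    then bins the unbiased sample weights to produce a profile comparable
    with :func:`wham_1d`.  Cross-check route only.
    """
    windows = [w for w in all_samples if len(w.retained) > 0]
    pooled = np.concatenate([w.retained for w in windows])
    n_i = np.array([len(w.retained) for w in windows], dtype=float)
    # (n_windows, n_total) reduced bias energies of every pooled sample
    u = np.stack([w.bias(pooled) / kT for w in windows])

    f = np.zeros(len(windows))
    for _ in range(max_iter):
        log_den = logsumexp(f[:, None] - u, b=n_i[:, None], axis=0)
        f_new = -logsumexp(-u - log_den[None, :], axis=1)
        f_new -= f_new[0]
        resid = float(np.max(np.abs(f_new - f)))
        f = f_new
        if resid < tol:
            break
    else:
        raise WhamConvergenceError(
            f"MBAR iteration did not converge (residual {resid:.3g} kT)",
            residual=resid,
        )

    log_w = -logsumexp(f[:, None] - u, b=n_i[:, None], axis=0)
    edges = np.linspace(pooled.min(), pooled.max(), n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    idx = np.clip(np.digitize(pooled, edges) - 1, 0, n_bins - 1)
    log_p = np.full(n_bins, -np.inf)
    for b in range(n_bins):
        sel = idx == b
        if np.any(sel):
            log_p[b] = logsumexp(log_w[sel])
    mask = np.isfinite(log_p)
    free = -kT * log_p[mask]
    free -= free.min()
    return FreeEnergyProfile(alpha=centers[mask], f=free, kT=kT,
                             window_offsets=kT * f)
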