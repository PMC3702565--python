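"""The standard synthetic validation benchmark, end to end.

This module pins down the reference study conditions for validating the
whole pipeline on the 2D curved-valley landscape — ensemble generation,
pathway construction, window layout, replica-exchange Langevin sampling,
WHAM — and measures the reconstruction against the brute-force quadrature
oracle.  Tests, examples and the acceptance script all run the same
benchmark through this module, so the conditions are defined in exactly
one place.

Conditions (see docs/methods.md for rationale): a harmonic tube of
stiffness 16 kT around a 120° arc of radius 6, tilted by 4 kT end to end
(or carved with a 12 kT angular well for the single-minimum variant);
a synthetic ensemble of 50,000 frames with sigma = 0.25 along an arc
extended 10% past each valley-floor endpoint; 100 projection bins with a
50-frame minimum; a P = 6 curve fit; 30 umbrella windows with
kappa = 3,111 kT; overdamped Langevin with dt = 0.005, swap attempts
every 20 steps, samples every 10 steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .hrex import SwapSchedule, run_hrex
from .pathway import PathCurve, bin_and_average, fit_curve, reparametrize
from .restraints import project, window_layout
from .toysim import (
    LangevinPropagator,
    SyntheticEnsembleSpec,
    ToyPotential,
    arc_endpoints,
    curved_valley_potential,
    make_synthetic_ensemble,
    reference_free_energy,
)
from .wham import FreeEnergyProfile, WindowSamples, count_minima, wham_1d

__all__ = [
    "BenchmarkResult",
    "tilted_valley",
    "single_well_valley",
    "extended_arc_spec",
    "build_benchmark_pathway",
    "sample_windows",
    "run_benchmark",
]

KT = 1.0
TILT = 4.0
WIDTH_K = 16.0
WELL_K = 12.0
KAPPA = 3111.0
N_WINDOWS = 30
N_FRAMES = 50_000
SIGMA = 0.25
N_BINS = 100
MIN_COUNT = 50
P_MODES = 6
DT = 0.005
SWAP_INTERVAL = 20
SAMPLE_INTERVAL = 10
ARC_EXTENSION = 0.10


def tilted_valley() -> ToyPotential:
    """The 4-kT-tilted curved valley (known end-to-end free-energy drop)."""
    return curved_valley_potential(tilt=TILT, width_k=WIDTH_K, end_k=0.0)


def single_well_valley() -> ToyPotential:
    """The single-minimum variant: an angular well at mid-arc."""
    return curved_valley_potential(width_k=WIDTH_K, well_k=WELL_K, end_k=0.0)


def extended_arc_spec(pot: ToyPotential, seed: int,
                      extend: float = ARC_EXTENSION) -> SyntheticEnsembleSpec:
    """Ensemble recipe along the valley arc, extended past both floor ends.

    Extending the sampled path ~10% beyond each endpoint mirrors pathways
    that reach past the endpoint crystal structures and keeps both
    endpoint states projecting well inside the profile.
    """
    p = pot.params
    th0, th1 = p["theta_range"]
    radius = p["radius"]
    d = extend * (th1 - th0)
    e0, e1 = th0 - d, th1 + d
    a = radius * np.array([np.cos(e0), np.sin(e0)])
    b = radius * np.array([np.cos(e1), np.sin(e1)])
    half = 0.5 * np.linalg.norm(b - a)
    sagitta = radius - np.sqrt(radius**2 - half**2)
    return SyntheticEnsembleSpec(a=a, b=b, shape="arc", bulge=sagitta,
                                 sigma=SIGMA, n_frames=N_FRAMES, seed=seed)


def build_benchmark_pathway(pot: ToyPotential, seed: int) -> PathCurve:
    """Ensemble -> bin averages -> smooth fit -> arc-length curve."""
    spec = extended_arc_spec(pot, seed)
    frames = make_synthetic_ensemble(spec)
    nodes = bin_and_average([frames], spec.a, spec.b, n_bins=N_BINS,
                            min_count=MIN_COUNT)
    return reparametrize(fit_curve(nodes, P=P_MODES))


def sample_windows(
    pot: ToyPotential,
    curve: PathCurve,
    seed: int,
    n_steps: int,
) -> tuple[list[WindowSamples], float]:
    """Replica-exchange umbrella sampling; returns per-window samples and
    the overall swap acceptance fraction."""
    ws = window_layout(curve, N_WINDOWS, KAPPA / curve.length**2)
    prop = LangevinPropagator(pot, dt=DT, kT=KT, biases=ws)
    x0 = np.stack([w.anchor for w in ws])
    res = run_hrex(
        prop,
        [w.energy for w in ws],
        x0,
        SwapSchedule(interval=SWAP_INTERVAL, seed=seed + 1),
        n_steps=n_steps,
        kT=KT,
        sample_interval=SAMPLE_INTERVAL,
        alpha_of=lambda i, x: ws[i].alpha_linear(x),
        seed=seed,
    )
    samples = [
        WindowSamples(index=w.index, alpha_ref=w.alpha_ref, kappa=w.kappa,
                      samples=s)
        for w, s in zip(ws, res.alpha_samples)
    ]
    return samples, res.acceptance_fraction


@dataclass
class BenchmarkResult:
    profile: FreeEnergyProfile
    oracle: FreeEnergyProfile
    rms_kt: float            # RMS deviation from the oracle on [0.05, 0.95]
    delta_f_kt: float        # end-to-end free-energy difference (WHAM)
    oracle_delta_f_kt: float
    acceptance: float
    n_minima: Optional[int]  # single-well variant only
    curve: PathCurve


def run_benchmark(
    seed: int,
    n_steps: int = 2_000_000,
    variant: str = "tilt",
    oracle_grid: int = 700,
) -> BenchmarkResult:
    """Full pipeline on the curved valley, scored against the oracle.

    ``variant`` selects the tilted landscape (known 4 kT end-to-end drop)
    or the single-well landscape (minima-count check).  All randomness
    derives from ``seed``.
    """
    if variant == "tilt":
        pot = tilted_valley()
    elif variant == "well":
        pot = single_well_valley()
    else:
        raise ValueError(f"unknown variant {variant!r}")

    curve = build_benchmark_pathway(pot, seed)
    samples, acceptance = sample_windows(pot, curve, seed + 7, n_steps)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        profile = wham_1d(samples, n_bins=200, kT=KT)
    oracle = reference_free_energy(pot, curve, profile.alpha, kT=KT,
                                   grid_points=oracle_grid)

    mask = (profile.alpha >= 0.05) & (profile.alpha <= 0.95)
    f_oracle = np.interp(profile.alpha[mask], oracle.alpha, oracle.f)
    resid = profile.f[mask] - f_oracle
    resid -= resid.mean()
    rms = float(np.sqrt(np.mean(resid**2)))

    a, b = arc_endpoints(pot)
    alpha_a = project(curve, a)
    alpha_b = project(curve, b)
    delta_f = profile.value_at(alpha_b) - profile.value_at(alpha_a)
    oracle_delta = float(
        np.interp(alpha_b, oracle.alpha, oracle.f)
        - np.interp(alpha_a, oracle.alpha, oracle.f)
    )

    n_minima = None
    if variant == "well":
        sub = FreeEnergyProfile(
            alpha=profile.alpha[mask], f=profile.f[mask] - profile.f[mask].min(),
            kT=KT,
        )
        n_minima = count_minima(sub, prominence=0.1)

    return BenchmarkResult(
        profile=profile,
        oracle=oracle,
        rms_kt=rms,
        delta_f_kt=float(delta_f),
        oracle_delta_f_kt=oracle_delta,
        acceptance=float(acceptance),
        n_minima=n_minima,
        curve=curve,
    )
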