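"""Hamiltonian replica exchange over umbrella windows.

Adjacent windows periodically attempt to swap their restraining potentials.
Swapping the biases of windows i and j holding configurations x_i and x_j
changes the combined Hamiltonian by

    Delta = [u_i(x_j) + u_j(x_i) - u_i(x_i) - u_j(x_j)] / kT,

and the attempt is accepted if Delta <= 0, otherwise with probability
exp(-Delta).  The base potential is identical in all windows and cancels
from Delta, so only bias energies are needed.

Bookkeeping convention: the state array is indexed by *window*, i.e. row w
always holds the configuration currently governed by window w's bias.  An
accepted swap therefore exchanges the two configurations between the rows
(equivalent to exchanging bias assignments between replicas, but it makes
the per-window sample series — what WHAM consumes — fall out directly).
Replica identities are tracked alongside so the permutation invariant can
be checked.

Randomness is split into two independent streams (dynamics vs swap
decisions), so disabling exchange leaves the dynamics stream untouched and
the run degenerates bit-for-bit into independent umbrella sampling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Protocol, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SwapSchedule",
    "HrexResult",
    "swap_delta",
    "attempt_swap",
    "run_hrex",
]

KT_300K = 0.5962  # kcal/mol at 300 K


@dataclass(frozen=True)
class SwapSchedule:
    """When and which adjacent pairs attempt to exchange.

    ``interval`` is in propagation steps.  Pairing alternates between the
    odd phase (0,1),(2,3),... and the even phase (1,2),(3,4),... so that no
    window takes part in two simultaneous attempts.
    """

    interval: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.interval < 1:
            raise ValueError("swap interval must be positive")

    def pairs(self, n_windows: int, phase: int) -> list[tuple[int, int]]:
        start = phase % 2
        return [(i, i + 1) for i in range(start, n_windows - 1, 2)]


class Propagator(Protocol):
    """Anything that can advance all window configurations by n steps."""

    def __call__(
        self, x: np.ndarray, n_steps: int, rng: np.random.Generator
    ) -> np.ndarray: ...


@dataclass
class HrexResult:
    """Exchange log plus per-window sample series."""

    exchange_log: pd.DataFrame  # columns: step, window_i, window_j, delta, accepted
    alpha_samples: list[np.ndarray]  # per window, linearised projection series
    configs: Optional[list[np.ndarray]]  # per window, sampled configurations
    replica_of_window: np.ndarray  # final replica id held by each window

    @property
    def acceptance_fraction(self) -> float:
        if len(self.exchange_log) == 0:
            return float("nan")
        return float(self.exchange_log["accepted"].mean())


def swap_delta(u_i, u_j, x_i, x_j, kT: float) -> float:
    """Dimensionless change in the combined Hamiltonian for a bias swap."""
    if kT <= 0:
        raise ValueError("kT must be positive")
    return (u_i(x_j) + u_j(x_i) - u_i(x_i) - u_j(x_j)) / kT

def attempt_swap(delta: float, rng: np.random.Generator) -> bool:
    """Metropolis decision: accept if delta <= 0, else with probability exp(-delta)."""
    if delta <= 0.0:
        return True
    return bool(rng.random() < np.exp(-delta))


def run_hrex(
    propagate: Propagator,
    biases: Sequence[Callable[[np.ndarray], float]],
    x0: np.ndarray,
    schedule: SwapSchedule,
    n_steps: int,
    kT: float = 1.0,
    sample_interval: int = 1,
    alpha_of: Optional[Callable[[int, np.ndarray], float]] = None,
    exchange: bool = True,
    keep_configs: bool = False,
    seed: int = 0,
) -> HrexResult:
    """Interleave propagation with scheduled adjacent-pair swap attempts.

    Parameters
    ----------
    propagate
        Advances the full (n_windows, dim) state array; row w must be
        propagated under window w's bias.
    biases
        Per-window bias energy functions of a single configuration (the
        shared base potential cancels from the swap criterion).
    x0
        Initial configurations, shape (n_windows, dim).
    alpha_of
        Optional map (window index, configuration) -> sampled collective
        coordinate; when given, its values are recorded every
        ``sample_interval`` steps as the per-window series WHAM consumes.
        Otherwise configurations themselves are recorded.
    exchange
        With False, swap machinery is skipped entirely and the run is
        plain independent umbrella sampling on the same dynamics stream.
    """
    x = np.array(x0, dtype=float)
    n_windows = len(biases)
    if x.shape[0] != n_windows:
        raise ValueError("x0 must have one row per window")
    if n_windows < 2:
        raise ValueError("need at least 2 windows")

    dyn_rng = np.random.default_rng(seed)
    swap_rng = np.random.default_rng(schedule.seed)

    replica = np.arange(n_windows)
    log_rows: list[tuple[int, int, int, float, bool]] = []
    samples: list[list[float]] = [[] for _ in range(n_windows)]
    configs: list[list[np.ndarray]] = [[] for _ in range(n_windows)]
    phase = 0

    step = 0
    while step < n_steps:
        n_block = min(schedule.interval, n_steps - step)
        for sub in range(n_block):
            try:
                x = propagate(x, 1, dyn_rng)
            except FloatingPointError as exc:  # pragma: no cover - defensive
                raise RuntimeError(
                    f"sampler failure at step {step + sub}"
                ) from exc
            if (step + sub + 1) % sample_interval == 0:
                for w in range(n_windows):
                    if alpha_of is not None:
                        samples[w].append(alpha_of(w, x[w]))
                    if keep_configs or alpha_of is None:
                        configs[w].append(x[w].copy())
        step += n_block
        if exchange and step < n_steps:
            for i, j in schedule.pairs(n_windows, phase):
                delta = swap_delta(
                    biases[i], biases[j], x[i], x[j], kT
                )
                ok = attempt_swap(delta, swap_rng)
                log_rows.append((step, i, j, float(delta), ok))
                if ok:
                    x[[i, j]] = x[[j, i]]
                    replica[[i, j]] = replica[[j, i]]
            phase += 1

    log = pd.DataFrame(
        log_rows, columns=["step", "window_i", "window_j", "delta", "accepted"]
    )
    return HrexResult(
        exchange_log=log,
        alpha_samples=[np.asarray(s) for s in samples],
        configs=(
            [np.asarray(c) for c in configs]
            if (keep_configs or alpha_of is None)
            else None
        ),
        replica_of_window=replica,
    )
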