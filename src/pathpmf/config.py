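"""Run configuration with the method's standard defaults.

The defaults are the reference protocol values: 100 projection segments,
one sine mode (P = 1), 30 umbrella windows spaced 1/29 apart, a Cartesian
spring constant K = 0.08 kcal/mol/Å² (kappa = K L² in curve-parameter
units), kT at 300 K, and replica-exchange attempts every 400 fs.  Every
random procedure takes an explicit seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

from .fileio import config_hash
from .hrex import KT_300K

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    n_bins: int = 100          # projection segments for pathway nodes
    P: int = 1                 # sine modes in the curve basis
    n_windows: int = 30        # umbrella windows over alpha in [0, 1]
    K: float = 0.08            # kcal/mol/Å², Cartesian tangent spring
    kT: float = KT_300K        # kcal/mol (300 K)
    hrex_interval: int = 200   # propagation steps between swap attempts
    equilibration_cut: float = 0.25
    wham_bins: int = 200
    seed: int = 0
    out_dir: str = "."

    def __post_init__(self) -> None:
        if self.n_bins < 2 or self.n_windows < 2:
            raise ValueError("n_bins and n_windows must be at least 2")
        if self.K <= 0 or self.kT <= 0:
            raise ValueError("K and kT must be positive")
        if self.P < 0:
            raise ValueError("P must be non-negative")

    def hash(self) -> str:
        return config_hash(asdict(self))
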