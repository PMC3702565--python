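"""Trajectory analyses: projections, domain geometry, RMSD tables, salt bridges.

These are the descriptive analyses applied to unrestrained and restrained
trajectories: projecting every frame onto the pathway to follow the
transition in time, tracking inter-domain centre distances (the classic
reduced picture of the open/closed motion of adenylate kinase and similar
hinged proteins), tabulating RMSDs of time-averaged conformations against
reference crystal structures, and assigning salt bridges only when a
directional hydrogen bond links the two side chains.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .geometry import Conformation, Ensemble, kabsch_align, mean_conformation, rmsd
from .pathway import PathCurve
from .restraints import project

__all__ = [
    "DomainDefinition",
    "SaltBridgeCriterion",
    "ADK_DOMAINS",
    "projection_timeseries",
    "domain_distances",
    "rmsd_table",
    "detect_salt_bridges",
]


@dataclass(frozen=True)
class DomainDefinition:
    """A named domain as a set of 1-based inclusive residue ranges."""

    name: str
    ranges: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.ranges:
            raise ValueError("domain must contain at least one range")
        spans = sorted(self.ranges)
        for (a0, a1), (b0, b1) in zip(spans[:-1], spans[1:]):
            if a1 >= b0:
                raise ValueError(f"overlapping ranges in domain {self.name}")
        for lo, hi in self.ranges:
            if lo > hi:
                raise ValueError(f"empty range {lo}-{hi} in domain {self.name}")

    def mask(self, labels: Sequence[int]) -> np.ndarray:
        lab = np.asarray(labels)
        m = np.zeros(len(lab), dtype=bool)
        for lo, hi in self.ranges:
            m |= (lab >= lo) & (lab <= hi)
        return m


#: The three domains of adenylate kinase in the standard residue numbering.
ADK_DOMAINS = (
    DomainDefinition("CORE", ((1, 29), (60, 121), (160, 214))),
    DomainDefinition("AMPbd", ((30, 59),)),
    DomainDefinition("LID", ((122, 159),)),
)


def projection_timeseries(
    ens: Ensemble, curve: PathCurve, reference: Conformation
) -> pd.DataFrame:
    """Pathway coordinate alpha of every frame as a function of time.

    Frames are Kabsch-aligned to the reference before the nonlinear
    closest-point projection, so rigid-body motion never leaks into alpha.
    """
    times = ens.times()
    alphas = np.empty(len(ens))
    for i, frame in enumerate(ens.frames):
        aligned, _ = kabsch_align(frame, reference)
        alphas[i] = project(curve, aligned)
    return pd.DataFrame({"time": times, "alpha": alphas})


def domain_distances(
    ens: Ensemble,
    domains: Sequence[DomainDefinition] = ADK_DOMAINS,
    pairs: Optional[Sequence[tuple[str, str]]] = None,
) -> pd.DataFrame:
    """Per-frame distances between unweighted Cα domain centres.

    Defaults to every domain pair; internal distances are invariant under
    rigid-body motion, so no alignment is applied.
    """
    by_name = {d.name: d for d in domains}
    if pairs is None:
        pairs = list(combinations(by_name, 2))
    labels = ens.frames[0].labels
    if labels is None:
        raise ValueError("ensemble frames carry no residue labels")
    masks = {}
    for d in domains:
        m = d.mask(labels)
        if not m.any():
            rng_txt = ", ".join(f"{lo}-{hi}" for lo, hi in d.ranges)
            raise ValueError(f"domain {d.name} ({rng_txt}) matches no residues")
        masks[d.name] = m

    cols: dict[str, np.ndarray] = {"time": ens.times()}
    for a, b in pairs:
        if a not in by_name or b not in by_name:
            raise ValueError(f"unknown domain in pair ({a}, {b})")
        cols[f"{a}-{b}"] = np.array(
            [
                np.linalg.norm(
                    f.as_atoms()[masks[a]].mean(axis=0)
                    - f.as_atoms()[masks[b]].mean(axis=0)
                )
                for f in ens.frames
            ]
        )
    return pd.DataFrame(cols)


def rmsd_table(
    ensembles: Mapping[str, Ensemble],
    references: Mapping[str, Conformation],
    last_fraction: float = 0.4,
) -> pd.DataFrame:
    """Aligned RMSD of trailing-window mean conformations against references.

    For each ensemble the frames in the trailing ``last_fraction`` are
    aligned and averaged; the mean is then superposed onto each reference
    and the RMSD reported.  Rows are references, columns are ensembles.
    """
    names = list(ensembles)
    ref_names = list(references)
    table = np.empty((len(ref_names), len(names)))
    for j, name in enumerate(names):
        ens = ensembles[name]
        # average in the frame of the first reference; alignment to each
        # reference happens again before the RMSD, so the choice is inert
        mean = mean_conformation(ens, references[ref_names[0]], last_fraction)
        for i, rname in enumerate(ref_names):
            aligned, r = kabsch_align(mean, references[rname])
            table[i, j] = r
    return pd.DataFrame(table, index=ref_names, columns=names)


# ---------------------------------------------------------------------------
# salt bridges


@dataclass(frozen=True)
class SaltBridgeCriterion:
    """Directional hydrogen-bond criterion for assigning a salt bridge.

    A Lys/Arg–Asp/Glu pair is assigned only when some donor nitrogen and
    acceptor oxygen are within ``distance_cutoff`` Å *and* a donor
    hydrogen makes a donor–H···acceptor angle of at least ``angle_cutoff``
    degrees.  Without hydrogens in the input, detection falls back to the
    heavy-atom distance alone and the result is flagged accordingly.
    """

    distance_cutoff: float = 3.5
    angle_cutoff: float = 130.0

    def __post_init__(self) -> None:
        if self.distance_cutoff <= 0 or self.angle_cutoff <= 0:
            raise ValueError("cutoffs must be positive")


_DONOR_ATOMS = {
    "LYS": {"NZ": ("HZ1", "HZ2", "HZ3")},
    "ARG": {
        "NE": ("HE",),
        "NH1": ("HH11", "HH12"),
        "NH2": ("HH21", "HH22"),
    },
}
_ACCEPTOR_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}


@dataclass
class SaltBridgeReport:
    """Per-frame detections plus pair occupancies over the frame window."""

    per_frame: list[list[tuple[int, int]]]
    occupancy: dict[tuple[int, int], float]
    hydrogen_based: bool


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle at vertex b of the triangle a-b-c, in degrees."""
    u, v = a - b, c - b
    cosv = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosv, -1.0, 1.0))))


def detect_salt_bridges(
    frames: Sequence, criterion: SaltBridgeCriterion = SaltBridgeCriterion()
) -> SaltBridgeReport:
    """Assign salt bridges in full-atom frames.

    ``frames`` is a sequence of atom arrays (e.g. biotite ``AtomArray``),
    each exposing ``coord``, ``atom_name``, ``res_name`` and ``res_id``
    attributes.  Eligible donors are Lys/Arg side-chain nitrogens, eligible
    acceptors Asp/Glu carboxylate oxygens.
    """
    per_frame: list[list[tuple[int, int]]] = []
    counts: dict[tuple[int, int], int] = {}
    any_h = False

    for frame in frames:
        coord = np.asarray(frame.coord, dtype=float)
        atom_name = np.asarray(frame.atom_name)
        res_name = np.asarray(frame.res_name)
        res_id = np.asarray(frame.res_id)

        donors = []  # (res_id, N coord, list of H coords)
        for rn, atom_map in _DONOR_ATOMS.items():
            for n_name, h_names in atom_map.items():
                sel = (res_name == rn) & (atom_name == n_name)
                for k in np.flatnonzero(sel):
                    rid = int(res_id[k])
                    hs = []
                    for hn in h_names:
                        hsel = (res_id == rid) & (atom_name == hn)
                        hs.extend(coord[hsel])
                    donors.append((rid, coord[k], hs))
        acceptors = []
        for rn, o_names in _ACCEPTOR_ATOMS.items():
            for o_name in o_names:
                sel = (res_name == rn) & (atom_name == o_name)
                for k in np.flatnonzero(sel):
                    acceptors.append((int(res_id[k]), coord[k]))

        found: set[tuple[int, int]] = set()
        for d_rid, n_xyz, hs in donors:
            if hs:
                any_h = True
            for a_rid, o_xyz in acceptors:
                if np.linalg.norm(n_xyz - o_xyz) > criterion.distance_cutoff:
                    continue
                if hs:
                    ok = any(
                        _angle_deg(n_xyz, h, o_xyz) >= criterion.angle_cutoff
                        for h in hs
                    )
                else:
                    ok = True  # heavy-atom fallback, flagged below
                if ok:
                    found.add((d_rid, a_rid))
        pairs = sorted(found)
        per_frame.append(pairs)
        for p in pairs:
            counts[p] = counts.get(p, 0) + 1

    n = max(len(per_frame), 1)
    occupancy = {p: c / n for p, c in sorted(counts.items())}
    return SaltBridgeReport(
        per_frame=per_frame, occupancy=occupancy, hydrogen_based=any_h
    )
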