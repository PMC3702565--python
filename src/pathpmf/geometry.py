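"""Rigid-body superposition and averaging in the flattened Cα-coordinate space.

A protein conformation is represented by the Cartesian positions of its N
Cα atoms, i.e. a single vector in a D = 3N dimensional space.  All pathway
and restraint machinery in this package operates on such vectors; this
module provides the elementary geometric operations on them: optimal
(Kabsch) superposition, root-mean-square deviation, and ensemble averaging
after alignment.

All superpositions are unweighted (every Cα counts equally) and always use
a proper rotation (determinant +1); mirror images are never produced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Conformation",
    "Ensemble",
    "kabsch_align",
    "kabsch_rotation",
    "rmsd",
    "mean_conformation",
]


@dataclass(frozen=True)
class Conformation:
    """A single conformation: N atoms as a flat vector of 3N coordinates (Å).

    Parameters
    ----------
    coords
        Flat array of length ``3 * n_atoms``, ordered (x, y, z) per atom.
    labels
        Optional 1-based residue identifiers, one per atom.
    """

    coords: np.ndarray
    labels: Optional[Sequence[int]] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float).ravel()
        if coords.size == 0 or coords.size % 3 != 0:
            raise ValueError(
                f"coordinate vector length must be a positive multiple of 3, got {coords.size}"
            )
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        object.__setattr__(self, "coords", coords)
        if self.labels is not None and len(self.labels) != coords.size // 3:
            raise ValueError("labels must have one entry per atom")

    @property
    def n_atoms(self) -> int:
        return self.coords.size // 3

    @property
    def dim(self) -> int:
        return self.coords.size

    def as_atoms(self) -> np.ndarray:
        """Return an (N, 3) view of the coordinates."""
        return self.coords.reshape(-1, 3)


@dataclass
class Ensemble:
    """An ordered sequence of conformations with a uniform atom count.

    ``dt`` is the frame time spacing in ps; it is bookkeeping only and does
    not affect any computation except reported time stamps.
    """

    frames: Sequence[Conformation]
    dt: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.frames) == 0:
            raise ValueError("ensemble must contain at least one frame")
        n = self.frames[0].n_atoms
        for i, f in enumerate(self.frames):
            if f.n_atoms != n:
                raise ValueError(f"frame {i} has {f.n_atoms} atoms, expected {n}")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return self.frames[0].n_atoms

    def as_array(self) -> np.ndarray:
        """Stack all frames into an (n_frames, 3N) array."""
        return np.stack([f.coords for f in self.frames])

    def times(self) -> np.ndarray:
        dt = 1.0 if self.dt is None else self.dt
        return dt * np.arange(len(self.frames))


def _check_pair(a: Conformation, b: Conformation) -> None:
    if a.n_atoms != b.n_atoms:
        raise ValueError(f"atom count mismatch: {a.n_atoms} vs {b.n_atoms}")


def kabsch_rotation(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Optimal proper rotation matrix aligning centred `mobile` onto centred `reference`.

    Both inputs are (N, 3) arrays already centred on their centroids.  The
    reflection-requiring degenerate case is resolved by flipping the sign of
    the singular vector with the smallest singular value, which forces
    det(R) = +1.
    """
    h = mobile.T @ reference
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    return vt.T @ diag @ u.T


def kabsch_align(
    mobile: Conformation, reference: Conformation
) -> tuple[Conformation, float]:
    """Least-RMSD rigid superposition of `mobile` onto `reference`.

    Returns the transformed conformation and the minimised RMSD.  Only
    proper rotations are used, so chirality is preserved.  Requires N >= 3
    non-collinear reference atoms for the rotation to be well determined.
    """
    _check_pair(mobile, reference)
    n = mobile.n_atoms
    if n < 3:
        raise ValueError(f"alignment requires at least 3 atoms, got {n}")
    mob = mobile.as_atoms()
    ref = reference.as_atoms()
    ref_c = ref - ref.mean(axis=0)
    # collinearity check on the reference: rank of the centred coordinates
    if np.linalg.matrix_rank(ref_c, tol=1e-8) < 2:
        raise ValueError("reference atoms are collinear; rotation is degenerate")
    mob_centroid = mob.mean(axis=0)
    rot = kabsch_rotation(mob - mob_centroid, ref_c)
    aligned = (mob - mob_centroid) @ rot.T + ref.mean(axis=0)
    out = Conformation(aligned.ravel(), labels=mobile.labels)
    return out, rmsd(out, reference)


def rmsd(a: Conformation, b: Conformation) -> float:
    """Root-mean-square deviation between two conformations, no alignment.

    Compose with :func:`kabsch_align` for the superposed RMSD.
    """
    _check_pair(a, b)
    diff = a.as_atoms() - b.as_atoms()
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def mean_conformation(
    ens: Ensemble, reference: Conformation, last_fraction: float = 1.0
) -> Conformation:
    """Average conformation over the trailing fraction of an ensemble.

    Each selected frame is Kabsch-aligned to `reference` before the
    component-wise average, so the mean reflects internal structure rather
    than rigid-body drift.
    """
    if not 0.0 < last_fraction <= 1.0:
        raise ValueError("last_fraction must lie in (0, 1]")
    n = len(ens)
    start = n - max(1, int(round(last_fraction * n)))
    selected = ens.frames[start:]
    if not selected:
        raise ValueError("empty frame selection")
    acc = np.zeros(ens.n_atoms * 3)
    for f in selected:
        aligned, _ = kabsch_align(f, reference)
        acc += aligned.coords
    return Conformation(acc / len(selected), labels=reference.labels)
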