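"""File formats: PDB input, and the package's text artifact formats.

Every artifact written here starts with ``#`` header lines recording the
tool version, a configuration hash and the seeds in play, so a profile or
window file can always be traced back to the run that produced it.  Units:
coordinates and arc length in Å, the curve parameter alpha dimensionless
in [0, 1], energies in kcal/mol on protein paths and kT units on toy
paths (stated per file in the header).

Curve and window files are JSON (self-describing, lossless round trip for
IEEE doubles); sample series, profiles and exchange logs are whitespace
columnar text.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from . import __version__
from .geometry import Conformation, Ensemble
from .pathway import PathCurve, reparametrize
from .restraints import UmbrellaWindow
from .wham import FreeEnergyProfile, WindowSamples

__all__ = [
    "read_pdb_ca",
    "write_pdb_ca",
    "read_text_trajectory",
    "write_text_trajectory",
    "write_curve",
    "read_curve",
    "write_windows",
    "read_windows",
    "write_samples",
    "read_samples",
    "write_profile",
    "read_profile",
    "write_exchange_log",
    "read_exchange_log",
]

PathLike = Union[str, Path]


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header(kind: str, units: str, seeds=None, cfg_hash: Optional[str] = None) -> str:
    lines = [
        f"# pathpmf {__version__} {kind}",
        f"# units: {units}",
        f"# config: {cfg_hash or 'n/a'}",
        f"# seeds: {seeds if seeds is not None else 'n/a'}",
    ]
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# PDB


def read_pdb_ca(path: PathLike) -> Ensemble:
    """Cα coordinates from a (possibly multi-model) PDB file.

    Atoms named ``CA`` are extracted in file order; residue ids (1-based
    PDB numbering) become the conformation labels.  Each model becomes one
    frame.
    """
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure()  # AtomArrayStack
    mask = stack.atom_name == "CA"
    frames = []
    labels = stack.res_id[mask].tolist()
    for model in stack:
        ca = model[mask]
        frames.append(Conformation(ca.coord.ravel(), labels=labels))
    return Ensemble(frames)


def write_pdb_ca(path: PathLike, ens: Ensemble) -> None:
    """Write an ensemble as a multi-model Cα-only PDB file."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = ens.n_atoms
    labels = ens.frames[0].labels or list(range(1, n + 1))
    coords = np.stack([f.as_atoms() for f in ens.frames])
    arr = struc.AtomArrayStack(len(ens.frames), n)
    arr.coord = coords
    arr.atom_name = np.full(n, "CA")
    arr.res_name = np.full(n, "GLY")
    arr.element = np.full(n, "C")
    arr.res_id = np.asarray(labels, dtype=int)
    arr.chain_id = np.full(n, "A")
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# plain-text trajectories


def write_text_trajectory(path: PathLike, frames: np.ndarray, seeds=None) -> None:
    """Frames as blank-line-separated blocks, three coordinates per line.

    ``frames`` is (n_frames, D); within a block each line carries one
    (x, y, z) triplet when D is a multiple of 3, otherwise the whole frame
    on one line.
    """
    frames = np.atleast_2d(np.asarray(frames, dtype=float))
    d = frames.shape[1]
    per_line = 3 if d % 3 == 0 else d
    with open(path, "w") as fh:
        fh.write(_header("trajectory", "Å", seeds=seeds))
        for fr in frames:
            for row in fr.reshape(-1, per_line):
                fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")
            fh.write("\n")


def read_text_trajectory(path: PathLike) -> np.ndarray:
    """Inverse of :func:`write_text_trajectory`; returns (n_frames, D)."""
    blocks: list[list[float]] = []
    current: list[float] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if line.startswith("#"):
                continue
            if not line:
                if current:
                    blocks.append(current)
                    current = []
                continue
            try:
                current.extend(float(tok) for tok in line.split())
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: malformed coordinate line") from exc
    if current:
        blocks.append(current)
    if not blocks:
        raise ValueError(f"{path}: no frames found")
    d = len(blocks[0])
    for i, b in enumerate(blocks):
        if len(b) != d:
            raise ValueError(f"{path}: frame {i} has {len(b)} values, expected {d}")
    return np.array(blocks)


# ---------------------------------------------------------------------------
# curves


def write_curve(path: PathLike, curve: PathCurve, seeds=None,
                cfg_hash: Optional[str] = None) -> None:
    """Self-describing JSON curve file: basis coefficients, arc table, length."""
    t_grid, s_grid = curve.arc_table
    doc = {
        "format": "pathpmf-curve",
        "version": __version__,
        "units": "Å; parameter dimensionless",
        "config": cfg_hash or "n/a",
        "seeds": seeds,
        "dim": curve.dim,
        "P": curve.n_modes,
        "uniform": curve.uniform,
        "a": curve.a.tolist(),
        "b": curve.b.tolist(),
        "c": curve.c.tolist(),
        "L": curve.length,
        "arc_table_t": t_grid.tolist(),
        "arc_table_s": s_grid.tolist(),
    }
    Path(path).write_text(json.dumps(doc))


def read_curve(path: PathLike) -> PathCurve:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "pathpmf-curve":
        raise ValueError(f"{path}: not a pathpmf curve file")
    curve = PathCurve(
        np.array(doc["a"]), np.array(doc["b"]), np.array(doc["c"]).reshape(doc["dim"], -1)
    )
    if doc["uniform"]:
        curve = reparametrize(curve)
    return curve


# ---------------------------------------------------------------------------
# umbrella windows


def write_windows(path: PathLike, windows: Sequence[UmbrellaWindow],
                  seeds=None, cfg_hash: Optional[str] = None) -> None:
    doc = {
        "format": "pathpmf-windows",
        "version": __version__,
        "units": "anchor Å; K energy/Å²; alpha dimensionless",
        "config": cfg_hash or "n/a",
        "seeds": seeds,
        "windows": [
            {
                "index": w.index,
                "alpha_ref": w.alpha_ref,
                "K": w.K,
                "L": w.L,
                "anchor": w.anchor.tolist(),
                "tangent": w.tangent.tolist(),
            }
            for w in windows
        ],
    }
    Path(path).write_text(json.dumps(doc))


def read_windows(path: PathLike) -> list[UmbrellaWindow]:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "pathpmf-windows":
        raise ValueError(f"{path}: not a pathpmf window file")
    return [
        UmbrellaWindow(
            index=w["index"],
            alpha_ref=w["alpha_ref"],
            anchor=np.array(w["anchor"]),
            tangent=np.array(w["tangent"]),
            K=w["K"],
            L=w["L"],
        )
        for w in doc["windows"]
    ]


# ---------------------------------------------------------------------------
# samples and profiles


def write_samples(path: PathLike, ws: WindowSamples, seeds=None,
                  cfg_hash: Optional[str] = None) -> None:
    """Per-window alpha sample series: columns (step, alpha)."""
    with open(path, "w") as fh:
        fh.write(_header("window-samples", "alpha dimensionless; kappa energy",
                         seeds=seeds, cfg_hash=cfg_hash))
        fh.write(f"# window: index={ws.index} alpha_ref={ws.alpha_ref:.17g} "
                 f"kappa={ws.kappa:.17g} cut={ws.cut:.17g}\n")
        for i, a in enumerate(ws.samples):
            fh.write(f"{i} {a:.17g}\n")


def read_samples(path: PathLike) -> WindowSamples:
    meta = None
    vals = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if line.startswith("# window:"):
                meta = dict(tok.split("=") for tok in line[len("# window:"):].split())
                continue
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected 'step alpha'")
            vals.append(float(parts[1]))
    if meta is None:
        raise ValueError(f"{path}: missing '# window:' metadata line")
    return WindowSamples(
        index=int(meta["index"]),
        alpha_ref=float(meta["alpha_ref"]),
        kappa=float(meta["kappa"]),
        samples=np.array(vals),
        cut=float(meta["cut"]),
    )


def write_profile(path: PathLike, profile: FreeEnergyProfile, seeds=None,
                  cfg_hash: Optional[str] = None, units: str = "kT") -> None:
    """Free-energy profile: columns (alpha, F, err)."""
    err = profile.err if profile.err is not None else np.full_like(profile.f, np.nan)
    with open(path, "w") as fh:
        fh.write(_header("free-energy-profile", f"alpha dimensionless; F {units}",
                         seeds=seeds, cfg_hash=cfg_hash))
        fh.write(f"# kT: {profile.kT:.17g}\n")
        fh.write("# alpha F err\n")
        for a, f, e in zip(profile.alpha, profile.f, err):
            fh.write(f"{a:.17g} {f:.17g} {e:.17g}\n")


def write_exchange_log(path: PathLike, log, seeds=None,
                       cfg_hash: Optional[str] = None) -> None:
    """Replica-exchange attempt log: columns (step, window_i, window_j,
    delta, accepted)."""
    with open(path, "w") as fh:
        fh.write(_header("exchange-log", "delta dimensionless (units of kT)",
                         seeds=seeds, cfg_hash=cfg_hash))
        fh.write("# step window_i window_j delta accepted\n")
        for row in log.itertuples(index=False):
            fh.write(f"{row.step} {row.window_i} {row.window_j} "
                     f"{row.delta:.17g} {int(row.accepted)}\n")


def read_exchange_log(path: PathLike):
    import pandas as pd

    df = pd.read_csv(
        path, sep=r"\s+", comment="#",
        names=["step", "window_i", "window_j", "delta", "accepted"],
    )
    df["accepted"] = df["accepted"].astype(bool)
    return df


def read_profile(path: PathLike) -> FreeEnergyProfile:
    rows = []
    kT = 1.0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("# kT:"):
                kT = float(line.split(":")[1])
                continue
            if not line or line.startswith("#"):
                continue
            rows.append([float(t) for t in line.split()])
    arr = np.array(rows)
    err = arr[:, 2] if arr.shape[1] > 2 and np.all(np.isfinite(arr[:, 2])) else None
    return FreeEnergyProfile(alpha=arr[:, 0], f=arr[:, 1], err=err, kT=kT)
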