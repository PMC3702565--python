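"""Shared fixtures: small conformations, curves and toy systems."""

import numpy as np
import pytest

from pathpmf import (
    Conformation,
    Ensemble,
    PathNodes,
    fit_curve,
    reparametrize,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def asym_points():
    """An asymmetric 4-atom conformation (no special symmetry axes)."""
    return Conformation(
        np.array([0.0, 0.0, 0.0, 1.0, 0.2, -0.1, 0.3, 2.0, 0.4, -0.5, 0.7, 3.0])
    )


@pytest.fixture
def random_conformation(rng):
    def make(n_atoms=50, labels=False):
        coords = rng.normal(0.0, 5.0, 3 * n_atoms)
        lab = list(range(1, n_atoms + 1)) if labels else None
        return Conformation(coords, labels=lab)

    return make


@pytest.fixture
def straight_curve():
    """Arc-length parametrised straight segment from origin to (3, 4, 0)."""
    nodes = PathNodes(np.linspace([0.0, 0.0, 0.0], [3.0, 4.0, 0.0], 20),
                      np.ones(20, dtype=int))
    return reparametrize(fit_curve(nodes, P=1))


@pytest.fixture
def semicircle_curve():
    """Arc-length parametrised unit semicircle in the (x, y) plane of 3D."""
    theta = np.linspace(0.0, np.pi, 101)
    pts = np.stack([np.cos(theta), np.sin(theta), np.zeros_like(theta)], axis=1)
    nodes = PathNodes(pts, np.ones(len(pts), dtype=int))
    return reparametrize(fit_curve(nodes, P=12))


def make_noisy_ensemble(base: Conformation, n_frames: int, sigma: float, seed: int,
                        labels=None) -> Ensemble:
    rng = np.random.default_rng(seed)
    frames = [
        Conformation(base.coords + rng.normal(0.0, sigma, base.dim), labels=labels)
        for _ in range(n_frames)
    ]
    return Ensemble(frames)
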