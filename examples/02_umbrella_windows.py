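"""Lay out tangent-only umbrella windows along a pathway.

Reproduces the reference window arithmetic: 30 windows spaced 1/29 apart
along the normalised arc length, Cartesian spring constant
K = 0.08 kcal/mol/A^2, and the equivalent curve-parameter spring constant
kappa = K L^2 for a pathway of length L = 197.2 A.
"""

import numpy as np

from pathpmf import PathNodes, fit_curve, reparametrize, window_layout, \
    umbrella_energy

# a straight 642-dimensional pathway scaled to the reference length
D, L = 642, 197.2
direction = np.ones(D) / np.sqrt(D)
nodes = PathNodes(np.outer(np.linspace(0, L, 50), direction),
                  np.ones(50, dtype=int))
curve = reparametrize(fit_curve(nodes, P=1))
print(f"curve length L = {curve.length:.1f} A")

K = 0.08
windows = window_layout(curve, 30, K)
w = windows[0]
print(f"{len(windows)} windows, spacing 1/{len(windows) - 1} "
      f"= {windows[1].alpha_ref:.5f}")
print(f"kappa = K L^2 = {w.kappa:.0f} kcal/mol "
      "(the curve-parameter spring constant)")

# the restraint acts only along the pathway tangent
x = w.anchor + 5.0 * w.tangent
print(f"5 A along the tangent: U = {umbrella_energy(w, x):.3f} kcal/mol "
      "(= K/2 * 25)")
perp = np.zeros(D)
perp[0], perp[1] = w.tangent[1], -w.tangent[0]
perp -= (perp @ w.tangent) * w.tangent
x_perp = w.anchor + 5.0 * perp / np.linalg.norm(perp)
print(f"5 A perpendicular:     U = {umbrella_energy(w, x_perp):.3f} kcal/mol "
      "(orthogonal motion is unrestrained)")
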