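# Methods

`pathpmf` computes a one-dimensional free-energy profile along a curved
pathway (a principal curve) through a high-dimensional conformational
space.  This note records the model, the numerical choices, and what the
synthetic validation does and does not demonstrate.

## Representation

A conformation is the flattened vector of N Cα positions, x ∈ ℝ^D with
D = 3N.  All geometry (superposition, projection, curve fitting) happens
in this space.  Superpositions are unweighted proper rotations (Kabsch via
SVD, smallest singular vector sign-corrected so det R = +1); mirror
solutions are never produced.  Rigid-body alignment to a fixed reference
structure removes the six exterior degrees of freedom before any pathway
operation, so the curve describes internal motion only.

## Pathway construction

1. **Line projection.** Each frame x is orthogonally projected onto the
   straight line through the two endpoint structures:
   λ = (x − a)·(b − a)/|b − a|².
2. **Binning.** The observed range [min λ, max λ] — not [0, 1] — is split
   into `n_bins` equal segments (default 100) and frames are averaged
   within each segment.  Using the observed range is why the pathway
   extends beyond both endpoint structures whenever the ensembles do.
   Bins holding fewer than `min_count` frames are dropped: a mean over a
   handful of frames carries noise comparable to the tube width and, at
   the range extremes, acts as a high-leverage point that can bend the
   global fit (we saw interior deviations an order of magnitude above the
   node noise before introducing the cutoff).  Even with the cutoff, bins
   at the extremes carry a selection bias — frames only reach there
   through favourable noise, so their mean sits off the tube centre —
   and pathway-recovery guarantees are therefore interior statements.
3. **Smooth fit.** The curve has, per dimension i,
   Z_i(t) = a_i + b_i t + Σ_{p=1..P} c_{i,p} sin(pπt), t ∈ [0, 1].
   The objective Σ_k |Z(t_k) − node_k|² is minimised jointly over the
   coefficients and the per-node parameters t_k (endpoints pinned at
   t = 0, 1; interior t_k initialised proportional to node index).  The
   basis is infinitely differentiable, which the tangent-linearised
   restraints below rely on.  P is a free parameter: P = 1 suffices for
   gently curved protein pathways; strongly bent test paths (e.g. a 120°
   circular arc) need P ≈ 5–8 for sub-10⁻³·L fidelity.
4. **Arc-length reparametrisation.** s(t) is tabulated on 2001 points with
   per-interval 5-point Gauss–Legendre quadrature; the inverse t(α) with
   α = s/L is a monotone PCHIP cubic.  After reparametrisation
   |dZ/dα| = L uniformly (verified to 10⁻³·L in tests).

**Optimiser.**  Pure alternation (linear least squares for coefficients ↔
per-node Newton for t_k) stalls: nodes can slide tangentially along the
curve almost for free, giving a long, nearly flat valley in which
alternating steps zigzag indefinitely.  After a bounded number of
alternating sweeps (50, relative tolerance 10⁻¹⁰) we therefore switch to
a joint trust-region Gauss–Newton refinement over all coefficients and
interior t_k, with an analytic sparse Jacobian and an evaluation budget
(150) rather than a gradient tolerance; the budget, not the tolerance, is
what terminates in the flat-valley regime, and the resulting geometric
accuracy is limited by basis truncation rather than by the optimiser.  A
non-finite or increased objective raises an error.

## Tangent-only umbrella restraints

Window i holds α_i = (i−1)/(n−1), the anchor Z_i = Z(α_i) and the frozen
unit tangent e_i.  Near Z_i the curve is replaced by its tangent line, so
the closest-point projection becomes linear, α_lin(x) = α_i + (x−Z_i)·e_i/L,
and the umbrella potential (κ/2)(α − α_i)², κ = K·L², becomes

    U_i(x) = (K/2) [(x − Z_i)·e_i]²,   F = −K [(x − Z_i)·e_i] e_i.

Displacements perpendicular to e_i cost exactly zero: all orthogonal
degrees of freedom stay unrestrained and are integrated out of the
resulting profile.  The approximation requires the tangent direction to
rotate little over one window spacing; the defaults (30 windows, spacing
1/29, K = 0.08 kcal/mol/Å², κ ≈ 3,111 kcal/mol for L ≈ 197 Å) mirror the
reference protocol for adenylate kinase.  The nonlinear projection
`project()` (coarse 401-point scan plus bounded refinement, boundary
values compared explicitly) is used for analysis only, never for forces.

Because U_i is a function of raw Cartesian coordinates it is not
rigid-body invariant; protein applications add a centroid restraint
(1,000 kcal/mol/Å²) and an orientation restraint (200 kcal/mol/degree²).
The "orientation angle" is implemented as the rotation angle of the
optimal superposition rotation onto the reference, θ = arccos((tr R −1)/2)
— a single axis-free scalar, smooth near zero, in degrees.  Its gradient
is evaluated by central finite differences of θ (the energy itself is
exact; a closed-form SVD gradient buys nothing at test scale).

## Hamiltonian replica exchange

Adjacent windows attempt to swap their restraining potentials every
`interval` steps, alternating odd/even pairings so no window is in two
simultaneous attempts.  The criterion is Metropolis on
Δ = [u_i(x_j) + u_j(x_i) − u_i(x_i) − u_j(x_j)]/kT; the shared base
Hamiltonian cancels.  Bookkeeping swaps configurations between window
slots (equivalent to swapping biases between replicas) so per-window
sample series fall out directly.  Dynamics and swap decisions draw from
two independent seeded streams; with exchange disabled the run is
bit-identical to independent umbrella sampling.

## WHAM and errors

Standard self-consistent histogram WHAM over the union of sampled α
(default 200 bins, ≈7 per window spacing — a bias/variance compromise;
convergence when max |Δf_i| < 10⁻⁸ kT, cap 10⁵ iterations), computed in
log space.  The default equilibration cut discards the first 25% of each
window's series, mirroring a 10-of-40-ns discard.  Adjacent windows with
no shared occupied bins trigger a warning (disconnected profile).

Errors: the mean restraint displacement relates to the local mean force,
F′(α_i) ≈ κ(α_i − ⟨α⟩_i).  The uncertainty of ⟨α⟩_i comes from block
averaging (10 blocks; blocks longer than the correlation time absorb
autocorrelation), each window carries the trapezoidal link length
Δα_i, and the per-link errors κ·σ(⟨α⟩_i)·Δα_i accumulate in quadrature
along the window chain starting from window 1 — so error bars represent
free-energy *differences* relative to the first window and grow
monotonically away from it.

A compact binless multistate-reweighting estimator (`mbar_profile`,
self-consistent over pooled samples, histogrammed only for display) is
included purely as an independent cross-check route; histogram WHAM is
the primary estimator.

## Synthetic validation system

The toy engine stands in for an MD code; only equilibrium statistics
matter for validating the estimator chain, so the sampler is overdamped
Euler–Maruyama Langevin (x ← x − (dt/γ)∇V + √(2kT dt/γ)ξ), vectorised
over windows.  Toy units set kT = 1 and γ = 1.

The reference landscape is a **curved valley**: a harmonic tube of
stiffness `width_k` around a circular arc (radius 6, arc 120°), an
optional linear tilt along the arc angle (imposing an exact end-to-end
floor energy difference), an optional harmonic angular well (the
single-minimum variant), and harmonic confinement of any extra
dimensions.  Beyond the arc ends the tilt flattens and the radial tube
continues smoothly; we deliberately avoid steep angular walls because a
wall whose curvature rivals κ makes end windows bistable at the
wall–valley junction, severing histogram overlap.

Synthetic ensembles place frames uniformly along a known path (straight
line, sinusoidal bulge — exactly representable at P = 1 — or circular
arc) plus i.i.d. Gaussian coordinate noise, emulating an equilibrated
transition tube of width σ.  The brute-force oracle integrates the
Boltzmann weight on a dense spatial grid (dim ≤ 3), assigns each grid
point to the α bin of its nearest curve point, and returns
−kT ln of the binned weights; an optional half-resolution repeat guards
against discretisation error.

**End-to-end configuration.**  The headline validation samples 30 windows
with κ = 3,111 kT over a 4-kT-tilted valley (width_k = 16, tube width
0.25).  The synthetic ensemble (50,000 frames, σ = 0.25, the equilibrium
tube width) runs along an arc extended 10% past each valley-floor
endpoint, so both endpoint states project well inside (α ≈ 0.08 and
0.92) — the same situation as a protein pathway extending beyond the
crystal structures — keeping the endpoint free-energy readout away from
the linearisation- and statistics-limited profile edges.  Sampling uses
dt = 0.005, swap attempts every 40 steps, samples every 20 steps.
Problem sizes (steps per window, quadrature grids) were chosen so the
statistical error sits comfortably below the validation tolerances while
the full pipeline completes in minutes on one CPU.

## What the synthetic tests do not show

* Real trajectory frames are time-correlated and non-Gaussian around the
  tube centre; the ensemble generator draws i.i.d. noise, so pathway
  recovery under realistic autocorrelation is not probed.
* The toy landscape has one tube; systems with multiple competing
  transition channels violate the single-curve premise, and the method
  averages over whichever channel the input ensembles visited.
* Force-field realism, solvent, thermostats and all-atom sampling
  efficiency are entirely out of scope; no claims about protein-scale
  convergence rates follow from the toy results.
* The local linear approximation is exercised at tube-width-to-curvature
  ratios typical of the reference protocol (tangent rotation ≈ 4° per
  window); much sharper curves would need more windows.

## Analyses

Projection time series Kabsch-align each frame to a reference before the
nonlinear projection.  Domain centres are unweighted Cα means over
residue ranges (defaults: the adenylate kinase LID 122–159, AMPbd 30–59,
CORE 1–29/60–121/160–214).  RMSD tables average the trailing fraction of
each trajectory after alignment and compare against each reference with
superposed RMSD.  Salt bridges are assigned only when a directional
hydrogen bond links the side chains: donor–acceptor heavy-atom distance
≤ 3.5 Å *and* donor–H···acceptor angle ≥ 130° (the principle is stated
in the literature without numbers; these defaults are conventional and
configurable).  Without hydrogens the heavy-atom distance alone decides
and the report is flagged `hydrogen_based = False`.  Occupancies are
reported raw, with no "frequent/occasional" verdict labels.

## Degenerate inputs and tie-breaks

Collinear reference structures make the optimal rotation ill-defined and
are rejected.  Zero projection range (all frames identical) is an error.
Empty α histogram bins are excluded from the profile rather than
interpolated.  `project()` clamps to the curve ends and compares the
boundary values explicitly, since bounded scalar minimisation never lands
exactly on a bound.  Curve evaluation outside [0, 1] (beyond 10⁻¹²
slack) is an error, not an extrapolation.
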