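# Methods

## Model

The package simulates a Boyden-chamber migration assay in one spatial
dimension.  Three compartments share one continuous axis: the lower well
(depth L_l, initially holding ligand at concentration c0), the filter
(thickness L_f, initially empty except for cells pressed against its upper
face), and the upper well (depth L_u, the cell reservoir at density n0).
All dynamics are solved in dimensionless form — lengths in units of L_f,
time in hours, cell density in units of n0, ligand in units of c0, per-cell
bound receptor numbers in units of the resting per-cell receptor contents
Γ_r (normal, CD95) and Γ_d (decoy, DcR3).

On the filter (0 ≤ x ≤ 1) the state is (n, c, ρ_r, ρ_d):

* cells move with flux K_n = −D_n n_x + χ n ∂ρ_r/∂x − μ n ∂ρ_d/∂x —
  random motility plus attraction up the bound-normal-receptor gradient and
  repulsion up the bound-decoy gradient — and obey n_t = −∂K_n/∂x;
* occupancies are advected with the per-cell velocity K_n/n and relax by
  mass-action kinetics with upregulation closures,
  ρ_t = −(K_n/n) ρ_x + k_a c (1 + (β−1)ρ) − (k_d + k_i)ρ per receptor
  class (β → δ for the decoy class), where the bracket is the per-cell
  free-receptor content implied by 𝓡_b+𝓡_f = Γ_r(n + β𝓡_b);
* the ligand diffuses over the whole chamber and is bound/released on the
  filter, c_t = D_c c_xx + k_d Γ̃_r n ρ_r − k_a c n Γ̃_r (1+(β−1)ρ_r) +
  (decoy analogue), with Γ̃ = Γ n0/c0.

In the wells c_t = D_c c_xx.  Boundary conditions: no ligand flux at the
chamber ends; flux continuity at the filter faces is automatic because c
lives on one continuous grid.  The filter-face rows of n are
reservoir-exchange laws n_t = −K_n/L at x = 0 and +K_n/L at x = 1 (L = cell
diameter in filter units); ρ_r, ρ_d carry zero-gradient conditions at the
faces, implemented as vanishing advection there.  Initially n = 0 on the
filter except n = 1 at the x = 1 node, ρ_r = ρ_d = 0, and c = 1 on the
lower-well nodes (including the x = 0 face), 0 elsewhere.

Assumptions inherited from the model class: radial variation in the chamber
is neglected; the upper well is not an explicitly depleting reservoir (only
the face node's exchange law sees it); internalized receptor–ligand
complexes are destroyed, not recycled, so the total ligand budget decays at
rate k_i1 𝓡_b + k_i2 𝓓_b.

## Parameters

Defaults are the literature/estimated values for glioma cells (units in the
`DimensionalParameters` docstring): D_n = 1.3e-10 cm²/s, D_c = 7.3e-6 cm²/s,
χ = 2e12 and μ = 1e10 cm²/(s·mol), k_a1 = 1.67e7 and k_a2 = 8.33e7
cm³/(s·ligand-unit), k_d1 = 0.0058/s, k_d2 = 0.0029/s, k_i1 = 0.004/s,
k_i2 = 8e-4/s, Γ_r = 4.98e-21 and Γ_d = 3.984e-21 mol/cell, cell diameter
L = 9.2e-4 cm, compartments (L_u, L_f, L_l) = (0.0375, 0.015, 0.03125) cm,
n0 = 4e5 cells/cm³, c0 = 6e-8 ligand-unit/cm³, T = 3600 s.  The
dimensionless upregulation rates default to β̃ = βΓ_r = 0.97 and
δ̃ = δΓ_d = 0.952; both stay below 1 or per-cell receptor numbers grow
without bound (validated).

The ligand unit is deliberately opaque.  The sources are inconsistent about
µg versus mol for c; since only the products k_a·T·c0 and the ratios
Γ·n0/c0 enter the dimensionless system, the package performs no molar-mass
conversion and treats c0 as a number in "ligand-units"/cm³.

## Discretization

Uniform grid with spacing h (default 0.02, i.e. 51 filter nodes, 280
chamber nodes; well depths are snapped to multiples of h and the deviation
recorded).  Spatial derivatives are central (second order); the
cell-diffusion term uses the standard 3-point Laplacian (a
divergence-of-central-gradient form would decouple even and odd nodes); the
face values of K_n use one-sided second-order differences for all three
gradients.  The per-cell advection velocity is K_n / max(n, 1e-12), and
advection is skipped entirely at nodes with n < 1e-12: occupancy is a
per-cell quantity, undefined without cells, so its dynamics stay purely
kinetic until cells arrive.

Two steppers share one right-hand side:

* **Forward Euler** with Δt bounded by the ligand-diffusion stability limit
  h²/(2 D̃_c) (1.7e-6 at the defaults; refused above the bound unless
  explicitly overridden).
* **IMEX** (default): Crank–Nicolson for the ligand diffusion over the whole
  chamber (one sparse LU factorization per run), explicit for advection and
  reaction.  Δt = 1e-4 h resolves the stiffest remaining explicit rate
  (≈ 880/h in the decoy kinetics) with λΔt ≈ 0.09; cross-scheme agreement
  with Euler is verified in the test suite at 0.5%.

Negative values in [−1e-10, 0) produced by the central stencils are clipped
to zero and counted; anything below −1e-10 aborts the run.  At intermediate
c0 the central advection occasionally overshoots this threshold during the
early transient; sweep rows then retry once with a first-order upwind
discretization of the occupancy advection (monotone; bias ≈ 0.2% in N_f at
the defaults) and record the fallback in the row status.  Both the trapezoid
ligand mass (conserved to 1e-10 over a full run with kinetics off) and the
convergence orders (2 in h against exact Neumann eigenmode decay, 1 in Δt by
Richardson extrapolation on the full model) are enforced by tests.

## Observables and sweeps

N_f = n0 ∫₀¹ n dx by the trapezoid rule (consistent with the second-order
stencil).  H = 1 − sup{x : n(x) < 1/n0}; the supremum over an empty set is
0 (H = 1), an all-sub-threshold profile gives H = 0, and the front position
is refined by linear interpolation between the bracketing nodes so that c0
sweeps are not quantized by the mesh.  Sweeps in c0 re-derive the
dimensionless parameter set per row — c0 enters through k̃_a = k_a T c0 and
Γ̃ = Γ n0/c0, the only reading under which the initial ligand concentration
affects the dimensionless dynamics at all.  The interior maximum of a swept
observable is located on the coarse grid and refined by golden-section
re-simulation between the bracketing neighbours (default bracket tolerance
1e-10 on c0; the acceptance computations use 2e-9, an order of magnitude
below their comparison tolerance).  The default sweep grid is geometric,
5e-9 … 1e-6, chosen wide enough that both the rise and the fall of the
migration observables lie strictly inside it (see "Parameter regime" below
for why the turning points sit above the experimentally motivated range).

## Sensitivity analysis

For each analyzed parameter p ∈ {χ, μ, β, δ, k_a2, k_d2, k_i2, Γ_d} (their
dimensionless values), the tangent fields s = ∂(n, c, ρ_r, ρ_d)/∂p obey
ds/dt = J(y)s + ∂F/∂p and are co-integrated with the primal trajectory on
the same grid and stepper.  The right-hand side of the tangent system is
evaluated matrix-free as a central difference of the discrete primal RHS in
the combined direction (s, e_p) — the same code path as the solver, so the
face rows and advection guards are linearized consistently — while the
ligand component of s reuses the Crank–Nicolson diffusion solve.  The
reported index S = p (∫₀¹ ∂n/∂p dx)/(∫₀¹ n dx) at τ = 5 is an elasticity:
invariant to the parameter's units (verified by differentiating the
dimensional coefficient instead).  An independent oracle — central finite
differences of two full primal solves at p(1 ± r) — agrees with the forward
route to within 5% at r = 1e-2, and the discrepancy falls fourfold when r is
halved, as it must for a second-order difference.

## Parameter regime and what the defaults imply

The printed parameter values place the model in a fast-binding,
fast-diffusion regime: k̃_a1 = k_a1·T·c0 = 3607/h and k̃_a2 = 17993/h, so
occupancies reach their closure equilibria within ~1/100 h, and
D̃_c = 116.8 homogenizes the ligand across the whole chamber by t ≈ 0.03 h.
Receptor gradients — the only chemotactic drive — therefore exist only
during a brief initial window, and the five-hour migration is dominated by
cell diffusion plus the face-exchange rows.  Consequences, all measured by
the acceptance computations: the decoy channel changes N_f(t=5) by under
0.01% (μ̃/χ̃ = μΓ_d/χΓ_r ≈ 0.004), the β̃ = 0.95 → 0.97 comparison changes
N_f by ≈ +1.3%, and the unimodal turning points of H(c0) and N_f(c0) sit
near c0 ≈ 1e-7 — above, not inside, the experimentally motivated
0.5–6 × 10⁻⁸ window.  The directions of all effects (β helps, δ and the
decoy channel hinder, attraction outweighs repulsion, H(c0) rises then
falls) are robust and tested; their magnitudes in this regime are small.

## Synthetic counts curves

The comparison path against flow-cytometry data needs a counts-versus-
concentration table.  The bundled generator is a synthetic stand-in, not
experimental data: a skewed gamma-type bump peak_count·(x/x_p)^a·
exp(a(1−x/x_p)) (a = 2) peaking at a stated FL1-H value (default 18,
matching the threshold reported for LN-229 cells), plus i.i.d. Gaussian
noise truncated at zero, fully determined by an explicit seed.  It emulates
the unimodal rise-then-fall of migrated-cell counts with ligand dose and the
counting noise of cytometry; it does not emulate inter-cell-line variation,
dose-spacing irregularities, or heteroscedastic noise, so agreement with it
exercises the comparison machinery (argmax location, min–max-normalized
RMSE, post-peak slope), not biological fidelity.  Model and data curves are
compared by shape only — each is min–max normalized on the overlapping
FL1-H range and never fitted.

## Numerical choices and edge cases

* Quadratures are trapezoid throughout; N_f is exactly additive over
  node-aligned subintervals.
* Golden-section refinement assumes unimodality of the swept observable
  between the bracketing coarse nodes; monotone samples raise "no interior
  maximum" rather than returning a boundary.
* A parameter whose default is zero (the no-decoy limit) cannot be perturbed
  multiplicatively; its finite-difference sensitivity is reported as exactly
  zero, which matches the forward tangent (the corresponding channel is
  absent).
* Ties in the parabolic argmax refinement (degenerate three-point fits)
  return the central sample.
* All randomness in the repository flows through explicitly seeded numpy
  generators; the PDE model itself is deterministic, and repeated runs are
  bit-identical on one platform.

## Known limitations

* One-dimensional geometry only; no radial variation, sedimentation, or
  alternative (Zigmond/Dunn/Insall) chamber types.
* Deterministic continuum model; no stochastic kinetics.
* The upwind fallback is first-order and slightly diffusive at the front
  foot; it is used only for runs whose central-difference transient would
  otherwise trip the positivity guard, and is always recorded.
* The tangent (sensitivity) fields are not clipped with the primal fields;
  clipping events are rare (≲ 0.1% of node-steps at the defaults) and
  forward/FD agreement bounds the induced error below the 5% oracle
  tolerance.
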