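# decoychemo

A deterministic simulator of glioma-cell chemotaxis through the porous filter
of a Boyden chamber, for modelers studying how **decoy receptors** reshape
ligand-driven cell migration.

Glioma cells carry the death receptor CD95 (Fas); its ligand CD95L is a
chemo-attractant once bound.  Many malignant cells also secrete or carry the
decoy receptor DcR3, which binds CD95L without transducing the migratory
signal and acts as a chemo-repellent channel.  `decoychemo` implements a
Keller–Segel-type model of this competition: four coupled PDEs for cell
density *n*, ligand concentration *c*, and the per-cell bound normal / decoy
receptor occupancies ρ_r, ρ_d, with the cell flux

```
K_n = -D_n ∂n/∂x + χ n ∂ρ_r/∂x - μ n ∂ρ_d/∂x
```

on the filter (0 ≤ x ≤ 1 in filter-thickness units), pure ligand diffusion
in the wells, reservoir-exchange boundary rows dn/dt = ∓K_n/L at the filter
faces, and receptor-upregulation closures
𝓡_b + 𝓡_f = Γ_r (n + β 𝓡_b) (and the δ/Γ_d analogue) that eliminate the
free-receptor fields.  On top of the solver the package provides:

* well-mixed mass-action kinetics with conservation-law test oracles;
* migration observables — the migrated count N_f = n₀∫₀¹ n dx and the
  wavefront penetration depth H = 1 − sup{x : n < 1/n₀};
* parameter sweeps in the initial ligand concentration c₀ with
  golden-section refinement of the unimodal optimum;
* forward sensitivity analysis (co-integrated tangent systems) of N_f with
  respect to eight parameters, cross-checked against a finite-difference
  oracle;
* a model–experiment comparison path for flow-cytometry count curves
  (FL1-H axis), with a seeded synthetic data generator.

The solver uses second-order central differences (h = 0.02 by default) with
either the forward Euler scheme (Δt ≤ h²/2D̃_c) or an IMEX stepper
(Crank–Nicolson ligand diffusion, explicit everything else) that reaches the
same answers at Δt = 10⁻⁴ hours.

## Worked example

```python
from decoychemo import DimensionalParameters, simulate, percent_change, no_decoy_overrides

params = DimensionalParameters()          # literature defaults, n0=4e5, c0=6e-8
full = simulate(params, t_max=5.0)        # IMEX, h=0.02, dt=1e-4
print(f"N_f(t=5) = {full.migrated_count():.1f} cells")
print(f"H(t=5)   = {full.penetration_depth():.4f}")

reduced = simulate(params, overrides=no_decoy_overrides(), t_max=5.0)
print(f"no-decoy gain = {percent_change(full.migrated_count(), reduced.migrated_count()):+.4f} %")
```

prints

```
N_f(t=5) = 17308.9 cells
H(t=5)   = 0.6994
no-decoy gain = +0.0017 %
```

Of the 4×10⁵ cells/cm³ loaded in the upper well, about 17 300 (per cm² of
filter) are inside the filter after five hours, and the wavefront — at the
one-cell detection threshold 1/n₀ — has covered 70% of the filter depth.
With the printed parameter values the decoy channel changes the count only
marginally: the dimensionless binding rates are so large (k̃_a1 = 3607/h)
that receptor occupancies saturate within a minute, and the ligand
homogenizes across the chamber by t ≈ 0.03 h, after which no receptor
gradients remain to steer the cells (see `docs/methods.md` for the regime
analysis and its consequences).

The same computations are scriptable from the shell:

```bash
decoychemo params-echo                      # dimensionless parameter set as JSON
decoychemo simulate --out runs/default     # snapshots, series, run metadata
decoychemo sensitivity --method both --out runs/table.csv
decoychemo experiment fig6a_no_decoy --out runs/fig6a
```

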