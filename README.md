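# porofem

Stabilized mixed finite elements for **finite-strain poroelasticity** —
coupled deformation and Darcy flow in soft, fluid-saturated media such as
cartilage, lung parenchyma, hydrogels or consolidating soil.

The solver computes three fields at once: the skeleton deformation χ, the
Darcy flux z = φ(v_f − v_s), and the pore pressure p, governed on the
deforming domain Ω(t) by

    −∇·(σ_e − p I) = ρ f,      k⁻¹ z + ∇p = ρ_f f,      ∇·(χ_t + z) = g,

with a neo-Hookean skeleton energy carrying a porosity log-barrier,
W(C) = μ/2(tr C − 3) + λ/4(J² − 1) − (μ + λ/2) ln(J − 1 + φ₀), and the
deformation-dependent permeability k = J⁻¹ F k₀ Fᵀ.

The discretization is deliberately low-order — continuous piecewise-linear
displacement and flux with piecewise-constant pressure (P1–P1–P0) — which
violates the inf-sup condition and would checkerboard. Stability is
restored by an interelement **pressure-jump penalty**
J(p,q) = Υ Σ_f h_f ∫_f ⟦p⟧⟦q⟧ ds on the pressure increment. The
discontinuous pressure space then pays off: steep pressure gradients at
drainage boundaries and permeability jumps are captured without
oscillations. Flux boundary conditions are enforced weakly by nodal
Lagrange multipliers, and each backward-Euler step is solved by an
updated-Lagrangian quasi-Newton iteration (exact residuals, simplified
Jacobian, sparse direct solves).

Who it is for: anyone who needs a transparent, fully-tested reference
implementation of stabilized three-field poroelasticity — to study the
method itself, to verify another code against the packaged benchmarks, or
to run moderate-size (≲50k dof) coupled simulations from Python.

## Worked example

Material response at a point (`python examples/01_constitutive_point.py`):

```
mu = 434.783 Pa, lambda = 186.335 Pa (from E, nu)
sigma_e(I) = -58.661 Pa * I   (non-zero: barrier pre-stress)
p_eq       = -58.661 Pa  -> total stress sigma_e - p_eq I = 1.1e-13 Pa
effective drained moduli about equilibrium: mu = 434.78, lambda = 310.18  (nu_eff = 0.2082 vs nominal 0.1500)
10% uniaxial stretch: W = 55.4348 Pa, k_11/k0 = 1.1000, k_22/k0 = 0.9091
```

Two things worth reading off these numbers. First, the porosity barrier
leaves the reference state pre-stressed; the printed p_eq is the uniform
pore pressure that balances it exactly (residual 1e−13), and the drivers
use it as the pressure datum. Second, increments about that equilibrated
state feel λ_eff = 310 Pa rather than the nominal 186 Pa — so the drained
Poisson ratio governing slow relaxation is 0.208, not 0.150. All analytic
comparisons use these effective moduli.

A full benchmark (`python examples/02_terzaghi_column.py`, ~half a
minute) consolidates a loaded, top-drained column of 60 cells and prints
the pressure profile against the classical series, ending with

```
overshoot at t=0.01 s: 8.48e-04 (the jump penalty keeps the unresolved drain layer monotone)
spurious oscillations: 0
max relative error vs series at t=1 s, away from the two drain cells: 0.50%
Newton iterations per step: at most 2
```

Switch the penalty off (`porofem benchmark terzaghi --upsilon 0`) and the
overshoot grows thirty-fold with sign-changing oscillations at the drain —
the inf-sup pathology the stabilization exists to suppress.

Other examples: `03_unconfined_cylinder.py` (stress relaxation of a
cylinder against the Bessel-root series), `04_swelling_cube.py`
(pressure-driven swelling with a low-permeability inclusion, J up to ~2.5),
`05_mesh_and_io.py` (mesh generators, hex→tet splits, VTU round trips).

## Command line

```bash
porofem run terzaghi                      # packaged config, full schedule
porofem run myproblem.toml --out results  # your own TOML setup
porofem benchmark unconfined --cells 1800
porofem mesh "box:8,8,8+tet24" -o cube.vtu
porofem check
```

Configs are TOML (see `src/porofem/configs/`); outputs are ascii VTU
snapshots, CSV convergence records and JSON reports.

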