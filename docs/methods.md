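# Methods

## Model

`porofem` solves quasi-static finite-strain poroelasticity for a fully
saturated mixture of an incompressible solid skeleton and an incompressible
pore fluid. The unknowns are three fields on the deforming body Ω(t):

* the deformation map χ(X, t) (equivalently the displacement u = χ − X),
* the Darcy flux z = φ(v_f − v_s), the volume flux of fluid relative to the
  skeleton,
* the pore pressure p.

The governing system on Ω(t) is

    −∇·(σ_e − p I) = ρ f          (mixture momentum)
    k⁻¹ z + ∇p      = ρ_f f        (Darcy's law)
    ∇·(χ_t + z)     = g            (mixture mass balance)

with the porosity tied to the volume change by J = (1 − φ₀)/(1 − φ),
J = det F, F = ∂χ/∂X. Boundary conditions: prescribed displacement and/or
total traction for the mixture; prescribed pressure and/or normal flux
q_D = z·n for the fluid. All spatial operators act in the current
configuration.

### Constitutive law

The skeleton is compressible neo-Hookean with a porosity log-barrier:

    W(C) = μ/2 (tr C − 3) + λ/4 (J² − 1) − (μ + λ/2) ln(J − 1 + φ₀),

with the effective Cauchy stress σ_e = J⁻¹ F (2 ∂W/∂C) Fᵀ, and an isotropic
reference permeability pushed forward as k = J⁻¹ F (k₀ I) Fᵀ. Because W
depends on C only through tr C and J, the second Piola stress is
S = μI + s(J)C⁻¹ with s(J) = λJ²/2 − (μ+λ/2)J/(J−1+φ₀), and the spatial
tangent is isotropic at *every* deformation state:

    Θ_ijkl = c1(J) δ_ij δ_kl + c2(J)(δ_ik δ_jl + δ_il δ_jk),
    c1 = s′(J),  c2 = −s(J)/J.

The assembly exploits this closed form; a generic fourth-order tensor and
Voigt-form (D, E) matrices exist for verification. All derivative code is
validated against central finite differences of W and of the assembled
residuals (relative errors ~1e−8, thresholds 1e−6/1e−5 in the suite).

### The reference state is pre-stressed

For φ₀ < 1 the barrier term does not vanish at F = I:
σ_e(I) = (μ + λ/2)(1 − 1/φ₀) I. This is a property of the law, not a bug; a
uniform pore pressure p_eq = (μ + λ/2)(1 − 1/φ₀) puts the mixture in exact
equilibrium (total stress zero). Two consequences drive several design
choices:

1. **Pressure datum.** All benchmark drivers impose drained-boundary
   pressures and initial pressures *relative to p_eq* and report p − p_eq.
   Without this gauge every run would begin with a spurious O(p_eq)
   swelling transient that no analytic solution contains.
2. **Effective moduli.** Increments about the equilibrated state behave
   like a stress-free isotropic solid with μ_eff = μ but
   λ_eff = λ + (μ + λ/2)(1 − φ₀²)/φ₀² (derived from the equivalent energy
   W − p_eq(J − 1); verified by finite differences of the total stress).
   With φ₀ = 0.9 and E = 1000 Pa, ν = 0.15 this gives ν_eff ≈ 0.208 — a
   39% shift of the drained Poisson ratio. Small-strain verification
   therefore evaluates the analytic series with (μ_eff, λ_eff); comparing
   against nominal (μ, λ) would test the wrong material.

## Discretization

Continuous piecewise-(tri)linear spaces for χ and z, piecewise-constant
pressure per cell (P1–P1–P0), on tet4 or hex8 meshes. Backward Euler in
time. This equal-low-order pair violates the inf-sup condition; stability
is restored by the interelement pressure-jump penalty

    J(p, q) = Υ Σ_faces h_f ∫_f ⟦p⟧ ⟦q⟧ ds,

acting on the pressure *increment* pⁿ − pⁿ⁻¹ in the discrete mass balance.
Each interior face contributes Υ h_f A_f [[1, −1], [−1, 1]] to its two
pressure dofs; h_f is the face diameter and both metrics are measured in
the current configuration. The matrix is symmetric positive semidefinite
with exactly the constant-pressure null vector on a connected mesh.

The stabilization parameter Υ is a trade-off: too small leaves
checkerboard modes and drain-layer overshoot; too large smooths genuine
pressure boundary layers and perturbs the transient (the consistency error
on the relaxation curve grows roughly like Υ(λ_eff + 2μ_eff), which is why
curves for Υ spanning three decades do *not* coincide at coarse
resolution). The practical rule implemented in the benchmark defaults:
start large and lower Υ decade by decade until the pressure profile is
oscillation-free. Reference values: 1e−3 (unconfined), 2e−5 (Terzaghi),
1e−4 (swelling).

### Flux boundary conditions

The nodal P1 flux space cannot impose z·n strongly on arbitrary surfaces,
so q_D is enforced weakly by a Lagrange multiplier field. The multiplier
carries **one dof per (surface tag, node) pair** — a continuous
piecewise-linear trace space. A facet-wise constant multiplier is *not*
usable here: a triangulated surface has about two facets per boundary
node, so facet-wise constants produce more constraint rows than the P1
normal trace has dofs and the saddle-point matrix becomes structurally
rank-deficient (observed as guaranteed factorization failure on every
tetrahedral mesh). At convergence the multiplier approximates the boundary
pore pressure on the flux-constrained surface.

Untagged fluid boundary = natural pressure condition p = 0 (the usual
mixed-form convention); a prescribed p_D enters the Darcy residual as the
boundary term ∫ p_D w·n. A mean-pressure gauge row is appended only when
no pressure datum reaches the system at all (every facet flux-constrained
and no free mixture surface) — activating it in any other case would
wrongly re-gauge a determined pressure.

## Solution procedure

Updated-Lagrangian quasi-Newton. At each iteration the weak forms are
integrated on the configuration of the previous iterate, and the linearized
system

    [ Ke   0      Bᵀ     0  ] [δχ]     [r1]
    [ 0    M      Bᵀ     Cᵀ ] [δz]  = −[r2]
    [ −B  −Δt B   Jstab  0  ] [δp]     [r3]
    [ 0    C      0      0  ] [δλ]     [r4]

is solved by sparse LU (COLAMD ordering; one step of iterative refinement
recovers the algebraic residual on nearly singular systems such as
Υ → 0). The retained Jacobian freezes the permeability, the integration
domain of the flux/mass rows, and the constraint normals; the residuals are
always exact, so converged solutions solve the full nonlinear problem.

Ke contains three parts: the material term built from (c1, c2), the
geometric term ∇φ_aᵀ σ_e ∇φ_b, **and the domain-variation kernel of the
pressure term, p(δ_il δ_jk − δ_ij δ_kl)**. The last term matters here
because the ambient pressure is O(μ) (see the pre-stress discussion):
dropping it leaves a permanent ~p_eq/(λ+2μ) ≈ 5% error in the Jacobian and
degrades Newton to a fixed linear rate (8–10 iterations); with it the
reference first step converges in 4 iterations with superlinear
contraction at both Υ = 1e−1 and Υ = 1e−3, and the whole block matrix
matches finite differences of the residuals to ~1e−8.

Convergence is declared on the Euclidean norms of the free-dof residual
and of the increment (defaults 1e−8 / 1e−9, at most 20 iterations).
Each step performs at least one correction even when the initial residual
is already below tolerance — a small residual still encodes the step's
physics (e.g. the boundary outflux of a draining column), and skipping it
freezes the evolution. Divergence (residual growth beyond 1e3× the best
seen, non-finite values, or a singular factorization) is reported as an
outcome, not an exception: it is the *expected* behaviour of the
unstabilized element. No line search or load stepping is used; none of the
benchmarks needs it.

## Analytic verification solutions

**Unconfined compression** (cylinder between smooth impermeable platens,
free-draining lateral surface, axial strain step ε₀): the small-strain
radial displacement at the rim is

    u/a = ε₀ [ν + (1−2ν)(1−ν) Σ_n exp(−α_n² t/t_g) / (α_n²(1−ν)² − (1−2ν))]

with α_n the roots of J₁(x) − (1−ν)xJ₀(x)/(1−2ν) = 0 and t_g = a²/((λ+2μ)k).
The modal denominator carries (1−2ν): with that factor the series satisfies
u/a(0) = ε₀/2 to machine precision for every ν and matches an independent
radial finite-difference solution of the linear biphasic problem to <2e−4
at all times; the frequently seen variant with (1−ν) misses the t = 0
identity by ~6% and overshoots the transient by ~5%. The root finder
brackets by sign scan and polishes with Brent's method; high-order roots
approach the zeros of J₀.

**Terzaghi consolidation** (unit column, drained loaded top): the
non-dimensional pressure is the standard series
p* = Σ 2 sin(ω_n x) exp(−ω_n² c t)/ω_n, ω_n = π(n+1/2), c = (λ+2μ)k,
with x measured from the drain. The decay exponent carries ω_n² (the form
without the square does not solve the diffusion equation). Truncation is
adaptive (tail bound < 1e−12); a Crank–Nicolson finite-difference solver of
the same initial-boundary-value problem serves as the independent oracle.

Both series are evaluated with the effective moduli when compared against
the FEM.

## Benchmarks and the sizes used

All benchmarks are self-contained (built-in mesh generators, parameters in
packaged TOML files). Problem sizes are chosen so the full verification
suite runs on one CPU in well under half an hour:

* **Unconfined compression**: structured tetrahedral cylinder (hex-pattern
  disk extruded in layers, conforming 3-tet prism splits). Newton
  convergence is probed on a ~3100-cell mesh; the relaxation trajectory
  uses 1800 cells. The time step comes from an a-priori rule: the smallest
  of {t_g/20, t_g/40, t_g/80, t_g/160} for which backward-Euler damping of
  the *analytic* series stays within 1% over the comparison window
  (selects t_g/80 here). Measured: max deviation from the series 2.0%
  over t/t_g ∈ [0.05, 2], late-time u/a within 0.4% of ε₀ν_eff, ≤4 Newton
  iterations per step. The driver uses a unit (1 m) radius: the parameter
  table's millimetre radius together with its SI permeability gives
  t_g ≈ 1e−6 s, irreconcilable with its 4 s time step, and only normalized
  time t/t_g is reported.
* **Terzaghi**: 60 slab cells of unit cross-section (with the face size
  h ≈ 1 the reference Υ = 2e−5 sits exactly at the documented
  "smallest non-oscillating" point; with cubic 1/60-sized cells the
  penalty is inert and no instability exists to suppress, so that reading
  cannot reproduce the reference behaviour). Measured: overshoot 8.5e−4
  with stabilization vs 2.4e−2 without; late profile within 0.5% of the
  series away from the two drain cells.
* **Swelling cube**: 8×8×8 hexes (or their 24-way tet split, 12288 cells)
  with a 500× low-permeability octant. The checkerboard indicator is the
  unit-penalty jump seminorm sqrt(Σ h A ⟦p⟧²), insensitive to the pressure
  datum. Measured on the uniform-permeability tet mesh after one step:
  the indicator is ~240× larger at Υ = 1e−12 than at Υ = 1e−4. Point
  histories use a reduced 4³ mesh and a 1.5 s horizon in examples/tests;
  the full 20 s schedule is in the packaged config.

The oscillation counter ignores sign changes below 1% of the applied
load (the plotted p/p0 scale): the reference evidence for "no
oscillations" is graphical, and the sub-percent wiggle left by a
0.2-cell-wide unresolved boundary layer is not the O(10%) checkerboard the
indicator is meant to flag.

## What the synthetic benchmarks do and do not show

The generators produce idealized geometries (structured boxes and
cylinders), homogeneous or two-level permeability, and step/ramp loads.
Passing tests therefore demonstrate: consistency of the implementation
(FD oracles), correct small-strain limits against closed-form solutions,
first-order time accuracy, and the stabilization's control of inf-sup
pathology. They do not establish accuracy for irregular anatomical
geometries, strongly graded meshes, anisotropic or deformation-dependent
permeability laws (only an isotropic k₀, plus a user-callable k₀(C) hook),
contact, or material heterogeneity beyond piecewise-constant permeability.

## Numerical choices and degenerate inputs

* Quadrature: degree 2 on tets (4 points), degree 3 on hexes (2×2×2) for
  all volume terms — the nonlinear stress under-integrates with 1-point
  rules; face terms use the centroid rule on triangles (exact for the
  linear integrands) and 2×2 Gauss on bilinear quads.
* Jump sign convention: left cell = lower index, jump = left − right;
  each interior face is stored once.
* Barrier violations (J ≤ 1 − φ₀) and inverted elements raise a
  step-rejection signal which the Newton driver converts into a recorded
  `diverged` outcome.
* Direct solves are checked to a 1e−8 relative algebraic residual after
  at most one refinement step; failures name the likely missing gauge/BC.
* Hex-to-tet splitting uses min-global-index face diagonals (6-way, always
  conforming across cells) or face+body centroids (24-way); boundary tags
  are inherited from the parent quad facets.
* The method itself is deterministic; randomness appears only in test
  fixtures and the FD probes, always explicitly seeded.

## Known limitations

* Mild locking of the P1–P0 pair in the undrained (incompressible)
  early-time limit: the instantaneous unconfined response converges slowly
  in h (a few percent at ~2000 cells). This is inherent to the element and
  is the main accuracy limit of the relaxation benchmark's first steps.
* The transient visibly depends on Υ above ~1e−2 at coarse resolution
  (consistency error ~ Υ·M_eff); the robustness claim that holds is
  insensitivity at the small-Υ end plus monotone growth of the deviation.
* Dead (non-follower) tractions only; the traction linearization is
  omitted, consistent with the quasi-Newton design.
* Direct sparse solves only; no iterative saddle-point preconditioning,
  so ~50k dofs is a practical ceiling.
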