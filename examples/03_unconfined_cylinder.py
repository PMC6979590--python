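"""Stress relaxation of a poroelastic cylinder in unconfined compression.

A 1%-strain axial step is applied between smooth impermeable platens; the
sample bulges radially (incompressible instantaneous response, u/a = eps0/2)
and then relaxes toward the drained value eps0 * nu_eff as pore fluid leaves
through the free-draining lateral surface.  The FEM curve is compared with
the small-strain relaxation series evaluated with the effective drained
moduli of the implemented law.  A coarse mesh keeps this under two minutes;
use target_cells=1800 (the verification default) for the reference numbers.
"""

from porofem.benchmarks import run_unconfined_benchmark

report = run_unconfined_benchmark(eps0=0.01, target_cells=600,
                                  t_end_factor=1.0, window=(0.05, 0.9))

s = report.scalars
print(f"mesh: {s['n_cells']:.0f} tetrahedra, dt = {s['dt']:.4f} s, "
      f"t_g = {s['t_g']:.3f} s, nu_eff = {s['nu_eff']:.4f}")
print("\n  t/t_g    u/a FEM     u/a series")
t = report.curves["t_over_tg"]
fem = report.curves["ua_fem"]
ser = report.curves["ua_series"]
for i in range(0, len(t), max(1, len(t) // 12)):
    print(f"  {t[i]:6.3f}   {fem[i]:.6f}   {ser[i]:.6f}")

print(f"\nmax relative deviation in the comparison window: "
      f"{100 * s['max_rel_err_window']:.2f}%")
print(f"late-time u/a = {s['ua_final']:.6f} vs drained limit "
      f"eps0*nu_eff = {s['ua_equilibrium_series']:.6f}")
print(f"Newton iterations per step: at most {s['max_newton_iterations']}")
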