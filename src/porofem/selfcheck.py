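"""Finite-difference and series oracles packaged as callable self-checks.

Each function *measures* a consistency error between two independent
routes -- closed-form constitutive code vs numerical differentiation of the
energy, assembled Jacobian blocks vs finite differences of the residuals,
series evaluators vs brute-force summation / a finite-difference PDE
solve -- and returns it.  ``run_all`` applies the documented thresholds.
These are the same quantities the test suite asserts; the CLI exposes them
as ``porofem check``.
"""

from __future__ import annotations

import numpy as np

from .analytic import (
    TerzaghiParams,
    characteristic_roots,
    terzaghi_fd_oracle,
    terzaghi_pressure,
)
from .assembly import (
    BoundaryConditions,
    DofMap,
    assemble_darcy_mass,
    assemble_divergence,
    assemble_elasticity_block,
    assemble_residuals,
    assemble_stabilization,
)
from .constitutive import (
    MaterialParams,
    second_piola_stress,
    strain_energy,
)
from .mesh import Mesh, _finish_mesh, build_box_hex_mesh
from .solver import SolutionState


def _random_admissible_F(rng, params, scale=0.2):
    while True:
        F = np.eye(3) + scale * rng.standard_normal((3, 3))
        if np.linalg.det(F) > 1.0 - params.phi0 + 0.05:
            return F


def _default_params(upsilon=1e-3):
    return MaterialParams.from_young_poisson(
        1000.0, 0.15, phi0=0.9, k0=1e-3, upsilon=upsilon
    )


def stress_energy_fd_error(n: int = 100, seed: int = 0) -> float:
    """Max relative error of <2 dW/dC, dC>/2 against central FD of W."""
    rng = np.random.default_rng(seed)
    params = _default_params()
    h = 1e-6
    worst = 0.0
    for _ in range(n):
        F = _random_admissible_F(rng, params)
        C = F.T @ F
        S = second_piola_stress(C, params)
        dC = rng.standard_normal((3, 3))
        dC = dC + dC.T
        dW = (strain_energy(C + h * dC, params) - strain_energy(C - h * dC, params)) / (2 * h)
        worst = max(worst, abs(dW - 0.5 * np.einsum("ij,ij", S, dC)) / max(abs(dW), 1e-30))
    return worst


def _single_tet():
    coords = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
    mesh = Mesh(ref_coords=coords, cells=np.array([[0, 1, 2, 3]]), cell_type="tet4")
    return _finish_mesh(mesh, lambda fc: "boundary")


def tangent_pairing_fd_error(n: int = 20, seed: int = 1) -> float:
    """Spatial-tangent linearization vs FD of the single-element stress term.

    Perturbs the nodal positions of one distorted tetrahedron and compares
    the assembled tangent action (material + geometric + pressure kernel at
    p = 0) with central differences of the internal-force residual.
    """
    rng = np.random.default_rng(seed)
    params = _default_params()
    mesh = _single_tet()
    bcs = BoundaryConditions()
    chi = mesh.ref_coords + 0.05 * rng.standard_normal(mesh.ref_coords.shape)
    mesh.cur_coords = chi.copy()
    mesh.check_volumes("cur")
    dm = DofMap(mesh, bcs)
    zeros = SolutionState(chi=mesh.ref_coords.copy(), z=np.zeros((4, 3)),
                          p=np.zeros(1), lam=np.zeros(0))

    def r1_of(flat):
        m2 = mesh.copy()
        m2.cur_coords = flat.reshape(-1, 3).copy()
        st = SolutionState(chi=m2.cur_coords, z=np.zeros((4, 3)), p=np.zeros(1),
                           lam=np.zeros(0))
        return assemble_residuals(m2, st, zeros, params, bcs, 0.1, 0.0, dm)[0]

    Ke = assemble_elasticity_block(mesh, params)
    h = 1e-7
    worst = 0.0
    for _ in range(n):
        d = rng.standard_normal(12)
        d /= np.linalg.norm(d)
        fd = (r1_of(chi.ravel() + h * d) - r1_of(chi.ravel() - h * d)) / (2 * h)
        worst = max(worst, np.linalg.norm(fd - Ke @ d) / np.linalg.norm(fd))
    return worst


def jacobian_blocks_fd_error(seed: int = 2) -> float:
    """All retained Jacobian blocks vs FD of (r1, r2, r3) on one hex element."""
    rng = np.random.default_rng(seed)
    params = _default_params()
    mesh = build_box_hex_mesh(1, 1, 1)
    bcs = BoundaryConditions()
    chi = mesh.ref_coords + 0.05 * rng.standard_normal(mesh.ref_coords.shape)
    mesh.cur_coords = chi.copy()
    mesh.check_volumes("cur")
    dm = DofMap(mesh, bcs)
    nn = mesh.n_nodes
    z = rng.standard_normal((nn, 3))
    p = 50.0 * rng.standard_normal(mesh.n_cells)
    prev = SolutionState(chi=mesh.ref_coords.copy(), z=np.zeros((nn, 3)),
                         p=np.zeros(mesh.n_cells), lam=np.zeros(0))
    dt = 0.1

    def residuals(chi_flat, z_, p_, move_mesh):
        m2 = mesh.copy()
        if move_mesh:
            m2.cur_coords = chi_flat.reshape(-1, 3).copy()
        st = SolutionState(chi=chi_flat.reshape(-1, 3), z=z_, p=p_, lam=np.zeros(0))
        return assemble_residuals(m2, st, prev, params, bcs, dt, 0.0, dm)

    Ke = assemble_elasticity_block(mesh, params, p_cell=p)
    M = assemble_darcy_mass(mesh, params)
    B = assemble_divergence(mesh)
    Js = assemble_stabilization(mesh, params.upsilon)
    h = 1e-6
    worst = 0.0
    for _ in range(5):
        dchi = rng.standard_normal(3 * nn)
        dchi /= np.linalg.norm(dchi)
        # r1 w.r.t. chi at fixed p over the deforming domain
        fd = (residuals(chi.ravel() + h * dchi, z, p, True)[0]
              - residuals(chi.ravel() - h * dchi, z, p, True)[0]) / (2 * h)
        worst = max(worst, np.linalg.norm(fd - Ke @ dchi) / np.linalg.norm(fd))
        # r3 w.r.t. chi at frozen geometry
        fd = (residuals(chi.ravel() + h * dchi, z, p, False)[2]
              - residuals(chi.ravel() - h * dchi, z, p, False)[2]) / (2 * h)
        worst = max(worst, np.linalg.norm(fd + B @ dchi) / max(np.linalg.norm(fd), 1e-30))
        dz = rng.standard_normal((nn, 3))
        fd = (residuals(chi.ravel(), z + h * dz, p, False)[1]
              - residuals(chi.ravel(), z - h * dz, p, False)[1]) / (2 * h)
        worst = max(worst, np.linalg.norm(fd - M @ dz.ravel()) / np.linalg.norm(fd))
        fd = (residuals(chi.ravel(), z + h * dz, p, False)[2]
              - residuals(chi.ravel(), z - h * dz, p, False)[2]) / (2 * h)
        worst = max(worst, np.linalg.norm(fd + dt * (B @ dz.ravel())) / np.linalg.norm(fd))
        dp = rng.standard_normal(mesh.n_cells)
        fd = (residuals(chi.ravel(), z, p + h * dp, False)[0]
              - residuals(chi.ravel(), z, p - h * dp, False)[0]) / (2 * h)
        worst = max(worst, np.linalg.norm(fd - B.T @ dp) / np.linalg.norm(fd))
        fd = (residuals(chi.ravel(), z, p + h * dp, False)[2]
              - residuals(chi.ravel(), z, p - h * dp, False)[2]) / (2 * h)
        ref = np.linalg.norm(Js @ dp)
        if ref > 0:
            worst = max(worst, np.linalg.norm(fd - Js @ dp) / ref)
    return worst


def unconfined_series_t0_error(n_terms_oracle: int = 100000) -> float:
    """|u/a(0) - eps0/2| via a brute-force partial sum with 1e5 roots.

    The t = 0 value of the relaxation series is the instantaneous
    incompressible response eps0/2; the production evaluator truncates far
    earlier, so this measures its truncation honestly.
    """
    nu = 0.2
    # for large x the characteristic equation is dominated by its x J0(x)
    # term, so high-order roots approach the J0 zeros ~ pi (n - 1/4)
    exact = characteristic_roots(nu, 60)
    n = np.arange(len(exact) + 1, n_terms_oracle + 1)
    approx = np.pi * (n - 0.25)
    alphas = np.concatenate([exact, approx])
    denom = alphas ** 2 * (1 - nu) ** 2 - (1 - 2 * nu)
    series = (1.0 / denom).sum()
    ua0 = nu + (1 - 2 * nu) * (1 - nu) * series
    return abs(ua0 - 0.5)


def terzaghi_series_vs_fd_error(t: float = 0.01) -> float:
    """|series - grid-converged FD solution| away from the drain layer.

    Compared at x in {0.3, 0.5, 0.7}; inside the early-time boundary layer
    the FD oracle itself would need a graded mesh to reach this accuracy.
    """
    params = TerzaghiParams(p0=1.0, lam=40.0, mu=40.0, k=1e-5)
    x = np.array([0.3, 0.5, 0.7])
    series = terzaghi_pressure(x, t, params)
    fd = terzaghi_fd_oracle(x, t, params, n_grid=4000, n_steps=8000)
    return float(np.abs(series - fd).max())


CHECKS = [
    ("stress vs FD of energy (rel)", stress_energy_fd_error, 1e-6),
    ("tangent vs FD of internal force (rel)", tangent_pairing_fd_error, 1e-5),
    ("Jacobian blocks vs FD of residuals (rel)", jacobian_blocks_fd_error, 1e-5),
    ("relaxation series t=0 limit (abs)", unconfined_series_t0_error, 1e-4),
    ("consolidation series vs FD PDE (abs)", terzaghi_series_vs_fd_error, 1e-5),
]


def run_all(echo=print) -> int:
    failures = 0
    for name, fn, tol in CHECKS:
        err = fn()
        ok = err < tol
        failures += 0 if ok else 1
        echo(f"  [{'ok' if ok else 'FAIL'}] {name}: {err:.3e} (tol {tol:g})")
    return failures
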