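"""Backward-Euler time stepping and the quasi-Newton iteration.

Each time step solves the nonlinear system by repeated linearized solves
K(u_i) du = -R(u_i, u^{n-1}) on the configuration of the previous iterate
(updated Lagrangian).  Convergence is monitored through the Euclidean norms
of the free-dof residual and of the increment, matching the two columns of
the convergence tables the method reports.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse.linalg as spla

from .assembly import (
    BoundaryConditions,
    DofMap,
    StepRejected,
    apply_essential_bcs,
    assemble_system,
    update_current_configuration,
)
from .constitutive import BarrierViolationError, MaterialParams
from .mesh import Mesh

__all__ = [
    "NewtonOptions",
    "ConvergenceRecord",
    "SolutionState",
    "SingularSystemError",
    "NewtonFailure",
    "newton_solve",
    "linear_solve",
    "time_loop",
    "write_convergence_csv",
]


class SingularSystemError(RuntimeError):
    """Linear system singular; usually a missing pressure gauge or BC."""


class NewtonFailure(RuntimeError):
    """A time step's Newton iteration did not converge."""

    def __init__(self, step: int, record: "ConvergenceRecord"):
        super().__init__(f"Newton iteration failed at step {step}: {record.outcome}")
        self.step = step
        self.record = record


@dataclass
class NewtonOptions:
    residual_tol: float = 1e-8
    increment_tol: float = 1e-9
    max_iterations: int = 20
    divergence_ratio: float = 1e3

    def __post_init__(self):
        if self.residual_tol <= 0 or self.increment_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be at least 1")


@dataclass
class ConvergenceRecord:
    """Per-iteration increment and residual norms of one Newton solve."""

    increment_norms: list = field(default_factory=list)
    residual_norms: list = field(default_factory=list)
    outcome: str = "max_iter"
    message: str = ""

    @property
    def iterations(self) -> int:
        return len(self.increment_norms)


@dataclass
class SolutionState:
    """Discrete solution at one time level."""

    chi: np.ndarray   # (N, 3) nodal current positions
    z: np.ndarray     # (N, 3) nodal Darcy flux
    p: np.ndarray     # (nc,)  cell pressures
    lam: np.ndarray   # (n_lambda,) facet multipliers
    t: float = 0.0

    @classmethod
    def initial(cls, mesh: Mesh, dofmap: DofMap, p0: float = 0.0) -> "SolutionState":
        return cls(
            chi=mesh.ref_coords.copy(),
            z=np.zeros((mesh.n_nodes, 3)),
            p=np.full(mesh.n_cells, float(p0)),
            lam=np.zeros(dofmap.n_lambda),
            t=0.0,
        )

    def copy(self) -> "SolutionState":
        return SolutionState(chi=self.chi.copy(), z=self.z.copy(),
                             p=self.p.copy(), lam=self.lam.copy(), t=self.t)


def linear_solve(K, rhs) -> np.ndarray:
    """Sparse direct solve with a residual check.

    Raises :class:`SingularSystemError` when the factorization fails or the
    algebraic residual is not small -- typically a sign that the pressure
    gauge or an essential boundary condition is missing.
    """
    try:
        lu = spla.splu(K.tocsc())
        x = lu.solve(rhs)
    except (RuntimeError, ValueError) as exc:
        raise SingularSystemError(
            "sparse factorization failed (singular matrix); check that the "
            "pressure level is fixed by a pressure/traction boundary "
            f"condition or the mean-pressure gauge [{exc}]"
        ) from exc
    if not np.all(np.isfinite(x)):
        raise SingularSystemError("linear solve produced non-finite values")
    nrm = np.linalg.norm(rhs)
    if nrm > 0:
        rel = np.linalg.norm(K @ x - rhs) / nrm
        if rel > 1e-10:
            # one step of iterative refinement recovers the residual on
            # ill-conditioned (e.g. nearly unstabilized) systems
            x = x + lu.solve(rhs - K @ x)
            rel = np.linalg.norm(K @ x - rhs) / nrm
        if rel > 1e-8 or not np.all(np.isfinite(x)):
            raise SingularSystemError(
                f"direct solve inaccurate (relative residual {rel:.2e}); "
                "system is singular or severely ill-conditioned"
            )
    return x


def _unpack(state: SolutionState, delta: np.ndarray, free_idx: np.ndarray,
            dofmap: DofMap) -> SolutionState:
    full = np.zeros(dofmap.n_total)
    full[free_idx] = delta
    nchi, nz, np_ = dofmap.n_chi, dofmap.n_z, dofmap.n_p
    new = state.copy()
    new.chi = state.chi + full[:nchi].reshape(-1, 3)
    new.z = state.z + full[nchi:nchi + nz].reshape(-1, 3)
    new.p = state.p + full[nchi + nz:nchi + nz + np_]
    if dofmap.n_lambda:
        new.lam = state.lam + full[nchi + nz + np_: nchi + nz + np_ + dofmap.n_lambda]
    return new


def newton_solve(mesh: Mesh, state_prev: SolutionState, t_n: float, dt: float,
                 params: MaterialParams, bcs: BoundaryConditions,
                 dofmap: DofMap, options: NewtonOptions | None = None,
                 k0_cell=None) -> tuple[SolutionState, ConvergenceRecord]:
    """One backward-Euler step solved by the quasi-Newton iteration.

    The initial guess is the previous state with the Dirichlet lift applied,
    so every iterate satisfies the essential conditions and the constrained
    increments vanish.  Divergence (residual growth beyond
    ``divergence_ratio`` times the smallest residual seen, or a singular
    linearized system) is reported through the record's outcome, not an
    exception: it is the expected behaviour of the unstabilized element.
    """
    options = options or NewtonOptions()
    record = ConvergenceRecord()
    state = state_prev.copy()
    state.t = t_n
    mask, presc = dofmap.prescribed_positions(t_n)
    chi_flat = state.chi.ravel().copy()
    chi_flat[mask] = presc[mask]
    state.chi = chi_flat.reshape(-1, 3)
    free = dofmap.free_mask()

    try:
        update_current_configuration(mesh, state.chi)
        system = assemble_system(mesh, state, state_prev, params, bcs, dt, t_n,
                                 dofmap, k0_cell)
    except (StepRejected, BarrierViolationError) as exc:
        record.outcome = "diverged"
        record.message = f"initial guess rejected: {exc}"
        return state, record

    res = system.full_residual()
    res_norm = float(np.linalg.norm(res[free]))
    best = res_norm
    for _it in range(options.max_iterations):
        # always take at least one correction per step: a small but nonzero
        # residual still encodes the step's evolution (e.g. boundary outflux)
        if res_norm == 0.0 or (_it > 0 and res_norm < options.residual_tol):
            record.outcome = "converged"
            return state, record
        K_ff, rhs_f, free_idx = apply_essential_bcs(
            system.full_matrix(), -res, dofmap
        )
        try:
            delta = linear_solve(K_ff, rhs_f)
        except SingularSystemError as exc:
            record.outcome = "diverged"
            record.message = str(exc)
            return state, record
        trial = _unpack(state, delta, free_idx, dofmap)
        inc_norm = float(np.linalg.norm(delta))
        try:
            update_current_configuration(mesh, trial.chi)
            system = assemble_system(mesh, trial, state_prev, params, bcs, dt,
                                     t_n, dofmap, k0_cell)
        except (StepRejected, BarrierViolationError) as exc:
            record.increment_norms.append(inc_norm)
            record.residual_norms.append(np.inf)
            record.outcome = "diverged"
            record.message = f"step rejected: {exc}"
            return state, record
        state = trial
        res = system.full_residual()
        res_norm = float(np.linalg.norm(res[free]))
        record.increment_norms.append(inc_norm)
        record.residual_norms.append(res_norm)
        if res_norm < options.residual_tol or inc_norm < options.increment_tol:
            record.outcome = "converged"
            return state, record
        if not np.isfinite(res_norm) or res_norm > options.divergence_ratio * max(best, 1e-300):
            record.outcome = "diverged"
            record.message = (
                f"residual grew to {res_norm:.3e} (best {best:.3e})"
            )
            return state, record
        best = min(best, res_norm)
    record.outcome = "max_iter"
    return state, record


def time_loop(mesh: Mesh, params: MaterialParams, bcs: BoundaryConditions,
              dt: float, T: float, p_init: float = 0.0,
              options: NewtonOptions | None = None, k0_cell=None,
              observer=None, dofmap: DofMap | None = None):
    """Run N = T/dt backward-Euler steps from the reference configuration.

    ``observer(step, state, record)`` is called after each converged step.
    A failed step aborts with :class:`NewtonFailure` carrying the step index
    and its convergence record.  Returns ``(states, records)`` where
    ``states[0]`` is the initial state.
    """
    if dt <= 0 or T < dt:
        raise ValueError("need dt > 0 and T >= dt")
    dofmap = dofmap or DofMap(mesh, bcs)
    nsteps = int(round(T / dt))
    state = SolutionState.initial(mesh, dofmap, p0=p_init)
    states = [state.copy()]
    records = []
    for n in range(1, nsteps + 1):
        t_n = n * dt
        state, record = newton_solve(mesh, state, t_n, dt, params, bcs,
                                     dofmap, options, k0_cell)
        records.append(record)
        if record.outcome != "converged":
            raise NewtonFailure(n, record)
        states.append(state.copy())
        if observer is not None:
            observer(n, state, record)
    return states, records


def write_convergence_csv(records, path) -> None:
    """Emit (step, iteration, increment norm, residual norm) rows."""
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["step", "iteration", "increment_norm", "residual_norm"])
        for s, rec in enumerate(records, start=1):
            for i, (inc, res) in enumerate(
                zip(rec.increment_norms, rec.residual_norms), start=1
            ):
                wr.writerow([s, i, f"{inc:.9e}", f"{res:.9e}"])
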