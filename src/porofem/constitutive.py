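"""Pointwise material response for the incompressible poroelastic mixture.

The solid skeleton is compressible-neo-Hookean with a porosity log-barrier,

    W(C) = mu/2 (tr C - 3) + lambda/4 (J^2 - 1) - (mu + lambda/2) ln(J - 1 + phi0),

which keeps the current fluid fraction ``phi = 1 - (1 - phi0)/J`` inside
``[0, 1)``: as the skeleton is squeezed towards zero pore space
(``J -> (1 - phi0)+``) the energy blows up.  A consequence of the barrier is
that the reference state is *not* stress-free for ``phi0 < 1``: at ``F = I``
the effective stress is the hydrostatic tensor ``(mu + lambda/2)(1 - 1/phi0) I``.
A uniform pore pressure of the same value puts the mixture in exact
equilibrium; :func:`equilibrium_pressure` returns it and
:func:`effective_lame_about_equilibrium` the small-strain moduli that govern
increments about that equilibrated state.

Because W depends on C only through tr C and J, the second elasticity tensor
pushes forward to an *isotropic* spatial tangent at every deformation:

    Theta_ijkl = c1(J) d_ij d_kl + c2(J) (d_ik d_jl + d_il d_jk),

with scalar coefficients returned by :func:`tangent_coefficients`.  The
assembly layer exploits this closed form; the generic fourth-order tensor is
available from :func:`spatial_tangent` for verification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MaterialParams",
    "PointKinematics",
    "BarrierViolationError",
    "lame_from_young_poisson",
    "kinematics_at_point",
    "strain_energy",
    "effective_stress",
    "second_piola_stress",
    "spatial_tangent",
    "tangent_coefficients",
    "permeability_current",
    "mixture_density",
    "equilibrium_pressure",
    "effective_lame_about_equilibrium",
]


class BarrierViolationError(ValueError):
    """J dropped to (or below) the porosity barrier ``1 - phi0``."""


def lame_from_young_poisson(E: float, nu: float) -> tuple[float, float]:
    """Lame parameters ``(mu, lambda)`` from Young's modulus and Poisson ratio."""
    if E <= 0.0:
        raise ValueError(f"Young's modulus must be positive, got {E}")
    if not -1.0 < nu < 0.5:
        raise ZeroDivisionError(
            f"Poisson ratio must lie in (-1, 0.5); nu={nu} makes the solid "
            "incompressible and lambda unbounded"
        )
    mu = E / (2.0 * (1.0 + nu))
    lam = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    return mu, lam


@dataclass
class MaterialParams:
    """Material and stabilization parameters of one poroelastic body.

    mu, lam : Pa            Lame parameters of the skeleton
    phi0    : -             initial (reference) fluid volume fraction
    k0      : m^3 s / kg    reference (dynamic) permeability, isotropic
    rho_s, rho_f : kg/m^3   intrinsic solid / fluid densities
    upsilon : -             pressure-jump stabilization parameter
    """

    mu: float
    lam: float
    phi0: float = 1.0
    k0: float = 1.0
    rho_s: float = 1.0e3
    rho_f: float = 1.0e3
    upsilon: float = 0.0
    k0_fn: object = field(default=None, repr=False)  # optional k0(C) hook

    def __post_init__(self):
        if self.mu <= 0.0:
            raise ValueError(f"shear modulus must be positive, got {self.mu}")
        if not 0.0 <= self.phi0 <= 1.0:
            raise ValueError(f"phi0 must lie in [0, 1], got {self.phi0}")
        if self.k0 <= 0.0:
            raise ValueError(f"permeability must be positive, got {self.k0}")
        if self.upsilon < 0.0:
            raise ValueError(f"upsilon must be non-negative, got {self.upsilon}")

    @classmethod
    def from_young_poisson(cls, E: float, nu: float, **kw) -> "MaterialParams":
        mu, lam = lame_from_young_poisson(E, nu)
        return cls(mu=mu, lam=lam, **kw)

    @property
    def young(self) -> float:
        return self.mu * (3.0 * self.lam + 2.0 * self.mu) / (self.lam + self.mu)

    @property
    def poisson(self) -> float:
        return self.lam / (2.0 * (self.lam + self.mu))

    @property
    def p_wave_modulus(self) -> float:
        return self.lam + 2.0 * self.mu


@dataclass(frozen=True)
class PointKinematics:
    """Deformation measures at one material point."""

    F: np.ndarray
    C: np.ndarray
    J: float
    phi: float


def _check_J(J: float, phi0: float) -> None:
    if not np.all(J > 1.0 - phi0):
        raise BarrierViolationError(
            f"J = {np.min(J):g} <= 1 - phi0 = {1.0 - phi0:g}: "
            "element compressed past the porosity barrier"
        )


def kinematics_at_point(ref_coords, cur_coords, ref_gradients, phi0: float) -> PointKinematics:
    """Deformation gradient and porosity from nodal positions.

    ``ref_gradients`` are the basis gradients w.r.t. the reference
    coordinates at the evaluation point, shape ``(n_nodes, 3)``.
    """
    x = np.asarray(cur_coords, dtype=float)
    g = np.asarray(ref_gradients, dtype=float)
    F = x.T @ g  # F_iJ = sum_k x_k,i dphi_k/dX_J
    J = float(np.linalg.det(F))
    _check_J(J, phi0)
    phi = 1.0 - (1.0 - phi0) / J
    return PointKinematics(F=F, C=F.T @ F, J=J, phi=phi)


def strain_energy(C, params: MaterialParams) -> float:
    """Helmholtz energy density W(C) of the skeleton (Pa)."""
    C = np.asarray(C, dtype=float)
    J = float(np.sqrt(np.linalg.det(C)))
    _check_J(J, params.phi0)
    mu, lam, phi0 = params.mu, params.lam, params.phi0
    return (
        0.5 * mu * (np.trace(C) - 3.0)
        + 0.25 * lam * (J * J - 1.0)
        - (mu + 0.5 * lam) * np.log(J - 1.0 + phi0)
    )


def _s_of_J(J, params: MaterialParams):
    """Coefficient of C^-1 in the second Piola stress: S = mu I + s(J) C^-1."""
    mu, lam, phi0 = params.mu, params.lam, params.phi0
    return 0.5 * lam * J * J - (mu + 0.5 * lam) * J / (J - 1.0 + phi0)


def _s_prime(J, params: MaterialParams):
    mu, lam, phi0 = params.mu, params.lam, params.phi0
    return lam * J - (mu + 0.5 * lam) * (phi0 - 1.0) / (J - 1.0 + phi0) ** 2


def second_piola_stress(C, params: MaterialParams) -> np.ndarray:
    """Second Piola-Kirchhoff stress S = 2 dW/dC."""
    C = np.asarray(C, dtype=float)
    J = float(np.sqrt(np.linalg.det(C)))
    _check_J(J, params.phi0)
    return params.mu * np.eye(3) + _s_of_J(J, params) * np.linalg.inv(C)


def effective_stress(F, params: MaterialParams) -> np.ndarray:
    """Effective Cauchy stress of the skeleton, sigma_e = J^-1 F S F^T."""
    F = np.asarray(F, dtype=float)
    J = float(np.linalg.det(F))
    _check_J(J, params.phi0)
    b = F @ F.T
    return (params.mu * b + _s_of_J(J, params) * np.eye(3)) / J


def tangent_coefficients(J, params: MaterialParams):
    """Isotropic coefficients ``(c1, c2)`` of the spatial tangent Theta.

    ``Theta_ijkl = c1 d_ij d_kl + c2 (d_ik d_jl + d_il d_jk)``; works on
    scalars or arrays of J.
    """
    _check_J(np.asarray(J), params.phi0)
    return _s_prime(J, params), -_s_of_J(J, params) / J


def spatial_tangent(F, params: MaterialParams) -> np.ndarray:
    """Fourth-order spatial tangent modulus tensor Theta (3,3,3,3).

    Push-forward ``J^-1 F F F F : 4 d2W/dC2`` of the material elasticity
    tensor; for this energy it collapses to the isotropic closed form of
    :func:`tangent_coefficients`.
    """
    F = np.asarray(F, dtype=float)
    J = float(np.linalg.det(F))
    c1, c2 = tangent_coefficients(J, params)
    I = np.eye(3)
    return (
        c1 * np.einsum("ij,kl->ijkl", I, I)
        + c2 * (np.einsum("ik,jl->ijkl", I, I) + np.einsum("il,jk->ijkl", I, I))
    )


def permeability_current(F, params: MaterialParams, k0=None) -> np.ndarray:
    """Permeability pushed forward to the current configuration.

    ``k = J^-1 F k0(C) F^T`` with the isotropic reference law
    ``k0(C) = k0 I`` unless ``params.k0_fn`` supplies a tensor-valued
    reference permeability.
    """
    F = np.asarray(F, dtype=float)
    J = float(np.linalg.det(F))
    if J <= 0.0:
        raise BarrierViolationError(f"non-positive volume ratio J = {J:g}")
    if params.k0_fn is not None:
        k0_ref = np.asarray(params.k0_fn(F.T @ F), dtype=float)
    else:
        k0s = params.k0 if k0 is None else k0
        if k0s <= 0.0:
            raise ValueError(f"permeability must be positive, got {k0s}")
        k0_ref = k0s * np.eye(3)
    return F @ k0_ref @ F.T / J


def mixture_density(phi, params: MaterialParams):
    """Current mixture density rho = rho_s (1 - phi) + rho_f phi."""
    phi = np.asarray(phi, dtype=float)
    if np.any(phi < 0.0) or np.any(phi >= 1.0):
        raise ValueError("porosity must lie in [0, 1)")
    out = params.rho_s * (1.0 - phi) + params.rho_f * phi
    return float(out) if out.ndim == 0 else out


def equilibrium_pressure(params: MaterialParams) -> float:
    """Uniform pore pressure balancing the barrier pre-stress at F = I.

    With ``p = (mu + lambda/2)(1 - 1/phi0)`` the state ``chi = X, z = 0`` is
    an exact equilibrium of the mixture (zero total stress).  Zero for
    ``phi0 = 1``.
    """
    if params.phi0 == 0.0:
        raise ValueError("phi0 = 0 leaves no fluid phase to equilibrate")
    return (params.mu + 0.5 * params.lam) * (1.0 - 1.0 / params.phi0)


def effective_lame_about_equilibrium(params: MaterialParams) -> tuple[float, float]:
    """Drained small-strain Lame moduli about the equilibrated reference.

    Subtracting the equilibrium pore-pressure work turns the skeleton into
    the stress-free hyperelastic law ``W - p_eq (J - 1)``, whose moduli at
    ``F = I`` are ``mu_eff = mu`` and
    ``lam_eff = lambda + (mu + lambda/2)(1 - phi0^2)/phi0^2``.
    These, not the nominal inputs, govern the small-strain response the
    analytic benchmark solutions see.
    """
    mu, lam, phi0 = params.mu, params.lam, params.phi0
    if phi0 == 0.0:
        raise ValueError("phi0 = 0 leaves no fluid phase to equilibrate")
    lam_eff = lam + (mu + 0.5 * lam) * (1.0 - phi0 * phi0) / (phi0 * phi0)
    return mu, lam_eff
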