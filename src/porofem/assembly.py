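"""Assembly of the block linear system of the stabilized three-field method.

Unknown ordering: nodal positions chi (3 per node), nodal Darcy flux z
(3 per node), piecewise-constant pressure p (1 per cell), one Lagrange
multiplier per (flux-surface tag, node) pair, and finally an optional
mean-pressure gauge multiplier when the pressure is only determined up to a
constant.  The quasi-Newton matrix is

    [ Ke   0      B^T    0   ]   [ d chi ]     [ r1 ]
    [ 0    M      B^T    C^T ]   [ d z   ] = - [ r2 ]
    [ -B  -dt B   Jstab  0   ]   [ d p   ]     [ r3 ]
    [ 0    C      0      0   ]   [ d lam ]     [ r4 ]

with all integrals evaluated in the current (trial) configuration
(updated Lagrangian).  The retained linearization freezes the permeability,
the domain and the facet normals; the residuals are always exact, so a
converged solution solves the full nonlinear problem.

Because the strain-energy law's spatial tangent is isotropic at every
deformation state (see :mod:`porofem.constitutive`), the material part of
``Ke`` is assembled from the two scalar coefficients ``(c1, c2)`` directly;
the Voigt-form matrices ``D`` and ``E`` are provided for verification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from . import elements
from .constitutive import MaterialParams, BarrierViolationError, mixture_density
from .elements import TET4, face_quadrature
from .mesh import Mesh

__all__ = [
    "BoundaryConditions",
    "DofMap",
    "BlockSystem",
    "StepRejected",
    "ConfigurationError",
    "update_current_configuration",
    "volume_geometry",
    "assemble_elasticity_block",
    "assemble_darcy_mass",
    "assemble_divergence",
    "assemble_stabilization",
    "assemble_residuals",
    "assemble_flux_constraint",
    "assemble_system",
    "apply_essential_bcs",
    "voigt_tangent_matrix",
    "strain_displacement_matrix",
    "default_quadrature_degree",
]


class StepRejected(RuntimeError):
    """Trial configuration is inadmissible (inverted element or barrier hit)."""


class ConfigurationError(ValueError):
    """Boundary-condition specification inconsistent with the mesh."""


def default_quadrature_degree(cell_type: str) -> int:
    # the nonlinear stress under-integrates with 1-point rules
    return 2 if cell_type == TET4 else 3


def _as_value(spec, x, t):
    """Evaluate a BC entry: constant scalar/vector or callable(x, t)."""
    if callable(spec):
        return spec(x, t)
    return spec


@dataclass
class BoundaryConditions:
    """Boundary data keyed by facet tag (or node-set name for dirichlet).

    dirichlet : tag/nodeset -> (mask, value); ``mask`` is a 3-tuple of bools
        selecting constrained components (rollers constrain one), ``value``
        the prescribed displacement u_D: a 3-vector or callable(X, t).
    traction  : tag -> Cauchy traction t_N: 3-vector, scalar (times outward
        normal), or callable(x, t).
    flux      : tag -> normal flux q_D (scalar or callable), enforced weakly
        by a Lagrange multiplier field with one dof per (tag, node) pair on
        the tagged surface.  A facet-wise constant multiplier space would
        over-constrain the piecewise-linear normal trace on simplicial
        boundaries (about two triangles per boundary node), making the
        saddle-point system structurally singular; the nodal space has
        exactly the trace resolution.
    pressure  : tag -> pore pressure p_D (scalar or callable); enters the
        Darcy equation as a natural boundary term.
    body_force: 3-vector or callable(x, t) (acceleration, m/s^2).
    source    : fluid source g (scalar or callable(x, t), 1/s).
    """

    dirichlet: dict = field(default_factory=dict)
    traction: dict = field(default_factory=dict)
    flux: dict = field(default_factory=dict)
    pressure: dict = field(default_factory=dict)
    body_force: object = None
    source: object = None

    def validate(self, mesh: Mesh) -> None:
        tags = set(mesh.boundary_tags())
        sets = set(mesh.node_sets)
        for key in self.dirichlet:
            if key not in tags and key not in sets:
                raise ConfigurationError(f"dirichlet key {key!r} matches no tag or node set")
        for name, d in (("traction", self.traction), ("flux", self.flux),
                        ("pressure", self.pressure)):
            for key in d:
                if key not in tags:
                    raise ConfigurationError(f"{name} tag {key!r} not present in mesh")
        overlap = set(self.flux) & set(self.pressure)
        if overlap:
            raise ConfigurationError(
                f"tags {sorted(overlap)} appear in both flux and pressure conditions"
            )


@dataclass
class DofMap:
    """Global degree-of-freedom layout and essential-constraint data."""

    mesh: Mesh
    bcs: BoundaryConditions
    n_nodes: int = 0
    n_cells: int = 0
    flux_facets: list = field(default_factory=list)
    flux_multipliers: list = field(default_factory=list)  # (tag, node) pairs
    gauge: bool = False
    chi_fixed: np.ndarray = None  # (3N,) bool
    _dirichlet_entries: list = field(default_factory=list)

    def __post_init__(self):
        mesh, bcs = self.mesh, self.bcs
        bcs.validate(mesh)
        self.n_nodes = mesh.n_nodes
        self.n_cells = mesh.n_cells
        self.flux_facets = [bf for bf in mesh.boundary_facets if bf[3] in bcs.flux]
        pairs = sorted({(bf[3], n) for bf in self.flux_facets for n in bf[2]})
        self.flux_multipliers = pairs
        fixed = np.zeros(3 * self.n_nodes, dtype=bool)
        owner = np.full(3 * self.n_nodes, -1, dtype=int)
        for key, (mask, value) in bcs.dirichlet.items():
            nodes = self._nodes_for(key)
            for comp, m in enumerate(mask):
                if not m:
                    continue
                dofs = 3 * nodes + comp
                clash = owner[dofs] >= 0
                if np.any(clash):
                    other = self._dirichlet_entries[owner[dofs][clash][0]][0]
                    if not self._compatible(key, other, comp):
                        raise ConfigurationError(
                            f"dof constrained by both {key!r} and {other!r} "
                            "with different values"
                        )
                owner[dofs] = len(self._dirichlet_entries)
                fixed[dofs] = True
            self._dirichlet_entries.append((key, np.asarray(nodes), mask, value))
        self.chi_fixed = fixed
        # pressure gauge: the constant mode survives only when no pressure
        # datum reaches the system -- no pressure tag, no *untagged* fluid
        # boundary (untagged facets impose p = 0 naturally in the mixed
        # form), and no free mixture surface
        all_flux = all(bf[3] in bcs.flux for bf in mesh.boundary_facets)
        has_gp = bool(bcs.pressure) or not all_flux
        has_gn = self._has_free_mixture_boundary()
        self.gauge = not (has_gp or has_gn)

    def _compatible(self, key_a, key_b, comp) -> bool:
        def val(key):
            _, (mask, value) = key, self.bcs.dirichlet[key]
            return value

        va, vb = val(key_a), val(key_b)
        if callable(va) or callable(vb):
            return False
        va = np.broadcast_to(np.asarray(va, dtype=float), (3,))
        vb = np.broadcast_to(np.asarray(vb, dtype=float), (3,))
        return np.isclose(va[comp], vb[comp])

    def _nodes_for(self, key) -> np.ndarray:
        if key in self.mesh.node_sets:
            return np.asarray(self.mesh.node_sets[key], dtype=int)
        nodes = set()
        for bf in self.mesh.boundary_facets:
            if bf[3] == key:
                nodes.update(bf[2])
        return np.array(sorted(nodes), dtype=int)

    def _has_free_mixture_boundary(self) -> bool:
        """True if some boundary facet has any unconstrained displacement dof."""
        for (_c, _f, ring, _tag) in self.mesh.boundary_facets:
            for n in ring:
                if not self.chi_fixed[3 * n: 3 * n + 3].all():
                    return True
        return False

    # -- layout ----------------------------------------------------------
    @property
    def n_chi(self) -> int:
        return 3 * self.n_nodes

    @property
    def n_z(self) -> int:
        return 3 * self.n_nodes

    @property
    def n_p(self) -> int:
        return self.n_cells

    @property
    def n_lambda(self) -> int:
        return len(self.flux_multipliers)

    @property
    def n_total(self) -> int:
        return self.n_chi + self.n_z + self.n_p + self.n_lambda + (1 if self.gauge else 0)

    def prescribed_positions(self, t: float) -> tuple[np.ndarray, np.ndarray]:
        """(mask, values): prescribed nodal positions chi = X + u_D at time t."""
        values = np.zeros(3 * self.n_nodes)
        for key, nodes, mask, value in self._dirichlet_entries:
            X = self.mesh.ref_coords[nodes]
            u = _as_value(value, X, t)
            u = np.broadcast_to(np.asarray(u, dtype=float), (len(nodes), 3))
            for comp, m in enumerate(mask):
                if m:
                    values[3 * nodes + comp] = X[:, comp] + u[:, comp]
        return self.chi_fixed, values

    def free_mask(self) -> np.ndarray:
        full = np.ones(self.n_total, dtype=bool)
        full[: self.n_chi] = ~self.chi_fixed
        return full


def update_current_configuration(mesh: Mesh, chi_nodal) -> Mesh:
    """Set the current coordinates to the trial deformation, in place.

    Raises :class:`StepRejected` if the trial configuration inverts any
    element, so the solver can reject the step instead of crashing.
    """
    chi = np.asarray(chi_nodal, dtype=float).reshape(mesh.n_nodes, 3)
    mesh.cur_coords = chi.copy()
    vols = mesh.cell_volumes("cur")
    if vols.min() <= 0.0 or not np.all(np.isfinite(vols)):
        raise StepRejected(
            f"trial configuration inverts element {int(np.argmin(vols))} "
            f"(volume {vols.min():g})"
        )
    return mesh


# -- shared per-call geometry -------------------------------------------

@dataclass
class VolumeGeometry:
    """Quadrature-point geometry shared by the volume-integral assemblers."""

    N: np.ndarray        # (nq, nn)       basis values
    grads: np.ndarray    # (ne, nq, nn, 3) gradients w.r.t. current coords
    dv: np.ndarray       # (ne, nq)       current-configuration weights
    F: np.ndarray        # (ne, nq, 3, 3) deformation gradient
    J: np.ndarray        # (ne, nq)
    xq: np.ndarray       # (ne, nq, 3)    quadrature point positions (current)


def volume_geometry(mesh: Mesh, degree: int | None = None,
                    phi0: float | None = None) -> VolumeGeometry:
    if degree is None:
        degree = default_quadrature_degree(mesh.cell_type)
    rule = elements.quadrature_rule(mesh.cell_type, degree)
    N, dN = elements.shape_table(mesh.cell_type, rule)
    Xe = mesh.ref_coords[mesh.cells]
    xe = mesh.cur_coords[mesh.cells]
    jac_cur = np.einsum("eki,qkj->eqij", xe, dN)
    jac_ref = np.einsum("eki,qkj->eqij", Xe, dN)
    det_cur = np.linalg.det(jac_cur)
    det_ref = np.linalg.det(jac_ref)
    if det_cur.min() <= 0.0 or det_ref.min() <= 0.0:
        raise StepRejected("non-positive map Jacobian at a quadrature point")
    grads = np.einsum("qkj,eqji->eqki", dN, np.linalg.inv(jac_cur))
    F = np.einsum("eqij,eqjk->eqik", jac_cur, np.linalg.inv(jac_ref))
    J = det_cur / det_ref
    if phi0 is not None and J.min() <= 1.0 - phi0:
        raise StepRejected(
            f"J = {J.min():g} reached the porosity barrier 1 - phi0 = {1.0 - phi0:g}"
        )
    dv = rule.weights[None, :] * det_cur
    xq = np.einsum("qk,eki->eqi", N, xe)
    return VolumeGeometry(N=N, grads=grads, dv=dv, F=F, J=J, xq=xq)


def _stress_fields(geom: VolumeGeometry, params: MaterialParams):
    """Batched sigma_e, tangent coefficients and k^-1 at the quadrature points."""
    F, J = geom.F, geom.J
    if J.min() <= 1.0 - params.phi0:
        raise BarrierViolationError(
            f"J = {J.min():g} <= 1 - phi0 = {1.0 - params.phi0:g}"
        )
    mu, lam, phi0 = params.mu, params.lam, params.phi0
    b = np.einsum("eqij,eqkj->eqik", F, F)
    s = 0.5 * lam * J * J - (mu + 0.5 * lam) * J / (J - 1.0 + phi0)
    sigma = (mu * b + s[..., None, None] * np.eye(3)) / J[..., None, None]
    c1 = lam * J - (mu + 0.5 * lam) * (phi0 - 1.0) / (J - 1.0 + phi0) ** 2
    c2 = -s / J
    return sigma, c1, c2


def _kinv_fields(geom: VolumeGeometry, params: MaterialParams, k0_cell=None):
    """k^-1 at the quadrature points: J F^-T k0(C)^-1 F^-1."""
    Finv = np.linalg.inv(geom.F)
    if params.k0_fn is not None:
        C = np.einsum("eqki,eqkj->eqij", geom.F, geom.F)
        k0_ref = np.asarray(params.k0_fn(C), dtype=float)
        if k0_ref.shape != C.shape:  # pointwise-only callable
            k0_ref = np.stack(
                [np.stack([np.asarray(params.k0_fn(Cq), dtype=float)
                           for Cq in Ce]) for Ce in C]
            )
        k0_inv = np.linalg.inv(k0_ref)
        return geom.J[..., None, None] * np.einsum(
            "eqki,eqkl,eqlj->eqij", Finv, k0_inv, Finv
        )
    binv = np.einsum("eqki,eqkj->eqij", Finv, Finv)
    k0 = params.k0 if k0_cell is None else np.asarray(k0_cell, dtype=float)
    if np.any(np.asarray(k0) <= 0.0):
        raise ValueError("permeability must be positive")
    scale = geom.J / (k0[:, None] if k0_cell is not None else k0)
    return scale[..., None, None] * binv


def _scatter_nodal_block(mesh: Mesh, Ke_elem: np.ndarray) -> sp.csr_matrix:
    """Scatter (ne, nn, 3, nn, 3) element blocks into a 3N x 3N CSR matrix."""
    ne, nn = Ke_elem.shape[0], Ke_elem.shape[1]
    dofs = (3 * mesh.cells[:, :, None] + np.arange(3)[None, None, :]).reshape(ne, 3 * nn)
    rows = np.repeat(dofs, 3 * nn, axis=1).ravel()
    cols = np.tile(dofs, (1, 3 * nn)).ravel()
    vals = Ke_elem.reshape(ne, 3 * nn, 3 * nn).ravel()
    n = 3 * mesh.n_nodes
    return sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


def assemble_elasticity_block(mesh: Mesh, params: MaterialParams,
                              geom: VolumeGeometry | None = None,
                              p_cell=None) -> sp.csr_matrix:
    """Tangent stiffness Ke of the momentum residual at fixed pressure.

    Material part (isotropic spatial tangent), geometric part
    ``grad(phi_a)^T sigma_e grad(phi_b)``, and -- when the cell pressures
    are supplied -- the domain-variation kernel of the ``-p div v`` term,
    ``p (d_il d_jk - d_ij d_kl)``.  The last term is not small here: the
    porosity barrier leaves an O(mu) equilibrium pressure in every problem,
    so dropping it would degrade the Newton contraction from superlinear to
    a fixed ~p/(lam+2mu) linear rate.  With it, Ke matches central finite
    differences of r1 w.r.t. nodal positions at fixed p.
    """
    if geom is None:
        geom = volume_geometry(mesh)
    sigma, c1, c2 = _stress_fields(geom, params)
    g, dv = geom.grads, geom.dv
    I3 = np.eye(3)
    w1 = dv * c1
    w2 = dv * c2
    if p_cell is not None:
        wp = dv * np.asarray(p_cell, dtype=float)[:, None]
        w1 = w1 - wp
        term = np.einsum("eq,eqaj,eqbi->eaibj", w2 + wp, g, g)
    else:
        term = np.einsum("eq,eqaj,eqbi->eaibj", w2, g, g)
    term += np.einsum("eq,eqai,eqbj->eaibj", w1, g, g)
    gram = np.einsum("eq,eqak,eqbk->eab", w2, g, g)
    geo = np.einsum("eq,eqak,eqkl,eqbl->eab", dv, g, sigma, g)
    term += np.einsum("eab,ij->eaibj", gram + geo, I3)
    return _scatter_nodal_block(mesh, term)


def assemble_darcy_mass(mesh: Mesh, params: MaterialParams,
                        geom: VolumeGeometry | None = None,
                        k0_cell=None) -> sp.csr_matrix:
    """Darcy mass matrix M with entries ``int k^-1 phi_a . phi_b``."""
    if geom is None:
        geom = volume_geometry(mesh)
    kinv = _kinv_fields(geom, params, k0_cell)
    Me = np.einsum("eq,qa,qb,eqij->eaibj", geom.dv, geom.N, geom.N, kinv)
    return _scatter_nodal_block(mesh, Me)


def assemble_divergence(mesh: Mesh, geom: VolumeGeometry | None = None) -> sp.csr_matrix:
    """Pressure-divergence coupling B with entries ``-int psi_k div phi_l``."""
    if geom is None:
        geom = volume_geometry(mesh)
    Be = -np.einsum("eq,eqbj->ebj", geom.dv, geom.grads)  # (ne, nn, 3)
    ne, nn = Be.shape[0], Be.shape[1]
    rows = np.repeat(np.arange(ne), 3 * nn)
    cols = (3 * mesh.cells[:, :, None] + np.arange(3)[None, None, :]).ravel()
    return sp.coo_matrix(
        (Be.ravel(), (rows, cols)), shape=(ne, 3 * mesh.n_nodes)
    ).tocsr()


def _face_metrics(mesh: Mesh, faces, config: str = "cur"):
    """Areas and diameters of homogeneous face rings, batched."""
    coords = mesh.cur_coords if config == "cur" else mesh.ref_coords
    rings = np.asarray([list(r) for r in faces], dtype=np.int64)
    x = coords[rings]  # (nf, 3 or 4, 3)
    nv = x.shape[1]
    pairs = [(i, j) for i in range(nv) for j in range(i + 1, nv)]
    d2 = np.stack([((x[:, i] - x[:, j]) ** 2).sum(axis=1) for i, j in pairs])
    diams = np.sqrt(d2.max(axis=0))
    if nv == 3:
        cr = np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0])
        areas = 0.5 * np.linalg.norm(cr, axis=1)
    else:
        g = 1.0 / np.sqrt(3.0)
        areas = np.zeros(len(x))
        for xi, eta in ((-g, -g), (g, -g), (-g, g), (g, g)):
            du = 0.25 * (-(1 - eta) * x[:, 0] + (1 - eta) * x[:, 1]
                         + (1 + eta) * x[:, 2] - (1 + eta) * x[:, 3])
            dv = 0.25 * (-(1 - xi) * x[:, 0] - (1 + xi) * x[:, 1]
                         + (1 + xi) * x[:, 2] + (1 - xi) * x[:, 3])
            areas += np.linalg.norm(np.cross(du, dv), axis=1)
    return areas, diams


def assemble_stabilization(mesh: Mesh, upsilon: float) -> sp.csr_matrix:
    """Pressure-jump penalty Jstab over interior faces.

    Each interior face f contributes ``upsilon * h_f * area_f`` times the
    2x2 jump block [[1,-1],[-1,1]] to its two adjacent pressure dofs; the
    face size ``h_f`` is the diameter measured in the current configuration.
    Symmetric positive-semidefinite with the constant-pressure null vector.
    """
    np_ = mesh.n_cells
    if upsilon < 0.0:
        raise ValueError("upsilon must be non-negative")
    if not mesh.interior_faces or upsilon == 0.0:
        return sp.csr_matrix((np_, np_))
    lefts = np.array([f[0] for f in mesh.interior_faces])
    rights = np.array([f[1] for f in mesh.interior_faces])
    areas, diams = _face_metrics(mesh, [f[2] for f in mesh.interior_faces])
    w = upsilon * diams * areas
    rows = np.concatenate([lefts, lefts, rights, rights])
    cols = np.concatenate([lefts, rights, lefts, rights])
    vals = np.concatenate([w, -w, -w, w])
    return sp.coo_matrix((vals, (rows, cols)), shape=(np_, np_)).tocsr()


def assemble_flux_constraint(mesh: Mesh, bcs: BoundaryConditions, dofmap: DofMap,
                             t: float = 0.0):
    """Weak flux constraint ``(z . n, l)_{Gamma_f} = (q_D, l)_{Gamma_f}``.

    The multiplier space is continuous piecewise-linear per tagged surface
    (one dof per (tag, node) pair), so the constraint row of multiplier
    ``(tag, a)`` reads ``int N_a z . n ds = int N_a q_D ds`` over the tagged
    facets.  Rows are built on the current configuration and treated as
    linear in the Newton matrix (normals frozen at the trial configuration).
    Returns ``(C, q)`` with C of shape (n_lambda, 3N).
    """
    nlam = dofmap.n_lambda
    mindex = {pair: i for i, pair in enumerate(dofmap.flux_multipliers)}
    rows, cols, vals = [], [], []
    q = np.zeros(nlam)
    for (cell, fid, ring, tag) in dofmap.flux_facets:
        coords = mesh.cur_coords[list(ring)]
        pts, wts, nrms = face_quadrature(coords)
        if wts.sum() <= 0.0:
            raise StepRejected(f"flux facet {ring} has zero current area")
        shp = _facet_shape(len(ring))
        for p_, w_, n_ in zip(pts, wts, nrms):
            sh = shp(coords, p_)
            qd = float(_as_value(bcs.flux[tag], p_, t))
            for a, node_a in enumerate(ring):
                s = mindex[(tag, node_a)]
                q[s] += w_ * sh[a] * qd
                for b, node_b in enumerate(ring):
                    for comp in range(3):
                        rows.append(s)
                        cols.append(3 * node_b + comp)
                        vals.append(w_ * sh[a] * sh[b] * n_[comp])
    C = sp.coo_matrix((vals, (rows, cols)), shape=(nlam, 3 * mesh.n_nodes))
    return C.tocsr(), q


def _facet_shape(nv: int):
    """Nodal shape values on a facet at a physical quadrature point."""
    if nv == 3:
        def tri(coords, x):
            # barycentric coordinates via least squares (planar triangle)
            A = np.vstack([coords.T, np.ones(3)])
            b = np.concatenate([x, [1.0]])
            lam, *_ = np.linalg.lstsq(A, b, rcond=None)
            return lam
        return tri

    def quad(coords, x):
        # bilinear inverse by two Newton steps from the centre
        xi = np.zeros(2)
        for _ in range(6):
            sh = 0.25 * np.array(
                [
                    (1 - xi[0]) * (1 - xi[1]),
                    (1 + xi[0]) * (1 - xi[1]),
                    (1 + xi[0]) * (1 + xi[1]),
                    (1 - xi[0]) * (1 + xi[1]),
                ]
            )
            d = 0.25 * np.array(
                [
                    [-(1 - xi[1]), -(1 - xi[0])],
                    [+(1 - xi[1]), -(1 + xi[0])],
                    [+(1 + xi[1]), +(1 + xi[0])],
                    [-(1 + xi[1]), +(1 - xi[0])],
                ]
            )
            r = sh @ coords - x
            Jm = d.T @ coords  # (2,3)
            delta = np.linalg.lstsq(Jm.T, r, rcond=None)[0]
            xi -= delta
            if np.linalg.norm(delta) < 1e-13:
                break
        sh = 0.25 * np.array(
            [
                (1 - xi[0]) * (1 - xi[1]),
                (1 + xi[0]) * (1 - xi[1]),
                (1 + xi[0]) * (1 + xi[1]),
                (1 - xi[0]) * (1 + xi[1]),
            ]
        )
        return sh
    return quad


def _surface_load(mesh: Mesh, facets, value_of_tag, t, into, sign=1.0,
                  normal_times_scalar=False):
    """Accumulate ``sign * int N_a v ds`` over tagged facets into a (3N,) vector.

    ``value_of_tag(tag)`` returns the BC entry; scalars are multiplied by the
    outward normal when ``normal_times_scalar`` (tractions) or used as the
    coefficient of the normal (pressure terms) -- both reduce to the same
    v = scalar * n form.
    """
    for (cell, fid, ring, tag) in facets:
        spec = value_of_tag(tag)
        coords = mesh.cur_coords[list(ring)]
        pts, wts, nrms = face_quadrature(coords)
        shp = _facet_shape(len(ring))
        for p_, w_, n_ in zip(pts, wts, nrms):
            v = _as_value(spec, p_, t)
            v = np.asarray(v, dtype=float)
            if v.ndim == 0:
                v = float(v) * n_
            sh = shp(coords, p_)
            for a, node in enumerate(ring):
                into[3 * node: 3 * node + 3] += sign * w_ * sh[a] * v
    return into


def assemble_residuals(mesh: Mesh, state, state_prev, params: MaterialParams,
                       bcs: BoundaryConditions, dt: float, t: float,
                       dofmap: DofMap, geom: VolumeGeometry | None = None,
                       Jstab: sp.csr_matrix | None = None,
                       C: sp.csr_matrix | None = None, q_rhs=None,
                       k0_cell=None):
    """Exact residuals (r1, r2, r3, r4) at the trial state.

    r1: mixture momentum (internal force minus body force and traction);
    r2: Darcy law including the pressure-BC boundary term and the
        multiplier coupling C^T lambda;
    r3: dt-scaled mass balance plus the pressure-increment jump term;
    r4: flux-constraint residual C z - q.
    """
    if geom is None:
        geom = volume_geometry(mesh, phi0=params.phi0)
    if Jstab is None:
        Jstab = assemble_stabilization(mesh, params.upsilon)
    if C is None or q_rhs is None:
        C, q_rhs = assemble_flux_constraint(mesh, bcs, dofmap, t)
    sigma, _c1, _c2 = _stress_fields(geom, params)
    kinv = _kinv_fields(geom, params, k0_cell)
    N, g, dv = geom.N, geom.grads, geom.dv
    cells = mesh.cells

    p = np.asarray(state.p, dtype=float)
    total = sigma - p[:, None, None, None] * np.eye(3)
    r1e = np.einsum("eq,eqij,eqaj->eai", dv, total, g)
    z_e = np.asarray(state.z, dtype=float)[cells]
    kz = np.einsum("eqij,eqj->eqi", kinv, np.einsum("qa,eai->eqi", N, z_e))
    r2e = np.einsum("eq,qa,eqi->eai", dv, N, kz)
    r2e -= np.einsum("eq,e,eqai->eai", dv, p, g)

    if bcs.body_force is not None:
        f = np.asarray(_as_value(bcs.body_force, geom.xq, t), dtype=float)
        f = np.broadcast_to(f, geom.xq.shape)
        phi = 1.0 - (1.0 - params.phi0) / geom.J
        rho = mixture_density(np.clip(phi, 0.0, 1.0 - 1e-15), params)
        r1e -= np.einsum("eq,qa,eqi->eai", dv * rho, N, f)
        r2e -= params.rho_f * np.einsum("eq,qa,eqi->eai", dv, N, f)

    dchi_e = (np.asarray(state.chi) - np.asarray(state_prev.chi))[cells]
    div_dchi = np.einsum("eqak,eak->eq", g, dchi_e)
    div_z = np.einsum("eqak,eak->eq", g, z_e)
    r3 = np.einsum("eq,eq->e", dv, div_dchi + dt * div_z)
    if bcs.source is not None:
        gsrc = np.asarray(_as_value(bcs.source, geom.xq, t), dtype=float)
        gsrc = np.broadcast_to(gsrc, dv.shape)
        r3 -= dt * np.einsum("eq,eq->e", dv, gsrc)
    r3 += Jstab @ (p - np.asarray(state_prev.p, dtype=float))

    r1 = np.zeros(3 * mesh.n_nodes)
    np.add.at(r1.reshape(-1, 3), cells.ravel(), r1e.reshape(-1, 3))
    r2 = np.zeros(3 * mesh.n_nodes)
    np.add.at(r2.reshape(-1, 3), cells.ravel(), r2e.reshape(-1, 3))

    if bcs.traction:
        facets = [bf for bf in mesh.boundary_facets if bf[3] in bcs.traction]
        _surface_load(mesh, facets, lambda tag: bcs.traction[tag], t, r1, sign=-1.0)
    if bcs.pressure:
        facets = [bf for bf in mesh.boundary_facets if bf[3] in bcs.pressure]
        _surface_load(mesh, facets, lambda tag: bcs.pressure[tag], t, r2, sign=+1.0)
    lam = np.asarray(getattr(state, "lam", np.zeros(dofmap.n_lambda)), dtype=float)
    if dofmap.n_lambda:
        r2 += C.T @ lam
    r4 = C @ np.asarray(state.z, dtype=float).ravel() - q_rhs
    return r1, r2, r3, r4


@dataclass
class BlockSystem:
    """Assembled quasi-Newton blocks and residuals at one trial state."""

    Ke: sp.csr_matrix
    M: sp.csr_matrix
    B: sp.csr_matrix
    Jstab: sp.csr_matrix
    C: sp.csr_matrix
    r1: np.ndarray
    r2: np.ndarray
    r3: np.ndarray
    r4: np.ndarray
    dt: float
    dofmap: DofMap
    cell_volumes: np.ndarray = None

    def full_matrix(self) -> sp.csr_matrix:
        dm, dt = self.dofmap, self.dt
        blocks = [
            [self.Ke, None, self.B.T, None],
            [None, self.M, self.B.T, self.C.T if dm.n_lambda else None],
            [-self.B, -dt * self.B, self.Jstab, None],
            [None, self.C if dm.n_lambda else None, None, None],
        ]
        if not dm.n_lambda:
            blocks = [row[:3] for row in blocks[:3]]
        K = sp.bmat(blocks, format="csr")
        if dm.gauge:
            vol = self.cell_volumes
            col = np.zeros((K.shape[0], 1))
            col[dm.n_chi + dm.n_z: dm.n_chi + dm.n_z + dm.n_p, 0] = vol
            K = sp.bmat([[K, col], [col.T, None]], format="csr")
        return K

    def export_matrix_market(self, directory, prefix: str = "block") -> None:
        """Dump the sparse blocks as MatrixMarket files for debugging."""
        from pathlib import Path

        from scipy.io import mmwrite

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, mat in (("Ke", self.Ke), ("M", self.M), ("B", self.B),
                          ("Jstab", self.Jstab), ("C", self.C)):
            if mat is not None and mat.shape[0] and mat.shape[1]:
                mmwrite(str(directory / f"{prefix}_{name}.mtx"), mat)

    def full_residual(self) -> np.ndarray:
        parts = [self.r1, self.r2, self.r3]
        if self.dofmap.n_lambda:
            parts.append(self.r4)
        if self.dofmap.gauge:
            parts.append(np.zeros(1))
        return np.concatenate(parts)


def assemble_system(mesh: Mesh, state, state_prev, params: MaterialParams,
                    bcs: BoundaryConditions, dt: float, t: float,
                    dofmap: DofMap, k0_cell=None) -> BlockSystem:
    """Assemble every block and residual on the current trial configuration."""
    geom = volume_geometry(mesh, phi0=params.phi0)
    Jstab = assemble_stabilization(mesh, params.upsilon)
    C, q_rhs = assemble_flux_constraint(mesh, bcs, dofmap, t)
    Ke = assemble_elasticity_block(mesh, params, geom,
                                   p_cell=np.asarray(state.p, dtype=float))
    M = assemble_darcy_mass(mesh, params, geom, k0_cell)
    B = assemble_divergence(mesh, geom)
    r1, r2, r3, r4 = assemble_residuals(
        mesh, state, state_prev, params, bcs, dt, t, dofmap,
        geom=geom, Jstab=Jstab, C=C, q_rhs=q_rhs, k0_cell=k0_cell,
    )
    vols = np.einsum("eq->e", geom.dv)
    return BlockSystem(Ke=Ke, M=M, B=B, Jstab=Jstab, C=C,
                       r1=r1, r2=r2, r3=r3, r4=r4, dt=dt, dofmap=dofmap,
                       cell_volumes=vols)


def apply_essential_bcs(K: sp.csr_matrix, rhs: np.ndarray, dofmap: DofMap,
                        increment_values: np.ndarray | None = None):
    """Reduce the full system to the free dofs.

    Constrained rows/columns are eliminated symmetrically; a nonzero
    prescribed increment (rare: the solver lifts Dirichlet data before
    assembling) is folded into the right-hand side.
    Returns ``(K_ff, rhs_f, free_index)``.
    """
    free = dofmap.free_mask()
    idx = np.nonzero(free)[0]
    K = K.tocsr()
    K_rows = K[idx].tocsc()
    K_ff = K_rows[:, idx]
    rhs_f = rhs[idx].copy()
    if increment_values is not None and np.any(increment_values[~free] != 0.0):
        fixed_idx = np.nonzero(~free)[0]
        rhs_f -= K_rows[:, fixed_idx] @ increment_values[fixed_idx]
    return K_ff.tocsr(), rhs_f, idx


# -- Voigt-form verification helpers ------------------------------------

_VOIGT = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]


def voigt_tangent_matrix(F, params: MaterialParams) -> np.ndarray:
    """6x6 tangent D in Voigt order (11, 22, 33, 12, 13, 23), engineering shear."""
    from .constitutive import tangent_coefficients

    J = float(np.linalg.det(np.asarray(F, dtype=float)))
    c1, c2 = tangent_coefficients(J, params)
    D = np.zeros((6, 6))
    D[:3, :3] = c1
    D[np.arange(3), np.arange(3)] += 2.0 * c2
    D[np.arange(3, 6), np.arange(3, 6)] = c2
    return D


def strain_displacement_matrix(grads) -> np.ndarray:
    """6 x 3n strain-displacement matrix E for the given nodal gradients."""
    g = np.asarray(grads, dtype=float)
    n = len(g)
    E = np.zeros((6, 3 * n))
    for a in range(n):
        E[0, 3 * a + 0] = g[a, 0]
        E[1, 3 * a + 1] = g[a, 1]
        E[2, 3 * a + 2] = g[a, 2]
        E[3, 3 * a + 0] = g[a, 1]
        E[3, 3 * a + 1] = g[a, 0]
        E[4, 3 * a + 0] = g[a, 2]
        E[4, 3 * a + 2] = g[a, 0]
        E[5, 3 * a + 1] = g[a, 2]
        E[5, 3 * a + 2] = g[a, 1]
    return E
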