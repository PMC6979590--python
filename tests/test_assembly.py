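"""Block assembly: FD consistency, operator identities, boundary conditions."""

import numpy as np
import pytest
import scipy.sparse.linalg as spla

from porofem.assembly import (
    BoundaryConditions,
    ConfigurationError,
    DofMap,
    StepRejected,
    apply_essential_bcs,
    assemble_darcy_mass,
    assemble_divergence,
    assemble_elasticity_block,
    assemble_flux_constraint,
    assemble_residuals,
    assemble_stabilization,
    assemble_system,
    strain_displacement_matrix,
    update_current_configuration,
    voigt_tangent_matrix,
    volume_geometry,
)
from porofem.constitutive import (
    MaterialParams,
    equilibrium_pressure,
    tangent_coefficients,
)
from porofem.elements import shape_functions
from porofem.mesh import build_box_hex_mesh, tetrahedralize
from porofem.solver import SolutionState


def make_state(mesh, chi=None, z=None, p=None, nlam=0):
    n = mesh.n_nodes
    return SolutionState(
        chi=mesh.ref_coords.copy() if chi is None else chi,
        z=np.zeros((n, 3)) if z is None else z,
        p=np.zeros(mesh.n_cells) if p is None else p,
        lam=np.zeros(nlam),
    )


@pytest.fixture
def distorted_tet_box(rng):
    mesh = tetrahedralize(build_box_hex_mesh(2, 2, 2), "six_per_hex")
    chi = mesh.ref_coords + 0.04 * rng.standard_normal(mesh.ref_coords.shape)
    mesh.cur_coords = chi.copy()
    mesh.check_volumes("cur")
    return mesh, chi


class TestUpdateConfiguration:
    def test_identity_and_translation(self):
        mesh = build_box_hex_mesh(2, 1, 1)
        v0 = mesh.cell_volumes("cur")
        update_current_configuration(mesh, mesh.ref_coords + [5.0, -3.0, 1.0])
        assert np.allclose(mesh.cell_volumes("cur"), v0)

    def test_dilation_scales_volumes(self):
        mesh = build_box_hex_mesh(2, 1, 1)
        v0 = mesh.cell_volumes("cur")
        update_current_configuration(mesh, 2.0 * mesh.ref_coords)
        assert np.allclose(mesh.cell_volumes("cur"), 8.0 * v0)

    def test_inverted_element_signals_rejection(self):
        mesh = build_box_hex_mesh(1, 1, 1)
        bad = mesh.ref_coords.copy()
        bad[:, 2] *= -1.0
        with pytest.raises(StepRejected):
            update_current_configuration(mesh, bad)


class TestJacobianBlocksMatchResiduals:
    """Central-difference oracles for every retained Jacobian block."""

    def test_full_quasi_newton_consistency(self):
        from porofem.selfcheck import jacobian_blocks_fd_error

        assert jacobian_blocks_fd_error() < 1e-5

    def test_elasticity_block_on_distorted_tets(self, distorted_tet_box, rng,
                                                soft_params):
        mesh, chi = distorted_tet_box
        bcs = BoundaryConditions()
        dm = DofMap(mesh, bcs)
        p = 30.0 * rng.standard_normal(mesh.n_cells)
        prev = make_state(mesh)

        def r1(flat):
            m2 = mesh.copy()
            m2.cur_coords = flat.reshape(-1, 3).copy()
            st = make_state(m2, chi=m2.cur_coords, p=p)
            return assemble_residuals(m2, st, prev, soft_params, bcs, 0.1, 0.0, dm)[0]

        Ke = assemble_elasticity_block(mesh, soft_params, p_cell=p)
        h = 1e-6
        d = rng.standard_normal(3 * mesh.n_nodes)
        d /= np.linalg.norm(d)
        fd = (r1(chi.ravel() + h * d) - r1(chi.ravel() - h * d)) / (2 * h)
        assert np.linalg.norm(fd - Ke @ d) / np.linalg.norm(fd) < 1e-5

    def test_small_strain_limit_is_linear_elasticity(self, single_tet):
        """With no barrier and F = I, Ke is the classical (mu, lam) element
        stiffness (symbolic small-strain oracle via the Voigt matrices)."""
        p = MaterialParams(mu=7.0, lam=3.0, phi0=1.0)
        Ke = assemble_elasticity_block(single_tet, p).toarray()
        grads, _ = [None, None]
        from porofem.elements import physical_gradients

        g, det = physical_gradients(single_tet.ref_coords, "tet4",
                                    (0.25, 0.25, 0.25))
        E = strain_displacement_matrix(g)
        D = np.zeros((6, 6))
        D[:3, :3] = p.lam
        D[np.arange(3), np.arange(3)] += 2 * p.mu
        D[3:, 3:] = np.eye(3) * p.mu
        K_lin = (E.T @ D @ E) * (det / 6.0)
        assert np.allclose(Ke, K_lin, atol=1e-10 * abs(K_lin).max())

    def test_rigid_translation_in_kernel_at_equilibrium(self, single_tet):
        p = MaterialParams(mu=7.0, lam=3.0, phi0=1.0)
        Ke = assemble_elasticity_block(single_tet, p)
        for comp in range(3):
            t = np.zeros((4, 3))
            t[:, comp] = 1.0
            assert np.linalg.norm(Ke @ t.ravel()) < 1e-10


class TestVoigtForm:
    def test_EtDE_equals_material_contraction(self, rng, soft_params):
        """The Voigt route EᵀDE must reproduce the closed-form isotropic
        contraction used by the fast assembly path."""
        mesh = build_box_hex_mesh(1, 1, 1)
        chi = mesh.ref_coords + 0.05 * rng.standard_normal((8, 3))
        update_current_configuration(mesh, chi)
        geom = volume_geometry(mesh)
        q = 2
        g = geom.grads[0, q]
        F = geom.F[0, q]
        c1, c2 = tangent_coefficients(np.linalg.det(F), soft_params)
        E = strain_displacement_matrix(g)
        D = voigt_tangent_matrix(F, soft_params)
        K_voigt = E.T @ D @ E
        I3 = np.eye(3)
        K_direct = (
            c1 * np.einsum("ai,bj->aibj", g, g)
            + c2 * np.einsum("aj,bi->aibj", g, g)
            + c2 * np.einsum("ak,bk,ij->aibj", g, g, I3)
        ).reshape(24, 24)
        assert np.allclose(K_voigt, K_direct, atol=1e-10 * abs(K_direct).max())


class TestDarcyMass:
    def test_symmetric_positive_definite(self, distorted_tet_box, rng, soft_params):
        mesh, _ = distorted_tet_box
        M = assemble_darcy_mass(mesh, soft_params)
        assert (abs(M - M.T) > 1e-12).nnz == 0
        for _ in range(5):
            x = rng.standard_normal(M.shape[0])
            assert x @ (M @ x) > 0.0

    def test_reference_mass_matrix_single_hex(self):
        """F = I, k0 = 1: M is the vector trilinear mass matrix, whose
        exact entries follow the 1D pattern (1/3, 1/6) per direction."""
        mesh = build_box_hex_mesh(1, 1, 1)
        p = MaterialParams(mu=1.0, lam=1.0, phi0=1.0, k0=1.0)
        M = assemble_darcy_mass(mesh, p).toarray()
        # same-node diagonal entry: (1/3)^3; edge-neighbour: (1/3)^2 * (1/6)
        assert M[0, 0] == pytest.approx((1 / 3) ** 3)
        assert M[0, 3] == pytest.approx((1 / 3) ** 2 * (1 / 6))  # node 1 in x
        assert M[0, 1] == 0.0  # different components never couple for k ~ I

    def test_doubling_k0_halves_entries(self, soft_params):
        mesh = build_box_hex_mesh(2, 1, 1)
        M1 = assemble_darcy_mass(mesh, soft_params)
        p2 = MaterialParams(mu=soft_params.mu, lam=soft_params.lam,
                            phi0=soft_params.phi0, k0=2 * soft_params.k0)
        M2 = assemble_darcy_mass(mesh, p2)
        assert np.allclose(M2.toarray(), 0.5 * M1.toarray())


    def test_user_permeability_law_matches_isotropic_path(self):
        mesh = build_box_hex_mesh(2, 1, 1)
        iso = MaterialParams(mu=1.0, lam=1.0, phi0=1.0, k0=2.0)
        fn = MaterialParams(
            mu=1.0, lam=1.0, phi0=1.0,
            k0_fn=lambda C: 2.0 * np.broadcast_to(np.eye(3), C.shape),
        )
        M1 = assemble_darcy_mass(mesh, iso).toarray()
        M2 = assemble_darcy_mass(mesh, fn).toarray()
        assert np.abs(M1 - M2).max() < 1e-13


def test_matrix_market_export(tmp_path, soft_params):
    mesh = build_box_hex_mesh(2, 1, 1)
    bcs = BoundaryConditions(pressure={"x0": 0.0})
    dm = DofMap(mesh, bcs)
    st = make_state(mesh)
    sys_ = assemble_system(mesh, st, st, soft_params, bcs, 0.1, 0.1, dm)
    sys_.export_matrix_market(tmp_path)
    names = {p.name for p in tmp_path.glob("*.mtx")}
    assert {"block_Ke.mtx", "block_M.mtx", "block_B.mtx", "block_Jstab.mtx"} <= names
    from scipy.io import mmread

    Ke = mmread(tmp_path / "block_Ke.mtx")
    assert Ke.shape == sys_.Ke.shape


class TestDivergence:
    def test_annihilates_uniform_translation(self, distorted_tet_box):
        mesh, _ = distorted_tet_box
        B = assemble_divergence(mesh)
        t = np.tile([1.0, -2.0, 0.5], mesh.n_nodes)
        assert np.abs(B @ t).max() < 1e-12

    def test_unit_dilation_row_value(self):
        mesh = build_box_hex_mesh(1, 1, 1)
        B = assemble_divergence(mesh)
        x = mesh.ref_coords.ravel()
        assert (B @ x)[0] == pytest.approx(-3.0)  # -int div(x) = -3 |K|

    def test_rows_match_gauss_theorem(self, distorted_tet_box, rng):
        """-int_K div(v) equals the outward surface flux of v (facet-flux
        oracle via the cell's own face quadrature)."""
        from porofem.elements import face_quadrature, local_facets

        mesh, _ = distorted_tet_box
        B = assemble_divergence(mesh)
        v = rng.standard_normal((mesh.n_nodes, 3))
        lhs = B @ v.ravel()
        cell = 3
        conn = mesh.cells[cell]
        flux = 0.0
        for loc in local_facets("tet4"):
            ring = [int(conn[i]) for i in loc]
            pts, wts, nrms = face_quadrature(mesh.cur_coords[ring])
            vmid = v[ring].mean(axis=0)  # linear field at the centroid
            flux += wts[0] * float(nrms[0] @ vmid)
        assert lhs[cell] == pytest.approx(-flux, rel=1e-10)


class TestStabilization:
    def test_uniform_pressure_in_null_space(self, distorted_tet_box):
        mesh, _ = distorted_tet_box
        J = assemble_stabilization(mesh, 1e-3)
        assert np.abs(J @ np.ones(mesh.n_cells)).max() < 1e-15

    def test_two_unit_cubes_block(self):
        """Shared unit face: h = sqrt(2), area 1, so the face contributes
        upsilon*sqrt(2)*[[1,-1],[-1,1]] (hand integration of the jump)."""
        mesh = build_box_hex_mesh(2, 1, 1, 2.0, 1.0, 1.0)
        J = assemble_stabilization(mesh, 1.0).toarray()
        s = np.sqrt(2.0)
        assert np.allclose(J, s * np.array([[1, -1], [-1, 1]]), rtol=1e-12)

    def test_linearity_in_upsilon(self, distorted_tet_box):
        mesh, _ = distorted_tet_box
        J1 = assemble_stabilization(mesh, 1e-3)
        J10 = assemble_stabilization(mesh, 1e-2)
        assert np.allclose(J10.toarray(), 10.0 * J1.toarray())

    def test_symmetric_psd_with_rank_deficiency_one(self):
        mesh = tetrahedralize(build_box_hex_mesh(2, 2, 2), "six_per_hex")
        J = assemble_stabilization(mesh, 1.0).toarray()
        assert np.allclose(J, J.T)
        ev = np.linalg.eigvalsh(J)
        assert ev.min() > -1e-12 * ev.max()
        assert (ev < 1e-10 * ev.max()).sum() == 1  # constants only


class TestFluxConstraint:
    def make_setup(self):
        mesh = build_box_hex_mesh(2, 2, 1)
        bcs = BoundaryConditions(flux={"z0": 0.0})
        dm = DofMap(mesh, bcs)
        return mesh, bcs, dm

    def test_tangential_field_satisfies_zero_flux(self):
        mesh, bcs, dm = self.make_setup()
        C, q = assemble_flux_constraint(mesh, bcs, dm)
        z = np.tile([1.0, 2.0, 0.0], mesh.n_nodes)  # tangential to z0
        assert np.abs(C @ z - q).max() < 1e-12

    def test_uniform_normal_flux_value(self):
        mesh, bcs, dm = self.make_setup()
        C, _ = assemble_flux_constraint(mesh, bcs, dm)
        c = 0.7
        z = np.tile([0.0, 0.0, -c], mesh.n_nodes)  # outward at z0 (n = -e_z)
        # each multiplier row integrates N_a (z.n); summing rows gives the
        # total outward flux c * area(z0) = c
        total = (C @ z).sum()
        assert total == pytest.approx(c)

    def test_one_multiplier_per_surface_node(self):
        mesh, bcs, dm = self.make_setup()
        nodes_on_z0 = {n for bf in mesh.boundary_facets if bf[3] == "z0"
                       for n in bf[2]}
        assert dm.n_lambda == len(nodes_on_z0)

    def test_converged_solve_annihilates_normal_flux(self, soft_params):
        """After a solve with q_D = 0, the weak normal flux through every
        constrained surface node is zero (post-solve verification)."""
        from porofem.solver import newton_solve

        mesh = build_box_hex_mesh(2, 2, 2)
        p_eq = equilibrium_pressure(soft_params)
        bcs = BoundaryConditions(
            dirichlet={
                "x0": ((True, False, False), (0.0, 0.0, 0.0)),
                "y0": ((False, True, False), (0.0, 0.0, 0.0)),
                "z0": ((False, False, True), (0.0, 0.0, 0.0)),
            },
            pressure={"x0": p_eq + 5.0, "x1": p_eq},
            flux={"y0": 0.0, "y1": 0.0, "z0": 0.0, "z1": 0.0},
        )
        dm = DofMap(mesh, bcs)
        st0 = SolutionState.initial(mesh, dm, p0=p_eq)
        st, rec = newton_solve(mesh, st0, 0.05, 0.05, soft_params, bcs, dm)
        assert rec.outcome == "converged"
        C, q = assemble_flux_constraint(mesh, bcs, dm)
        zmax = np.abs(st.z).max()
        assert np.abs(C @ st.z.ravel() - q).max() < 1e-10 * max(zmax, 1.0)


class TestResidualEquilibria:
    def test_barrier_state_self_equilibrated_by_uniform_pressure(self, soft_params):
        """chi = X, z = 0, p = p_eq is an exact discrete equilibrium."""
        mesh = tetrahedralize(build_box_hex_mesh(2, 2, 2), "six_per_hex")
        bcs = BoundaryConditions(
            pressure={t: equilibrium_pressure(soft_params)
                      for t in ("x0", "x1", "y0", "y1", "z0", "z1")}
        )
        dm = DofMap(mesh, bcs)
        p_eq = equilibrium_pressure(soft_params)
        st = make_state(mesh, p=np.full(mesh.n_cells, p_eq))
        r1, r2, r3, r4 = assemble_residuals(mesh, st, st, soft_params, bcs,
                                            0.1, 0.0, dm)
        scale = abs(p_eq)
        assert np.abs(r1).max() < 1e-12 * scale
        assert np.abs(r2).max() < 1e-12 * scale
        assert np.abs(r3).max() < 1e-14

    def test_hydrostatic_traction_balanced_by_matching_pressure(self, soft_params):
        """Dead traction -p_hat n with interior p = p_hat + p_eq leaves the
        momentum residual zero (discrete divergence-theorem identity)."""
        mesh = build_box_hex_mesh(2, 2, 2)
        p_hat = 3.7
        p_eq = equilibrium_pressure(soft_params)
        bcs = BoundaryConditions(
            traction={t: -p_hat for t in ("x0", "x1", "y0", "y1", "z0", "z1")}
        )
        dm = DofMap(mesh, bcs)
        st = make_state(mesh, p=np.full(mesh.n_cells, p_hat + p_eq))
        r1, _, _, _ = assemble_residuals(mesh, st, st, soft_params, bcs,
                                         0.1, 0.0, dm)
        assert np.abs(r1).max() < 1e-12 * p_hat

    def test_no_motion_zero_mass_residual(self, distorted_tet_box, soft_params):
        mesh, chi = distorted_tet_box
        bcs = BoundaryConditions()
        dm = DofMap(mesh, bcs)
        st = make_state(mesh, chi=chi, p=np.full(mesh.n_cells, 2.0))
        r3 = assemble_residuals(mesh, st, st, soft_params, bcs, 0.1, 0.0, dm)[2]
        assert np.abs(r3).max() < 1e-14


class TestEssentialBCs:
    def test_zero_values_reduce_to_row_column_deletion(self, soft_params):
        mesh = build_box_hex_mesh(1, 1, 1)
        bcs = BoundaryConditions(
            dirichlet={"z0": ((True, True, True), (0.0, 0.0, 0.0))},
            pressure={"z1": 0.0},
        )
        dm = DofMap(mesh, bcs)
        st = make_state(mesh, nlam=dm.n_lambda)
        sys_ = assemble_system(mesh, st, st, soft_params, bcs, 0.1, 0.0, dm)
        K = sys_.full_matrix()
        r = sys_.full_residual()
        K_ff, rhs, idx = apply_essential_bcs(K, -r, dm)
        free = dm.free_mask()
        dense = K.toarray()[np.ix_(free, free)]
        assert np.allclose(K_ff.toarray(), dense)

    def test_pure_dirichlet_pressure_problem_needs_gauge(self, soft_params):
        """All-displacement-Dirichlet, no pressure BC: the pressure level is
        free, the gauge row restores solvability (null-space check)."""
        mesh = build_box_hex_mesh(2, 1, 1)
        full = ((True, True, True), (0.0, 0.0, 0.0))
        tags = ("x0", "x1", "y0", "y1", "z0", "z1")
        bcs = BoundaryConditions(
            dirichlet={t: full for t in tags},
            flux={t: 0.0 for t in tags},
        )
        dm = DofMap(mesh, bcs)
        assert dm.gauge
        st = make_state(mesh, nlam=dm.n_lambda)
        sys_ = assemble_system(mesh, st, st, soft_params, bcs, 0.1, 0.0, dm)
        K_full, rhs, _ = apply_essential_bcs(sys_.full_matrix(),
                                             -sys_.full_residual(), dm)
        lu = spla.splu(K_full.tocsc())
        x = lu.solve(rhs)
        assert np.all(np.isfinite(x))
        # without the gauge the same matrix is singular
        K_ng = K_full[:-1, :][:, :-1].tocsc()
        sing = np.linalg.svd(K_ng.toarray(), compute_uv=False)
        assert sing.min() < 1e-12 * sing.max()

    def test_conflicting_dirichlet_values_raise(self):
        mesh = build_box_hex_mesh(1, 1, 1)
        bcs = BoundaryConditions(
            dirichlet={
                "x0": ((True, False, False), (1.0, 0.0, 0.0)),
                "z0": ((True, False, False), (2.0, 0.0, 0.0)),
            }
        )
        with pytest.raises(ConfigurationError):
            DofMap(mesh, bcs)

    def test_unknown_tag_raises(self):
        mesh = build_box_hex_mesh(1, 1, 1)
        bcs = BoundaryConditions(traction={"nope": 1.0})
        with pytest.raises(ConfigurationError):
            DofMap(mesh, bcs)
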