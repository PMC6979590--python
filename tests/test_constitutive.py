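"""Material model: kinematics, energy, stress, tangent, permeability."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import special_ortho_group

from porofem.constitutive import (
    BarrierViolationError,
    MaterialParams,
    effective_lame_about_equilibrium,
    effective_stress,
    equilibrium_pressure,
    kinematics_at_point,
    lame_from_young_poisson,
    mixture_density,
    permeability_current,
    second_piola_stress,
    spatial_tangent,
    strain_energy,
)
from conftest import random_admissible_F


class TestLameConversion:
    @pytest.mark.parametrize("E,nu,mu,lam", [
        (1000.0, 0.15, 1000.0 / 2.3, 150.0 / 0.805),
        (100.0, 0.25, 40.0, 40.0),
        (123.0, 0.0, 61.5, 0.0),
    ])
    def test_printed_formulas(self, E, nu, mu, lam):
        got_mu, got_lam = lame_from_young_poisson(E, nu)
        assert got_mu == pytest.approx(mu, rel=1e-14)
        assert got_lam == pytest.approx(lam, rel=1e-14, abs=1e-14)

    def test_incompressible_limit_raises(self):
        with pytest.raises(ZeroDivisionError):
            lame_from_young_poisson(100.0, 0.5)

    def test_round_trip_through_params(self):
        p = MaterialParams.from_young_poisson(250.0, 0.3)
        assert p.young == pytest.approx(250.0)
        assert p.poisson == pytest.approx(0.3)


class TestKinematics:
    ref_grads = np.array(
        [[-1.0, -1, -1], [1, 0, 0], [0, 1, 0], [0, 0, 1]]
    )
    ref = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])

    def test_identity_map(self):
        k = kinematics_at_point(self.ref, self.ref, self.ref_grads, 0.9)
        assert np.allclose(k.F, np.eye(3))
        assert k.J == pytest.approx(1.0)
        assert k.phi == pytest.approx(0.9)

    def test_uniform_dilation_porosity(self):
        k = kinematics_at_point(self.ref, 2 * self.ref, self.ref_grads, 0.9)
        assert k.J == pytest.approx(8.0)
        assert k.phi == pytest.approx(1.0 - 0.1 / 8.0)

    def test_random_affine_map_recovers_matrix(self, rng):
        A = np.eye(3) + 0.2 * rng.standard_normal((3, 3))
        cur = self.ref @ A.T + rng.standard_normal(3)
        k = kinematics_at_point(self.ref, cur, self.ref_grads, 0.9)
        assert np.allclose(k.F, A, atol=1e-12)
        assert np.allclose(k.C, A.T @ A, atol=1e-12)

    def test_collapse_past_barrier_raises(self):
        with pytest.raises(BarrierViolationError):
            kinematics_at_point(self.ref, 0.3 * self.ref, self.ref_grads, 0.9)


class TestStrainEnergy:
    def test_reference_state_zero_when_fully_fluid(self):
        p = MaterialParams(mu=10.0, lam=5.0, phi0=1.0)
        assert strain_energy(np.eye(3), p) == pytest.approx(0.0, abs=1e-14)

    def test_reference_state_with_barrier(self):
        p = MaterialParams(mu=10.0, lam=5.0, phi0=0.9)
        expected = -(p.mu + 0.5 * p.lam) * np.log(0.9)
        assert strain_energy(np.eye(3), p) == pytest.approx(expected)

    def test_log_barrier_blows_up(self):
        p = MaterialParams(mu=10.0, lam=5.0, phi0=0.9)
        j_vals = [0.2, 0.12, 0.102]
        energies = [strain_energy(j ** (2 / 3) * np.eye(3), p) for j in j_vals]
        assert energies[0] < energies[1] < energies[2]
        with pytest.raises(BarrierViolationError):
            strain_energy(0.05 ** (2 / 3) * np.eye(3), p)


class TestEffectiveStress:
    def test_symmetry(self, rng, soft_params):
        for _ in range(20):
            F = random_admissible_F(rng)
            s = effective_stress(F, soft_params)
            assert np.allclose(s, s.T, atol=1e-12 * abs(s).max())

    def test_reference_residual_stress(self, soft_params):
        s = effective_stress(np.eye(3), soft_params)
        p = soft_params
        expected = (p.mu + 0.5 * p.lam) * (1.0 - 1.0 / p.phi0)
        assert np.allclose(s, expected * np.eye(3), rtol=1e-12)

    def test_stress_energy_consistency(self, rng, soft_params):
        """<2 dW/dC, dC>/2 against central finite differences of W."""
        h = 1e-6
        worst = 0.0
        for _ in range(100):
            F = random_admissible_F(rng)
            C = F.T @ F
            S = second_piola_stress(C, soft_params)
            dC = rng.standard_normal((3, 3))
            dC = dC + dC.T
            dW = (strain_energy(C + h * dC, soft_params)
                  - strain_energy(C - h * dC, soft_params)) / (2 * h)
            worst = max(worst, abs(dW - 0.5 * np.einsum("ij,ij", S, dC)) / abs(dW))
        assert worst < 1e-6

    def test_frame_invariance(self, rng, soft_params):
        for _ in range(20):
            F = random_admissible_F(rng)
            Q = special_ortho_group.rvs(3, random_state=rng)
            w1 = strain_energy(F.T @ F, soft_params)
            w2 = strain_energy((Q @ F).T @ (Q @ F), soft_params)
            assert w2 == pytest.approx(w1, rel=1e-12, abs=1e-12)


class TestSpatialTangent:
    def test_minor_symmetries(self, rng, soft_params):
        F = random_admissible_F(rng)
        T = spatial_tangent(F, soft_params)
        assert np.allclose(T, T.transpose(1, 0, 2, 3), atol=1e-10)
        assert np.allclose(T, T.transpose(0, 1, 3, 2), atol=1e-10)

    def test_reduces_to_isotropic_elasticity_without_barrier(self):
        p = MaterialParams(mu=7.0, lam=3.0, phi0=1.0)
        T = spatial_tangent(np.eye(3), p)
        I = np.eye(3)
        expected = (p.lam * np.einsum("ij,kl->ijkl", I, I)
                    + p.mu * (np.einsum("ik,jl->ijkl", I, I)
                              + np.einsum("il,jk->ijkl", I, I)))
        assert np.allclose(T, expected, atol=1e-12)

    def test_matches_fd_of_stress_pairing(self):
        """Linearized internal force vs FD of the element stress residual."""
        from porofem.selfcheck import tangent_pairing_fd_error

        assert tangent_pairing_fd_error() < 1e-5


class TestPermeability:
    def test_identity_and_dilation(self, soft_params):
        k0 = soft_params.k0
        assert np.allclose(permeability_current(np.eye(3), soft_params), k0 * np.eye(3))
        k = permeability_current(2 * np.eye(3), soft_params)
        assert np.allclose(k, 0.5 * k0 * np.eye(3))

    def test_positive_definite_for_random_F(self, rng, soft_params):
        for _ in range(20):
            F = random_admissible_F(rng)
            ev = np.linalg.eigvalsh(permeability_current(F, soft_params))
            assert ev.min() > 0.0

    def test_user_supplied_reference_law(self):
        aniso = np.diag([1.0, 2.0, 3.0])
        p = MaterialParams(mu=1.0, lam=1.0, k0_fn=lambda C: aniso)
        assert np.allclose(permeability_current(np.eye(3), p), aniso)

    def test_invalid_k0_raises(self, soft_params):
        with pytest.raises(ValueError):
            permeability_current(np.eye(3), soft_params, k0=-1.0)


class TestMixtureDensity:
    def test_limits_and_uniform(self):
        p = MaterialParams(mu=1.0, lam=1.0, rho_s=2000.0, rho_f=1000.0)
        assert mixture_density(0.0, p) == pytest.approx(2000.0)
        assert mixture_density(1.0 - 1e-12, p) == pytest.approx(1000.0, rel=1e-9)
        q = MaterialParams(mu=1.0, lam=1.0, rho_s=1200.0, rho_f=1200.0)
        assert mixture_density(0.37, q) == pytest.approx(1200.0)

    def test_out_of_range_raises(self):
        p = MaterialParams(mu=1.0, lam=1.0)
        with pytest.raises(ValueError):
            mixture_density(1.5, p)


class TestPointwiseProperties:
    """Property-based checks over sampled deformation states."""

    comps = st.floats(-0.25, 0.25, allow_nan=False)

    @staticmethod
    def _F_from(draw_vals):
        return np.eye(3) + np.asarray(draw_vals, dtype=float).reshape(3, 3)

    @given(st.lists(comps, min_size=9, max_size=9))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_stress_symmetric_and_permeability_spd(self, vals):
        p = MaterialParams.from_young_poisson(1000.0, 0.15, phi0=0.9, k0=1e-3)
        F = self._F_from(vals)
        if np.linalg.det(F) <= 1.0 - p.phi0 + 0.05:
            return  # outside the admissible set the model rightly refuses
        s = effective_stress(F, p)
        assert np.abs(s - s.T).max() <= 1e-11 * max(np.abs(s).max(), 1.0)
        ev = np.linalg.eigvalsh(permeability_current(F, p))
        assert ev.min() > 0.0

    @given(st.lists(comps, min_size=9, max_size=9))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_energy_depends_on_F_only_through_C(self, vals):
        p = MaterialParams.from_young_poisson(1000.0, 0.15, phi0=0.9)
        F = self._F_from(vals)
        if np.linalg.det(F) <= 1.0 - p.phi0 + 0.05:
            return
        # QR gives an exact rotation factor; W(QF) must equal W(F)
        Q, _ = np.linalg.qr(np.eye(3) + 0.1 * np.arange(9.0).reshape(3, 3))
        w1 = strain_energy(F.T @ F, p)
        w2 = strain_energy((Q @ F).T @ (Q @ F), p)
        assert w2 == pytest.approx(w1, rel=1e-10, abs=1e-10)


class TestEquilibriumState:
    def test_equilibrium_pressure_balances_reference_stress(self, soft_params):
        p_eq = equilibrium_pressure(soft_params)
        total = effective_stress(np.eye(3), soft_params) - p_eq * np.eye(3)
        assert np.allclose(total, 0.0, atol=1e-12)

    def test_effective_moduli_match_fd_of_total_stress(self, soft_params):
        """The shifted law's small-strain moduli, probed by uniaxial and
        shear finite differences of the equilibrated total stress."""
        p_eq = equilibrium_pressure(soft_params)
        mu_e, lam_e = effective_lame_about_equilibrium(soft_params)
        e = 1e-7
        F = np.diag([1 + e, 1, 1])
        sig = effective_stress(F, soft_params) - p_eq * np.eye(3)
        assert sig[0, 0] / e == pytest.approx(lam_e + 2 * mu_e, rel=1e-5)
        assert sig[1, 1] / e == pytest.approx(lam_e, rel=1e-5)
        G = np.eye(3)
        G[0, 1] = e
        sig = effective_stress(G, soft_params) - p_eq * np.eye(3)
        assert sig[0, 1] / e == pytest.approx(mu_e, rel=1e-5)

    def test_no_correction_without_barrier(self):
        p = MaterialParams(mu=3.0, lam=2.0, phi0=1.0)
        assert equilibrium_pressure(p) == pytest.approx(0.0)
        mu_e, lam_e = effective_lame_about_equilibrium(p)
        assert (mu_e, lam_e) == (pytest.approx(3.0), pytest.approx(2.0))
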