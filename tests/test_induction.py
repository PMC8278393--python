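"""Induced-dipole response: assembly, solver, energy, derivatives."""

import numpy as np
import pytest
from conftest import central_fd_gradient, central_fd_jacobian
from scipy.optimize import minimize

from pespectra.induction import (
    ConditioningError,
    assemble_response_matrix,
    induction_energy,
    induction_report,
    nuclear_potential_derivatives,
    solve_induced_moments,
    total_site_field,
)
from pespectra.multiindex import MultiIndex
from pespectra.system import CoreAtom, EnvironmentSite


def _polarizable_site(position, alpha=8.0, fragment_id=0, **kw):
    return EnvironmentSite(position=position, fragment_id=fragment_id,
                           polarizability=np.eye(3) * alpha, **kw)


def _proton(position, charge=1.0):
    return CoreAtom(position=np.asarray(position, float), charge=charge,
                    mass=1.0, element="H")


class TestAssembly:
    def test_single_isotropic_site_diagonal(self):
        r = assemble_response_matrix([_polarizable_site([0, 0, 0], alpha=8.0)])
        np.testing.assert_allclose(r.matrix, np.eye(3) / 8.0)

    def test_same_fragment_pairs_are_excluded(self):
        sites = [
            _polarizable_site([0, 0, 0], fragment_id=0),
            _polarizable_site([0, 0, 3], fragment_id=0),
        ]
        r = assemble_response_matrix(sites)
        assert np.all(r.matrix[:3, 3:] == 0.0)

    def test_dipole_dipole_coupling_block_value(self):
        sites = [
            _polarizable_site([0, 0, 0], fragment_id=0),
            _polarizable_site([0, 0, 4], fragment_id=1),
        ]
        r = assemble_response_matrix(sites)
        # off-diagonal block is -T2; T2_zz = 2/r^3 = 2/64 on the axis
        assert r.matrix[2, 5] == pytest.approx(-2.0 / 64.0)
        assert r.matrix[0, 3] == pytest.approx(1.0 / 64.0)

    def test_singular_polarizability_names_the_site(self):
        bad = EnvironmentSite(position=[0, 0, 0], fragment_id=0, element="Xx",
                              polarizability=np.diag([1.0, 1.0, 0.0]))
        # a singular (but PSD) polarizability is caught at inversion
        with pytest.raises(ConditioningError, match="site 0"):
            assemble_response_matrix([bad])

    def test_symmetric_and_positive_definite_on_fixture(self, small_system):
        _, sites = small_system
        r = assemble_response_matrix(sites)
        np.testing.assert_allclose(r.matrix, r.matrix.T, atol=1e-14)
        assert np.linalg.eigvalsh(r.matrix).min() > 0


class TestFields:
    def test_single_charge_field_magnitude(self):
        sites = [_polarizable_site([0, 0, 0])]
        f = total_site_field(sites, [_proton([0, 0, 3])])
        # field at the site points away from the positive charge: -z here
        np.testing.assert_allclose(f.nuclear, [0, 0, -1.0 / 9.0], atol=1e-14)

    def test_own_fragment_multipoles_do_not_contribute(self):
        dipole_site = EnvironmentSite(position=[0, 0, 2], fragment_id=0,
                                      multipoles={1: [0, 0, 0.5]})
        pol = _polarizable_site([0, 0, 0], fragment_id=0)
        f = total_site_field([pol, dipole_site], [])
        np.testing.assert_allclose(f.total, 0.0, atol=1e-15)

    def test_foreign_fragment_multipoles_do_contribute(self):
        dipole_site = EnvironmentSite(position=[0, 0, 2], fragment_id=1,
                                      multipoles={1: [0, 0, 0.5]})
        pol = _polarizable_site([0, 0, 0], fragment_id=0)
        f = total_site_field([pol, dipole_site], [])
        assert np.linalg.norm(f.multipole) > 0

    def test_nuclear_field_is_minus_gradient_of_potential(self, rng, small_system):
        core, sites = small_system
        f = total_site_field(sites, core)
        from pespectra.induction import polarizable_indices
        idx = polarizable_indices(sites)
        h = 1e-5
        for a_local, si in enumerate(idx[:4]):
            pos = sites[si].position

            def vnuc(p):
                return sum(
                    at.charge / np.linalg.norm(p - at.position) for at in core
                )

            for comp in range(3):
                e = np.zeros(3)
                e[comp] = h
                fd = -(vnuc(pos + e) - vnuc(pos - e)) / (2 * h)
                assert f.nuclear[3 * a_local + comp] == pytest.approx(fd, rel=1e-7)


class TestSolver:
    def test_single_site_solution_is_alpha_times_field(self):
        sites = [_polarizable_site([0, 0, 0], alpha=8.0)]
        r = assemble_response_matrix(sites)
        f = total_site_field(sites, [_proton([0, 0, 3])])
        mu = solve_induced_moments(r, f)
        np.testing.assert_allclose(mu.moments, 8.0 * f.total, atol=1e-12)

    def test_zero_field_gives_zero_moments(self):
        sites = [_polarizable_site([0, 0, 0])]
        r = assemble_response_matrix(sites)
        mu = solve_induced_moments(r, np.zeros(3))
        assert np.all(mu.moments == 0.0)

    def test_iterative_matches_dense_solve(self, small_system):
        core, sites = small_system
        r = assemble_response_matrix(sites)
        f = total_site_field(sites, core)
        mu = solve_induced_moments(r, f, tol=1e-10)
        dense = np.linalg.solve(r.matrix, f.total)
        assert np.linalg.norm(mu.moments - dense) / np.linalg.norm(dense) < 1e-9

    def test_solver_is_deterministic(self, small_system):
        core, sites = small_system
        r = assemble_response_matrix(sites)
        f = total_site_field(sites, core)
        m1 = solve_induced_moments(r, f)
        m2 = solve_induced_moments(r, f)
        assert np.array_equal(m1.moments, m2.moments)


class TestEnergy:
    def test_single_site_closed_form(self):
        alpha = 5.0
        sites = [_polarizable_site([0, 0, 0], alpha=alpha)]
        core = [_proton([0, 0, 3])]
        rep = induction_report(sites, core)
        e_field = 1.0 / 9.0
        assert rep.energy == pytest.approx(-0.5 * alpha * e_field**2, rel=1e-12)

    def test_quadratic_in_core_charges(self):
        sites = [_polarizable_site([0, 0, 0])]
        e1 = induction_report(sites, [_proton([0, 0, 3], charge=1.0)]).energy
        e2 = induction_report(sites, [_proton([0, 0, 3], charge=2.0)]).energy
        assert e2 == pytest.approx(4.0 * e1, rel=1e-12)
        # gradient shares the bilinear-in-Z structure
        g1 = induction_report(sites, [_proton([0, 0, 3], charge=1.0)]).gradient
        g2 = induction_report(sites, [_proton([0, 0, 3], charge=2.0)]).gradient
        np.testing.assert_allclose(g2, 4.0 * g1, rtol=1e-10)

    def test_always_stabilizing_on_fixtures(self, small_system):
        core, sites = small_system
        assert induction_report(sites, core).energy <= 0.0

    def test_matches_brute_force_minimization(self):
        """E_ind equals the minimum of the explicit polarization functional."""
        sites = [
            _polarizable_site([0, 0, 0], alpha=4.0, fragment_id=0),
            _polarizable_site([0, 0, 5], alpha=6.0, fragment_id=1),
        ]
        core = [_proton([3, 0, 2.5])]
        r = assemble_response_matrix(sites)
        f = total_site_field(sites, core)

        def functional(mu):
            return 0.5 * mu @ r.matrix @ mu - mu @ f.total

        res = minimize(functional, np.zeros(6), method="BFGS", tol=1e-14)
        e_ind = induction_report(sites, core).energy
        assert e_ind == pytest.approx(res.fun, rel=1e-8)
        # perturbing mu away from the solution raises the functional
        mu_star = solve_induced_moments(r, f).moments
        assert functional(mu_star + 1e-3) >= functional(mu_star)


class TestPotentialDerivatives:
    def test_first_derivative_matches_finite_differences(self, small_system):
        core, sites = small_system
        site_pos = sites[0].position
        for alpha in (MultiIndex(0, 0, 0), MultiIndex(1, 0, 0), MultiIndex(0, 1, 1)):
            d = nuclear_potential_derivatives(core, site_pos, alpha, 1)

            def vnuc_alpha():
                from pespectra.multiindex import tensor_table
                return sum(
                    at.charge
                    * tensor_table(at.position, site_pos, alpha.order)[alpha.as_tuple()]
                    for at in core
                )

            fd = central_fd_gradient(vnuc_alpha, core)
            assert np.abs(d - fd).max() < 1e-8

    def test_second_derivative_symmetric_in_g1_g2(self, small_system):
        core, sites = small_system
        d2 = nuclear_potential_derivatives(core, sites[0].position,
                                           MultiIndex(0, 0, 1), 2)
        np.testing.assert_allclose(d2, d2.T, atol=1e-13)

    def test_decay_with_distance(self):
        core = [_proton([0, 0, 0])]
        alpha = MultiIndex(0, 0, 1)
        vals = [
            np.abs(nuclear_potential_derivatives(core, np.array([0, 0, r]),
                                                 alpha, 1)).max()
            for r in (5.0, 10.0, 20.0)
        ]
        # |alpha| = 1, d = 1: decay like r^-3
        assert vals[1] == pytest.approx(vals[0] / 8, rel=1e-6)
        assert vals[2] == pytest.approx(vals[1] / 8, rel=1e-6)


class TestInductionDerivatives:
    def test_gradient_matches_finite_differences(self, small_system):
        core, sites = small_system
        rep = induction_report(sites, core, derivatives=1)
        fd = central_fd_gradient(
            lambda: induction_report(sites, core, derivatives=0).energy, core
        )
        assert np.abs(rep.gradient - fd).max() < 1e-6

    def test_gradient_zero_without_polarizable_sites(self, small_system):
        core, _ = small_system
        bare = [EnvironmentSite(position=[0, 0, 9], fragment_id=0,
                                multipoles={0: [0.4]})]
        rep = induction_report(bare, core)
        assert rep.energy == 0.0
        assert np.all(rep.gradient == 0.0)

    def test_hessian_matches_finite_differences(self, small_system):
        core, sites = small_system
        rep = induction_report(sites, core, derivatives=2)
        fd = central_fd_jacobian(
            lambda: induction_report(sites, core, derivatives=1).gradient, core
        )
        assert np.abs(rep.hessian - fd).max() < 1e-6
        np.testing.assert_allclose(rep.hessian, rep.hessian.T, atol=1e-12)

    def test_response_contraction_is_negative_semidefinite(self, small_system):
        """−(∂F/∂g)ᵀ A⁻¹ (∂F/∂g) as a quadratic form can only stabilize."""
        from pespectra.induction import _field_first_derivative
        core, sites = small_system
        r = assemble_response_matrix(sites)
        dF = _field_first_derivative(r, sites, core)
        m = -dF.T @ np.linalg.solve(r.matrix, dF)
        assert np.linalg.eigvalsh(0.5 * (m + m.T)).max() <= 1e-10

    def test_single_site_hessian_closed_form(self):
        """One atom + one isotropic site: E_ind = −½αZ²/r⁴ has an analytic Hessian."""
        alpha, z, r = 3.0, 1.0, 4.0
        sites = [_polarizable_site([0, 0, 0], alpha=alpha)]
        core = [_proton([0, 0, r], charge=z)]
        rep = induction_report(sites, core)
        # E(r) = -alpha z^2 / (2 r^4): E'' along z = -10 alpha z^2 / r^6;
        # transverse curvature = E'(r)/r = 2 alpha z^2 / r^6
        e_zz = -10.0 * alpha * z**2 / r**6
        e_xx = 2.0 * alpha * z**2 / r**6
        np.testing.assert_allclose(rep.hessian, np.diag([e_xx, e_xx, e_zz]),
                                   atol=1e-12)


def test_fragment_relabeling_leaves_energies_invariant(small_system):
    core, sites = small_system
    e0 = induction_report(sites, core).energy
    relabeled = []
    n_frag = max(s.fragment_id for s in sites) + 1
    from dataclasses import replace
    for s in sites:
        relabeled.append(replace(s, fragment_id=(s.fragment_id + 3) % n_frag + 100))
    e1 = induction_report(relabeled, core).energy
    assert e1 == pytest.approx(e0, rel=1e-12)
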