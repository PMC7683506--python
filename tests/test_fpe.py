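"""Fokker-Planck approximations, correction coefficients, moment closures."""

import numpy as np
import pytest

from crnflow.fpe import (DiracMixture, GridDensity1D, cle_diffusion,
                         cle_equilibrium_linear, correction_coefficients,
                         default_cmax, e1_correction, equilibrium_densities,
                         liouville_energy_identity_residual,
                         liouville_transport, moment_closures, solve_fpe_1d,
                         stirling_partition_Z, uniform_grid)
from crnflow.rre import logmean, onsager_matrix


@pytest.fixture(scope="module")
def grid20(linear_db):
    _, db = linear_db
    V = 20.0
    edges = uniform_grid(default_cmax(db, V), 400)
    return db, V, edges


class TestEquilibria:
    def test_normalisation_and_zero_entropy(self, grid20):
        db, V, edges = grid20
        wt, wv, energy = equilibrium_densities(db, V, edges)
        widths = np.diff(edges)
        assert wt @ widths == pytest.approx(1.0, abs=1e-12)
        assert wv @ widths == pytest.approx(1.0, abs=1e-12)
        assert energy(wv, refined=True) == pytest.approx(0.0, abs=1e-12)
        assert energy(wt, refined=False) == pytest.approx(0.0, abs=1e-12)

    def test_laplace_limit_of_partition(self):
        # Z(v) sqrt(v / 2 pi) -> 1
        ratios = [stirling_partition_Z(v) * np.sqrt(v / (2 * np.pi))
                  for v in (1e2, 1e3, 1e4)]
        gaps = [abs(r - 1.0) for r in ratios]
        assert gaps[0] < 0.01 and gaps[1] < gaps[0] and gaps[2] < gaps[1]

    def test_entropy_expansion(self, grid20):
        # E_V(rho) = E(rho) + (1/V) int (rho log rho + E^V_1 rho)
        db, V, edges = grid20
        _, wv, energy = equilibrium_densities(db, V, edges)
        centers = 0.5 * (edges[:-1] + edges[1:])
        widths = np.diff(edges)
        rho = np.exp(-0.5 * ((centers - 1.4) / 0.3) ** 2)
        rho /= rho @ widths
        lhs = energy(rho, refined=True)
        from crnflow.rre import boltzmann
        E_vals = db.c_star[0] * boltzmann(centers / db.c_star[0])
        e1 = np.array([e1_correction(db, V, [c]) for c in centers])
        rhs = float((rho * E_vals) @ widths) + float(
            (rho * np.log(rho) + e1 * rho) @ widths) / V
        assert lhs == pytest.approx(rhs, abs=1e-8)


class TestCLEDiffusion:
    def test_linear_closed_form(self, linear_db):
        _, db = linear_db
        for c in (0.5, 1.0, 3.0):
            assert cle_diffusion(db, [c])[0, 0] == pytest.approx((1 + c) / 2,
                                                                 rel=1e-13)

    def test_matches_onsager_at_equilibrium(self, random_nets):
        for _, db, _ in random_nets[:8]:
            Kc = cle_diffusion(db, db.c_star)
            K = onsager_matrix(db, db.c_star)
            assert np.allclose(Kc, K, rtol=1e-12, atol=1e-14)

    def test_dominates_onsager(self, random_nets):
        for _, db, c in random_nets:
            diff = cle_diffusion(db, c) - onsager_matrix(db, c)
            assert np.min(np.linalg.eigvalsh(diff)) >= -1e-10

    def test_log_vs_arithmetic_mean_bound(self):
        # max relative deviation of Lambda(1,c) from (1+c)/2 on [1/3, 3]
        c = np.linspace(1 / 3, 3.0, 10_000)
        lam = logmean(np.ones_like(c), c)
        arith = (1 + c) / 2
        assert np.max(np.abs(lam - arith) / arith) <= 0.10
        # the other relative-error base satisfies the bound as well
        assert np.max(np.abs(lam - arith) / lam) <= 0.10


class TestSolver:
    def test_simple_variant_keeps_equilibrium(self, grid20):
        db, V, edges = grid20
        wt, wv, _ = equilibrium_densities(db, V, edges)
        traj = solve_fpe_1d(db, "simple", GridDensity1D(edges, wt, V),
                            [0.0, 0.2], dt=0.01)
        assert np.max(np.abs(traj[-1].rho - wt)) < 1e-12
        traj = solve_fpe_1d(db, "simple_av", GridDensity1D(edges, wv, V),
                            [0.0, 0.2], dt=0.01)
        assert np.max(np.abs(traj[-1].rho - wv)) < 1e-12

    def test_mass_conserved(self, grid20):
        db, V, edges = grid20
        centers = 0.5 * (edges[:-1] + edges[1:])
        rho0 = np.exp(-0.5 * ((centers - 2.0) / 0.3) ** 2)
        rho0 /= rho0 @ np.diff(edges)
        for variant in ("simple", "cle"):
            traj = solve_fpe_1d(db, variant, GridDensity1D(edges, rho0, V),
                                [0.0, 1.0], dt=0.01)
            assert traj[-1].mass() == pytest.approx(1.0, abs=1e-12)

    def test_entropy_decays_along_simple_flow(self, grid20):
        db, V, edges = grid20
        wt, _, energy = equilibrium_densities(db, V, edges)
        centers = 0.5 * (edges[:-1] + edges[1:])
        rho0 = np.exp(-0.5 * ((centers - 1.8) / 0.2) ** 2)
        rho0 /= rho0 @ np.diff(edges)
        traj = solve_fpe_1d(db, "simple", GridDensity1D(edges, rho0, V),
                            np.linspace(0, 2, 11), dt=0.01)
        vals = [energy(r, refined=False) for r in traj]
        assert all(v2 <= v1 + 1e-12 for v1, v2 in zip(vals, vals[1:]))

    def test_cle_converges_to_printed_equilibrium(self, grid20):
        db, V, edges = grid20
        centers = 0.5 * (edges[:-1] + edges[1:])
        rho0 = np.exp(-0.5 * ((centers - 2.0) / np.sqrt(2.0 / V)) ** 2)
        rho0 /= rho0 @ np.diff(edges)
        traj = solve_fpe_1d(db, "cle", GridDensity1D(edges, rho0, V),
                            [0.0, 20.0], dt=0.01)
        rho_eq = cle_equilibrium_linear(1.0, 1.0, V, edges)
        l1 = np.sum(np.abs(traj[-1].rho - rho_eq) * np.diff(edges))
        assert l1 <= 1e-3


class TestCorrections:
    def test_b1_closed_form(self, linear_db):
        _, db = linear_db
        cc = correction_coefficients(db, 0, [2.0], V=10.0)
        assert cc.b_hat1 == pytest.approx(1.5, rel=1e-14)     # (1 + 2)/2

    def test_b1_equals_lambda_plus_upsilon1_gradE(self, linear_db):
        # b^_1 = Lambda_0 + Upsilon_1 (gamma . DE) is the printed cancellation
        _, db = linear_db
        for c in (0.5, 1.3, 2.7):
            cc = correction_coefficients(db, 0, [c], V=10.0)
            gradE = -np.log(c)            # gamma = -1 for 0 <-> X
            assert cc.Lambda0 + cc.Upsilon1 * gradE == pytest.approx(
                cc.b_hat1, rel=1e-10)

    def test_upsilon1_vanishes_at_balance(self, linear_db):
        _, db = linear_db
        vals = [abs(correction_coefficients(db, 0, [1.0 + eps], V=10.0).Upsilon1)
                for eps in (0.1, 0.01, 1e-4, 1e-9)]
        assert all(v2 < v1 for v1, v2 in zip(vals, vals[1:]))
        assert vals[-1] < 1e-9

    def test_parabolicity(self, linear_db):
        _, db = linear_db
        q = np.linspace(-1e3, 1e3, 4001)
        for c in (0.4, 1.0, 2.5):
            cc = correction_coefficients(db, 0, [c], V=10.0)
            assert np.min(cc.parabolicity(q)) >= -1e-12

    def test_theta_ordering_enforced(self, linear_db):
        _, db = linear_db
        with pytest.raises(ValueError):
            correction_coefficients(db, 0, [1.0], V=10.0, theta1=0.8, theta2=0.4)


class TestMomentClosures:
    def test_cme_moments_follow_rre(self):
        V = 20.0
        t = np.linspace(0, 3, 31)
        mom = moment_closures(1.0, 1.0, V, c0=2.0, t_grid=t)
        c_exact = 1 + np.exp(-t)
        assert np.max(np.abs(mom["e_hat"] - c_exact)) < 1e-9
        assert np.max(np.abs(mom["v_hat"] - c_exact / V)) < 1e-9

    def test_cle_moments_coincide_with_cme_moments(self):
        V = 20.0
        t = np.linspace(0, 3, 31)
        mom = moment_closures(1.0, 1.0, V, c0=2.0, t_grid=t)
        assert np.max(np.abs(mom["a"] - mom["e_hat"])) < 1e-9
        assert np.max(np.abs(mom["A"] / V - mom["v_hat"])) < 1e-9

    def test_fp_variance_fixed_point(self):
        # A_V' = -2 A_V + 2 Lambda(1, a_V): the stationary value is
        # Lambda(1, a_V*), approaching Lambda(1,1) = 1 in the a_V -> 1
        # (large-V) limit; at finite V the mean carries an O(1/V) bias.
        t = np.linspace(0, 30, 61)
        for V, tol in ((20.0, 0.05), (2000.0, 5e-4)):
            mom = moment_closures(1.0, 1.0, V, c0=2.0, t_grid=t)
            assert mom["A_V"][-1] == pytest.approx(
                logmean(1.0, mom["a_V"][-1]), abs=1e-6)
            assert mom["A_V"][-1] == pytest.approx(1.0, abs=tol)
            assert mom["a_V"][-1] == pytest.approx(1.0, abs=tol)


class TestLiouville:
    def test_equilibrium_atom_is_fixed(self, linear_db):
        net, db = linear_db
        mix = DiracMixture([1.0], [db.c_star])
        snaps, energies = liouville_transport(net, mix, [0, 1, 2], db=db)
        assert np.max(np.abs(snaps[-1].locations - db.c_star)) < 1e-10
        assert np.max(np.abs(energies)) < 1e-12

    def test_single_atom_follows_explicit_solution(self, linear_db):
        net, db = linear_db
        t = np.linspace(0, 2, 9)
        snaps, _ = liouville_transport(net, DiracMixture([1.0], [[2.0]]), t)
        locs = np.array([s.locations[0, 0] for s in snaps])
        assert np.max(np.abs(locs - (1 + np.exp(-t)))) < 1e-8

    def test_weights_constant_under_transport(self, linear_db):
        net, db = linear_db
        mix = DiracMixture([0.5, 0.5], [[0.5], [2.5]])
        snaps, _ = liouville_transport(net, mix, np.linspace(0, 3, 7))
        for s in snaps:
            assert np.array_equal(s.weights, mix.weights)

    def test_energy_dissipation_identity(self, linear_db):
        net, db = linear_db
        t = np.linspace(0, 2, 201)
        mix = DiracMixture([0.3, 0.7], [[0.4], [2.2]])
        snaps, _ = liouville_transport(net, mix, t, db=db)
        res = liouville_energy_identity_residual(db, snaps, t)
        assert res < 1e-4          # trapezoid-quadrature limited

    def test_energy_identity_on_random_networks(self, random_nets):
        t = np.linspace(0, 1, 101)
        for net, db, c in random_nets[:4]:
            mix = DiracMixture([1.0], [c])
            snaps, energies = liouville_transport(net, mix, t, db=db)
            res = liouville_energy_identity_residual(db, snaps, t)
            assert res < 1e-3 * max(1.0, energies[0])
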