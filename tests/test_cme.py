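"""Chemical master equation: generator, equilibrium, dissipation, propagation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crnflow.cme import (LatticeDistribution, TruncatedLattice, build_generator,
                         cme_dissipation_force, cme_dual_dissipation,
                         cme_entropy, cme_entropy_gradient,
                         energy_dissipation_residual, integrate_cme,
                         lattice_moments, poisson_distribution,
                         poisson_equilibrium, poisson_weights_fn,
                         rate_coefficient, stationarity_residual,
                         verify_detailed_balance)
from crnflow.network import (ReactionNetwork, example_two_pair_network,
                             parse_reaction_text, random_db_network,
                             solve_detailed_balance)


class TestRateCoefficient:
    @pytest.mark.parametrize("alpha,n,V,expected", [
        ([1], [4], 3.0, 5.0),            # V (n+1)!/(V n!) = n+1
        ([0], [7], 2.5, 2.5),            # empty product: V
        ([2], [3], 2.0, (3 + 2) * (3 + 1) / 2.0),
        ([1, 1], [2, 3], 4.0, 4.0 * 3 * 4 / 16),
    ])
    def test_values(self, alpha, n, V, expected):
        assert rate_coefficient(alpha, n, V) == pytest.approx(expected, rel=1e-14)

    def test_zero_outside_lattice(self):
        assert rate_coefficient([1], [-1], 1.0) == 0.0
        assert rate_coefficient([0, 1], [2, -3], 1.0) == 0.0

    def test_large_counts_no_overflow(self):
        val = rate_coefficient([2], [500], 10.0)
        assert val == pytest.approx(501 * 502 / 10.0, rel=1e-12)


class TestGenerator:
    def test_linear_stencil(self, linear_db):
        # du_n/dt = V a u_{n-1} - (V a + b n) u_n + b (n+1) u_{n+1}
        net, db = linear_db
        V = 4.0
        lat = TruncatedLattice(np.array([30]), V)
        B = build_generator(net, lat).toarray()
        n = 7
        assert B[n, n - 1] == pytest.approx(V)
        assert B[n, n] == pytest.approx(-(V + n))
        assert B[n, n + 1] == pytest.approx(n + 1)

    def test_two_pair_five_band_stencil(self):
        # a=2, b=1: du_n = V u_{n-2} + 4V u_{n-1}
        #   - (5V + 4n + n(n-1)/V) u_n + 4(n+1) u_{n+1} + (n+2)(n+1)/V u_{n+2}
        net = example_two_pair_network(2, 1)
        V = 3.0
        lat = TruncatedLattice(np.array([25]), V)
        B = build_generator(net, lat).toarray()
        n = 6
        assert B[n, n - 2] == pytest.approx(V)
        assert B[n, n - 1] == pytest.approx(4 * V)
        assert B[n, n] == pytest.approx(-(5 * V + 4 * n + n * (n - 1) / V))
        assert B[n, n + 1] == pytest.approx(4 * (n + 1))
        assert B[n, n + 2] == pytest.approx((n + 2) * (n + 1) / V)

    def test_column_sums_vanish(self, random_nets):
        for net, db, _ in random_nets[:5]:
            lat = TruncatedLattice.from_detailed_balance(db, 3.0, 1e-10)
            B = build_generator(net, lat)
            colsum = np.max(np.abs(np.asarray(B.sum(axis=0))))
            # zero up to a few ulps of the largest stored rate
            assert colsum <= 1e-12 * max(1.0, np.abs(B.data).max())


class TestEquilibrium:
    def test_untruncated_weight_at_zero(self, linear_db):
        _, db = linear_db
        lat = TruncatedLattice(np.array([60]), 1.0)
        w = poisson_equilibrium(db, lat)
        assert w.u[0] == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_stationarity_and_normalisation(self, two_pair_db):
        net, db = two_pair_db
        lat = TruncatedLattice.from_detailed_balance(db, 10.0)
        w = poisson_equilibrium(db, lat)
        assert w.u.sum() == pytest.approx(1.0, abs=1e-14)
        B = build_generator(net, lat)
        assert np.max(np.abs(B @ w.u)) < 1e-12

    def test_detailed_balance_identity_random(self, random_nets):
        for net, db, _ in random_nets[:8]:
            lat = TruncatedLattice.from_detailed_balance(db, 4.0)
            viol, field = verify_detailed_balance(net, db, lat)
            assert viol <= 1e-10
            assert field.shape == (lat.n_states,)


class TestPoissonResiduals:
    def test_two_pair_without_db_printed_polynomial(self):
        # a=7, b=1: inserting Poisson(2V) gives
        # e^{-2V}(2V)^{n-2}/n! (-12V^3 + 12nV^2 - 3n(n-1)V)
        net = example_two_pair_network(7, 1)
        for V in (1.0, 2.0):
            fn = poisson_weights_fn([2.0], V)
            for n in (1, 2, 5, 9):
                res = stationarity_residual(net, np.array([[n]]), V, fn)[0]
                import math
                pred = (np.exp(-2 * V) * (2 * V) ** (n - 2) / math.factorial(n)
                        * (-12 * V ** 3 + 12 * n * V ** 2 - 3 * n * (n - 1) * V))
                assert res == pytest.approx(pred, rel=1e-10, abs=1e-14)

    def test_value_quoted_at_V1_n2(self):
        net = example_two_pair_network(7, 1)
        res = stationarity_residual(net, np.array([[2]]), 1.0,
                                    poisson_weights_fn([2.0], 1.0))[0]
        assert res == pytest.approx(3 * np.exp(-2.0), rel=1e-12)

    def test_microscopically_irreversible_network(self):
        # 0 -> X at rate 2 and 2X -> 0 at rate 1: macroscopic equilibrium c*=1
        # but Poisson(V) is not stationary: residual
        # e^{-V} V^{n-1}/n! (2Vn - V^2 - n(n-1))
        import math
        net = ReactionNetwork(("X",), [[0], [2]], [[1], [0]], [2.0, 1.0],
                              [0.0, 0.0])
        V = 3.0
        fn = poisson_weights_fn([1.0], V)
        for n in (1, 3, 6):
            res = stationarity_residual(net, np.array([[n]]), V, fn)[0]
            pred = (np.exp(-V) * V ** (n - 1) / math.factorial(n)
                    * (2 * V * n - V ** 2 - n * (n - 1)))
            assert res == pytest.approx(pred, rel=1e-10)


@pytest.fixture(scope="module")
def setup(two_pair_db):
    net, db = two_pair_db
    V = 8.0
    lat = TruncatedLattice.from_detailed_balance(db, V)
    w = poisson_equilibrium(db, lat).u
    rng = np.random.default_rng(42)
    u = w * rng.uniform(0.5, 2.0, size=w.size)
    u /= u.sum()
    return net, db, lat, w, u


class TestEntropyDissipation:
    def test_entropy_zero_at_equilibrium(self, setup):
        net, db, lat, w, _ = setup
        assert cme_entropy(w, w, lat.V) == pytest.approx(0.0, abs=1e-15)

    def test_quadratic_dissipation_equals_G_form(self, setup):
        # Psi*_V(u, DE_V(u)) = (1/2V) sum nu_hat G(u_a/w_a, u_b/w_b)
        net, db, lat, w, u = setup
        mu = cme_entropy_gradient(u, w, lat.V)
        psi = cme_dual_dissipation(net, lat, u, mu, "quadratic")
        from crnflow.cme import _reaction_pairs
        total = 0.0
        for r in range(net.n_reactions):
            base, ia, ib = _reaction_pairs(net, lat, r)
            nu = net.k_bw[r] * rate_coefficient(net.beta[r], base, lat.V) * w[ib]
            a, b = u[ia] / w[ia], u[ib] / w[ib]
            total += np.sum(nu * (a - b) * (np.log(a) - np.log(b))) / (2 * lat.V)
        assert psi == pytest.approx(total, rel=1e-10)

    def test_cosh_force_equals_generator_action(self, setup):
        net, db, lat, w, u = setup
        B = build_generator(net, lat)
        force = cme_dissipation_force(net, lat, u, w)
        assert np.max(np.abs(force - B @ u)) <= 1e-8 * np.max(np.abs(B @ u))

    def test_energy_dissipation_balance(self, setup):
        net, db, lat, w, u = setup
        B = build_generator(net, lat)
        assert energy_dissipation_residual(net, lat, B, u, w) < 1e-10

    @given(st.floats(0.01, 100), st.floats(0.01, 100), st.floats(-5, 5))
    @settings(deadline=None, max_examples=200)
    def test_affine_lower_bound_of_G(self, a, b, omega):
        # G(a,b) >= g(omega) a + g(-omega) b with g(w) = 1 - e^{-w} + w
        G = (a - b) * (np.log(a) - np.log(b))
        g = lambda w: 1.0 - np.exp(-w) + w
        assert G >= g(omega) * a + g(-omega) * b - 1e-9 * (1 + abs(G))


class TestPropagation:
    def test_poisson_family_is_exactly_propagated(self, linear_db):
        net, db = linear_db
        V = 20.0
        lat = TruncatedLattice.from_detailed_balance(db, V, 1e-14,
                                                     extra_means=[2.5])
        B = build_generator(net, lat)
        u0 = poisson_distribution(lat, [2.0])
        traj = integrate_cme(B, u0, [0.0, 1.0])
        target = poisson_distribution(lat, [1 + np.exp(-1.0)])
        tv = 0.5 * np.sum(np.abs(traj[-1].u - target.u))
        assert tv <= 1e-6

    def test_moment_odes(self, linear_db):
        # de/dt = 1 - e, dv/dt = -2v + (1+e)/V along the CME flow
        net, db = linear_db
        V = 20.0
        lat = TruncatedLattice.from_detailed_balance(db, V, 1e-14,
                                                     extra_means=[2.5])
        B = build_generator(net, lat)
        u0 = poisson_distribution(lat, [2.0])
        ts = np.linspace(0.0, 1.0, 11)
        traj = integrate_cme(B, u0, ts)
        e = np.array([lattice_moments(d)[0][0] for d in traj])
        v = np.array([lattice_moments(d)[1][0] for d in traj])
        e_exact = 1 + np.exp(-ts)
        v_exact = e_exact / V
        assert np.max(np.abs(e - e_exact)) < 1e-6
        assert np.max(np.abs(v - v_exact)) < 1e-6

    def test_equilibrium_is_stationary(self, two_pair_db):
        net, db = two_pair_db
        lat = TruncatedLattice.from_detailed_balance(db, 10.0)
        B = build_generator(net, lat)
        w = poisson_equilibrium(db, lat)
        traj = integrate_cme(B, w, [0.0, 2.0])
        assert np.max(np.abs(traj[-1].u - w.u)) < 1e-12

    def test_mass_conservation(self, two_pair_db):
        net, db = two_pair_db
        lat = TruncatedLattice.from_detailed_balance(db, 10.0)
        B = build_generator(net, lat)
        u0 = poisson_distribution(lat, [1.7])
        traj = integrate_cme(B, u0, np.linspace(0, 1, 5))
        for d in traj:
            assert abs(d.u.sum() - 1.0) < 1e-10

    def test_invariant_sets_are_preserved(self):
        # X1 <-> X2 conserves n1 + n2: support stays on the initial diagonal
        net = parse_reaction_text("species: X1 X2\nX1 <-> X2 ; kf=1 kb=2\n")
        db = solve_detailed_balance(net)
        lat = TruncatedLattice(np.array([12, 12]), 4.0)
        B = build_generator(net, lat)
        u0 = np.zeros(lat.n_states)
        start = lat.flat_index(np.array([3, 5]))
        u0[start] = 1.0
        traj = integrate_cme(B, LatticeDistribution(u0, lat), [0.0, 1.5])
        total = lat.states.sum(axis=1)
        off_class = traj[-1].u[total != 8]
        assert np.max(np.abs(off_class)) < 1e-12

    def test_entropy_decay_along_flow(self, two_pair_db):
        net, db = two_pair_db
        V = 10.0
        lat = TruncatedLattice.from_detailed_balance(db, V, extra_means=[2.0])
        B = build_generator(net, lat)
        w = poisson_equilibrium(db, lat).u
        u0 = poisson_distribution(lat, [1.8])
        traj = integrate_cme(B, u0, np.linspace(0, 2, 15))
        ents = [cme_entropy(d.u, w, V) for d in traj]
        assert np.all(np.diff(ents) <= 1e-10)
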