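import numpy as np
import pytest
from scipy.integrate import solve_ivp

import nicheweb as nw
from conftest import make_pair_community


def isolated_species(rho=1.0):
    """A 1+1 community whose two species are linked but with Omega_m = 0,
    i.e. two independent logistic species."""
    comm = nw.BipartiteCommunity(
        centers_A=[0.2], centers_P=[0.8], width=0.1, theta=np.ones((1, 1)),
    )
    cp = nw.build_couplings(comm, nw.InteractionIntensities(0.0, 0.0))
    return comm, cp, nw.DynamicsParams(rho=rho)


class TestGrowthRate:
    def test_logistic_fixed_point(self):
        comm, cp, p = isolated_species()
        rate = nw.growth_rate(comm, cp, p, abundances=np.ones(2))
        np.testing.assert_allclose(rate, 0.0, atol=1e-14)

    def test_zero_abundance_is_absorbing(self, small_community, params):
        cp = nw.build_couplings(small_community, nw.InteractionIntensities(0.2, 0.1))
        n = small_community.abundances
        n[3] = 0.0
        rate = nw.growth_rate(small_community, cp, params, abundances=n)
        assert rate[3] == 0.0

    def test_mutualistic_pair_hand_value(self):
        # rho 1, gamma 0.1, h 0.1, both n = 1: rate = 1 - 1 + 0.1/1.1
        comm, cp = make_pair_community(gamma_strength=0.1)
        p = nw.DynamicsParams(handling=0.1)
        rate = nw.growth_rate(comm, cp, p, abundances=np.ones(2))
        np.testing.assert_allclose(rate, 0.1 / 1.1, rtol=1e-12)

    def test_holling_denominator_counts_only_partners(self, rng):
        """An unlinked partner must not enter the saturation term."""
        comm = nw.BipartiteCommunity(
            centers_A=[0.5], centers_P=[0.5, 0.5], width=0.1,
            theta=np.array([[1, 0]]),
        )
        cp = nw.build_couplings(comm, nw.InteractionIntensities(0.1, 0.0))
        p = nw.DynamicsParams(handling=0.5)
        rate = nw.growth_rate(comm, cp, p, abundances=np.array([1.0, 1.0, 5.0]))
        # denominator is 1 + 0.5 * 1 (only the linked plant), not 1 + 0.5 * 6
        assert rate[0] == pytest.approx(1.0 - 1.0 + 0.1 / 1.5, rel=1e-12)


class TestRelaxation:
    def test_single_logistic_equilibrium(self):
        comm, cp, p = isolated_species()
        eq = nw.relax_to_equilibrium(comm, cp, p)
        assert eq.converged
        np.testing.assert_allclose(eq.abundances, 1.0, atol=1e-8)

    def test_two_identical_competitors(self):
        omega_c = 0.3
        comm = nw.BipartiteCommunity(
            centers_A=[0.5, 0.5], centers_P=[0.1, 0.9], width=0.1,
            theta=np.eye(2),
        )
        cp = nw.build_couplings(comm, nw.InteractionIntensities(0.0, omega_c))
        eq = nw.relax_to_equilibrium(comm, cp, nw.DynamicsParams())
        np.testing.assert_allclose(
            eq.abundances[:2], 1.0 / (1.0 + omega_c), rtol=1e-7
        )

    def test_equilibrium_residual_definition(self, small_community, params):
        cp = nw.build_couplings(small_community, nw.InteractionIntensities(0.15, 0.05))
        eq = nw.relax_to_equilibrium(small_community, cp, params)
        assert eq.converged
        rate = nw.growth_rate(small_community, cp, params, eq.abundances)
        assert np.abs(rate).max() <= params.relax_tol

    def test_matches_stiff_ivp_oracle(self, rng, params):
        """Independent oracle: LSODA integration of the same vector field."""
        comm = nw.BipartiteCommunity.random(5, 5, 0.5, 0.1, rng)
        cp = nw.build_couplings(comm, nw.InteractionIntensities(0.15, 0.08))
        eq = nw.relax_to_equilibrium(comm, cp, params, update_community=False)

        sol = solve_ivp(
            lambda t, n: nw.growth_rate(comm, cp, params, np.maximum(n, 0)),
            [0, 5000], np.ones(comm.M), method="LSODA", rtol=1e-12, atol=1e-12,
        )
        np.testing.assert_allclose(eq.abundances, sol.y[:, -1], atol=1e-7)

    def test_decoupled_species_reach_rho(self, rng):
        comm = nw.BipartiteCommunity.random(4, 4, 0.5, 0.1, rng)
        cp = nw.build_couplings(comm, nw.InteractionIntensities(0.0, 0.0))
        rho = np.linspace(0.5, 2.0, comm.M)
        eq = nw.relax_to_equilibrium(comm, cp, nw.DynamicsParams(rho=rho))
        np.testing.assert_allclose(eq.abundances, rho, rtol=1e-7)

    def test_nonnegativity_preserved(self, rng, params):
        comm = nw.BipartiteCommunity.random(6, 6, 0.4, 0.1, rng)
        comm.abundances = rng.uniform(0, 2, comm.M)
        cp = nw.build_couplings(comm, nw.InteractionIntensities(0.25, 0.1))
        eq = nw.relax_to_equilibrium(comm, cp, params)
        assert (eq.abundances >= 0).all()


class TestJacobian:
    def test_single_logistic_closed_form(self):
        comm, cp, p = isolated_species()
        J = nw.jacobian(comm, cp, p, abundances=np.ones(2))
        # d/dn [n(1 - n)] at n* = 1 is -1, species independent
        np.testing.assert_allclose(J, -np.eye(2), atol=1e-14)

    def test_against_finite_differences(self, rng, params):
        """Central finite differences on random 5+5 communities."""
        for _ in range(5):
            comm = nw.BipartiteCommunity.random(5, 5, 0.5, 0.1, rng)
            cp = nw.build_couplings(comm, nw.InteractionIntensities(0.2, 0.1))
            n0 = rng.uniform(0.2, 1.5, comm.M)
            J = nw.jacobian(comm, cp, params, abundances=n0)
            Jfd = np.empty_like(J)
            h = 1e-6
            for j in range(comm.M):
                e = np.zeros(comm.M)
                e[j] = h
                Jfd[:, j] = (
                    nw.growth_rate(comm, cp, params, n0 + e)
                    - nw.growth_rate(comm, cp, params, n0 - e)
                ) / (2 * h)
            assert np.abs(J - Jfd).max() < 1e-6

    def test_pure_competition_block_form(self, rng):
        """h = 0, Omega_m = 0: J = diag(g) + diag(n) * (-beta) blockwise."""
        comm = nw.BipartiteCommunity.random(4, 4, 0.5, 0.1, rng)
        cp = nw.build_couplings(comm, nw.InteractionIntensities(0.0, 0.2))
        p = nw.DynamicsParams(handling=0.0)
        n0 = rng.uniform(0.3, 1.2, comm.M)
        J = nw.jacobian(comm, cp, p, abundances=n0)
        nA, nP = n0[:4], n0[4:]
        gA = 1.0 - cp.beta_A @ nA
        gP = 1.0 - cp.beta_P @ nP
        expected = np.diag(np.concatenate([gA, gP]))
        expected[:4, :4] += -nA[:, None] * cp.beta_A
        expected[4:, 4:] += -nP[:, None] * cp.beta_P
        np.testing.assert_allclose(J, expected, atol=1e-12)


class TestStability:
    def test_single_logistic_S_equals_rho(self):
        comm, cp, p = isolated_species()
        eq = nw.relax_to_equilibrium(comm, cp, p)
        st = nw.stability(eq, comm, cp, p)
        assert st.S == pytest.approx(1.0, abs=1e-7)

    def test_slowest_mode_sets_S(self):
        comm = nw.BipartiteCommunity(
            centers_A=[0.2], centers_P=[0.8], width=0.1, theta=np.ones((1, 1)),
        )
        cp = nw.build_couplings(comm, nw.InteractionIntensities(0.0, 0.0))
        p = nw.DynamicsParams(rho=np.array([1.0, 0.5]))
        eq = nw.relax_to_equilibrium(comm, cp, p)
        st = nw.stability(eq, comm, cp, p)
        assert st.S == pytest.approx(0.5, abs=1e-7)

    def test_requires_converged_equilibrium(self, small_community, params):
        cp = nw.build_couplings(small_community, nw.InteractionIntensities(0.1, 0.05))
        bad = nw.EquilibriumState(
            abundances=np.ones(small_community.M), residual=1.0,
            feasible=True, converged=False,
        )
        with pytest.raises(ValueError):
            nw.stability(bad, small_community, cp, params)
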