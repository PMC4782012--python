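"""Two-mass oscillator and hopping leg: modes, contact, integrators.

The leg's equations of motion are cross-checked against an independent
symbolic (Lagrangian) derivation evaluated with sympy.
"""

import numpy as np
import pytest

from neuromodal.mechanics import (
    LegModel,
    TwoMassModel,
    contact_wrench,
    integrate,
    leg_dynamics_step,
    leg_torques,
    two_mass_accel,
)


class TestTwoMass:
    def test_equilibrium_has_zero_acceleration(self):
        m = TwoMassModel()
        np.testing.assert_allclose(two_mass_accel(m, np.zeros(2)), 0.0)

    def test_eigenfrequencies_from_table_parameters(self):
        m = TwoMassModel(m=0.5, k0=8.0, k1=15.0)
        w = m.eigenfrequencies()
        assert w[0] == pytest.approx(4.0)
        assert w[1] == pytest.approx(np.sqrt(76.0))
        # eigenvectors of the stiffness matrix are the (anti-)symmetric modes
        evals, evecs = np.linalg.eigh(m.stiffness_matrix())
        inphase = evecs[:, 0]
        assert abs(inphase[0]) == pytest.approx(abs(inphase[1]))

    def test_initial_deviation_excites_both_modes_equally(self):
        # phi(0) = (0, 0.1) decomposes as 0.05*(1,1) + 0.05*(-1,1)
        phi0 = np.array([0.0, 0.1])
        c_in = phi0 @ np.array([1, 1]) / 2
        c_anti = phi0 @ np.array([-1, 1]) / 2
        assert c_in == pytest.approx(0.05)
        assert c_anti == pytest.approx(0.05)

    def test_undamped_energy_drift_small(self):
        m = TwoMassModel(d0=0.0, phi=np.array([0.0, 0.1]))
        e0 = m.energy()
        dt = 1e-4
        for _ in range(10_000):  # 1 s
            m.step(np.zeros(2), dt)
        assert abs(m.energy() - e0) / e0 < 1e-3

    def test_passivity_with_damping(self):
        m = TwoMassModel(phi=np.array([0.0, 0.1]))
        e_prev = m.energy()
        dt = 1e-4
        for _ in range(20):
            for _ in range(500):
                m.step(np.zeros(2), dt)
            e = m.energy()
            assert e < e_prev + 1e-12
            e_prev = e

    def test_order_one_energy_convergence(self):
        def drift(dt):
            m = TwoMassModel(d0=0.0, phi=np.array([0.0, 0.1]))
            e0 = m.energy()
            worst = 0.0
            for _ in range(int(1.0 / dt)):
                m.step(np.zeros(2), dt)
                worst = max(worst, abs(m.energy() - e0))
            return worst

        ratio = drift(2e-4) / drift(1e-4)
        assert 1.5 < ratio < 3.0

    def test_eigenvector_forcing_leaves_orthogonal_mode_passive(self):
        # drive along (1,1) at the in-phase eigenfrequency: the anti-phase
        # coordinate stays at its unforced (zero) level
        m = TwoMassModel(d0=0.1)
        dt = 1e-4
        anti = []
        for k in range(100_000):
            f = 0.5 * np.sin(4.0 * k * dt) * np.array([1.0, 1.0])
            m.step(f, dt)
            anti.append((m.phi[1] - m.phi[0]) / 2)
        inphase_amp = np.abs(m.phi).max()
        assert np.abs(anti[-20_000:]).max() < 1e-6 * max(inphase_amp, 1.0)

    def test_euler_matches_analytic_mode_solution(self):
        # undriven, undamped: superpose the two closed-form modes over 10 s
        m = TwoMassModel(d0=0.0, phi=np.array([0.0, 0.1]))
        res = integrate(m, None, "euler", 1e-4, 10.0)
        t = res["t"]
        w1, w2 = 4.0, np.sqrt(76.0)
        analytic = 0.05 * np.cos(w1 * t)[:, None] * np.array([1.0, 1.0]) + \
            0.05 * np.cos(w2 * t)[:, None] * np.array([-1.0, 1.0])
        err = np.abs(res["phi"] - analytic).max()
        assert err < 0.001  # < 1% of the 0.1 m amplitude

    def test_adaptive_scheme_agrees_with_euler(self):
        m1 = TwoMassModel(phi=np.array([0.0, 0.1]))
        m2 = TwoMassModel(phi=np.array([0.0, 0.1]))
        f = np.zeros((10_000, 2))
        r1 = integrate(m1, f, "euler", 1e-4, 1.0)
        r2 = integrate(m2, f, "adaptive", 1e-4, 1.0)
        assert np.abs(r1["phi"] - r2["phi"]).max() < 1e-4


class TestLegKinematics:
    def test_symmetric_crouch_puts_foot_under_trunk(self):
        leg = LegModel()
        x, z = leg.foot_position()
        assert x == pytest.approx(0.0, abs=1e-12)

    def test_full_extension_touches_ground_at_h0(self):
        leg = LegModel(phi=np.zeros(2), h=0.0)
        x, z = leg.foot_position()
        assert z == pytest.approx(0.0, abs=1e-12)

    def test_foot_height_against_independent_geometry(self, rng):
        leg = LegModel()
        for _ in range(20):
            leg.h = rng.uniform(-0.05, 0.1)
            leg.phi = rng.uniform(0, 1.5, 2)
            a1 = leg.phi[0]
            a2 = leg.phi[0] - leg.phi[1]
            z_expect = leg.h + 2 * leg.l - leg.l * np.cos(a1) - leg.l * np.cos(a2)
            assert leg.foot_position()[1] == pytest.approx(z_expect)

    def test_jacobian_matches_finite_differences(self, rng):
        leg = LegModel()
        leg.h = 0.03
        leg.phi = np.array([0.4, 0.9])
        J = leg.foot_jacobian()
        eps = 1e-7
        q0 = np.array([leg.h, *leg.phi])
        for j in range(3):
            q = q0.copy()
            q[j] += eps
            leg2 = LegModel(h=q[0], phi=q[1:])
            num = (leg2.foot_position() - leg.foot_position()) / eps
            np.testing.assert_allclose(J[:, j], num, atol=1e-5)


class TestLegDynamics:
    def test_equations_match_symbolic_lagrangian(self, rng):
        sympy = pytest.importorskip("sympy")
        import sympy as sp

        t = sp.Symbol("t")
        h, p1, p2 = [sp.Function(n)(t) for n in ("h", "p1", "p2")]
        m0, m1, l, g = 0.5, 0.1, 0.106, 9.81
        a1, a2 = p1, p1 - p2
        zh = h + 2 * l
        xt, zt = (l / 2) * sp.sin(a1), zh - (l / 2) * sp.cos(a1)
        xs = l * sp.sin(a1) + (l / 2) * sp.sin(a2)
        zs = zh - l * sp.cos(a1) - (l / 2) * sp.cos(a2)
        Iseg = m1 * l**2 / 12
        d = lambda e: sp.diff(e, t)
        T = (m0 * d(zh) ** 2 / 2 + m1 * (d(xt) ** 2 + d(zt) ** 2) / 2
             + Iseg * d(a1) ** 2 / 2 + m1 * (d(xs) ** 2 + d(zs) ** 2) / 2
             + Iseg * d(a2) ** 2 / 2)
        V = g * (m0 * zh + m1 * zt + m1 * zs)
        L = T - V
        q = [h, p1, p2]
        qd = [d(x) for x in q]
        EL = [sp.diff(sp.diff(L, qd[i]), t) - sp.diff(L, q[i]) for i in range(3)]
        qdd = [sp.Symbol(f"dd{i}") for i in range(3)]
        EL = [e.subs(list(zip([d(x) for x in qd], qdd))) for e in EL]
        syms = [sp.Symbol(s) for s in ("hs", "q1", "q2", "v0", "v1", "v2")]
        # substitute derivatives before the bare coordinate functions
        EL = [e.subs({qd[i]: syms[3 + i] for i in range(3)})
               .subs({q[i]: syms[i] for i in range(3)}) for e in EL]
        fns = [sp.lambdify(syms + qdd, e) for e in EL]

        leg = LegModel(m0=m0, m1=m1, l=l)
        for _ in range(5):
            state = rng.uniform(-1, 1, 6)
            leg.h, leg.phi, leg.v = state[0], state[1:3].copy(), state[3:].copy()
            M = leg.mass_matrix()
            p = leg.bias_forces()
            acc = rng.uniform(-1, 1, 3)
            lhs = M @ acc + p
            for i in range(3):
                expect = fns[i](*state, *acc)
                assert lhs[i] == pytest.approx(expect, rel=1e-9, abs=1e-9)

    def test_mass_matrix_symmetric_positive_definite(self, rng):
        leg = LegModel()
        for _ in range(20):
            leg.phi = rng.uniform(-1.5, 2.5, 2)
            M = leg.mass_matrix()
            np.testing.assert_allclose(M, M.T)
            assert np.all(np.linalg.eigvalsh(M) > 0)

    def test_airborne_energy_conservation(self):
        # no damping, no actuation, no contact: Hamiltonian is conserved
        leg = LegModel(d0=0.0, d1=0.0, h=0.5)  # high above ground
        leg.v = np.array([0.1, 0.3, -0.2])
        e0 = leg.energy()
        integrate(leg, None, "rk4", 1e-4, 0.25)  # stays clear of the ground
        assert abs(leg.energy() - e0) / abs(e0) < 1e-6

    def test_stationary_without_gravity_at_spring_equilibrium(self):
        leg = LegModel(g=0.0, h=0.5)
        state0 = (leg.h, leg.phi.copy(), leg.v.copy())
        for _ in range(1000):
            tau = leg_torques(leg, np.zeros(2), 0.0)
            leg_dynamics_step(leg, tau, 1e-4)
        assert leg.h == pytest.approx(state0[0], abs=1e-10)
        np.testing.assert_allclose(leg.phi, state0[1], atol=1e-10)

    def test_drop_initialization_and_first_apex_scheme_agreement(self):
        def first_apex(scheme):
            leg = LegModel()  # drop: h = 0, phi = phi0, zero velocity
            forces = np.zeros((20_000, 2))
            res = integrate(leg, forces, scheme, 1e-4, 2.0)
            from neuromodal.analysis import jump_metrics
            js = jump_metrics(res["t"], res["h"], res["contact"], min_flight=0.0)
            return js.apex_heights[0]

        a_rk4 = first_apex("rk4")
        a_adaptive = first_apex("adaptive")
        assert abs(a_rk4 - a_adaptive) < 1e-3  # within 1 mm

    def test_divergence_raises(self):
        leg = LegModel()
        with pytest.raises((FloatingPointError, ValueError)):
            for _ in range(100):
                leg_dynamics_step(leg, np.array([1e12, -1e12]), 1e-4)


class TestActuationAndContact:
    def test_spring_equilibrium_zero_torque(self):
        leg = LegModel()
        np.testing.assert_allclose(leg_torques(leg, np.zeros(2), 0.0), 0.0)

    def test_torque_linear_in_motor_signal(self):
        leg = LegModel()
        w_nm = np.array([1.5, 0.8])
        t1 = leg_torques(leg, w_nm, 1.0)
        t2 = leg_torques(leg, w_nm, 3.0)
        slope = (t2 - t1) / 2.0
        np.testing.assert_allclose(slope, np.array([leg.k0, leg.k1]) * w_nm)

    def test_pure_damping_contribution(self):
        leg = LegModel()
        leg.v = np.array([0.0, 1.0, 1.0])
        tau = leg_torques(leg, np.zeros(2), 0.0)
        np.testing.assert_allclose(tau, [-leg.d0, -leg.d1])

    def test_contact_zero_above_ground(self):
        leg = LegModel(h=0.3)
        np.testing.assert_allclose(contact_wrench(leg), 0.0)

    def test_static_penetration_normal_force(self):
        leg = LegModel(phi=np.zeros(2), h=-1e-3)  # foot 1 mm under ground
        Q = contact_wrench(leg)
        # generalized force on h equals the upward normal force k_g * delta
        assert Q[0] == pytest.approx(leg.contact.stiffness * 1e-3)

    def test_no_adhesion_on_rapid_withdrawal(self):
        leg = LegModel(phi=np.zeros(2), h=-1e-4)
        leg.v = np.array([10.0, 0.0, 0.0])  # fast upward
        Q = contact_wrench(leg)
        assert Q[0] >= 0.0
        assert Q[0] == 0.0  # damper would pull; clamped instead
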