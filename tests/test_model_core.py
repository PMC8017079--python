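"""Right-hand side, calcium balance, Jacobian and the trapping box."""

import math

import numpy as np
import pytest

from dcnsim import (NeuronState, StimulusProtocol, build_system,
                    calcium_rate, jacobian, rhs, standard_parameters)
from dcnsim.core import steady_state, time_constant


@pytest.fixture(scope="module")
def p():
    return standard_parameters()


@pytest.fixture(scope="module")
def sysm(p):
    return build_system(p)


def random_states(p, n, rng):
    for _ in range(n):
        yield np.array([
            rng.uniform(-90.0, 40.0),
            rng.uniform(p.Ca_base, 5.0),
            rng.uniform(0.0, 1.0), rng.uniform(0.0, 1.0),
            rng.uniform(0.0, 1.0), rng.uniform(0.0, 1.0)])


class TestCalciumRate:
    def test_zero_at_baseline_without_ca_currents(self, p):
        p0 = p.evolve(P_CaH=0.0, P_CaT=0.0)
        s = NeuronState(V=-50.0, Ca=p.Ca_base, h_NaV=0.5, m_Kdr=0.1,
                        m_CaT=0.2, h_CaT=0.5)
        assert calcium_rate(s, p0) == pytest.approx(0.0, abs=1e-12)

    def test_positive_below_baseline(self, p):
        p0 = p.evolve(P_CaH=0.0, P_CaT=0.0)
        s = NeuronState(V=-50.0, Ca=0.5 * p.Ca_base, h_NaV=0.5, m_Kdr=0.1,
                        m_CaT=0.2, h_CaT=0.5)
        assert calcium_rate(s, p0) > 0

    def test_negative_above_external(self, p):
        # trapping property of the shell balance; gating at its steady
        # state (the fully de-inactivated CaT corner at hyperpolarized V is
        # dynamically unreachable, see docs/methods.md)
        g = p.gating
        for V in (-80.0, -56.0, -38.0, 0.0):
            s = NeuronState(V=V, Ca=p.Ca_out * 1.01,
                            h_NaV=steady_state(g["h_NaV"], V),
                            m_Kdr=steady_state(g["m_Kdr"], V),
                            m_CaT=steady_state(g["m_CaT"], V),
                            h_CaT=steady_state(g["h_CaT"], V))
            assert calcium_rate(s, p) < 0

    def test_high_precision_transcription(self, p):
        # independent 50-digit transcription of the balance equation
        import sympy

        s = NeuronState(V=-45.0, Ca=0.8, h_NaV=0.3, m_Kdr=0.2, m_CaT=0.5,
                        h_CaT=0.02)
        from dcnsim import membrane_currents

        cur = membrane_currents(s, p)
        I = sympy.Float(cur.I_CaH, 50) + sympy.Float(cur.I_CaT, 50)
        Rc, de, k, BT, KD, F = (sympy.Float(v, 50) for v in
                                (p.R_c, p.delta, p.k_pump, p.B_T, p.K_D, p.F))
        Ca, Cab = sympy.Float(0.8, 50), sympy.Float(p.Ca_base, 50)
        num = I * Rc / F + 2 * k * (Ca - Cab) * (Rc - de)
        den = de * (2 * Rc - de) * (1 + BT / (KD * (1 + sympy.Float(1e-11, 50)
                                                    * Ca / KD) ** 2))
        expected = float((-num / den).evalf(50))
        assert calcium_rate(s, p) == pytest.approx(expected, rel=1e-12)


class TestRHS:
    def test_zero_at_fixed_point(self, p, sd_fp):
        f = rhs(0.0, NeuronState.from_array(sd_fp.state),
                StimulusProtocol(0.0), p)
        assert np.max(np.abs(f)) < 1e-8

    def test_gating_component_zero_at_steady_state(self, p):
        V = -52.0
        g = p.gating
        s = NeuronState(V=V, Ca=0.2,
                        h_NaV=steady_state(g["h_NaV"], V),
                        m_Kdr=steady_state(g["m_Kdr"], V),
                        m_CaT=steady_state(g["m_CaT"], V),
                        h_CaT=steady_state(g["h_CaT"], V))
        f = rhs(0.0, s, StimulusProtocol(0.0), p)
        assert np.max(np.abs(f[2:])) < 1e-14

    def test_gating_component_matches_first_order_form(self, p, sysm):
        rng = np.random.default_rng(7)
        names = ["h_NaV", "m_Kdr", "m_CaT", "h_CaT"]
        for y in random_states(p, 5, rng):
            f = sysm.rhs_autonomous(y)
            for i, name in enumerate(names, start=2):
                spec = p.gating[name]
                expect = ((steady_state(spec, y[0]) - y[i])
                          / time_constant(spec, y[0]))
                assert f[i] == pytest.approx(expect, rel=1e-12)

    def test_finite_difference_consistency_along_trajectory(self, p,
                                                            firing_state):
        # the numerically differentiated solution matches the vector field
        from dcnsim.simulate import integrate

        traj = integrate(p, StimulusProtocol(0.0), firing_state, (0.0, 0.05),
                         rtol=1e-10)
        sysm = build_system(p, I_DC=0.0)
        t, y = traj.t, traj.y
        for i in range(50, 2450, 240):
            dy = (y[i + 1] - y[i - 1]) / (t[i + 1] - t[i - 1])
            f = sysm.rhs_autonomous(y[i])
            scale = np.maximum(np.abs(f), 1e-3 * np.max(np.abs(f)))
            assert np.max(np.abs(dy - f) / scale) < 5e-2


class TestJacobian:
    def test_matches_central_differences(self, p, sysm):
        rng = np.random.default_rng(11)
        for y in random_states(p, 4, rng):
            J = sysm.jacobian(y)
            for j in range(6):
                # central-difference step balancing truncation against the
                # cancellation noise of the difference quotient
                h = 1e-5 * max(abs(y[j]), 0.1)
                yp, ym = y.copy(), y.copy()
                yp[j] += h
                ym[j] -= h
                col = (sysm.rhs_autonomous(yp) - sysm.rhs_autonomous(ym)) / (2 * h)
                tol = 1e-4 * np.abs(col) + 1e-6 * np.abs(col).max() + 1e-10
                assert (np.abs(J[:, j] - col) <= tol).all()

    def test_gating_row_diagonal(self, p, sysm):
        y = np.array([-48.0, 0.3, 0.2, 0.25, 0.4, 0.01])
        J = sysm.jacobian(y)
        assert J[2, 2] == pytest.approx(
            -1.0 / time_constant(p.gating["h_NaV"], y[0]), rel=1e-10)
        # gating rows couple only to V and themselves
        assert J[2, 1] == 0.0 and J[2, 3] == 0.0

    def test_sd_state_is_stable(self, sd_fp):
        assert sd_fp.stable
        assert sd_fp.eigenvalues.real.max() < 0


class TestTrappingBox:
    def test_vector_field_points_inward(self, p, sysm):
        """On each face of the physiological box the flow is inward."""
        rng = np.random.default_rng(3)
        E_min = min(p.E_Na, p.E_K, p.E_Leak, p.E_TCN)
        E_max = max(p.E_Na, p.E_K, p.E_Leak, p.E_TCN, p.E_Ca_max)
        interior = lambda: np.array([
            rng.uniform(E_min + 1, E_max - 1),
            rng.uniform(p.Ca_base * 1.01, p.Ca_out * 0.99),
            rng.uniform(0.01, 0.99), rng.uniform(0.01, 0.99),
            rng.uniform(0.01, 0.99), rng.uniform(0.01, 0.99)])
        for _ in range(40):
            y = interior()
            for i in range(2, 6):
                lo, hi = y.copy(), y.copy()
                lo[i], hi[i] = 0.0, 1.0
                assert sysm.rhs_autonomous(lo)[i] > 0
                assert sysm.rhs_autonomous(hi)[i] < 0
            from dcnsim.core import steady_state as ss
            ca_lo, ca_hi = y.copy(), y.copy()
            for z in (ca_lo, ca_hi):
                for i, name in enumerate(("h_NaV", "m_Kdr", "m_CaT",
                                          "h_CaT"), start=2):
                    z[i] = ss(p.gating[name], z[0])
            ca_lo[1], ca_hi[1] = p.Ca_base, p.Ca_out
            assert sysm.rhs_autonomous(ca_lo)[1] >= 0
            assert sysm.rhs_autonomous(ca_hi)[1] <= 0
            v_lo, v_hi = y.copy(), y.copy()
            v_lo[0], v_hi[0] = E_min, E_max
            assert sysm.rhs_autonomous(v_lo)[0] > 0
            assert sysm.rhs_autonomous(v_hi)[0] < 0
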