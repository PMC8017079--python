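"""Model equations: gating kinetics, membrane currents, calcium balance,
right-hand side and Jacobian.

All public functions operate in the package's unit system (mV, s, nA/cm^2,
uS/cm^2, uM, cm/s), in which both the constant-field (GHK) calcium
currents and the submembrane calcium shell balance are dimensionally exact
with no hidden conversion factors (see docs/methods.md, "Units and the
calcium subsystem").

The Jacobian is computed by complex-step differentiation: every expression
in the right-hand side is analytic in the state, so d f/d y_j =
Im(f(y + ih e_j))/h to machine precision.  The independent check against
central finite differences lives in the test suite.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .params import ModelParameters, NeuronState, GatingSpec
from .stimulus import StimulusProtocol

__all__ = [
    "steady_state",
    "time_constant",
    "ghk_current",
    "kca_open_fraction",
    "membrane_currents",
    "calcium_rate",
    "rhs",
    "jacobian",
    "CurrentBreakdown",
    "System",
    "build_system",
]


# --------------------------------------------------------------------------
# Gating kinetics
# --------------------------------------------------------------------------

def steady_state(spec: GatingSpec, V: float) -> float:
    """Boltzmann steady state x_inf(V) of one gating variable."""
    return _boltzmann(V, spec.V_half, spec.slope, spec.sign, math.exp)


def _boltzmann(V, half, slope, sign, exp):
    # sign=+1 rises with V (activation), sign=-1 falls (inactivation)
    z = -sign * (V - half) / slope
    zr = z.real if isinstance(z, complex) else z
    if zr > 500.0:  # avoid overflow; the limit is exact to double precision
        return 0.0 * z
    return 1.0 / (1.0 + exp(z))


def time_constant(spec: GatingSpec, V: float) -> float:
    """Bell-shaped voltage-dependent time constant tau_x(V) in seconds."""
    if spec.instantaneous:
        raise ValueError(f"{spec.name} is instantaneous; its tau is undefined")
    return _tau(V, spec.tau_base, spec.tau_amp, spec.tau_asym,
                spec.V_tau1, spec.V_tau2, spec.k_tau1, spec.k_tau2, math.exp,
                spec.tau_flip)


def _tau(V, t0, t1, asym, V1, V2, k1, k2, exp, flip=False):
    # Bell-shaped denominator e^{-(V-V1)/k1} + asym e^{(V-V2)/k2}: the first
    # exponential falls and the second rises with V, so tau peaks between the
    # two centres and tends to t0 at +-inf (the thalamic T-current form).
    # flip reverses both signs (mirror-image bell; differs only when the
    # shape is asymmetric).
    if flip:
        a = (V - V1) / k1
        b = -(V - V2) / k2
    else:
        a = -(V - V1) / k1
        b = (V - V2) / k2
    ar = a.real if isinstance(a, complex) else a
    br = b.real if isinstance(b, complex) else b
    if ar > 500.0 or br > 500.0:
        return t0 + 0.0 * a
    return t0 + t1 / (exp(a) + asym * exp(b))


# --------------------------------------------------------------------------
# Currents
# --------------------------------------------------------------------------

def _ghk(P, V, Ca_in, Ca_out, zF, RT, exp):
    """Constant-field Ca current, nA/cm^2.

    With P in cm/s, V in mV and concentrations in uM this expression is
    dimensionally exact (1 uM = 1e-9 mol/cm^3 and 1 nA = 1e-9 A cancel),
    so no conversion factor appears.
    """
    u = zF * V * 1e-3 / RT
    a = exp(-u)
    ur = u.real if isinstance(u, complex) else u
    if abs(ur) < 1e-4:
        fac = 1.0 + u / 2.0 + u * u / 12.0  # removable singularity at V=0
    else:
        fac = u / (1.0 - a)
    return P * zF * fac * (Ca_in - a * Ca_out)


def ghk_current(P: float, V: float, Ca_in: float, params: ModelParameters) -> float:
    """GHK calcium current for permeability P (cm/s) at voltage V (mV).

    Zero exactly when Ca_in = alpha(V) * Ca_out (the calcium Nernst
    potential); inward (negative) below it, outward above.
    """
    if P < 0:
        raise ValueError("P must be >= 0")
    if not (math.isfinite(V) and math.isfinite(Ca_in)) or Ca_in <= 0:
        raise ValueError("V and Ca_in must be finite, Ca_in > 0")
    return _ghk(P, V, Ca_in, params.Ca_out, params.z_Ca * params.F,
                params.RT, math.exp)


def kca_open_fraction(Ca: float, params: ModelParameters) -> float:
    """Hill-type SK open fraction w = Ca^n / (C_KCa^n + Ca^n), n = 5."""
    if Ca < 0:
        raise ValueError("Ca must be >= 0")
    n = params.hill_KCa
    cn = Ca ** n
    return cn / (params.C_KCa ** n + cn)


@dataclass(frozen=True)
class CurrentBreakdown:
    """Per-channel membrane currents (nA/cm^2, outward positive)."""

    I_NaV: float
    I_Kdr: float
    I_TCN: float
    I_KCa: float
    I_Leak: float
    I_CaH: float
    I_CaT: float
    I_KdrS: float = 0.0

    @property
    def I_total(self) -> float:
        return (self.I_NaV + self.I_Kdr + self.I_TCN + self.I_KCa
                + self.I_Leak + self.I_CaH + self.I_CaT + self.I_KdrS)


def membrane_currents(state: NeuronState, params: ModelParameters) -> CurrentBreakdown:
    """Evaluate every membrane current at the given state."""
    sysm = build_system(params)
    return sysm.currents(state.as_array(sysm.dim))


def calcium_rate(state: NeuronState, params: ModelParameters) -> float:
    """d[Ca]/dt (uM/s): shell balance of Ca influx, extrusion and fast buffer."""
    sysm = build_system(params)
    return float(sysm.rhs_autonomous(state.as_array(sysm.dim))[1])


def rhs(t: float, state: NeuronState, protocol: StimulusProtocol,
        params: ModelParameters) -> np.ndarray:
    """Full model right-hand side at time t under the given protocol."""
    drive = protocol.segment_drive(t)
    sysm = build_system(params, drive=drive)
    return sysm.rhs_autonomous(state.as_array(sysm.dim))


def jacobian(state: NeuronState, I_DC: float, params: ModelParameters) -> np.ndarray:
    """Jacobian of the autonomous (tonic-input) system at the given state."""
    sysm = build_system(params, I_DC=I_DC)
    return sysm.jacobian(state.as_array(sysm.dim))


# --------------------------------------------------------------------------
# Compiled system
# --------------------------------------------------------------------------

class System:
    """A parameter set compiled into fast RHS / Jacobian callables.

    ``drive`` is the constant-coefficient input (I_const, G, G*E) of one
    protocol segment: I_S = I_const - G*V + GE.  State layout is
    (V, Ca, h_NaV, m_Kdr, m_CaT, h_CaT[, m_KdrS]); frozen variables (Ca in
    the 3-variable subsystem, h_CaT in the h_CaT-as-parameter variant) keep
    a zero derivative and their value is pinned inside the RHS, so their
    rows and columns drop out of stability analysis via ``active``.
    """

    def __init__(self, params: ModelParameters, drive=(0.0, 0.0, 0.0)):
        self.params = params
        self.drive = tuple(map(float, drive))
        self.has_kdrs = params.g_KdrS > 0
        self.dim = 7 if self.has_kdrs else 6
        self.names = params.state_names
        frozen = np.zeros(self.dim, dtype=bool)
        if params.ca_frozen:
            frozen[1] = True
        if params.h_CaT_frozen is not None:
            frozen[5] = True
        self.frozen = frozen
        self.active = np.nonzero(~frozen)[0]

        p = params
        g = p.gating
        self._c = dict(
            C=p.C, gL=p.g_Leak, gNa=p.g_NaV, gK=p.g_Kdr, gT=p.g_TCN,
            gKCa=p.g_KCa, PH=p.P_CaH, PT=p.P_CaT, EL=p.E_Leak, ENa=p.E_Na,
            EK=p.E_K, ET=p.E_TCN, Cout=p.Ca_out, Cab=p.Ca_base,
            CK=p.C_KCa, nH=p.hill_KCa, Rc=p.R_c, de=p.delta, kp=p.k_pump,
            BT=p.B_T, KD=p.K_D, zF=p.z_Ca * p.F, RT=p.RT, F=p.F,
            gKS=p.g_KdrS, tauKS=p.kdrs_tau_factor,
            hfix=p.h_CaT_frozen, cafix=p.ca_frozen,
            mNa=g["m_NaV"], hNa=g["h_NaV"], mK=g["m_Kdr"],
            mH=g["m_CaH"], mT=g["m_CaT"], hT=g["h_CaT"],
        )
        # constant denominator pieces of the calcium balance
        self._ca_shell = p.delta * (2.0 * p.R_c - p.delta)
        # Source coefficient of the shell balance: I_Ca (nA/cm^2) -> uM/s
        # carries no extra factor in this unit system (flux I/zF with z=2
        # against the cylindrical shell geometry; see docs/methods.md).
        self._ca_srcf = p.R_c / p.F
        self._ca_snkf = 2.0 * p.k_pump * (p.R_c - p.delta)

    # -- scalar helpers (exp chosen by caller: math.exp or cmath.exp) ------

    def _gates(self, V, exp):
        c = self._c
        mNa = _boltzmann(V, c["mNa"].V_half, c["mNa"].slope, 1.0, exp)
        mH = _boltzmann(V, c["mH"].V_half, c["mH"].slope, 1.0, exp)
        return mNa, mH

    def currents(self, y, exp=math.exp, drive_V=None):
        """CurrentBreakdown at state vector y."""
        c = self._c
        V, Ca = y[0], y[1]
        if c["cafix"]:
            Ca = c["Cab"]
        hNa, mK, mT = y[2], y[3], y[4]
        hT = c["hfix"] if c["hfix"] is not None else y[5]
        mNa, mH = self._gates(V, exp)
        I_NaV = c["gNa"] * mNa ** 3 * hNa * (V - c["ENa"])
        I_Kdr = c["gK"] * mK ** 4 * (V - c["EK"])
        I_TCN = c["gT"] * (V - c["ET"])
        n = c["nH"]
        can = Ca ** n
        w = can / (c["CK"] ** n + can)
        I_KCa = c["gKCa"] * w * (V - c["EK"])
        I_Leak = c["gL"] * (V - c["EL"])
        I_CaH = _ghk(c["PH"] * mH, V, Ca, c["Cout"], c["zF"], c["RT"], exp)
        I_CaT = _ghk(c["PT"] * mT ** 2 * hT, V, Ca, c["Cout"], c["zF"], c["RT"], exp)
        I_KdrS = 0.0
        if self.has_kdrs:
            I_KdrS = c["gKS"] * y[6] ** 4 * (V - c["EK"])
        return CurrentBreakdown(I_NaV=I_NaV, I_Kdr=I_Kdr, I_TCN=I_TCN,
                                I_KCa=I_KCa, I_Leak=I_Leak, I_CaH=I_CaH,
                                I_CaT=I_CaT, I_KdrS=I_KdrS)

    def _rhs_core(self, y, exp):
        c = self._c
        V = y[0]
        Ca = c["Cab"] if c["cafix"] else y[1]
        hNa, mK, mT = y[2], y[3], y[4]
        hT = c["hfix"] if c["hfix"] is not None else y[5]

        cur = self.currents(y, exp=exp)
        i_const, G, GE = self.drive
        I_S = i_const - G * V + GE
        dV = (I_S - cur.I_total) / c["C"]

        # calcium shell balance (rapid-buffer denominator)
        if c["cafix"]:
            dCa = 0.0
        else:
            src = self._ca_srcf * (cur.I_CaH + cur.I_CaT)
            snk = self._ca_snkf * (Ca - c["Cab"])
            buf = 1.0 + c["BT"] / (c["KD"] * (1.0 + 1e-11 * Ca / c["KD"]) ** 2)
            dCa = -(src + snk) / (self._ca_shell * buf)

        out = [dV, dCa]
        for spec, x in ((c["hNa"], hNa), (c["mK"], mK), (c["mT"], mT)):
            inf = _boltzmann(V, spec.V_half, spec.slope, spec.sign, exp)
            tau = _tau(V, spec.tau_base, spec.tau_amp, spec.tau_asym,
                       spec.V_tau1, spec.V_tau2, spec.k_tau1, spec.k_tau2, exp,
                       spec.tau_flip)
            out.append((inf - x) / tau)
        if c["hfix"] is not None:
            out.append(0.0)
        else:
            spec = c["hT"]
            inf = _boltzmann(V, spec.V_half, spec.slope, spec.sign, exp)
            tau = _tau(V, spec.tau_base, spec.tau_amp, spec.tau_asym,
                       spec.V_tau1, spec.V_tau2, spec.k_tau1, spec.k_tau2, exp,
                       spec.tau_flip)
            out.append((inf - y[5]) / tau)
        if self.has_kdrs:
            spec = c["mK"]
            inf = _boltzmann(V, spec.V_half, spec.slope, spec.sign, exp)
            tau = c["tauKS"] * _tau(V, spec.tau_base, spec.tau_amp, spec.tau_asym,
                                    spec.V_tau1, spec.V_tau2, spec.k_tau1,
                                    spec.k_tau2, exp, spec.tau_flip)
            out.append((inf - y[6]) / tau)
        return out

    # -- public callables --------------------------------------------------

    def rhs_autonomous(self, y) -> np.ndarray:
        return np.asarray(self._rhs_core(y, math.exp), dtype=float)

    def rhs(self, t, y) -> np.ndarray:  # solve_ivp signature
        return self.rhs_autonomous(y)

    def jacobian(self, y, t=None) -> np.ndarray:
        """Complex-step Jacobian d(rhs)/d(state)."""
        n = self.dim
        J = np.empty((n, n), dtype=float)
        h = 1e-20
        yc = np.asarray(y, dtype=complex)
        for j in range(n):
            yp = yc.copy()
            yp[j] += 1j * h
            col = self._rhs_core(yp, cmath.exp)
            for i in range(n):
                J[i, j] = col[i].imag / h if isinstance(col[i], complex) else 0.0
        J[self.frozen, :] = 0.0
        return J

    def jac(self, t, y) -> np.ndarray:  # solve_ivp signature
        return self.jacobian(y)

    def eigenvalues(self, y) -> np.ndarray:
        """Eigenvalues of the Jacobian restricted to the active variables."""
        J = self.jacobian(y)[np.ix_(self.active, self.active)]
        return np.linalg.eigvals(J)

    def with_drive(self, drive) -> "System":
        s = System.__new__(System)
        s.__dict__.update(self.__dict__)
        s.drive = tuple(map(float, drive))
        return s

    # -- equilibrium helpers ----------------------------------------------

    def gating_inf(self, V: float) -> dict:
        g = self.params.gating
        return {name: steady_state(g[name], V)
                for name in ("h_NaV", "m_Kdr", "m_CaT", "h_CaT")}

    def equilibrium_calcium(self, V: float) -> float:
        """[Ca] solving the shell balance at fixed V (closed-form).

        The GHK currents are affine in [Ca], so the balance
        src_coeff*(A*Ca + B) + snk_coeff*(Ca - Ca_b) = 0 is linear.
        """
        c = self._c
        if c["cafix"]:
            return c["Cab"]
        ginf = self.gating_inf(V)
        mH = steady_state(c["mH"], V)
        hT = c["hfix"] if c["hfix"] is not None else ginf["h_CaT"]
        P_eff = c["PH"] * mH + c["PT"] * ginf["m_CaT"] ** 2 * hT
        # I_Ca(Ca) = A*Ca + B
        u = c["zF"] * V * 1e-3 / c["RT"]
        a = math.exp(-u)
        fac = (1.0 + u / 2.0 + u * u / 12.0) if abs(u) < 1e-4 else u / (1.0 - a)
        A = P_eff * c["zF"] * fac
        B = -A * a * c["Cout"]
        s1, s2 = self._ca_srcf, self._ca_snkf
        Ca = (s2 * c["Cab"] - s1 * B) / (s1 * A + s2)
        return float(Ca)

    def equilibrium_state(self, V: float) -> np.ndarray:
        """Full state with gating at x_inf(V) and [Ca] at its balance point."""
        ginf = self.gating_inf(V)
        y = [V, self.equilibrium_calcium(V), ginf["h_NaV"], ginf["m_Kdr"],
             ginf["m_CaT"], ginf["h_CaT"]]
        if self.params.h_CaT_frozen is not None:
            y[5] = self.params.h_CaT_frozen
        if self.has_kdrs:
            y.append(ginf["m_Kdr"])
        return np.array(y, dtype=float)

    def required_IDC(self, V: float) -> float:
        """Tonic current making V a fixed point (I_DC = sum of ion currents)."""
        return float(self.currents(self.equilibrium_state(V)).I_total)


def build_system(params: ModelParameters, I_DC: float = 0.0,
                 drive: Optional[Sequence[float]] = None) -> System:
    """Compile a parameter set into a System with the given tonic drive."""
    if drive is None:
        drive = (I_DC, 0.0, 0.0)
    return System(params, drive=drive)
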