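"""Model parameters and state containers.

The model is an isopotential, conductance-based description of a deep
cerebellar nuclei neuron (DCNn) with six membrane currents (NaV, Kdr, TCN,
KCa, Leak and the two GHK calcium currents CaH/CaT) and six state variables
(V, [Ca], h_NaV, m_Kdr, m_CaT, h_CaT).  ``ModelParameters`` is the single
source of truth for a model variant; default construction reproduces the
published standard parameter set.

Units
-----
V in mV, time in s, currents in nA/cm^2, conductances in uS/cm^2, calcium
concentrations in uM, permeabilities in cm/s.  With these choices the
voltage equation ``C dV/dt = -sum(I) + I_S`` needs no extra conversion
factor (C in uF/cm^2, dV/dt in mV/s).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional

__all__ = [
    "GatingSpec",
    "ModelParameters",
    "NeuronState",
    "standard_parameters",
    "STATE_NAMES",
]

# Physical constants (SI)
FARADAY = 96485.0  # C/mol
GAS_CONSTANT = 8.314  # J/(mol K)

STATE_NAMES = ("V", "Ca", "h_NaV", "m_Kdr", "m_CaT", "h_CaT")


@dataclass(frozen=True)
class GatingSpec:
    """Voltage dependence of one activation/inactivation variable.

    The steady state is a Boltzmann function of V centred at ``V_half`` with
    slope ``slope`` (> 0); ``kind`` selects the monotonicity (activation
    variables increase with V, inactivation variables decrease).  The time
    constant is the standard single-peaked form

        tau(V) = tau_base + tau_amp / (e^{(V-V_tau1)/k_tau1}
                                       + tau_asym * e^{-(V-V_tau2)/k_tau2})

    which tends to ``tau_base`` for V -> +-inf.  Variables flagged
    ``instantaneous`` (m_NaV, m_CaH) are replaced by their steady state and
    their tau parameters are never evaluated.
    """

    name: str
    kind: str  # "activation" | "inactivation"
    V_half: float  # mV
    slope: float  # mV, > 0
    exponent: int = 1
    tau_base: float = 0.0  # s
    tau_amp: float = 0.0  # s
    tau_asym: float = 1.0
    V_tau1: float = 0.0  # mV
    V_tau2: float = 0.0  # mV
    k_tau1: float = 1.0  # mV
    k_tau2: float = 1.0  # mV
    instantaneous: bool = False
    #: orientation of the first exponential in the tau denominator.  False:
    #: e^{-(V-V_tau1)/k_tau1} (falling) + asym e^{(V-V_tau2)/k_tau2} (rising),
    #: the thalamic T-current form whose peak can exceed tau_amp.  True: both
    #: signs flipped.  The two coincide when V_tau1 = V_tau2, k_tau1 = k_tau2
    #: and tau_asym = 1; for tau_asym != 1 they put the peak on opposite
    #: sides of the centre (see docs/methods.md).
    tau_flip: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("activation", "inactivation"):
            raise ValueError(f"{self.name}: kind must be activation|inactivation")
        if self.slope <= 0:
            raise ValueError(f"{self.name}: slope must be > 0")
        if self.exponent < 1:
            raise ValueError(f"{self.name}: exponent must be a positive integer")
        if not self.instantaneous:
            if self.tau_amp <= 0:
                raise ValueError(f"{self.name}: tau_amp must be > 0")
            if self.tau_base < 0:
                raise ValueError(f"{self.name}: tau_base must be >= 0")
            if self.k_tau1 <= 0 or self.k_tau2 <= 0:
                raise ValueError(f"{self.name}: k_tau1, k_tau2 must be > 0")
            if self.tau_asym <= 0:
                raise ValueError(f"{self.name}: tau_asym must be > 0")

    @property
    def sign(self) -> float:
        """+1 for activation, -1 for inactivation (steady-state exponent sign)."""
        return 1.0 if self.kind == "activation" else -1.0


def _standard_gating() -> Dict[str, GatingSpec]:
    return {
        # Instantaneous activation of the fast Na current (quasi-steady state).
        "m_NaV": GatingSpec("m_NaV", "activation", V_half=-32.0, slope=8.5,
                            exponent=3, instantaneous=True),
        "h_NaV": GatingSpec("h_NaV", "inactivation", V_half=-55.0, slope=5.5,
                            exponent=1, tau_base=5e-3, tau_amp=3e-2, tau_asym=1.0,
                            V_tau1=-65.0, V_tau2=-65.0, k_tau1=7.0, k_tau2=7.0),
        # tau_flip puts the tau_m_Kdr peak on the hyperpolarized side of the
        # centre (-36 mV); the opposite orientation abolishes the firing
        # attractor altogether (see docs/methods.md).
        "m_Kdr": GatingSpec("m_Kdr", "activation", V_half=-25.0, slope=11.5,
                            exponent=4, tau_base=0.0, tau_amp=5.4e-3, tau_asym=0.6,
                            V_tau1=-30.0, V_tau2=-30.0, k_tau1=25.0, k_tau2=25.0,
                            tau_flip=True),
        # High-threshold Ca current: instantaneous activation, no inactivation.
        "m_CaH": GatingSpec("m_CaH", "activation", V_half=-22.0, slope=4.53,
                            exponent=1, instantaneous=True),
        "m_CaT": GatingSpec("m_CaT", "activation", V_half=-56.0, slope=6.2,
                            exponent=2, tau_base=2e-4, tau_amp=3.33e-4, tau_asym=1.0,
                            V_tau1=-131.0, V_tau2=-15.8, k_tau1=16.7, k_tau2=18.2),
        # The slow-inactivation time constant rows of the parameter table are
        # those of tau_h_CaT (the CaH current itself never inactivates).
        "h_CaT": GatingSpec("h_CaT", "inactivation", V_half=-80.0, slope=4.0,
                            exponent=1, tau_base=1.2e-2, tau_amp=2.0, tau_asym=1.0,
                            V_tau1=-81.0, V_tau2=-81.0, k_tau1=8.0, k_tau2=8.0),
    }


@dataclass(frozen=True)
class ModelParameters:
    """Complete parameter set of one model variant.

    Defaults reproduce the standard published set, with two documented
    exceptions fixed once by calibration against the model's printed
    anchors (silent-state and TTX voltages, pulse-switching thresholds,
    block-induced transitions; see docs/methods.md): the high-threshold Ca
    permeability ``P_CaH`` and the unprinted constants ``C_KCa`` (0.2 uM,
    pinned by the SK open fraction ~1e-3 at [Ca] = 50 nM with Hill
    coefficient 5), ``Ca_base`` (0.05 uM, the baseline reached when the Ca
    currents are blocked) and ``Ca_out`` (0.45 mM).
    """

    # Membrane
    C: float = 1.0  # uF/cm^2
    # Maximum conductances (uS/cm^2) and permeabilities (cm/s)
    g_Leak: float = 2e1
    g_NaV: float = 5e3
    g_Kdr: float = 4.5e3
    g_TCN: float = 4.5e1
    g_KCa: float = 10.0
    #: High-threshold Ca permeability.  The published table prints
    #: 2e-4 cm/s, which is dimensionally incompatible with the model's own
    #: fixed-point anchors (it would make I_CaH at the silent depolarized
    #: state ~100x too large to balance); the default is the recalibrated
    #: value that reproduces those anchors (see docs/methods.md).
    P_CaH: float = 2.2e-5
    P_CaT: float = 7e-4
    # Reversal potentials (mV)
    E_Leak: float = -60.0
    E_Na: float = 86.0
    E_K: float = -80.0
    E_TCN: float = -34.0
    E_Cl: float = -75.0
    # Calcium dynamics
    Ca_out: float = 450.0  # uM ([Ca]_o, calibrated; see docstring)
    Ca_base: float = 0.05  # uM ([Ca]_b)
    C_KCa: float = 0.2  # uM, SK half-activation
    hill_KCa: int = 5
    R_c: float = 5e-4  # cm, cell radius
    delta: float = 3e-4  # cm, submembrane shell thickness
    k_pump: float = 1e-2  # cm/s, extrusion rate
    B_T: float = 1.5e2  # uM, total fast buffer
    K_D: float = 1.0  # uM, buffer dissociation constant
    # Physics
    T: float = 298.0  # K
    F: float = FARADAY
    R: float = GAS_CONSTANT
    z_Ca: int = 2
    # Gating specs
    gating: Dict[str, GatingSpec] = field(default_factory=_standard_gating)
    # Variant hooks ------------------------------------------------------
    # Slow delayed-rectifier clone (Kv2-like): same voltage dependence as
    # m_Kdr, time constant scaled by kdrs_tau_factor.  Active iff g_KdrS > 0
    # (adds a 7th state variable m_KdrS).
    g_KdrS: float = 0.0
    kdrs_tau_factor: float = 11.0
    # Freeze h_CaT at a constant value (it leaves the dynamical state).
    h_CaT_frozen: Optional[float] = None
    # Freeze [Ca] at Ca_base (used by the 3-variable subsystem).
    ca_frozen: bool = False

    def __post_init__(self) -> None:
        for name in ("g_Leak", "g_NaV", "g_Kdr", "g_TCN", "g_KCa", "g_KdrS",
                     "P_CaH", "P_CaT", "k_pump", "B_T"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.C <= 0 or self.T <= 0 or self.K_D <= 0 or self.C_KCa <= 0:
            raise ValueError("C, T, K_D and C_KCa must be > 0")
        if not 0 < self.delta < self.R_c:
            raise ValueError("need 0 < delta < R_c")
        if not 0 < self.Ca_base < self.Ca_out:
            raise ValueError("need 0 < Ca_base < Ca_out")
        if self.h_CaT_frozen is not None and not 0 <= self.h_CaT_frozen <= 1:
            raise ValueError("h_CaT_frozen must lie in [0, 1]")
        expected = {"m_NaV", "h_NaV", "m_Kdr", "m_CaH", "m_CaT", "h_CaT"}
        if set(self.gating) != expected:
            raise ValueError(f"gating must define exactly {sorted(expected)}")

    # Convenience --------------------------------------------------------
    def evolve(self, **edits) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **edits)

    @property
    def RT(self) -> float:
        return self.R * self.T

    @property
    def E_Ca_max(self) -> float:
        """Upper calcium Nernst potential (RT/2F) ln(Ca_out/Ca_base), mV."""
        import math

        return 1e3 * self.RT / (self.z_Ca * self.F) * math.log(self.Ca_out / self.Ca_base)

    @property
    def state_names(self) -> tuple:
        if self.g_KdrS > 0:
            return STATE_NAMES + ("m_KdrS",)
        return STATE_NAMES


@dataclass(frozen=True)
class NeuronState:
    """The six (or, with the slow-Kdr variant, seven) state variables."""

    V: float  # mV
    Ca: float  # uM
    h_NaV: float
    m_Kdr: float
    m_CaT: float
    h_CaT: float
    m_KdrS: Optional[float] = None

    def __post_init__(self) -> None:
        if self.Ca <= 0:
            raise ValueError("Ca must be > 0")
        for name in ("h_NaV", "m_Kdr", "m_CaT", "h_CaT"):
            x = getattr(self, name)
            if not 0.0 <= x <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {x}")
        if self.m_KdrS is not None and not 0.0 <= self.m_KdrS <= 1.0:
            raise ValueError("m_KdrS must lie in [0, 1]")

    def as_array(self, n: Optional[int] = None):
        import numpy as np

        base = [self.V, self.Ca, self.h_NaV, self.m_Kdr, self.m_CaT, self.h_CaT]
        if self.m_KdrS is not None or (n is not None and n == 7):
            base.append(self.m_KdrS if self.m_KdrS is not None else 0.0)
        return np.array(base, dtype=float)

    @classmethod
    def from_array(cls, y) -> "NeuronState":
        y = list(map(float, y))
        extra = {"m_KdrS": y[6]} if len(y) == 7 else {}
        return cls(V=y[0], Ca=y[1], h_NaV=y[2], m_Kdr=y[3], m_CaT=y[4],
                   h_CaT=y[5], **extra)


def standard_parameters() -> ModelParameters:
    """The standard published parameter set."""
    return ModelParameters()
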