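"""Model variants and dimensional reductions.

Covers: channel blocks, the h_CaT-as-parameter variant, the slow
delayed-rectifier (Kv2-like) add-on, the +10 mV CaT voltage shift, chloride
reversal variants, the 3-variable {V, m_Kdr, h_NaV} subsystem, and the
planar reductions obtained by replacing one recovery variable with a fitted
power law of the other.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import System, _boltzmann, _tau, build_system, steady_state
from .params import GatingSpec, ModelParameters, standard_parameters

__all__ = [
    "VariantSpec",
    "PowerLawFit",
    "make_variant",
    "preset",
    "PRESETS",
    "make_3d_subsystem",
    "project_spike",
    "fit_power_law",
    "make_2d_subsystem",
    "System2D",
]


# --------------------------------------------------------------------------
# Variant construction
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantSpec:
    """Edits applied on top of a base parameter set.

    ``edits`` entries address parameters by dotted path, e.g.
    ``("P_CaH", 0.0)`` or ``("gating.m_CaT.V_half", -46.0)``.  ``frozen``
    may pin h_CaT to a constant or freeze [Ca] at its baseline.
    """

    edits: Tuple[Tuple[str, object], ...] = ()
    h_CaT_frozen: Optional[float] = None
    ca_frozen: bool = False


def _apply_edit(params: ModelParameters, path: str, value) -> ModelParameters:
    parts = path.split(".")
    if parts[0] == "gating":
        if len(parts) != 3:
            raise KeyError(f"gating edit must be gating.<var>.<field>: {path}")
        _, var, fld = parts
        if var not in params.gating:
            raise KeyError(f"unknown gating variable {var!r}")
        if fld not in GatingSpec.__dataclass_fields__:
            raise KeyError(f"unknown gating field {fld!r}")
        gating = dict(params.gating)
        gating[var] = replace(gating[var], **{fld: value})
        return params.evolve(gating=gating)
    if parts[0] not in ModelParameters.__dataclass_fields__:
        raise KeyError(f"unknown parameter {path!r}")
    return params.evolve(**{parts[0]: value})


def make_variant(spec: VariantSpec,
                 base: Optional[ModelParameters] = None) -> ModelParameters:
    """Parameter set for a variant; usable by every simulate/bifurcation op."""
    p = base if base is not None else standard_parameters()
    for path, value in spec.edits:
        p = _apply_edit(p, path, value)
    if spec.h_CaT_frozen is not None:
        p = p.evolve(h_CaT_frozen=float(spec.h_CaT_frozen))
    if spec.ca_frozen:
        p = p.evolve(ca_frozen=True)
    return p


def _shift_cat(params: ModelParameters, dv: float) -> ModelParameters:
    """Shift every CaT voltage-dependence centre by dv mV (activation and
    inactivation midpoints and both tau centres)."""
    gating = dict(params.gating)
    for var in ("m_CaT", "h_CaT"):
        g = gating[var]
        gating[var] = replace(g, V_half=g.V_half + dv, V_tau1=g.V_tau1 + dv,
                              V_tau2=g.V_tau2 + dv)
    return params.evolve(gating=gating)


PRESETS: Dict[str, VariantSpec] = {
    "standard": VariantSpec(),
    "block_CaH": VariantSpec(edits=(("P_CaH", 0.0),)),
    "block_CaT": VariantSpec(edits=(("P_CaT", 0.0),)),
    "block_NaV": VariantSpec(edits=(("g_NaV", 0.0),)),
    "kdr_slow": VariantSpec(edits=(("g_KdrS", 4.5e3),)),
    "kdr_slow_3.3x": VariantSpec(edits=(("g_KdrS", 3.3 * 4.5e3),)),
    "ecl_-85": VariantSpec(edits=(("E_Cl", -85.0),)),
}


def preset(name: str, base: Optional[ModelParameters] = None) -> ModelParameters:
    """Named variant preset (includes 'cat_shift_+10mV')."""
    if name == "cat_shift_+10mV":
        return _shift_cat(base if base is not None else standard_parameters(),
                          +10.0)
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; known: "
                       f"{sorted(PRESETS) + ['cat_shift_+10mV']}")
    return make_variant(PRESETS[name], base)


def make_3d_subsystem(params: Optional[ModelParameters] = None) -> ModelParameters:
    """The {V, m_Kdr, h_NaV} subsystem: Ca currents removed, [Ca] frozen at
    baseline (the SK current then sits at its ~1e-3 resting open fraction).

    The returned parameter set keeps the 6-variable layout; the frozen
    calcium and the two (now driveless) CaT gates are excluded from
    stability analysis automatically.
    """
    p = params if params is not None else standard_parameters()
    return p.evolve(P_CaH=0.0, P_CaT=0.0, ca_frozen=True)


# --------------------------------------------------------------------------
# Spike-cycle projection and power-law fit
# --------------------------------------------------------------------------

def _resample_arclength(x: np.ndarray, y: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polyline uniformly in (normalized) arclength."""
    ds = np.hypot(np.diff(x), np.diff(y))
    s = np.concatenate([[0.0], np.cumsum(ds)])
    if s[-1] == 0:
        raise ValueError("degenerate curve")
    s /= s[-1]
    si = np.linspace(0.0, 1.0, n, endpoint=False)
    return np.column_stack([np.interp(si, s, x), np.interp(si, s, y)])


def project_spike(traj, n_points: int = 400, min_cycles: int = 3) -> dict:
    """Project the spiking trajectory onto the (m_Kdr, h_NaV) plane.

    Cycles are delimited by spike times; each cycle is resampled uniformly
    in arclength and the point-wise mean over cycles is returned together
    with the individual cycles.
    """
    from .simulate import detect_spikes

    sp = detect_spikes(traj)
    if sp.n < min_cycles + 1:
        raise RuntimeError(f"need >= {min_cycles + 1} spikes, got {sp.n}")
    m = traj.column("m_Kdr")
    h = traj.column("h_NaV")
    cycles = []
    for t0, t1 in zip(sp.spike_times[:-1], sp.spike_times[1:]):
        sel = (traj.t >= t0) & (traj.t <= t1)
        if sel.sum() < 20:
            continue
        cycles.append(_resample_arclength(m[sel], h[sel], n_points))
    if len(cycles) < min_cycles:
        raise RuntimeError("too few usable cycles")
    mean_cycle = np.mean(cycles, axis=0)
    return {"mean": mean_cycle, "cycles": cycles}


@dataclass(frozen=True)
class PowerLawFit:
    """Fit y = a / x**b between the two recovery variables."""

    a: float
    b: float
    residual: float  # RMS residual of log y
    direction: str  # "h_of_m" (h_NaV vs m_Kdr) or "m_of_h"

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("prefactor a must be > 0")

    def __call__(self, x):
        return self.a * x ** (-self.b)


def fit_power_law(curve: np.ndarray, direction: str = "h_of_m") -> PowerLawFit:
    """Ordinary least squares on log-log coordinates of the (mean) cycle.

    ``curve`` is an (n, 2) array of (m_Kdr, h_NaV) points.  direction
    "h_of_m" fits h_NaV = a / m_Kdr**b; "m_of_h" fits m_Kdr = a / h_NaV**b.
    """
    curve = np.asarray(curve, dtype=float)
    if curve.ndim != 2 or curve.shape[1] != 2 or len(curve) < 4:
        raise ValueError("curve must be an (n>=4, 2) array")
    if direction == "h_of_m":
        x, y = curve[:, 0], curve[:, 1]
    elif direction == "m_of_h":
        x, y = curve[:, 1], curve[:, 0]
    else:
        raise ValueError("direction must be 'h_of_m' or 'm_of_h'")
    good = (x > 0) & (y > 0)
    lx, ly = np.log(x[good]), np.log(y[good])
    A = np.column_stack([np.ones_like(lx), -lx])
    coef, *_ = np.linalg.lstsq(A, ly, rcond=None)
    resid = float(np.sqrt(np.mean((A @ coef - ly) ** 2)))
    return PowerLawFit(a=float(np.exp(coef[0])), b=float(coef[1]),
                       residual=resid, direction=direction)


# --------------------------------------------------------------------------
# Planar (2-variable) reductions
# --------------------------------------------------------------------------

class System2D:
    """Two-variable reduction {V, x} of the Ca-free subsystem.

    The eliminated recovery variable is replaced, inside its current, by
    the fitted power law of the retained one (clipped to [0, 1]).  The
    retained variable keeps its own voltage-dependent time constant, or
    the eliminated variable's one when ``tau_source='swapped'``.
    Interface-compatible with the full System for integration, fixed-point
    sweeps and shooting.
    """

    dim = 2

    def __init__(self, params: ModelParameters, retained: str,
                 fit: PowerLawFit, tau_source: str = "matching",
                 drive=(0.0, 0.0, 0.0), reverse: bool = False):
        if retained not in ("h_NaV", "m_Kdr"):
            raise ValueError("retained must be 'h_NaV' or 'm_Kdr'")
        expected = {"h_NaV": "m_of_h", "m_Kdr": "h_of_m"}[retained]
        if fit.direction != expected:
            raise ValueError(f"retained {retained} needs a fit with "
                             f"direction {expected!r}, got {fit.direction!r}")
        if tau_source not in ("matching", "swapped"):
            raise ValueError("tau_source must be 'matching' or 'swapped'")
        self.params = params
        self.retained = retained
        self.fit = fit
        self.tau_source = tau_source
        self.drive = tuple(map(float, drive))
        self.reverse = bool(reverse)
        self.names = ("V", retained)
        self.frozen = np.zeros(2, dtype=bool)
        self.active = np.array([0, 1])
        g = params.gating
        self._own = g[retained]
        self._other = g["m_Kdr" if retained == "h_NaV" else "h_NaV"]
        self._tau_spec = self._own if tau_source == "matching" else self._other
        # constant SK contribution at baseline calcium
        n = params.hill_KCa
        self._wb = params.Ca_base ** n / (params.C_KCa ** n + params.Ca_base ** n)

    # -- core ------------------------------------------------------------

    def _sub(self, x, exp):
        """Eliminated variable from the power law, clipped to [0, 1]."""
        xr = x.real if isinstance(x, complex) else x
        if xr <= 1e-12:
            return 1.0
        val = self.fit.a * x ** (-self.fit.b)
        vr = val.real if isinstance(val, complex) else val
        if vr > 1.0:
            return 1.0
        if vr < 0.0:
            return 0.0
        return val

    def _rhs_core(self, y, exp):
        p = self.params
        V, x = y[0], y[1]
        g = p.gating
        mNa = _boltzmann(V, g["m_NaV"].V_half, g["m_NaV"].slope, 1.0, exp)
        if self.retained == "h_NaV":
            h = x
            mK = self._sub(x, exp)
        else:
            mK = x
            h = self._sub(x, exp)
        I_Na = p.g_NaV * mNa ** 3 * h * (V - p.E_Na)
        I_K = p.g_Kdr * mK ** 4 * (V - p.E_K)
        I_T = p.g_TCN * (V - p.E_TCN)
        I_L = p.g_Leak * (V - p.E_Leak)
        I_KCa = p.g_KCa * self._wb * (V - p.E_K)
        i_const, G, GE = self.drive
        I_S = i_const - G * V + GE
        dV = (I_S - (I_Na + I_K + I_T + I_L + I_KCa)) / p.C
        own = self._own
        inf = _boltzmann(V, own.V_half, own.slope, own.sign, exp)
        ts = self._tau_spec
        tau = _tau(V, ts.tau_base, ts.tau_amp, ts.tau_asym, ts.V_tau1,
                   ts.V_tau2, ts.k_tau1, ts.k_tau2, exp, ts.tau_flip)
        out = [dV, (inf - x) / tau]
        if self.reverse:
            out = [-v for v in out]
        return out

    # -- System-compatible surface ----------------------------------------

    def rhs_autonomous(self, y):
        return np.asarray(self._rhs_core(y, math.exp), dtype=float)

    def rhs(self, t, y):
        return self.rhs_autonomous(y)

    def jacobian(self, y, t=None):
        J = np.empty((2, 2))
        h = 1e-20
        yc = np.asarray(y, dtype=complex)
        for j in range(2):
            yp = yc.copy()
            yp[j] += 1j * h
            col = self._rhs_core(yp, cmath.exp)
            for i in range(2):
                J[i, j] = col[i].imag / h if isinstance(col[i], complex) else 0.0
        return J

    def jac(self, t, y):
        return self.jacobian(y)

    def eigenvalues(self, y):
        return np.linalg.eigvals(self.jacobian(y))

    def with_drive(self, drive) -> "System2D":
        return System2D(self.params, self.retained, self.fit,
                        self.tau_source, drive=drive, reverse=self.reverse)

    def reversed(self) -> "System2D":
        """Time-reversed copy (turns the unstable cycle into an attractor)."""
        return System2D(self.params, self.retained, self.fit, self.tau_source,
                        drive=self.drive, reverse=not self.reverse)

    def equilibrium_state(self, V: float) -> np.ndarray:
        return np.array([V, steady_state(self._own, V)])

    def required_IDC(self, V: float) -> float:
        y = self.equilibrium_state(V)
        i_const, G, GE = self.drive
        dV = self._rhs_core(y, math.exp)[0]
        # dV = (I_S - sum I)/C with current drive; solve for the I_DC that
        # zeroes it instead
        return float(i_const - dV * self.params.C)


def make_2d_subsystem(params: ModelParameters, retained: str,
                      fit: PowerLawFit, tau_source: str = "matching",
                      I_DC: float = 0.0) -> System2D:
    """Build the planar reduction with the given retained variable."""
    return System2D(params, retained, fit, tau_source,
                    drive=(I_DC, 0.0, 0.0))
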