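"""Fixed-point branches, limit cycles, folds and two-parameter scans.

Fixed points are computed exactly by parametrizing the equilibrium branch
by the membrane voltage: at equilibrium every gating variable equals its
steady state, the calcium balance is a closed-form linear solve, and the
tonic current that makes V stationary is simply I_DC(V) = sum of ion
currents.  Saddle-nodes are sign changes of dI_DC/dV and Hopf points are
sign changes of the leading eigenvalue's real part along the branch.

Limit cycles are located by direct simulation (the stable branch is
followed by natural-parameter continuation with reseeding and bisection on
cycle existence, which brackets the folds of limit cycles), and refined by
single-shooting Newton on a Poincare section with free period.  Floquet
multipliers come from the monodromy matrix integrated along the refined
cycle.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, root

from .core import System, build_system
from .params import ModelParameters
from .simulate import (SAMPLE_RATE, Trajectory, default_atol, detect_spikes,
                       integrate, spontaneous_init)
from .stimulus import StimulusProtocol


def _as_system(params) -> System:
    """Accept either a parameter set or a pre-built system (e.g. a planar
    reduction) everywhere a vector field is needed."""
    return build_system(params) if isinstance(params, ModelParameters) else params

__all__ = [
    "FixedPoint",
    "LimitCycleSolution",
    "Branch",
    "find_fixed_point",
    "fp_branch",
    "find_limit_cycle",
    "lc_branch",
    "isola_bounds",
    "two_param_fp_scan",
    "pulse_threshold_curve",
]

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Fixed points
# --------------------------------------------------------------------------

@dataclass
class FixedPoint:
    state: np.ndarray
    I_DC: float
    eigenvalues: np.ndarray  # of the active sub-Jacobian
    stable: bool

    @property
    def V(self) -> float:
        return float(self.state[0])


@dataclass
class Branch:
    kind: str  # "FP" | "LC"
    parameter: str
    points: list
    bifurcations: List[Tuple[str, float]] = field(default_factory=list)


def _fp_from_V(sysm: System, V: float) -> FixedPoint:
    y = sysm.equilibrium_state(V)
    I_DC = sysm.required_IDC(V)
    ev = sysm.with_drive((I_DC, 0.0, 0.0)).eigenvalues(y)
    return FixedPoint(state=y, I_DC=I_DC, eigenvalues=ev,
                      stable=bool(np.all(ev.real < 0)))


def find_fixed_point(params: ModelParameters, I_DC: float, V_guess: float,
                     half_width: float = 10.0) -> FixedPoint:
    """Fixed point with voltage near V_guess at tonic current I_DC."""
    sysm = _as_system(params)
    f = lambda V: sysm.required_IDC(V) - I_DC
    grid = np.linspace(V_guess - half_width, V_guess + half_width, 41)
    vals = np.array([f(v) for v in grid])
    # bracket closest to the guess
    sign_change = np.nonzero(vals[:-1] * vals[1:] <= 0)[0]
    if len(sign_change) == 0:
        raise RuntimeError(f"no fixed point with V in "
                           f"[{grid[0]:.1f}, {grid[-1]:.1f}] at I_DC={I_DC:g}")
    mid = 0.5 * (grid[sign_change] + grid[sign_change + 1])
    i = sign_change[np.argmin(np.abs(mid - V_guess))]
    V0 = brentq(f, grid[i], grid[i + 1], xtol=1e-12, rtol=8.9e-16)
    fp = _fp_from_V(sysm, V0)
    res = np.max(np.abs(sysm.with_drive((I_DC, 0.0, 0.0)).rhs_autonomous(fp.state)))
    if res > 1e-6:
        raise RuntimeError(f"fixed-point residual too large: {res:g}")
    return fp


def fp_branch(params: ModelParameters, I_range: Tuple[float, float],
              V_range: Tuple[float, float] = (-95.0, -20.0),
              n: int = 400) -> Branch:
    """Equilibrium branch with stability flags and SN/Hopf detection.

    The branch is swept in V (it is a graph over V), so folds in I_DC need
    no arclength switching; points outside I_range are dropped after
    bifurcation detection.
    """
    sysm = _as_system(params)
    Vs = np.linspace(V_range[0], V_range[1], n)
    pts = [_fp_from_V(sysm, V) for V in Vs]
    Is = np.array([p.I_DC for p in pts])
    bifs: List[Tuple[str, float]] = []
    dI = np.diff(Is)
    for i in range(1, len(dI)):
        if dI[i - 1] * dI[i] < 0:
            bifs.append(("SN", float(Is[i])))
    lead = np.array([p.eigenvalues.real.max() for p in pts])
    for i in range(1, len(pts)):
        if lead[i - 1] * lead[i] < 0:
            # a real eigenvalue through zero is the saddle-node already
            # caught by the dI/dV sign change; only a complex pair crossing
            # is a Hopf point
            if np.iscomplex(pts[i].eigenvalues[np.argmax(pts[i].eigenvalues.real)]):
                bifs.append(("Hopf", float(0.5 * (Is[i - 1] + Is[i]))))
    lo, hi = min(I_range), max(I_range)
    keep = [p for p in pts if lo <= p.I_DC <= hi]
    bifs = [(k, v) for k, v in bifs if lo <= v <= hi]
    return Branch("FP", "I_DC", keep, bifs)


# --------------------------------------------------------------------------
# Limit cycles: probes and continuation
# --------------------------------------------------------------------------

@dataclass
class CycleProbe:
    fires: bool
    freq: float
    V_min: float
    V_max: float
    end_state: np.ndarray


def probe_cycle(params: ModelParameters, I_DC: float, seed: np.ndarray,
                t_settle: float = 2.5, t_measure: float = 0.5,
                rtol: float = 1e-8) -> CycleProbe:
    """Integrate from seed and report whether sustained spiking persists."""
    traj = integrate(params, StimulusProtocol(I_DC=I_DC), seed,
                     (0.0, t_settle + t_measure), rtol=rtol)
    tail = traj.window(t_settle)
    sp = detect_spikes(tail)
    if sp.n >= 3:
        return CycleProbe(True, sp.mean_frequency(), float(tail.V.min()),
                          float(tail.V.max()), traj.final_state())
    return CycleProbe(False, 0.0, float(tail.V.min()), float(tail.V.max()),
                      traj.final_state())


def lc_branch(params: ModelParameters, I_start: float, direction: int,
              seed: np.ndarray, I_limit: float, step0: float = 50.0,
              step_max: float = 400.0, fold_tol: float = 1.0,
              t_settle: float = 2.5, record: bool = True) -> dict:
    """Follow the stable-cycle branch in I_DC until it folds.

    Natural-parameter stepping with reseeding from the previous cycle;
    on failure the step is halved, so the branch end (fold of limit
    cycles) is bracketed to ``fold_tol`` by bisection on cycle existence.
    Returns the fold current, the cycle frequency just inside the fold,
    and the recorded branch points.
    """
    assert direction in (-1, 1)
    probe0 = probe_cycle(params, I_start, seed, t_settle=t_settle)
    if not probe0.fires:
        raise RuntimeError(f"no stable cycle at I_DC={I_start:g} to continue")
    I_good, good = I_start, probe0
    points = [(I_start, probe0)]
    step = step0
    while step >= fold_tol:
        I_try = I_good + direction * step
        if direction * (I_try - I_limit) > 0:
            I_try = I_limit
        pr = probe_cycle(params, I_try, good.end_state, t_settle=t_settle)
        if pr.fires:
            I_good, good = I_try, pr
            if record:
                points.append((I_try, pr))
            if I_try == I_limit:
                break
            step = min(step * 2.0, step_max)
        else:
            step *= 0.5
    # refine frequency at the fold with a longer measurement
    final = probe_cycle(params, I_good, good.end_state, t_settle=t_settle,
                        t_measure=1.0)
    return {
        "I_fold": I_good,
        "freq_fold": final.freq if final.fires else good.freq,
        "V_min_fold": final.V_min,
        "V_max_fold": final.V_max,
        "end_state": final.end_state,
        "points": points,
        "hit_limit": I_good == I_limit,
    }


def isola_bounds(params: ModelParameters, seed: Optional[np.ndarray] = None,
                 I_seed: float = 0.0, I_min: float = -3e3, I_max: float = 1e4,
                 settle_time: float = 30.0, fold_tol: float = 1.0,
                 t_settle: float = 2.5) -> dict:
    """Fold currents and frequencies bounding the isola of limit cycles.

    The stable-cycle branch is continued down and up in I_DC from a
    converged spontaneous-firing state; 'no isola' is reported if no
    sustained cycle exists at the seeding current.
    """
    if seed is None:
        traj = integrate(params, StimulusProtocol(I_DC=I_seed),
                         spontaneous_init(params), (0.0, settle_time))
        seed = traj.final_state()
        if detect_spikes(traj.window(settle_time - 1.0)).n < 3:
            raise RuntimeError("no isola: spontaneous firing is not "
                               "sustained at the seeding current")
    down = lc_branch(params, I_seed, -1, seed, I_min, fold_tol=fold_tol,
                     t_settle=t_settle)
    up = lc_branch(params, I_seed, +1, seed, I_max, fold_tol=fold_tol,
                   t_settle=t_settle)
    return {
        "I_F1": down["I_fold"], "f_F1": down["freq_fold"],
        "I_F2": up["I_fold"], "f_F2": up["freq_fold"],
        "down": down, "up": up,
    }


# --------------------------------------------------------------------------
# Shooting refinement and Floquet multipliers
# --------------------------------------------------------------------------

@dataclass
class LimitCycleSolution:
    anchor: np.ndarray  # state on the Poincare section
    period: float
    I_DC: float
    floquet_multipliers: np.ndarray  # nontrivial multipliers
    stable: bool
    V_min: float
    V_max: float
    residual: float

    @property
    def frequency(self) -> float:
        return 1.0 / self.period


def _flow(sysm: System, y0: np.ndarray, T: float, rtol: float = 1e-10,
          dense: bool = False):
    atol = default_atol(sysm.dim) * 1e-2
    sol = solve_ivp(sysm.rhs, (0.0, T), y0, method="LSODA", jac=sysm.jac,
                    rtol=rtol, atol=atol, dense_output=dense)
    if not sol.success:
        raise RuntimeError(f"flow integration failed: {sol.message}")
    return sol


def _section_crossings(sysm: System, y0: np.ndarray, t_max: float,
                       V_sec: float) -> Tuple[np.ndarray, np.ndarray]:
    """Times and states of upward V = V_sec crossings."""
    ev = lambda t, y: y[0] - V_sec
    ev.direction = 1.0
    atol = default_atol(sysm.dim) * 1e-2
    sol = solve_ivp(sysm.rhs, (0.0, t_max), y0, method="LSODA", jac=sysm.jac,
                    rtol=1e-10, atol=atol, events=ev)
    if not sol.success:
        raise RuntimeError(f"flow integration failed: {sol.message}")
    return sol.t_events[0], sol.y_events[0]


def find_limit_cycle(params: ModelParameters, I_DC: float, seed: np.ndarray,
                     want: str = "stable", V_sec: float = -40.0,
                     period_hint: Optional[float] = None,
                     t_transient: float = 2.0,
                     max_period: float = 1.0) -> LimitCycleSolution:
    """Refine a limit cycle by single-shooting Newton with free period.

    For ``want='stable'`` the seed is relaxed onto the cycle by simulation
    first; for ``want='unstable'`` the seed must already lie close to the
    saddle cycle (e.g. from a separatrix bisection or a fold) and is used
    directly.  The Poincare section is the plane V = V_sec crossed upward;
    if the seed orbit never crosses it, the plane through the seed's own
    voltage is used instead.
    """
    sysm = _as_system(params).with_drive((I_DC, 0.0, 0.0))

    if want == "stable":
        tr = integrate(params, StimulusProtocol(I_DC=I_DC), seed,
                       (0.0, t_transient))
        y_run = tr.final_state()
    else:
        y_run = np.asarray(seed, dtype=float)

    horizon = 4.0 * (period_hint or 0.1)
    t_ev, y_ev = _section_crossings(sysm, y_run, horizon, V_sec)
    if len(t_ev) < 2:
        V_sec = float(y_run[0])
        t_ev, y_ev = _section_crossings(sysm, y_run, horizon, V_sec)
        if len(t_ev) < 2:
            raise RuntimeError("seed orbit never returns to the section")
    anchor0 = y_ev[-1].copy()
    T0 = float(t_ev[-1] - t_ev[-2])

    free = [i for i in range(sysm.dim) if i != 0 and not sysm.frozen[i]]
    scales = np.maximum(np.abs(anchor0[free]), 1e-3)

    def residual(z):
        y0 = anchor0.copy()
        y0[0] = V_sec
        y0[free] = z[:-1] * scales
        T = z[-1] * T0
        yT = _flow(sysm, y0, T).y[:, -1]
        r = (yT - y0)
        out = np.empty(len(free) + 1)
        out[0] = r[0] / 50.0
        out[1:] = r[free] / scales
        return out

    z0 = np.concatenate([anchor0[free] / scales, [1.0]])
    sol = root(residual, z0, method="hybr",
               options={"xtol": 1e-12, "maxfev": 200 * (len(free) + 1)})
    res = float(np.max(np.abs(sol.fun)))
    if not sol.success and res > 1e-8:
        raise RuntimeError(f"shooting Newton did not converge (residual {res:g})")
    anchor = anchor0.copy()
    anchor[0] = V_sec
    anchor[free] = sol.x[:-1] * scales
    T = float(sol.x[-1] * T0)
    if not 0 < T < max_period:
        raise RuntimeError(f"unphysical period {T:g} s")

    mult = floquet_multipliers(sysm, anchor, T)
    stable = bool(np.all(np.abs(mult) < 1.0))
    dense = _flow(sysm, anchor, T, dense=True)
    ts = np.linspace(0.0, T, 2000)
    Vs = dense.sol(ts)[0]
    return LimitCycleSolution(anchor=anchor, period=T, I_DC=I_DC,
                              floquet_multipliers=mult, stable=stable,
                              V_min=float(Vs.min()), V_max=float(Vs.max()),
                              residual=res)


def floquet_multipliers(sysm: System, anchor: np.ndarray, T: float,
                        rtol: float = 1e-9) -> np.ndarray:
    """Nontrivial Floquet multipliers from the monodromy matrix.

    The variational equations are integrated over one period for the
    active variables only; the multiplier closest to 1 (the trivial one
    along the flow) is removed.
    """
    act = sysm.active
    m = len(act)

    def rhs_var(t, z):
        y = z[:sysm.dim]
        M = z[sysm.dim:].reshape(m, m)
        dy = sysm.rhs_autonomous(y)
        J = sysm.jacobian(y)[np.ix_(act, act)]
        return np.concatenate([dy, (J @ M).ravel()])

    z0 = np.concatenate([anchor, np.eye(m).ravel()])
    sol = solve_ivp(rhs_var, (0.0, T), z0, method="LSODA", rtol=rtol,
                    atol=1e-10)
    if not sol.success:
        raise RuntimeError(f"variational integration failed: {sol.message}")
    M = sol.y[sysm.dim:, -1].reshape(m, m)
    mult = np.linalg.eigvals(M)
    i_triv = int(np.argmin(np.abs(mult - 1.0)))
    return np.delete(mult, i_triv)


# --------------------------------------------------------------------------
# Two-parameter scan in external calcium
# --------------------------------------------------------------------------

def two_param_fp_scan(params: ModelParameters, ca_out_grid: Sequence[float],
                      I_window: Tuple[float, float] = (-1e3, 5e3),
                      n_V: int = 400) -> dict:
    """Stability of the equilibrium branch over a grid of [Ca]_out (uM).

    For each [Ca]_out the full branch is swept and the fixed points whose
    I_DC falls inside I_window are tested for eigenvalue instability.
    Returns the per-grid-point table and the smallest [Ca]_out at which
    the branch carries an unstable fixed point (Hopf onset).
    """
    rows = []
    onset = None
    for ca in ca_out_grid:
        br = fp_branch(params.evolve(Ca_out=float(ca)), I_window, n=n_V)
        n_unst = sum(not p.stable for p in br.points)
        max_re = max((p.eigenvalues.real.max() for p in br.points),
                     default=-np.inf)
        rows.append({"Ca_out": float(ca), "n_unstable": n_unst,
                     "max_real_eig": float(max_re),
                     "bifurcations": br.bifurcations})
        if onset is None and n_unst > 0:
            onset = float(ca)
    return {"table": rows, "hopf_onset": onset}


# --------------------------------------------------------------------------
# Pulse-threshold curves
# --------------------------------------------------------------------------

def _switches(params: ModelParameters, I_DC: float, start: np.ndarray,
              amplitude: float, duration: float, direction: str,
              settle_after: float = 3.0) -> bool:
    """Does a square current pulse of given amplitude/duration switch the
    regime (F->SD or SD->F)?"""
    from .stimulus import PulseSpec

    proto = StimulusProtocol(I_DC=I_DC, pulses=(
        PulseSpec("ideal_current", 0.1, 0.1 + duration, amplitude),))
    traj = integrate(params, proto, start,
                     (0.0, 0.1 + duration + settle_after))
    tail = traj.window(traj.t[-1] - 0.5)
    fires = detect_spikes(tail).n > 0
    return (not fires) if direction == "F->SD" else fires


def pulse_threshold_curve(params: ModelParameters, durations: Sequence[float],
                          direction: str = "F->SD", I_DC: float = 0.0,
                          start: Optional[np.ndarray] = None,
                          amp_lo: float = 0.0, amp_hi: float = -2e4,
                          n_bisect: int = 12,
                          settle_after: float = 3.0) -> List[dict]:
    """Minimum-|amplitude| pulse that triggers the transition, per duration.

    Bisection on the pulse amplitude with the asymptotic regime as the
    oracle.  amp_lo must fail and amp_hi must succeed (else 'no transition'
    is reported for that duration).
    """
    if direction not in ("F->SD", "SD->F"):
        raise ValueError("direction must be 'F->SD' or 'SD->F'")
    if start is None:
        if direction == "F->SD":
            tr = integrate(params, StimulusProtocol(I_DC=I_DC),
                           spontaneous_init(params), (0.0, 30.0))
            start = tr.final_state()
        else:
            fp = find_fixed_point(params, I_DC, -38.0)
            start = fp.state
    out = []
    for d in durations:
        lo, hi = amp_lo, amp_hi
        if _switches(params, I_DC, start, lo, d, direction, settle_after):
            out.append({"duration": d, "threshold": lo, "status": "lo-switches"})
            continue
        if not _switches(params, I_DC, start, hi, d, direction, settle_after):
            out.append({"duration": d, "threshold": None,
                        "status": "no transition"})
            continue
        for _ in range(n_bisect):
            mid = 0.5 * (lo + hi)
            if _switches(params, I_DC, start, mid, d, direction, settle_after):
                hi = mid
            else:
                lo = mid
        out.append({"duration": d, "threshold": hi, "status": "ok"})
    return out
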