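"""Time integration, spike detection and asymptotic-regime classification.

The model is stiff (sub-millisecond spikes riding on second-scale calcium
and h_CaT dynamics), so the default integrator is LSODA with the analytic
(complex-step) Jacobian.  Square stimulus pulses make the vector field
discontinuous in time; the integrator is restarted at every pulse edge
rather than stepping across the discontinuity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .core import System, build_system
from .params import ModelParameters, NeuronState
from .stimulus import StimulusProtocol, breakpoints

__all__ = [
    "Trajectory",
    "SpikeAnnotation",
    "integrate",
    "detect_spikes",
    "classify_regime",
    "settle",
    "spontaneous_init",
    "FixedPointEstimate",
    "LimitCycleEstimate",
]

#: default uniform sampling rate of the stored solution (Hz); 50 kHz gives
#: 20 us resolution, ample for ~1 ms spikes (>= 20 samples per ms).
SAMPLE_RATE = 5e4

SPIKE_THRESHOLD = -20.0  # mV
REFRACTORY = 2e-3  # s


def default_atol(dim: int) -> np.ndarray:
    # V (mV), Ca (uM), gating...
    atol = np.full(dim, 1e-12)
    atol[0] = 1e-6
    atol[1] = 1e-9
    return atol


@dataclass
class Trajectory:
    """Sampled solution of the model under a protocol."""

    t: np.ndarray
    y: np.ndarray  # shape (len(t), dim)
    names: Sequence[str]
    params: ModelParameters
    protocol: StimulusProtocol
    method: str = "LSODA"
    rtol: float = 1e-8
    atol: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def V(self) -> np.ndarray:
        return self.y[:, 0]

    @property
    def Ca(self) -> np.ndarray:
        return self.y[:, 1]

    def column(self, name: str) -> np.ndarray:
        return self.y[:, list(self.names).index(name)]

    def final_state(self) -> np.ndarray:
        return self.y[-1].copy()

    def window(self, t0: float, t1: Optional[float] = None) -> "Trajectory":
        """Sub-trajectory with t in [t0, t1]."""
        if t1 is None:
            t1 = self.t[-1]
        m = (self.t >= t0) & (self.t <= t1)
        return Trajectory(self.t[m], self.y[m], self.names, self.params,
                          self.protocol, self.method, self.rtol, self.atol)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.y, index=pd.Index(self.t, name="t"),
                            columns=list(self.names))

    def write_csv(self, path, currents: bool = False) -> None:
        df = self.to_frame()
        if currents:
            sysm = build_system(self.params)
            cols = {k: [] for k in ("I_NaV", "I_Kdr", "I_TCN", "I_KCa",
                                    "I_Leak", "I_CaH", "I_CaT")}
            for row in self.y:
                cur = sysm.currents(row)
                for k in cols:
                    cols[k].append(getattr(cur, k))
            for k, v in cols.items():
                df[k] = v
        header = (f"# dcnsim trajectory; method={self.method} "
                  f"rtol={self.rtol:g} I_DC={self.protocol.I_DC:g}\n")
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh)


@dataclass
class SpikeAnnotation:
    """Spike times and shape measures extracted from a trajectory."""

    spike_times: np.ndarray  # s, upward threshold crossings
    overshoots: np.ndarray  # mV, local max after each crossing
    undershoots: np.ndarray  # mV, local min before the next crossing
    threshold: float = SPIKE_THRESHOLD

    @property
    def n(self) -> int:
        return len(self.spike_times)

    @property
    def amplitudes(self) -> np.ndarray:
        """Overshoot minus following undershoot, mV (length n-1)."""
        return self.overshoots[:-1] - self.undershoots[:-1]

    @property
    def isis(self) -> np.ndarray:
        return np.diff(self.spike_times)

    @property
    def instantaneous_frequency(self) -> np.ndarray:
        return 1.0 / self.isis

    def mean_frequency(self, duration: Optional[float] = None) -> float:
        """Spike count divided by duration (mean of 1/ISI if duration None)."""
        if duration is not None:
            return self.n / duration
        if self.n < 2:
            return 0.0
        return float(1.0 / np.mean(self.isis))


def spontaneous_init(params: ModelParameters) -> np.ndarray:
    """Conventional initial condition: V = -60 mV, gating at steady state,
    [Ca] at baseline.  For the standard model this lies in the firing basin.
    """
    sysm = build_system(params)
    y = sysm.equilibrium_state(-60.0)
    y[1] = params.Ca_base
    return y


def integrate(params: ModelParameters,
              protocol: StimulusProtocol,
              initial: Union[NeuronState, np.ndarray],
              t_span,
              rtol: float = 1e-8,
              atol: Optional[np.ndarray] = None,
              method: str = "LSODA",
              sample_rate: float = SAMPLE_RATE) -> Trajectory:
    """Integrate the model under the protocol over t_span.

    The integration is restarted at every pulse edge; within a segment the
    active-pulse set (and hence the vector field) is constant in time.
    Gating variables are never clipped inside the solver.
    """
    t0, t1 = map(float, t_span)
    if not t1 > t0:
        raise ValueError("t_span must be increasing")
    # a pre-built system (e.g. a planar reduction) may be passed instead of
    # a parameter set
    sysm = build_system(params) if isinstance(params, ModelParameters) else params
    if atol is None:
        atol = default_atol(sysm.dim)
    y = np.asarray(initial.as_array(sysm.dim) if isinstance(initial, NeuronState)
                   else initial, dtype=float)
    if y.shape != (sysm.dim,):
        raise ValueError(f"initial state must have {sysm.dim} components")

    edges = [t for t in breakpoints(protocol) if t0 < t < t1]
    seg_bounds = [t0] + edges + [t1]
    ts, ys = [], []
    for a, b in zip(seg_bounds[:-1], seg_bounds[1:]):
        drive = protocol.segment_drive(0.5 * (a + b))
        seg = sysm.with_drive(drive)
        n_pts = max(int(round((b - a) * sample_rate)), 2)
        t_eval = np.linspace(a, b, n_pts + 1)
        sol = solve_ivp(seg.rhs, (a, b), y, method=method, jac=seg.jac,
                        rtol=rtol, atol=atol, t_eval=t_eval)
        if not sol.success:
            raise RuntimeError(f"integration failed at t={sol.t[-1]:.6g} s: "
                               f"{sol.message}")
        y = sol.y[:, -1]
        keep = slice(None) if not ts else slice(1, None)
        ts.append(sol.t[keep])
        ys.append(sol.y[:, keep])
    return Trajectory(np.concatenate(ts), np.concatenate(ys, axis=1).T,
                      sysm.names, params, protocol, method, rtol, atol)


def detect_spikes(traj: Trajectory, threshold: float = SPIKE_THRESHOLD,
                  refractory: float = REFRACTORY) -> SpikeAnnotation:
    """Threshold-crossing spike detection with overshoot/undershoot measures."""
    t, V = traj.t, traj.V
    above = V >= threshold
    up = np.nonzero(~above[:-1] & above[1:])[0]
    down = np.nonzero(above[:-1] & ~above[1:])[0]

    spike_t, over, under, up_idx = [], [], [], []
    last = -np.inf
    for i in up:
        # linear interpolation of the crossing time
        tc = t[i] + (threshold - V[i]) * (t[i + 1] - t[i]) / (V[i + 1] - V[i])
        if tc - last < refractory:
            continue
        last = tc
        spike_t.append(tc)
        up_idx.append(i)

    for k, i in enumerate(up_idx):
        j_down = down[down > i]
        j_end = up_idx[k + 1] if k + 1 < len(up_idx) else len(V) - 1
        if len(j_down) and j_down[0] < j_end:
            over.append(V[i:j_down[0] + 2].max())
            under.append(V[j_down[0]:j_end + 1].min())
        else:  # trace ends mid-spike
            over.append(V[i:j_end + 1].max())
            under.append(np.nan)
    return SpikeAnnotation(np.asarray(spike_t), np.asarray(over),
                           np.asarray(under), threshold)


@dataclass
class FixedPointEstimate:
    kind: str
    state: np.ndarray
    V: float
    residual: float


@dataclass
class LimitCycleEstimate:
    kind: str
    period: float
    frequency: float
    V_min: float
    V_max: float
    end_state: np.ndarray


def _polish_fixed_point(sysm: System, I_DC: float, V_near: float,
                        half_width: float = 6.0) -> Optional[FixedPointEstimate]:
    """Locate the fixed point with V within half_width of V_near (if any)."""
    f = lambda V: sysm.required_IDC(V) - I_DC
    grid = np.linspace(V_near - half_width, V_near + half_width, 25)
    vals = [f(v) for v in grid]
    for a, b, fa, fb in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
        if fa == 0.0 or fa * fb < 0:
            V0 = brentq(f, a, b, xtol=1e-12) if fa * fb < 0 else a
            y0 = sysm.equilibrium_state(V0)
            res = float(np.max(np.abs(sysm.with_drive((I_DC, 0, 0)).rhs_autonomous(y0))))
            return FixedPointEstimate("FP", y0, float(V0), res)
    return None


def classify_regime(params: ModelParameters, protocol: StimulusProtocol,
                    initial, horizon: float, rtol: float = 1e-8) -> str:
    """Asymptotic regime after the protocol: 'F', 'SD' or 'undecided'.

    F: spikes occur in the final 0.5 s.  SD: no spikes there and the final
    voltage sits within 2 mV of a fixed point of the autonomous system.
    """
    if horizon < protocol.t_last + 1.0:
        raise ValueError("horizon must leave >= 1 s of free evolution "
                         "after the last pulse")
    traj = integrate(params, protocol, initial, (0.0, horizon), rtol=rtol)
    tail = traj.window(horizon - 0.5)
    if detect_spikes(tail).n > 0:
        return "F"
    V_end = float(np.mean(tail.V[-max(2, int(0.1 * SAMPLE_RATE)):]))
    sysm = build_system(params) if isinstance(params, ModelParameters) else params
    fp = _polish_fixed_point(sysm, protocol.I_DC, V_end)
    if fp is not None and abs(fp.V - V_end) <= 2.0:
        return "SD"
    return "undecided"


def settle(params: ModelParameters, I_DC: float, initial,
           max_time: float = 12.0, rtol: float = 1e-8,
           period_rtol: float = 1e-3):
    """Run the autonomous system to its attractor.

    Returns a FixedPointEstimate (max |rhs| below 1e-9 after Newton polish)
    or a LimitCycleEstimate whose period is stable to ``period_rtol`` over
    the last 5 cycles.  Raises RuntimeError on non-convergence.
    """
    protocol = StimulusProtocol(I_DC=I_DC)
    sysm = build_system(params) if isinstance(params, ModelParameters) else params
    y = np.asarray(initial.as_array(sysm.dim) if isinstance(initial, NeuronState)
                   else initial, dtype=float)
    t_done = 0.0
    chunk = 1.0
    while t_done < max_time:
        traj = integrate(params, protocol, y, (0.0, chunk), rtol=rtol)
        y = traj.final_state()
        t_done += chunk
        sp = detect_spikes(traj)
        if sp.n >= 6:
            isis = sp.isis[-5:]
            if np.ptp(isis) <= period_rtol * np.mean(isis):
                period = float(np.mean(isis))
                tail = traj.window(sp.spike_times[-6], sp.spike_times[-1])
                return LimitCycleEstimate("LC", period, 1.0 / period,
                                          float(tail.V.min()),
                                          float(tail.V.max()), y)
        elif sp.n == 0:
            scale = np.maximum(np.abs(y), 1e-3)
            rel = np.abs(sysm.with_drive((I_DC, 0, 0)).rhs_autonomous(y)) / scale
            if rel.max() < 1e-4:  # near-stationary: polish
                fp = _polish_fixed_point(sysm, I_DC, float(y[0]))
                if fp is not None and abs(fp.V - y[0]) < 2.0:
                    return fp
    raise RuntimeError(f"no attractor reached within {max_time} s "
                       f"(last V={y[0]:.2f} mV)")
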