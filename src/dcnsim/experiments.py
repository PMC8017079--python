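"""Named, reproducible experiments: each figure-level protocol as one call.

Every experiment builds its variant and stimulus from the registry entry,
runs the package's own simulation/continuation machinery, optionally writes
CSV/JSON artifacts, and reports a pass/fail against its registered
qualitative expectation.  All experiments are deterministic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Dict, Optional

import numpy as np

from .bifurcation import (find_fixed_point, fp_branch, isola_bounds,
                          pulse_threshold_curve, two_param_fp_scan)
from .params import ModelParameters, standard_parameters
from .simulate import detect_spikes, integrate, spontaneous_init
from .stimulus import PulseSpec, StimulusProtocol
from .variants import fit_power_law, make_3d_subsystem, preset, project_spike

log = logging.getLogger(__name__)

__all__ = ["run_experiment", "list_experiments", "EXPERIMENTS"]

_F_STATE_CACHE: Dict[tuple, np.ndarray] = {}


def firing_state(params: ModelParameters, settle: float = 15.0) -> np.ndarray:
    """Converged spontaneous-firing state of the given variant (cached)."""
    key = (id(type(params)), json.dumps(sorted(
        (k, str(v)) for k, v in params.__dict__.items()
        if not isinstance(v, dict))), settle)
    if key not in _F_STATE_CACHE:
        traj = integrate(params, StimulusProtocol(0.0),
                         spontaneous_init(params), (0.0, settle))
        if detect_spikes(traj.window(settle - 1.0)).n == 0:
            raise RuntimeError("variant does not fire spontaneously")
        _F_STATE_CACHE[key] = traj.final_state()
    return _F_STATE_CACHE[key].copy()


def _regime(params, proto, y0, horizon=4.0):
    traj = integrate(params, proto, y0, (0.0, horizon))
    tail = traj.window(horizon - 0.5)
    return ("F" if detect_spikes(tail).n > 0 else "SD"), traj


def _pulse(amplitude, t0=0.5, dur=0.3, kind="ideal_current", E_rev=None):
    return StimulusProtocol(0.0, (PulseSpec(kind, t0, t0 + dur, amplitude,
                                            E_rev=E_rev),))


# -- runners ----------------------------------------------------------------

def _run_pulse_from_F(amp, expect):
    def run(out):
        p = standard_parameters()
        yF = firing_state(p)
        regime, traj = _regime(p, _pulse(amp), yF)
        sp = detect_spikes(traj.window(0.8, 2.0))
        basal = detect_spikes(traj.window(0.0, 0.5)).mean_frequency()
        peak = float(sp.instantaneous_frequency.max()) if sp.n > 2 else 0.0
        _write_traj(out, traj)
        return {"regime": regime, "final_V": float(np.mean(traj.V[-500:])),
                "rebound_peak_Hz": peak, "basal_Hz": basal,
                "passed": regime == expect}
    return run


def _run_pulse_from_SD(amp, dur, expect):
    def run(out):
        p = standard_parameters()
        ySD = find_fixed_point(p, 0.0, -38.0).state
        regime, traj = _regime(p, _pulse(amp, dur=dur), ySD)
        _write_traj(out, traj)
        return {"regime": regime, "passed": regime == expect}
    return run


def _run_isola(out):
    p = standard_parameters()
    res = isola_bounds(p, seed=firing_state(p))
    summary = {k: float(res[k]) for k in ("I_F1", "f_F1", "I_F2", "f_F2")}
    summary["passed"] = res["I_F1"] < 0 < res["I_F2"]
    if out:
        rows = [(I, pr.freq, pr.V_min, pr.V_max)
                for br in (res["down"], res["up"]) for I, pr in br["points"]]
        _write_csv(out, "lc_branch.csv", "I_DC,freq,V_min,V_max", rows)
    return summary


def _run_nav_block(out):
    p = standard_parameters().evolve(g_NaV=0.0)
    traj = integrate(p, StimulusProtocol(0.0),
                     firing_state(standard_parameters()), (0.0, 5.0))
    fp = find_fixed_point(p, 0.0, float(traj.V[-1]))
    _write_traj(out, traj)
    return {"V_stable": fp.V, "stable": fp.stable,
            "passed": fp.stable and detect_spikes(traj.window(4.0)).n == 0}


def _run_ca_scan(out):
    p = standard_parameters()
    grid = np.arange(500.0, 2001.0, 20.0)
    res = two_param_fp_scan(p, grid)
    if out:
        rows = [(r["Ca_out"], r["n_unstable"], r["max_real_eig"])
                for r in res["table"]]
        _write_csv(out, "ca_scan.csv", "Ca_out,n_unstable,max_real_eig", rows)
    return {"hopf_onset_uM": res["hopf_onset"],
            "passed": res["hopf_onset"] is not None}


def _run_cah_block(I_DC, expect):
    def run(out):
        p = standard_parameters()
        yF = firing_state(p)
        regime, traj = _regime(p.evolve(P_CaH=0.0), StimulusProtocol(I_DC),
                               yF, horizon=6.0)
        _write_traj(out, traj)
        return {"regime": regime, "passed": regime == expect}
    return run


def _run_cat_block_pulse(out):
    p = standard_parameters().evolve(P_CaT=0.0)
    traj0 = integrate(p, StimulusProtocol(0.0),
                      firing_state(standard_parameters()), (0.0, 8.0))
    regime, traj = _regime(p, _pulse(-3.9e3), traj0.final_state())
    _write_traj(out, traj)
    return {"regime": regime, "passed": regime == "F"}


def _run_threshold_curve(out):
    p = standard_parameters()
    res = pulse_threshold_curve(p, durations=(0.1, 0.2, 0.3),
                                start=firing_state(p), n_bisect=8)
    ths = [r["threshold"] for r in res]
    ok = all(t is not None for t in ths) and all(
        abs(a) >= abs(b) - 1e-9 for a, b in zip(ths, ths[1:]))
    if out:
        _write_csv(out, "threshold_curve.csv", "duration,threshold",
                   [(r["duration"], r["threshold"]) for r in res])
    return {"thresholds": ths, "passed": ok}


def _run_sd_window(out):
    p = standard_parameters()
    ySD = find_fixed_point(p, 0.0, -38.0).state
    fates = {}
    for amp in (-0.3e3, -1e3, -8e3):
        fates[f"{amp:g}"] = _regime(p, _pulse(amp), ySD)[0]
    ok = (fates["-300"] == "SD" and fates["-1000"] == "F"
          and fates["-8000"] == "SD")
    return {"fates": fates, "passed": ok}


def _run_synaptic(variant, g_list, expect_any_switch):
    def run(out):
        base = standard_parameters()
        p = preset(variant) if variant != "standard" else base
        yF = firing_state(p)
        fates = {}
        switched = None
        for g in g_list:
            proto = _pulse(g, kind="conductance", E_rev=p.E_Cl)
            regime, traj = _regime(p, proto, yF)
            fates[f"{g:g}"] = regime
            if regime == "SD" and switched is None:
                switched = (g, traj.final_state())
        result = {"fates": fates}
        if expect_any_switch:
            ok = switched is not None
            if ok:  # a second, moderate pulse must restore firing
                _, ySD = switched
                regime2, _ = _regime(p, _pulse(100.0, kind="conductance",
                                               E_rev=p.E_Cl), ySD)
                result["second_pulse"] = regime2
                ok = regime2 == "F"
        else:
            ok = switched is None
        result["passed"] = ok
        return result
    return run


def _run_3d_cusp(out):
    p3 = make_3d_subsystem()
    res = {}
    for gt in (45.0, 0.0):
        br = fp_branch(p3.evolve(g_TCN=gt), (-3000.0, 8000.0), n=800)
        res[f"g_TCN={gt:g}"] = {"n_SN": sum(k == "SN" for k, _ in
                                            br.bifurcations)}
    res["passed"] = (res["g_TCN=45"]["n_SN"] == 0
                     and res["g_TCN=0"]["n_SN"] == 2)
    return res


def _run_reduction_fits(out):
    p3 = make_3d_subsystem()
    traj = integrate(p3, StimulusProtocol(0.0), spontaneous_init(p3),
                     (0.0, 3.0))
    proj = project_spike(traj.window(1.5))
    fh = fit_power_law(proj["mean"], "h_of_m")
    fm = fit_power_law(proj["mean"], "m_of_h")
    if out:
        _write_csv(out, "projection.csv", "m_Kdr,h_NaV",
                   [tuple(r) for r in proj["mean"]])
    return {"h_of_m": {"a": fh.a, "b": fh.b},
            "m_of_h": {"a": fm.a, "b": fm.b},
            "passed": abs(fh.a - 0.07) / 0.07 < 0.25}


def _run_kdr_slow(factor, out_key):
    def run(out):
        p = standard_parameters().evolve(g_KdrS=factor * 4.5e3)
        y0 = np.append(spontaneous_init(standard_parameters()), 0.0)
        traj = integrate(p, StimulusProtocol(0.0), y0, (0.0, 20.0))
        sp = detect_spikes(traj.window(15.0))
        _write_traj(out, traj)
        return {"frequency_Hz": sp.mean_frequency(), "passed": sp.n > 3}
    return run


# -- artifact helpers -------------------------------------------------------

def _write_traj(out: Optional[Path], traj) -> None:
    if out:
        traj.write_csv(Path(out) / "trajectory.csv")


def _write_csv(out, name, header, rows) -> None:
    if out:
        with open(Path(out) / name, "w") as fh:
            fh.write(header + "\n")
            for r in rows:
                fh.write(",".join(f"{v:.10g}" if isinstance(v, float) else
                                  str(v) for v in r) + "\n")


# -- registry ---------------------------------------------------------------

@dataclass(frozen=True)
class Experiment:
    name: str
    description: str
    runner: Callable

EXPERIMENTS: Dict[str, Experiment] = {}


def _register(name, description, runner):
    EXPERIMENTS[name] = Experiment(name, description, runner)


_register("fig1_A1", "-2 uA/cm2 300 ms pulse from firing: firing resumes",
          _run_pulse_from_F(-2e3, "F"))
_register("fig1_A2", "-2.5 uA/cm2 300 ms pulse: firing resumes with rebound",
          _run_pulse_from_F(-2.5e3, "F"))
_register("fig1_A3", "-3.9 uA/cm2 300 ms pulse: switch to the silent "
          "depolarized state", _run_pulse_from_F(-3.9e3, "SD"))
_register("fig1_D1", "from SD, -0.5 uA/cm2 300 ms pulse returns firing",
          _run_pulse_from_SD(-0.5e3, 0.3, "F"))
_register("fig1_D2", "from SD, a depolarizing pulse (20 uA/cm2, 100 ms) "
          "returns firing", _run_pulse_from_SD(2e4, 0.1, "F"))
_register("fig2_isola", "fold currents and frequencies bounding the isola",
          _run_isola)
_register("fig2_C", "Na-channel block: stable depolarized fixed point",
          _run_nav_block)
_register("fig3_scan", "external-calcium scan for the Hopf onset",
          _run_ca_scan)
_register("fig4_A", "CaH block at zero bias triggers F->SD", _run_cah_block(0.0, "SD"))
_register("fig4_D", "CaH block with 37 nA/cm2 bias does not switch",
          _run_cah_block(37.0, "F"))
_register("fig5_A2", "CaT block abolishes the pulse-triggered F->SD switch",
          _run_cat_block_pulse)
_register("fig5_C", "minimum switching amplitude vs pulse duration",
          _run_threshold_curve)
_register("fig6_B", "SD->F needs an effective amplitude window "
          "(too-large pulses fail)", _run_sd_window)
_register("fig9_A", "inhibitory conductance pulses never switch F->SD "
          "(E_rev=-75 mV)", _run_synaptic("standard",
                                          (100.0, 500.0, 1000.0), False))
_register("fig9_B", "+10 mV CaT shift: a conductance pulse switches F->SD "
          "and a second one restores F",
          _run_synaptic("cat_shift_+10mV", (200.0, 500.0, 1000.0), True))
_register("fig9_C", "E_Cl=-85 mV: conductance pulses switch F<->SD",
          _run_synaptic("ecl_-85", (200.0, 500.0, 1000.0), True))
_register("fig7_B", "tonic-cationic conductance controls saddle-nodes of "
          "the 3D subsystem", _run_3d_cusp)
_register("fig8_fits", "power-law fits of the (m_Kdr, h_NaV) spike projection",
          _run_reduction_fits)
_register("fig10_A2", "slow delayed-rectifier add-on: spontaneous frequency",
          _run_kdr_slow(1.0, "kdr_slow"))


def list_experiments() -> list:
    return [(e.name, e.description) for e in EXPERIMENTS.values()]


def run_experiment(name: str, outdir: Optional[str] = None) -> dict:
    """Run a registered experiment; writes artifacts into outdir if given."""
    if name not in EXPERIMENTS:
        raise KeyError(f"unknown experiment {name!r}; see list_experiments()")
    out = None
    if outdir:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
    result = EXPERIMENTS[name].runner(out)
    result["experiment"] = name
    if out:
        (out / "summary.json").write_text(json.dumps(result, indent=2,
                                                     default=float) + "\n")
    return result
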