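# dcnsim

Simulation and bifurcation analysis of a biophysical model of deep
cerebellar nuclei neurons (DCNn) — the cerebellum's output neurons.
Experiments show that these cells can switch reversibly between two
self-sustained modes: pacemaker firing of fast Na spikes (the **F** state)
and a silent depolarized plateau near −38 mV (the **SD** state). `dcnsim`
implements a six-variable conductance-based model of this
electro-responsiveness and the dynamical-systems tooling to analyse it:
the F state is a **stable limit cycle on an isola** — a closed loop of
periodic solutions in the (I_DC, V) diagram, disconnected from the branch
of fixed points and bounded by two folds of limit cycles — coexisting with
the stable SD fixed point, and square current or synaptic-conductance
pulses move the state across the separatrix between the two basins.

The model (mV, s, nA/cm², µM):

```
C dV/dt     = −(I_NaV + I_Kdr + I_TCN + I_KCa + I_Leak + I_CaH + I_CaT) + I_S
d[Ca]/dt    = shell balance of GHK Ca influx, linear extrusion, fast buffer
dx/dt       = (x∞(V) − x)/τ_x(V)   for x ∈ {h_NaV, m_Kdr, m_CaT, h_CaT}
```

with Hodgkin–Huxley kinetics (`I_NaV = g m∞³ h (V−E_Na)`,
`I_Kdr = g m⁴ (V−E_K)`), a tonic cationic current `I_TCN` (reversal
−34 mV) that stabilizes the SD plateau, an SK-type Ca-gated K current with
Hill gating `[Ca]⁵/(C_KCa⁵+[Ca]⁵)`, and Goldman–Hodgkin–Katz (constant
field) high-threshold (CaH) and transient low-threshold (CaT) calcium
currents. The de-inactivation of CaT by hyperpolarization is what lets
large current pulses switch F→SD, and its absence of de-inactivation at
the spike undershoot is why blocking it leaves pacemaking intact. See
`docs/methods.md` for the full parameter story, including where the
published constant set is internally inconsistent and how this package
resolves it.

Audience: computational neuroscientists and dynamical-systems modellers
who want a tested, scriptable version of this model — its variants
(channel blocks, slow Kv2-like delayed rectifier, CaT voltage shifts,
frozen-h_CaT), its reductions (the 3-variable {V, m_Kdr, h_NaV} subsystem
and the planar power-law reductions), and its bifurcation structure.

## Worked example

```python
import numpy as np
from dcnsim import standard_parameters, StimulusProtocol, PulseSpec
from dcnsim.simulate import integrate, detect_spikes, spontaneous_init
from dcnsim.bifurcation import find_fixed_point

p = standard_parameters()

# settle onto the firing attractor (calcium is slow: ~8 s relaxation)
traj = integrate(p, StimulusProtocol(I_DC=0.0), spontaneous_init(p), (0, 15.0))
sp = detect_spikes(traj.window(10.0))
print(f"spontaneous rate {sp.mean_frequency():.1f} Hz, "
      f"spike amplitude {np.mean(sp.amplitudes):.1f} mV, "
      f"undershoot {np.nanmean(sp.undershoots[:-1]):.1f} mV")

# a -3.9 uA/cm2, 300 ms pulse switches the neuron to the silent state
pulse = StimulusProtocol(0.0, (PulseSpec("ideal_current", 0.5, 0.8, -3.9e3),))
after = integrate(p, pulse, traj.final_state(), (0, 4.5))
print(f"spikes in final 0.5 s: {detect_spikes(after.window(4.0)).n}, "
      f"settled V = {after.V[-1]:.1f} mV")
print(f"SD fixed point: {find_fixed_point(p, 0.0, -38.0).V:.2f} mV")
```

prints

```
spontaneous rate 31.4 Hz, spike amplitude 64.0 mV, undershoot -57.2 mV
spikes in final 0.5 s: 0, settled V = -39.2 mV
SD fixed point: -38.62 mV
```

i.e. a ~31 Hz pacemaker with ~64 mV spikes that the pulse leaves in the
silent depolarized state near −38 mV — while a −2.5 µA/cm² pulse only
produces a transient rebound acceleration and firing resumes.

The same protocols are packaged as named experiments:

```
dcnsim list-experiments
dcnsim experiment fig1_A3        # the pulse-switch protocol above
dcnsim experiment fig2_isola     # continue the cycle branch to both folds
dcnsim simulate --tmax 5 --out traj.csv
dcnsim bifurcate --range -3000:5000 --out outdir/
dcnsim scan2p --ca 500:2000:20 --out scan.csv
```

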