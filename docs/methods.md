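# Methods

`dcnsim` implements a single-compartment conductance-based model of a deep
cerebellar nuclei neuron (DCNn) and the dynamical-systems toolkit needed to
analyse its two coexisting stable states: a spontaneously firing mode (F, a
stable limit cycle of fast Na spikes) and a silent depolarized mode (SD, a
stable fixed point near −38 mV). This note records the model, its unit
system, the places where the published constant set is internally
inconsistent and the choices this package makes there, the numerical
machinery, and what the test suite does and does not establish.

## Model

State variables: membrane potential `V` (mV), free cytosolic calcium
`[Ca]` (µM), and the gating variables `h_NaV`, `m_Kdr`, `m_CaT`, `h_CaT`
(the slow-Kdr variant adds `m_KdrS`). Currents (nA/cm², outward positive):

* `I_NaV = g_NaV · m_NaV∞(V)³ · h_NaV · (V − E_Na)` — fast Na current with
  instantaneous activation (quasi-steady-state approximation).
* `I_Kdr = g_Kdr · m_Kdr⁴ · (V − E_K)` — fast delayed rectifier (Kv3-like).
* `I_TCN = g_TCN · (V − E_TCN)` — tonic cationic current, `E_TCN = −34 mV`;
  it is inward everywhere on the equilibrium branch and is what keeps the
  SD state depolarized.
* `I_KCa = g_KCa · w([Ca]) · (V − E_K)` — SK-type Ca-gated K current with
  instantaneous Hill gating `w = [Ca]⁵ / (C_KCa⁵ + [Ca]⁵)`.
* `I_Leak = g_Leak · (V − E_Leak)`.
* `I_CaH`, `I_CaT` — high-threshold (instantaneous activation, no
  inactivation) and low-threshold transient Ca currents through the
  Goldman–Hodgkin–Katz constant-field relation.

Gating follows `dx/dt = (x∞(V) − x)/τ_x(V)` with Boltzmann steady states
(activation rising, inactivation falling with V) and the standard
single-peaked time constant

```
τ_x(V) = τ_x0 + τ_x1 / ( e^{−(V−V_τ1)/k_τ1} + α_τ e^{+(V−V_τ2)/k_τ2} )
```

whose two exponentials fall and rise with V, so τ peaks between the two
centres and tends to `τ_x0` at ±∞ — the form used by thalamic T-current
models, from which the CaT kinetics here descend. For gates with
`V_τ1 = V_τ2`, `k_τ1 = k_τ2`, `α_τ = 1` the orientation of the ± signs is
irrelevant; for `m_CaT` only this orientation is non-degenerate (the
mirrored one collapses τ_m_CaT to a flat 0.2 ms). For `m_Kdr`
(`α_τ = 0.6`) the orientation is genuinely a choice; the package uses the
mirrored form (`GatingSpec.tau_flip`), placing the τ peak at −36 mV, for
two independent reasons: the opposite orientation destroys the firing
attractor altogether, and the slow-Kdr calibration anchor
(`τ_KdrS = 11 × τ_Kdr = 12 ms` at +12 mV) holds only for this orientation
(11 × 1.0 ms).

Calcium obeys a submembrane-shell balance with a linear
extrusion/uptake term and a fast-buffer denominator:

```
d[Ca]/dt = − [ (I_CaH + I_CaT)·R_c/F + 2k([Ca]−[Ca]_b)(R_c−δ) ]
           / [ δ(2R_c−δ)·(1 + B_T/(K_D(1+10⁻¹¹[Ca]/K_D)²)) ]
```

With the listed constants the buffer denominator is effectively the
constant 151, which makes `[Ca]` the slowest variable of the model:
buffered relaxation time ≈ 8 s. Spontaneous-firing measurements therefore
discard a 10 s transient before measuring the attractor.

## Units and the calcium subsystem

The unit system is mV, s, nA/cm², µS/cm², µM, cm/s. Two identities make
it clean: `C dV/dt = (I_S − ΣI)/C` needs no conversion factor
(µF and µS against mV and nA), and the GHK current

```
I = P · zF · u/(1−e^{−u}) · ([Ca] − e^{−u}[Ca]_o),   u = zFV/RT
```

is exact in nA/cm² with `P` in cm/s and concentrations in µM (the
10⁻⁹ mol/cm³ of a µM cancels the 10⁻⁹ A of a nA). The removable
singularity at V = 0 is handled by a 4th-order series for |u| < 10⁻⁴.
Likewise the shell balance above is dimensionally exact with **no**
numerical prefactor on the current term.

Two constants in the published set are incompatible with the model's own
anchor behaviours under any common reading, and this package deviates from
them deliberately:

* **P_CaH.** The listed 2×10⁻⁴ cm/s gives `I_CaH(−38 mV) ≈ −3.4 µA/cm²`,
  which cannot be balanced at the silent depolarized state: the SD voltage
  (−38 mV) and the TTX voltage (−44.4 mV) are both reproduced by the
  Na/Kdr/TCN/Leak subsystem alone to within a fraction of a millivolt, and
  the equilibrium branch is nearly identical with and without the Ca
  currents — all of which require subthreshold `I_CaH` of order tens of
  nA/cm². The default is the recalibrated `P_CaH = 2.2×10⁻⁵ cm/s`, which
  preserves those anchors while keeping the high-threshold current strong
  enough during spikes for its block to matter (see below). `P_CaT` keeps
  its listed value: the de-inactivated T current must reach µA/cm² scale
  to produce rebound firing and the pulse-triggered F→SD switch.
* **The shell-balance prefactor.** The transcribed balance carries a
  literal 10² on the current term. Retaining it, any configuration with a
  T current strong enough for the transition phenomenology accumulates
  µM-scale `[Ca]`, saturates the SK current and extinguishes the firing
  state within seconds. The physically derived factor is exactly 1 in
  this unit system, and that is what the package uses.

The three constants absent from the published table: `C_KCa = 0.2 µM`
(pinned by the SK open fraction ≈ 10⁻³ at `[Ca] = 50 nM` with Hill
coefficient 5), `[Ca]_b = 0.05 µM` (the baseline reached when the Ca
currents are blocked), and `[Ca]_o = 450 µM`. The last was fixed once by
calibrating against the qualitative transition contract — the −2.5 µA/cm²
pulse must fail to switch F→SD while −3.9 µA/cm² succeeds, blocking the
high-threshold Ca current must switch at zero bias but not at
37 nA/cm², and blocking the T current must abolish the pulse-triggered
switch — together with the SD/TTX voltages. Physiological external
calcium is 1–2 mM; in this implementation those values put the resting
state just past the switch threshold (the −2.5 µA/cm² pulse already
switches), so the working point sits at the low edge. All four constants
are ordinary config fields.

## What the model reproduces, and at what fidelity

At the standard parameter set the model fires spontaneously at 31.4 Hz
(printed: 28.9) with 64 mV spikes (67) and a −57.2 mV undershoot (−58.1);
the SD state sits at −38.6 mV (−38), the TTX state at −43.7 mV (−44.4).
The bistability machinery is quantitatively close and qualitatively exact:
the firing state is an isola of limit cycles bounded by two folds (here at
−131 and +3684 nA/cm², printed −255.3 and +4256, with cycle frequencies
24.7/99.1 Hz vs 17.8/108); between them a stable fixed point, a stable
cycle and an unstable cycle coexist (the unstable cycle is computed
explicitly by separatrix bisection + shooting; its leading Floquet
multiplier exceeds 1). Raising external calcium destabilizes the
equilibrium branch through a Hopf point at 1.16 mM (printed 1.26). The
slow-Kdr (Kv2-like) variant lowers the rate to 26.2 Hz (25.5) at equal
conductance and 20.9 Hz (20) at 3.3×. The residual quantitative offsets
share one root cause — the inconsistent printed Ca/SK constants force a
compromise calibration — and are reported as measured; no tolerance was
widened to cover them.

The reduction chain behaves as published: the Ca-free 3-variable
`{V, m_Kdr, h_NaV}` subsystem keeps the fixed-point branch (to < 1 mV) and
the isola; reducing the tonic cationic conductance bends its equilibrium
branch through a cusp (at ≈ 11.75 µS/cm²) into a two-saddle-node
hysteresis loop at `g_TCN = 0`. The spike cycle projected onto the
`(m_Kdr, h_NaV)` plane is a closed curve with exactly two self-
intersections; ordinary least squares on log–log coordinates of the mean
cycle gives `h_NaV = 0.071/m_Kdr^0.585` and `m_Kdr = 0.0133/h_NaV^1.61`
(printed 0.07/0.65 and 0.0145/1.6). The planar `{V, h_NaV}` reduction is
bistable, its unstable cycle is the separatrix (verified by direct basin
sampling), and swapping in τ_m_Kdr destroys the cycle while leaving the
fixed point untouched. One reduction property disagrees with the printed
account: our `{V, m_Kdr}` reduction does fire repetitively (slow ~10 Hz
oscillations), with either fitted or printed power-law coefficients.

## Numerics

* Integrator: LSODA with the analytic Jacobian, rtol 10⁻⁸ by default,
  per-variable atol (10⁻⁶ mV, 10⁻⁹ µM, 10⁻¹² for gating), uniform 50 kHz
  output sampling; integration restarts at every pulse edge, so each
  segment has a time-constant vector field. Gating variables are never
  clipped inside the solver.
* Jacobian: complex-step differentiation of the (analytic) right-hand
  side, exact to machine precision; validated against central finite
  differences in the tests.
* Fixed points: the equilibrium branch is a graph over V (gating at
  steady state; the calcium balance is affine in `[Ca]`, hence a
  closed-form solve; `I_DC(V) = ΣI` explicit), so branches are swept in V
  with no continuation failures; saddle-nodes are sign changes of
  dI_DC/dV, Hopf points are complex-pair crossings of the active
  sub-Jacobian (frozen variables are excluded from stability).
* Limit cycles: the stable branch is continued in I_DC by
  natural-parameter stepping with reseeding (step halved on failure), so
  each fold of cycles is bracketed by bisection on cycle existence to
  1 nA/cm²; existence probes integrate 2.5 s and ask for spikes in the
  final 0.5 s. Cycles are refined by single-shooting Newton on the
  Poincaré section V = −40 mV (upward), unknowns = off-section state +
  free period, flows at rtol 10⁻¹⁰; Floquet multipliers come from the
  monodromy matrix of the active variables (trivial multiplier removed).
  Unstable cycles are seeded by bisecting the segment between the fixed
  point and a stable-cycle point on basin membership (40 bisections) and
  riding the separatrix for a few turns; typical shooting residuals are
  ~10⁻¹³.
* Pulse-threshold curves: 8–12 bisections on amplitude with the
  asymptotic-regime classifier (spikes in the last 0.5 s vs settling
  within 2 mV of a fixed point) as oracle.
* Problem sizes: spontaneous-firing measurements use 10 s settling + 5 s
  measurement (15 s for the seven-variable slow-Kdr variant); isola
  continuation ≈ 20 probes per direction; the external-calcium scan uses
  a 20 µM grid over 0.5–2.0 mM with 400 V-points per branch.

## Degenerate inputs and edge rules

Conductance pulses require `E_rev` and non-negative amplitude; pulses with
`t_end ≤ t_start` are rejected at construction. Overlapping pulses are
legal (contributions add) and logged. The GHK current rejects non-finite
V and non-positive internal calcium. Frozen state variables (h_CaT as a
parameter; `[Ca]` in the 3-variable subsystem) keep zero derivative, are
pinned inside the RHS, and drop out of stability analysis. The spike
detector uses a −20 mV threshold with a 2 ms refractory period; spikes are
~1 ms wide and ~65 mV tall, so the threshold is far from both extremes.

## Known limitations

* The quantitative offsets listed above (firing rate +9%, fold currents,
  Hopf onset −8%) are intrinsic to the compromise calibration; matching
  all printed numbers simultaneously is impossible under any reading of
  the published constants that we found, and the package favours the
  transition phenomenology.
* The trapping-box argument for `[Ca]` fails on the dynamically
  unreachable corner (hyperpolarized V with fully open, fully
  de-inactivated T channels and `[Ca]` at its ceiling); boundedness is
  asserted on faces with steady-state gating and along trajectories.
* Homoclinic bifurcations are flagged, never certified; cusps are
  reported at grid resolution; criticality of Hopf points is not
  classified.
* The model is isopotential and deterministic: no channel noise, no
  temperature dependence, no dendritic structure.
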