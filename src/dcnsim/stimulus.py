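"""Stimulation protocols: tonic bias current plus square pulses.

The input current is I_S = I_DC + I_phi where the phasic part is a sum of
square pulses gated by two Heaviside step functions of time.  Two pulse
kinds are supported:

* ``ideal_current`` — an ideal current source (infinite internal
  resistance); contributes its amplitude (nA/cm^2) directly, positive
  amplitudes depolarize.
* ``conductance`` — a synaptic-like source with conductance g (uS/cm^2)
  and reversal potential E_rev (mV); contributes -g (V - E_rev), so that
  the membrane is pulled toward E_rev while the pulse is active.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

__all__ = ["PulseSpec", "StimulusProtocol", "input_current", "breakpoints"]

log = logging.getLogger(__name__)

IDEAL = "ideal_current"
CONDUCTANCE = "conductance"


@dataclass(frozen=True)
class PulseSpec:
    kind: str  # ideal_current | conductance
    t_start: float  # s
    t_end: float  # s
    amplitude: float  # nA/cm^2 (ideal) or uS/cm^2 (conductance, >= 0)
    E_rev: float = None  # mV, conductance pulses only

    def __post_init__(self) -> None:
        if self.kind not in (IDEAL, CONDUCTANCE):
            raise ValueError(f"unknown pulse kind {self.kind!r}")
        if not self.t_start < self.t_end:
            raise ValueError("pulse needs t_start < t_end")
        if self.kind == CONDUCTANCE:
            if self.amplitude < 0:
                raise ValueError("conductance amplitude must be >= 0")
            if self.E_rev is None:
                raise ValueError("conductance pulse needs E_rev")

    def active(self, t: float) -> bool:
        return self.t_start <= t < self.t_end


@dataclass(frozen=True)
class StimulusProtocol:
    I_DC: float = 0.0  # nA/cm^2
    pulses: Tuple[PulseSpec, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        pulses = tuple(sorted(self.pulses, key=lambda p: p.t_start))
        object.__setattr__(self, "pulses", pulses)
        for a, b in zip(pulses, pulses[1:]):
            if b.t_start < a.t_end:
                log.warning("overlapping pulses at t=%.4g s", b.t_start)

    @property
    def t_last(self) -> float:
        """End time of the last pulse (0 if there are none)."""
        return max((p.t_end for p in self.pulses), default=0.0)

    def segment_drive(self, t: float) -> Tuple[float, float, float]:
        """Drive coefficients (I_const, G, G*E) for the segment containing t.

        Between breakpoints the active-pulse set is constant, so the total
        input is I_const - G*V + GE with constant coefficients.
        """
        i_const = self.I_DC
        g_tot = 0.0
        ge_tot = 0.0
        for p in self.pulses:
            if p.active(t):
                if p.kind == IDEAL:
                    i_const += p.amplitude
                else:
                    g_tot += p.amplitude
                    ge_tot += p.amplitude * p.E_rev
        return i_const, g_tot, ge_tot


def input_current(t: float, V: float, protocol: StimulusProtocol) -> float:
    """Total input current I_S (nA/cm^2) at time t and membrane voltage V."""
    i_const, g_tot, ge_tot = protocol.segment_drive(t)
    return i_const - g_tot * V + ge_tot


def breakpoints(protocol: StimulusProtocol) -> List[float]:
    """Sorted unique pulse edges; the integrator restarts at each of them."""
    edges = set()
    for p in protocol.pulses:
        edges.add(p.t_start)
        edges.add(p.t_end)
    return sorted(edges)
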