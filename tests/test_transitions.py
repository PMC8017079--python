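"""State transitions between firing (F) and silent depolarized (SD) modes."""

import numpy as np
import pytest

from dcnsim import PulseSpec, StimulusProtocol, standard_parameters
from dcnsim.simulate import detect_spikes, integrate


@pytest.fixture(scope="module")
def p():
    return standard_parameters()


def pulse_proto(amp, dur=0.3, t0=0.5, kind="ideal_current", E_rev=None):
    return StimulusProtocol(0.0, (PulseSpec(kind, t0, t0 + dur, amp,
                                            E_rev=E_rev),))


def regime_after(p, proto, y0, horizon=4.5):
    traj = integrate(p, proto, y0, (0.0, horizon))
    return ("F" if detect_spikes(traj.window(horizon - 0.5)).n > 0 else "SD",
            traj)


class TestPulsesFromFiring:
    def test_moderate_pulses_do_not_switch(self, p, firing_state):
        for amp in (-2e3, -2.5e3):
            regime, _ = regime_after(p, pulse_proto(amp), firing_state)
            assert regime == "F", f"pulse {amp} should not switch"

    def test_large_pulse_switches_to_sd(self, p, firing_state, sd_fp):
        regime, traj = regime_after(p, pulse_proto(-3.9e3), firing_state)
        assert regime == "SD"
        assert np.mean(traj.V[-2000:]) == pytest.approx(sd_fp.V, abs=1.5)

    def test_rebound_after_moderate_pulse(self, p, firing_state):
        _, traj = regime_after(p, pulse_proto(-2.5e3), firing_state)
        basal = detect_spikes(traj.window(0.0, 0.5)).mean_frequency()
        reb = detect_spikes(traj.window(0.8, 1.6))
        assert reb.n > 2
        assert reb.instantaneous_frequency.max() > 1.3 * basal

    def test_calcium_dips_during_pulse_and_recovers(self, p, firing_state):
        _, traj = regime_after(p, pulse_proto(-2.5e3), firing_state)
        ca_before = traj.window(0.3, 0.5).Ca.mean()
        ca_during = traj.window(0.75, 0.8).Ca.min()
        ca_after = traj.window(0.8, 1.4).Ca.max()
        assert ca_during < ca_before  # hyperpolarization shuts Ca influx
        assert ca_after > ca_during  # rebound calcium influx at break


class TestPulsesFromSilent:
    def test_hyperpolarizing_window(self, p, sd_fp):
        # an effective amplitude window: too small and too large both fail
        fates = {}
        for amp in (-0.3e3, -1e3, -8e3):
            fates[amp], _ = regime_after(p, pulse_proto(amp), sd_fp.state)
        assert fates[-0.3e3] == "SD"
        assert fates[-1e3] == "F"
        assert fates[-8e3] == "SD"

    def test_depolarizing_pulse_also_switches(self, p, sd_fp):
        regime, _ = regime_after(p, pulse_proto(2e4, dur=0.1), sd_fp.state)
        assert regime == "F"

    def test_transition_reversibility(self, p, firing_state):
        """F -> SD by the large hyperpolarizing pulse, then back to F."""
        regime, traj = regime_after(p, pulse_proto(-3.9e3), firing_state)
        assert regime == "SD"
        regime2, _ = regime_after(p, pulse_proto(-1e3), traj.final_state())
        assert regime2 == "F"


class TestChannelBlocks:
    def test_cah_block_switches_at_zero_bias_only(self, p, firing_state):
        pb = p.evolve(P_CaH=0.0)
        regime0, _ = regime_after(pb, StimulusProtocol(0.0), firing_state,
                                  horizon=6.0)
        assert regime0 == "SD"
        regime37, _ = regime_after(pb, StimulusProtocol(37.0), firing_state,
                                   horizon=6.0)
        assert regime37 == "F"

    def test_cat_block_abolishes_pulse_switch(self, p, firing_state):
        pb = p.evolve(P_CaT=0.0)
        # let the blocked model settle on its own firing attractor first
        traj = integrate(pb, StimulusProtocol(0.0), firing_state, (0.0, 8.0))
        assert detect_spikes(traj.window(7.0)).n > 3
        regime, _ = regime_after(pb, pulse_proto(-3.9e3), traj.final_state())
        assert regime == "F"

    def test_both_ca_blocked_reaches_silent_state_near_minus38(self, p,
                                                               firing_state):
        pb = p.evolve(P_CaH=0.0, P_CaT=0.0)
        traj = integrate(pb, StimulusProtocol(0.0), firing_state, (0.0, 6.0))
        tail = traj.window(5.5)
        assert detect_spikes(tail).n == 0
        assert np.mean(tail.V) == pytest.approx(-38.0, abs=1.5)


class TestSynapticPulses:
    def test_inhibitory_conductance_cannot_switch_standard(self, p,
                                                           firing_state):
        for g in (100.0, 500.0, 1000.0):
            proto = pulse_proto(g, kind="conductance", E_rev=p.E_Cl)
            regime, _ = regime_after(p, proto, firing_state)
            assert regime == "F", f"g={g} should not switch the standard model"

    def test_cat_shift_makes_synaptic_switch_possible(self, firing_state):
        from dcnsim.variants import preset

        ps = preset("cat_shift_+10mV")
        traj = integrate(ps, StimulusProtocol(0.0), firing_state, (0.0, 8.0))
        assert detect_spikes(traj.window(7.0)).n > 3
        yF = traj.final_state()
        proto = pulse_proto(500.0, kind="conductance", E_rev=ps.E_Cl)
        regime, traj2 = regime_after(ps, proto, yF)
        assert regime == "SD"
        # a second, moderate pulse restores firing (the pulses that switch
        # back have smaller amplitude, as for injected current pulses)
        proto2 = pulse_proto(100.0, kind="conductance", E_rev=ps.E_Cl)
        regime2, _ = regime_after(ps, proto2, traj2.final_state())
        assert regime2 == "F"

    def test_low_chloride_reversal_behaves_like_the_shift(self, firing_state):
        from dcnsim.variants import preset

        pe = preset("ecl_-85")
        proto = pulse_proto(500.0, kind="conductance", E_rev=pe.E_Cl)
        regime, traj2 = regime_after(pe, proto, firing_state)
        assert regime == "SD"
        proto2 = pulse_proto(100.0, kind="conductance", E_rev=pe.E_Cl)
        regime2, _ = regime_after(pe, proto2, traj2.final_state())
        assert regime2 == "F"
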