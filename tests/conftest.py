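"""Shared fixtures.

The expensive objects (a converged spontaneous-firing state, the isola
bounds, the 3-variable projection fits) are computed once per session and
shared across unit, property and acceptance tests.
"""

import numpy as np
import pytest

from dcnsim import standard_parameters, StimulusProtocol
from dcnsim.bifurcation import find_fixed_point, isola_bounds
from dcnsim.simulate import detect_spikes, integrate, spontaneous_init
from dcnsim.variants import fit_power_law, make_3d_subsystem, project_spike

#: settling time used before measuring the firing attractor; calcium is the
#: slowest variable (~8 s relaxation), so spontaneous-firing measurements
#: discard a 10 s transient (see docs/methods.md).
SETTLE = 12.0


@pytest.fixture(scope="session")
def std():
    return standard_parameters()


@pytest.fixture(scope="session")
def firing_state(std):
    """State on the firing attractor at zero bias."""
    traj = integrate(std, StimulusProtocol(0.0), spontaneous_init(std),
                     (0.0, SETTLE))
    assert detect_spikes(traj.window(SETTLE - 1.0)).n > 3
    return traj.final_state()


@pytest.fixture(scope="session")
def spont(std, firing_state):
    """A 5 s steady spontaneous-firing trajectory and its spike annotation."""
    traj = integrate(std, StimulusProtocol(0.0), firing_state, (0.0, 5.0))
    return traj, detect_spikes(traj)


@pytest.fixture(scope="session")
def sd_fp(std):
    """The silent depolarized fixed point at zero bias."""
    return find_fixed_point(std, 0.0, -38.0)


@pytest.fixture(scope="session")
def isola(std, firing_state):
    """Fold currents and frequencies of the isola of limit cycles."""
    return isola_bounds(std, seed=firing_state)


@pytest.fixture(scope="session")
def projection_fits(std):
    """Spike projection of the 3-variable subsystem and its power-law fits."""
    p3 = make_3d_subsystem(std)
    traj = integrate(p3, StimulusProtocol(0.0), spontaneous_init(p3),
                     (0.0, 3.0))
    proj = project_spike(traj.window(1.5))
    return {
        "proj": proj,
        "h_of_m": fit_power_law(proj["mean"], "h_of_m"),
        "m_of_h": fit_power_law(proj["mean"], "m_of_h"),
        "traj": traj,
    }
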