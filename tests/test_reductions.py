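"""Model variants, the 3-variable subsystem and the planar reductions."""

import numpy as np
import pytest

from dcnsim import StimulusProtocol, standard_parameters
from dcnsim.bifurcation import find_fixed_point, fp_branch
from dcnsim.simulate import detect_spikes, integrate, spontaneous_init
from dcnsim.variants import (PowerLawFit, VariantSpec, fit_power_law,
                             make_2d_subsystem, make_3d_subsystem,
                             make_variant, preset, project_spike)


@pytest.fixture(scope="module")
def p():
    return standard_parameters()


class TestVariants:
    def test_block_presets_zero_the_right_channel(self, p):
        assert preset("block_CaH").P_CaH == 0.0
        assert preset("block_CaT").P_CaT == 0.0
        assert preset("block_NaV").g_NaV == 0.0
        assert preset("kdr_slow").g_KdrS == p.g_Kdr

    def test_dotted_path_edits(self, p):
        v = VariantSpec(edits=(("gating.m_CaT.V_half", -46.0),
                               ("g_TCN", 30.0)))
        q = make_variant(v, p)
        assert q.gating["m_CaT"].V_half == -46.0
        assert q.g_TCN == 30.0
        assert p.gating["m_CaT"].V_half == -56.0  # base untouched

    def test_unknown_path_rejected(self, p):
        with pytest.raises(KeyError):
            make_variant(VariantSpec(edits=(("no_such", 1.0),)), p)
        with pytest.raises(KeyError):
            make_variant(VariantSpec(edits=(("gating.m_CaT.bogus", 1.0),)), p)

    def test_cat_shift_moves_all_four_centres(self, p):
        q = preset("cat_shift_+10mV", p)
        for var in ("m_CaT", "h_CaT"):
            assert q.gating[var].V_half == p.gating[var].V_half + 10.0
            assert q.gating[var].V_tau1 == p.gating[var].V_tau1 + 10.0
            assert q.gating[var].V_tau2 == p.gating[var].V_tau2 + 10.0

    def test_slow_kdr_reduces_spontaneous_frequency(self, p, spont):
        _, sp = spont
        f0 = sp.mean_frequency()
        pS = preset("kdr_slow")
        y0 = np.append(spontaneous_init(p), 0.0)
        traj = integrate(pS, StimulusProtocol(0.0), y0, (0.0, 18.0))
        w = detect_spikes(traj.window(13.0))
        assert w.n > 3
        assert w.mean_frequency() < 0.92 * f0


class Test3DSubsystem:
    def test_fp_branch_nearly_identical_to_standard(self, p, sd_fp):
        p3 = make_3d_subsystem(p)
        fp3 = find_fixed_point(p3, 0.0, -38.0)
        assert fp3.V == pytest.approx(sd_fp.V, abs=1.0)
        assert fp3.stable
        # three active variables only
        assert len(fp3.eigenvalues) == 5  # V, hNaV, mKdr + two idle CaT gates

    def test_fires_spontaneously(self, p):
        p3 = make_3d_subsystem(p)
        traj = integrate(p3, StimulusProtocol(0.0), spontaneous_init(p3),
                         (0.0, 3.0))
        assert detect_spikes(traj.window(2.0)).n > 30
        assert np.allclose(traj.Ca, p.Ca_base)  # frozen calcium

    def test_cusp_appears_as_gtcn_is_reduced(self):
        p3 = make_3d_subsystem()
        n_sn = {}
        for gt in (45.0, 11.75, 0.0):
            br = fp_branch(p3.evolve(g_TCN=gt), (-3000.0, 8000.0), n=800)
            n_sn[gt] = sum(k == "SN" for k, _ in br.bifurcations)
        assert n_sn[45.0] == 0
        assert n_sn[0.0] == 2  # hysteresis loop between two saddle-nodes
        assert n_sn[11.75] >= n_sn[45.0]


@pytest.fixture(scope="module")
def proj(projection_fits):
    return projection_fits


@pytest.fixture(scope="module")
def s2h(p, projection_fits):
    return make_2d_subsystem(p, "h_NaV", projection_fits["m_of_h"])


class TestProjection:
    def test_curve_inside_unit_square(self, proj):
        mean = proj["proj"]["mean"]
        assert (mean >= 0.0).all() and (mean <= 1.0).all()

    def test_cycle_to_cycle_consistency(self, proj):
        cycles = proj["proj"]["cycles"]
        ref = proj["proj"]["mean"]
        scale = np.ptp(ref, axis=0)
        for c in cycles:
            assert np.max(np.abs(c - ref) / scale) < 0.08

    def test_projection_has_two_double_points(self, proj):
        """The projected cycle self-intersects exactly twice."""
        c = proj["proj"]["mean"]
        # normalize coordinates so segment intersection is well-conditioned
        c = (c - c.min(axis=0)) / np.ptp(c, axis=0)
        n = len(c)
        seg = np.array([c, np.roll(c, -1, axis=0)]).transpose(1, 0, 2)

        def cross2(u, v):
            return u[0] * v[1] - u[1] * v[0]

        def intersects(a0, a1, b0, b1):
            d1 = cross2(a1 - a0, b0 - a0)
            d2 = cross2(a1 - a0, b1 - a0)
            d3 = cross2(b1 - b0, a0 - b0)
            d4 = cross2(b1 - b0, a1 - b0)
            return (d1 * d2 < 0) and (d3 * d4 < 0)

        count = 0
        for i in range(n):
            for j in range(i + 2, n):
                if i == 0 and j == n - 1:
                    continue
                if intersects(seg[i, 0], seg[i, 1], seg[j, 0], seg[j, 1]):
                    count += 1
        assert count == 2

    def test_power_law_exact_recovery(self):
        x = np.linspace(0.05, 0.7, 200)
        y = 0.1 / x ** 1.2
        fit = fit_power_law(np.column_stack([x, y]), "h_of_m")
        assert fit.a == pytest.approx(0.1, abs=1e-6)
        assert fit.b == pytest.approx(1.2, abs=1e-6)
        assert fit.residual < 1e-12

    def test_fit_directions_are_distinct(self, proj):
        fh, fm = proj["h_of_m"], proj["m_of_h"]
        assert fh.direction == "h_of_m" and fm.direction == "m_of_h"
        # OLS in the two directions gives different exponents on a noisy cloud
        assert fm.b != pytest.approx(1.0 / fh.b, rel=1e-3)


class TestPlanarReductions:
    def test_retained_h_keeps_bistability(self, s2h):
        fp = find_fixed_point(s2h, 0.0, -46.0)
        assert fp.stable
        traj = integrate(s2h, StimulusProtocol(0.0), np.array([-60.0, 0.6]),
                         (0.0, 3.0))
        assert detect_spikes(traj.window(2.0)).n > 20

    def test_swapped_tau_loses_the_cycle_but_not_the_fixed_point(
            self, p, projection_fits, s2h):
        s2s = make_2d_subsystem(p, "h_NaV", projection_fits["m_of_h"],
                                tau_source="swapped")
        fp = find_fixed_point(s2h, 0.0, -46.0)
        fp_s = find_fixed_point(s2s, 0.0, -46.0)
        assert fp_s.V == pytest.approx(fp.V, abs=1e-6)  # FP branch unchanged
        for x0 in (0.3, 0.6, 0.9):
            traj = integrate(s2s, StimulusProtocol(0.0),
                             np.array([-60.0, x0]), (0.0, 3.0))
            assert detect_spikes(traj.window(2.0)).n == 0

    def test_unstable_cycle_separates_the_plane(self, p, projection_fits,
                                                s2h):
        from dcnsim.bifurcation import find_limit_cycle

        fp = find_fixed_point(s2h, 0.0, -46.0)
        rev = s2h.reversed()
        tr = integrate(rev, StimulusProtocol(0.0),
                       fp.state + np.array([3.0, 0.01]), (0.0, 2.0))
        lc = find_limit_cycle(s2h, 0.0, tr.final_state(), want="unstable",
                              V_sec=float(tr.final_state()[0]),
                              period_hint=0.025)
        assert not lc.stable
        assert np.abs(lc.floquet_multipliers).max() > 1.0
        # inside the orbit -> fixed point; outside -> stable cycle
        inside = fp.state + 0.5 * (lc.anchor - fp.state)
        outside = fp.state + 1.2 * (lc.anchor - fp.state)
        tr_in = integrate(s2h, StimulusProtocol(0.0), inside, (0.0, 3.0))
        tr_out = integrate(s2h, StimulusProtocol(0.0), outside, (0.0, 3.0))
        assert detect_spikes(tr_in.window(2.5)).n == 0
        assert abs(tr_in.V[-1] - fp.V) < 0.5
        assert detect_spikes(tr_out.window(2.5)).n > 10

    def test_inconsistent_fit_pairing_rejected(self, p, projection_fits):
        with pytest.raises(ValueError):
            make_2d_subsystem(p, "h_NaV", projection_fits["h_of_m"])
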