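"""Electrophysiology layer: limits, Nernst/GHK, firing-rate reduction."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scnsim.electro import (
    chloride_in,
    conductance_Ca,
    conductance_K,
    conductance_KCa,
    excitatory_conductance,
    firing_rate,
    gaba_release,
    membrane_resistance,
    nernst,
    permeability_K,
    resting_potential,
    snapshot,
)
from scnsim.params import BODY_TO_ROOM, MembraneParams, rt_over_f

P = MembraneParams()


class TestConductances:
    def test_potassium_basal_and_saturation_limits(self):
        assert conductance_K(0.0, P) == pytest.approx(9.7)
        assert conductance_K(1e9, P) == pytest.approx(P.g_Ko + P.v_gk, rel=1e-6)

    def test_calcium_conductance_monotone_in_per_mrna(self):
        vals = [conductance_Ca(m, P) for m in [0.0, 0.5, 1.0, 2.0, 4.0]]
        assert vals[0] == 0.0
        assert all(a < b for a, b in zip(vals, vals[1:]))
        assert vals[-1] < P.v_Ca

    def test_bk_conductance_maximal_when_cry_low(self):
        assert conductance_KCa(0.0, P) == pytest.approx(P.v_KCa)
        assert conductance_KCa(10.0, P) < conductance_KCa(1.0, P)

    def test_excitatory_ampa_term_vanishes_at_zero_sodium_current(self):
        g0 = excitatory_conductance(0.0, 0.15, P)
        # only the NMDA branch remains: v_ex2 / (1 + K_ex2 * Ca)
        assert g0 == pytest.approx(P.v_ex2 / (1.0 + P.K_ex2 * 0.15))

    def test_nmda_term_monotone_decreasing_in_calcium(self):
        g1 = excitatory_conductance(3.0, 0.1, P)
        g2 = excitatory_conductance(3.0, 0.2, P)
        assert g2 < g1

    def test_negative_inputs_rejected(self):
        for fn in (conductance_K, conductance_Ca, conductance_KCa):
            with pytest.raises(ValueError):
                fn(-1.0, P)


class TestSynapticChemistry:
    def test_gaba_baseline_without_vip(self):
        assert gaba_release(0.0, P) == pytest.approx(P.GABA_o)

    def test_gaba_saturates_at_basal_plus_max(self):
        assert gaba_release(1e9, P) == pytest.approx(
            P.GABA_o + P.v_GABA, rel=1e-6)

    def test_chloride_gaba_free_limit(self):
        # negative-power saturation -> v_Cl2 as GABA -> 0 (convergence is
        # slow, ~GABA^0.2, so probe very deep into the limit)
        lo = chloride_in(1.0, 0.0, P)
        near = chloride_in(1.0, 1e-30, P)
        assert lo == pytest.approx(near, rel=1e-4)
        assert lo == pytest.approx(P.Cl_o + P.v_Cl2
                                   + P.v_Cl1 * 1.0 / (P.K_Cl1 + 1.0))

    def test_chloride_decreasing_in_gaba(self):
        cl = [chloride_in(2.0, g, P) for g in [0.2, 1.0, 5.0, 20.0]]
        assert all(a > b for a, b in zip(cl, cl[1:]))


class TestNernstGHK:
    def test_nernst_symmetry_and_valence(self):
        assert nernst(10.0, 10.0, 1, 37.0) == pytest.approx(0.0)
        e_plus = nernst(20.0, 2.0, 1, 37.0)
        assert nernst(20.0, 2.0, -1, 37.0) == pytest.approx(-e_plus)
        assert nernst(20.0, 2.0, 2, 37.0) == pytest.approx(e_plus / 2.0)

    def test_nernst_rejects_nonpositive_concentration(self):
        with pytest.raises(ValueError):
            nernst(0.0, 1.0, 1, 37.0)

    def test_ghk_reduces_to_monovalent_ghk_without_calcium(self):
        """With P_Ca -> 0 the implicit flux balance equals the closed-form
        monovalent GHK potential (independent oracle)."""
        p = MembraneParams(P_Ca=1e-15)
        vt = rt_over_f(p.T)
        E_K = p.E_K_room * BODY_TO_ROOM
        E_Na = p.E_Na_room * BODY_TO_ROOM
        K_in = p.K_ex * math.exp(-E_K / vt)
        Na_in = p.Na_ex * math.exp(-E_Na / vt)
        for P_K, Cl_in in [(0.3, 10.0), (0.5, 15.0), (0.8, 19.0)]:
            v = resting_potential(P_K, Cl_in, 0.15, p)
            expected = vt * math.log(
                (P_K * p.K_ex + p.P_Na * p.Na_ex + p.P_Cl * Cl_in)
                / (P_K * K_in + p.P_Na * Na_in + p.P_Cl * p.Cl_ex))
            assert v == pytest.approx(expected, abs=1e-6)

    def test_ghk_single_ion_limit_recovers_nernst(self):
        p = MembraneParams(P_Na=1e-15, P_Cl=1e-15, P_Ca=1e-15)
        v = resting_potential(0.5, 15.0, 0.15, p)
        assert v == pytest.approx(p.E_K_room * BODY_TO_ROOM, abs=1e-5)

    def test_degenerate_ghk_rejected(self):
        with pytest.raises(ValueError):
            resting_potential(0.0, 15.0, 0.15, P)

    def test_permeability_maximal_when_bmal1_low(self):
        assert permeability_K(0.0, P) == pytest.approx(P.v_PK)
        assert permeability_K(3.0, P) < permeability_K(1.0, P)


class TestFiringRate:
    def test_subthreshold_returns_zero_not_error(self):
        assert firing_rate(RI=-30.0, V_reset=-26.5, theta=-10.5, tau_m=0.1) == 0.0
        # exactly at threshold: infinite time to spike
        assert firing_rate(RI=-10.5, V_reset=-26.5, theta=-10.5, tau_m=0.1) == 0.0

    def test_closed_form_value(self):
        # f = 1 / (tau * ln((RI - Vres)/(RI - theta)))
        f = firing_rate(RI=0.0, V_reset=-26.5, theta=-10.5, tau_m=0.1)
        assert f == pytest.approx(1.0 / (0.1 * math.log(26.5 / 10.5)))

    @settings(max_examples=50, deadline=None)
    @given(ri=st.floats(-10.0, 40.0), ri2=st.floats(-10.0, 40.0))
    def test_monotone_in_drive(self, ri, ri2):
        lo, hi = sorted([ri, ri2])
        f_lo = firing_rate(lo, -26.5, -10.5, 0.1)
        f_hi = firing_rate(hi, -26.5, -10.5, 0.1)
        assert f_hi >= f_lo


class TestSnapshot:
    def args(self):
        return dict(MP=2.0, CC=6.0, BC=2.2, Ca_eff=0.15, VIP_eff=0.2)

    def test_reconstruction_identities(self):
        s = snapshot(params=P, **self.args())
        g_sum = s.g_ex + s.g_GABA + s.g_Na + s.g_Ca + s.g_K + s.g_KCa + s.g_L
        assert s.R_star == pytest.approx(1.0 / g_sum)
        assert s.tau_m == pytest.approx(s.R_star * P.C_m)
        i_star = (s.g_ex * P.E_ex + s.g_GABA * s.E_GABA
                  + s.g_Na * s.E_Na + s.g_Ca * s.E_Ca
                  + s.g_K * s.E_K + s.g_KCa * s.E_K + s.g_L * s.E_L)
        assert s.I_star == pytest.approx(i_star)
        assert s.g_L == pytest.approx(1.0 / s.R)

    def test_injected_current_raises_firing(self):
        s0 = snapshot(params=P, **self.args())
        s1 = snapshot(params=P, I_app=200.0, **self.args())
        assert s1.f_r > s0.f_r
        assert s1.I_star - s0.I_star == pytest.approx(200.0)

    def test_nimodipine_zeroes_ltype_conductance(self):
        s = snapshot(params=P, nimodipine=True, **self.args())
        assert s.g_Ca == 0.0
        assert s.I_Ca == 0.0

    def test_currents_evaluated_at_resting_potential(self):
        s = snapshot(params=P, **self.args())
        assert s.I_K == pytest.approx(s.g_K * (s.V_rest - s.E_K))
        assert s.I_inhib == pytest.approx(s.g_GABA * (s.V_rest - s.E_GABA))
        assert s.I_Na < 0  # inward at rest
        assert s.I_K > 0   # outward at rest

    def test_gaba_scaling_hooks(self):
        s_block = snapshot(params=P, gaba_scale=0.0, **self.args())
        assert s_block.GABA == 0.0
        s_add = snapshot(params=P, gaba_add=5.0, **self.args())
        s0 = snapshot(params=P, **self.args())
        assert s_add.GABA == pytest.approx(s0.GABA + 5.0)
        # less chloride accumulation and a more negative reversal under GABA
        assert s_add.E_GABA < s0.E_GABA

    def test_resistance_law_peaks_with_depolarization(self):
        assert membrane_resistance(-42.0, P) > membrane_resistance(-50.0, P)


class TestControlAttractorRanges(object):
    """Realized circadian operating ranges of the membrane quantities."""

    def test_resting_potential_band(self, control_traj):
        _, v = control_traj.series("V_rest")
        assert v.min() > -55.0 and v.max() < -38.0
        assert v.max() - v.min() > 5.0  # sustained circadian modulation

    def test_firing_rate_band_and_day_peak(self, control_traj):
        from scnsim.metrics import phase_CT
        t, fr = control_traj.series("f_r")
        _, ca = control_traj.series("Ca")
        assert fr.min() > 1.0 and fr.max() < 12.0
        ct = phase_CT(fr, t, ca)
        assert 3.0 < ct < 12.0  # subjective day

    def test_chloride_and_resistance_bands(self, control_traj):
        _, cl = control_traj.series("Cl_in")
        _, r = control_traj.series("R")
        assert cl.min() > 8.0 and cl.max() < 20.0
        assert r.min() > 0.5 and r.max() < 2.5

    def test_gk_matches_reported_statistics(self, control_traj):
        _, gk = control_traj.series("g_K")
        assert gk.mean() == pytest.approx(11.3, abs=1.0)

    def test_bk_current_peaks_at_night(self, control_traj):
        from scnsim.metrics import phase_CT
        t, ikca = control_traj.series("I_KCa")
        _, ca = control_traj.series("Ca")
        ct = phase_CT(np.abs(ikca), t, ca)
        assert ct > 15.0 or ct < 1.0  # subjective night
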