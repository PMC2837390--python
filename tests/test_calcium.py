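"""Two-pool calcium model: closed-form values, mass bookkeeping, blockades."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scnsim.calcium import (
    CalciumBlockade,
    calcium_derivatives,
    efflux_rate,
    influx_rate,
    store_release_v3,
    store_uptake_v2,
)
from scnsim.params import CalciumParams

P = CalciumParams()


class TestMembraneFluxes:
    def test_efflux_zero_cry_limit(self):
        # CC**0.1 -> 0 as CC -> 0: the printed saturating form vanishes
        assert efflux_rate(0.0, P) == pytest.approx(0.0)

    def test_efflux_at_nominal_cry_matches_hand_calculation(self):
        # k = 3.3 * 12**0.1 / (0.02 + 12**0.1), evaluated independently:
        # 12**0.1 = 1.2820890, so k = 3.2493122 per uM per hour
        assert efflux_rate(12.0, P) == pytest.approx(3.2493122, abs=1e-6)

    def test_influx_zero_bmal1_limit_and_hand_value(self):
        assert influx_rate(0.0, P) == pytest.approx(0.0)
        # v_o = 0.09 * 2.41**4.5 / (4.5 + 2.41**4.5); 2.41**4.5 = 52.36956
        assert influx_rate(2.41, P) == pytest.approx(0.0828784, abs=1e-6)

    def test_influx_bounded_by_saturation_ceiling(self):
        for bc in [0.1, 1.0, 5.0, 50.0]:
            assert influx_rate(bc, P) < P.v_vo
        # far in saturation the bound is attained to machine precision
        assert influx_rate(1e6, P) <= P.v_vo * (1.0 + 1e-12)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            efflux_rate(-1.0, P)
        with pytest.raises(ValueError):
            influx_rate(-1.0, P)


class TestStoreFluxes:
    def test_uptake_vanishes_without_cytosolic_calcium(self):
        assert store_uptake_v2(0.0, P) == pytest.approx(0.0)

    def test_release_vanishes_with_empty_store(self):
        assert store_release_v3(0.5, 0.0, P) == pytest.approx(0.0)

    def test_uptake_half_saturation_identity(self):
        # Hill form: v2(K_2) = V_M2 / 2
        assert store_uptake_v2(P.K_2, P) == pytest.approx(P.V_M2 / 2.0)

    def test_fluxes_bounded_by_maximum_rates(self):
        for ca in [0.05, 0.5, 5.0, 50.0]:
            assert 0.0 <= store_uptake_v2(ca, P) < P.V_M2
            assert 0.0 <= store_release_v3(ca, 10.0, P) < P.V_M3


class TestDerivatives:
    def test_full_shutoff_zero_fixed_point(self):
        """With influx, leak and store exchange all off, Ca = 0 is a fixed
        point of both pools."""
        p = CalciumParams(v_1=1e-300, k_f=1e-300, v_vo=1e-300)
        dca, dst = calcium_derivatives(0.0, 0.0, 12.0, 2.41, p,
                                       CalciumBlockade.RYANODINE_BLOCK)
        assert dca == pytest.approx(0.0, abs=1e-12)
        assert dst == pytest.approx(0.0, abs=1e-12)

    def test_ip3_blockade_zeroes_only_the_ip3_term(self):
        base = calcium_derivatives(0.1, 0.1, 12.0, 2.41, P, "none")
        blocked = calcium_derivatives(0.1, 0.1, 12.0, 2.41, P, "ip3_block")
        assert base[0] - blocked[0] == pytest.approx(P.v_1 * P.beta_IP3)
        assert base[1] == pytest.approx(blocked[1])

    def test_ryanodine_blockade_zeroes_store_release(self):
        ca, store = 0.4, 2.5
        v3 = store_release_v3(ca, store, P)
        base = calcium_derivatives(ca, store, 12.0, 2.41, P, "none")
        blocked = calcium_derivatives(ca, store, 12.0, 2.41, P,
                                      "ryanodine_block")
        assert base[0] - blocked[0] == pytest.approx(v3)
        assert blocked[1] - base[1] == pytest.approx(v3)

    def test_unknown_blockade_rejected(self):
        with pytest.raises(ValueError):
            calcium_derivatives(0.1, 0.1, 12.0, 2.41, P, "nifedipine")

    @settings(max_examples=50, deadline=None)
    @given(ca=st.floats(0.0, 5.0), store=st.floats(0.0, 5.0),
           cc=st.floats(0.0, 20.0), bc=st.floats(0.0, 5.0))
    def test_store_exchange_antisymmetry(self, ca, store, cc, bc):
        """d(Ca + Ca_store)/dt equals the membrane terms alone: internal
        store exchange cancels exactly."""
        dca, dst = calcium_derivatives(ca, store, cc, bc, P, "none")
        membrane = (influx_rate(bc, P) + P.v_1 * P.beta_IP3
                    - efflux_rate(cc, P) * ca ** P.v)
        assert dca + dst == pytest.approx(membrane, rel=1e-12, abs=1e-12)


class TestAttractorProperties:
    def test_calcium_peaks_once_per_cycle_in_subjective_day(self, control_traj):
        """Cytosolic Ca is rhythmic with the clock period and peaks in the
        circadian-day half of the cycle (it defines CT 1.5)."""
        from scnsim.metrics import estimate_period, peak_times_values
        t, ca = control_traj.series("Ca")
        _, mp = control_traj.series("M_P")
        per_ca = estimate_period(ca, t)
        per_mp = estimate_period(mp, t)
        assert per_ca == pytest.approx(per_mp, abs=0.1)
        pt, _ = peak_times_values(t, ca)
        assert len(pt) >= 10  # one peak per cycle over the analysis window
        assert np.all(np.diff(pt) > 0.8 * per_ca)

    def test_daytime_calcium_substantially_above_night(self, control_traj):
        """The day peak sits well above the night trough (the model's
        realized day/night contrast; see the methods note)."""
        _, ca = control_traj.series("Ca")
        assert ca.max() / ca.min() > 1.5

    def test_efflux_rate_varies_with_the_cry_rhythm(self, control_traj):
        from scnsim.metrics import estimate_period
        t, cc = control_traj.series("C_C")
        k = np.array([efflux_rate(v, P) for v in cc])
        assert estimate_period(k, t) == pytest.approx(
            estimate_period(cc, t), abs=0.1)
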