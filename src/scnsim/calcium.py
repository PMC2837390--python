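"""Two-pool intracellular calcium dynamics.

Cytosolic calcium (Ca, uM) exchanges with a ryanodine-sensitive store
(Ca_store, uM) and with the extracellular space:

    dCa/dt       = v_o(B_C) + v_1*beta_IP3 - v_2(Ca) + v_3(Ca, Ca_store)
                   + k_f*Ca_store - k(C_C)*Ca**v
    dCa_store/dt = v_2(Ca) - v_3(Ca, Ca_store) - k_f*Ca_store

Membrane influx v_o saturates in cytosolic BMAL1 (B_C) and efflux rate k
in cytosolic CRY (C_C); neither form is mechanistic — they impose the
experimentally observed circadian gating of the calcium fluxes on the
clock phase.  Store uptake v_2 is a Hill pump in Ca; release v_3 is
calcium-induced calcium release, gated by both store filling and cytosolic
Ca.  The IP3-store release v_1*beta_IP3 is held constant.

Pharmacological hooks: an IP3 blocker zeroes v_1, a ryanodine blocker
zeroes v_3.  Both are applied constitutively for a whole run.
"""

from __future__ import annotations

from enum import Enum

import numpy as np

from .params import CalciumParams

__all__ = [
    "CalciumBlockade",
    "efflux_rate",
    "influx_rate",
    "store_uptake_v2",
    "store_release_v3",
    "calcium_derivatives",
]


class CalciumBlockade(str, Enum):
    """Constitutive store blockades."""

    NONE = "none"
    IP3_BLOCK = "ip3_block"          # v_1 := 0
    RYANODINE_BLOCK = "ryanodine_block"  # v_3 := 0


def _check_nonneg(name: str, value: float) -> None:
    if value < 0:
        raise ValueError(f"{name} must be non-negative, got {value}")


def efflux_rate(CC: float, params: CalciumParams) -> float:
    """Calcium efflux rate coefficient k (1/(uM h)), saturating in C_C (nM).

    k = v_kk * CC**nkk / (K_kk + CC**nkk); the efflux term in the calcium
    balance is k * Ca**v.
    """
    _check_nonneg("CC", CC)
    x = CC ** params.nkk
    return params.v_kk * x / (params.K_kk + x)


def influx_rate(BC: float, params: CalciumParams) -> float:
    """Calcium influx v_o (uM/h), saturating in cytosolic BMAL1 (nM).

    v_o = v_vo * BC**nvo / (K_vo + BC**nvo).
    """
    _check_nonneg("BC", BC)
    x = BC ** params.nvo
    return params.v_vo * x / (params.K_vo + x)


def store_uptake_v2(Ca: float, params: CalciumParams) -> float:
    """Pumping of cytosolic Ca into the ryanodine store (uM/h)."""
    _check_nonneg("Ca", Ca)
    can = Ca ** params.n
    return params.V_M2 * can / (params.K_2 ** params.n + can)


def store_release_v3(Ca: float, Ca_store: float, params: CalciumParams) -> float:
    """Calcium-induced calcium release from the store (uM/h).

    Gated by store filling (Hill in Ca_store, threshold K_R) and activated
    by cytosolic Ca (Hill, threshold K_A).
    """
    _check_nonneg("Ca", Ca)
    _check_nonneg("Ca_store", Ca_store)
    ym = Ca_store ** params.m
    cap = Ca ** params.p
    return (params.V_M3
            * ym / (params.K_R ** params.m + ym)
            * cap / (params.K_A ** params.p + cap))


def calcium_derivatives(
    Ca: float,
    Ca_store: float,
    CC: float,
    BC: float,
    params: CalciumParams,
    blockade: CalciumBlockade | str = CalciumBlockade.NONE,
) -> tuple[float, float]:
    """(dCa/dt, dCa_store/dt) in uM/h.

    Store exchange is antisymmetric: every uptake/release/leak term appears
    with opposite signs in the two balances, so d(Ca + Ca_store)/dt equals
    the membrane terms (influx + IP3 release - efflux) alone.
    """
    blockade = CalciumBlockade(blockade)
    _check_nonneg("Ca", Ca)
    _check_nonneg("Ca_store", Ca_store)

    v1 = 0.0 if blockade is CalciumBlockade.IP3_BLOCK else params.v_1
    v2 = store_uptake_v2(Ca, params)
    v3 = (0.0 if blockade is CalciumBlockade.RYANODINE_BLOCK
          else store_release_v3(Ca, Ca_store, params))
    vo = influx_rate(BC, params)
    k = efflux_rate(CC, params)
    leak = params.k_f * Ca_store
    efflux = k * Ca ** params.v

    dCa = vo + v1 * params.beta_IP3 - v2 + v3 + leak - efflux
    dCa_store = v2 - v3 - leak
    return dCa, dCa_store


def scaled_output(Ca: float, params: CalciumParams) -> float:
    """Cytosolic calcium as seen by downstream consumers (uM).

    The scaling factor mimics pharmacological manipulation of effective
    calcium levels; internal store dynamics always use the unscaled value.
    """
    return params.ca_scale * Ca
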