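"""VIP autocrine release and the Ca/VIP -> kinase -> phospho-CREB cascade.

The neuron releases VIP as a saturating function of its own firing rate and
the released concentration acts back on the same cell (autocrine loop):

    dVIP/dt = v_VIP * f_r**n_VIP / (K_VIP + f_r**n_VIP)
              - k_dVIP * VIP**n_dVIP

Calcium and VIP jointly activate protein kinases (Michaelian, additive):

    v_k = V_MK * Ca / (K_MK + Ca) + V_beta * VIP / (K_beta + VIP)

and the kinase phosphorylates CREB, modelled as a Michaelian
phosphorylation/dephosphorylation cycle over a conserved total CB_T:

    dCB/dt = v_k * (CB_T - CB) / (K_D + CB_T - CB)
             - V_dCB * CB / (K_D + CB)

Phospho-CREB finally drives Per transcription additively over the basal
rate (see :mod:`scnsim.core_clock`):

    v_sP = v_sP0 + C_T * CB / (K_c + CB)

Under VIP blockade the VIP concentration is zeroed only where it enters
GABA release and kinase activation; the VIP state itself keeps evolving.
VIP application adds a constant offset at those same two entry points.
"""

from __future__ import annotations

from .params import SignalParams

__all__ = [
    "vip_derivative",
    "kinase_rate",
    "creb_derivative",
    "per_transcription_rate",
]


def _check_nonneg(name: str, value: float) -> None:
    if value < 0:
        raise ValueError(f"{name} must be non-negative, got {value}")


def vip_derivative(f_r: float, VIP: float, params: SignalParams) -> float:
    """dVIP/dt (nM/h): spike-frequency-driven release minus depletion."""
    _check_nonneg("f_r", f_r)
    _check_nonneg("VIP", VIP)
    x = f_r ** params.n_VIP
    production = params.v_VIP * x / (params.K_VIP + x)
    depletion = params.k_dVIP * VIP ** params.n_dVIP if VIP > 0 else 0.0
    return production - depletion


def kinase_rate(Ca: float, VIP: float, params: SignalParams) -> float:
    """Kinase activity v_k (nM/h) from calcium (uM) and VIP (nM)."""
    _check_nonneg("Ca", Ca)
    _check_nonneg("VIP", VIP)
    ca_term = params.V_MK * Ca / (params.K_MK + Ca)
    vip_term = params.V_beta * VIP / (params.K_beta + VIP)
    return ca_term + vip_term


def creb_derivative(CB: float, v_k: float, params: SignalParams) -> float:
    """dCB/dt (nM/h) of the phospho-CREB pool; CB stays in [0, CB_T]."""
    if not 0.0 <= CB <= params.CB_T:
        raise ValueError(
            f"CB = {CB} outside the admissible range [0, {params.CB_T}]"
        )
    free = params.CB_T - CB
    phospho = v_k * free / (params.K_D + free)
    dephospho = params.V_dCB * CB / (params.K_D + CB)
    return phospho - dephospho


def per_transcription_rate(CB: float, params: SignalParams, v_sP0: float) -> float:
    """Full Per transcription rate v_sP (nM/h): basal + CREB activation."""
    _check_nonneg("CB", CB)
    return v_sP0 + params.C_T * CB / (params.K_c + CB)
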