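"""Algebraic electrophysiology layer of the SCN neuron model.

At every circadian time point the membrane is treated as quasi-static:
conductances, reversal potentials, the GHK resting potential, membrane
resistance and the firing rate are pure functions of the slow (hour-scale)
state variables.  The spike-generating machinery itself is reduced to a
leaky integrate-and-fire firing-rate code:

    C_m dV/dt = -sum_r g_r (V - E_r) + I_app
              = (-V + R* I*) / R*          with
    R*   = 1 / sum_r g_r                   (GOhm)
    I*   = sum_r g_r E_r + I_app           (pA)
    tau_m = R* C_m                         (s)

Between a reset at V_reset and the threshold theta the voltage relaxes
exponentially toward R* I*; if R* I* > theta the neuron fires periodically
with rate

    f_r = 1 / ( tau_m * ln[(R* I* - V_reset) / (R* I* - theta)] )   (Hz)

and is silent otherwise.  theta and V_reset ride on the resting potential
(theta = V_rest + 20 mV, V_reset = V_rest + 4 mV), so circadian changes in
V_rest shift the firing threshold with the membrane operating point.

Circadian gating of the conductances is phenomenological: g_K and g_Ca
follow Per mRNA, g_KCa follows cytosolic CRY, the potassium permeability
P_K follows cytosolic BMAL1, the excitatory (AMPA/NMDA) conductance follows
the sodium current and cytosolic calcium, and the GABA/chloride pathway
follows VIP and Per mRNA.  None of these laws is mechanistic; they impose
experimentally observed phase relationships.

Unit regime: conductances nS, potentials mV, currents pA, resistances
GOhm, capacitance nF, calcium uM, everything else nM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

from .params import BODY_TO_ROOM, MembraneParams, rt_over_f

__all__ = [
    "ElectroSnapshot",
    "conductance_K",
    "conductance_Ca",
    "conductance_KCa",
    "excitatory_conductance",
    "gaba_release",
    "chloride_in",
    "nernst",
    "permeability_K",
    "resting_potential",
    "membrane_resistance",
    "firing_rate",
    "snapshot",
]

# smallest calcium concentration (uM) used in reciprocal-power laws; keeps
# the NMDA term and E_Ca finite if a trajectory touches zero
_CA_FLOOR = 1e-9


def _check_nonneg(name: str, value: float) -> None:
    if value < 0:
        raise ValueError(f"{name} must be non-negative, got {value}")


def conductance_K(MP: float, params: MembraneParams) -> float:
    """Delayed-rectifier potassium conductance (nS), saturating in Per mRNA."""
    _check_nonneg("MP", MP)
    return params.g_Ko + params.v_gk * MP / (params.K_gk + MP)


def conductance_Ca(MP: float, params: MembraneParams) -> float:
    """L-type calcium conductance (nS), Hill in Per mRNA."""
    _check_nonneg("MP", MP)
    x = MP ** params.n_Ca
    return params.v_Ca * x / (params.K_Ca + x)


def conductance_KCa(CC: float, params: MembraneParams) -> float:
    """BK-channel conductance (nS); the negative exponent on cytosolic CRY
    makes it peak when CRY is low (subjective night)."""
    _check_nonneg("CC", CC)
    # v * CC**-1 / (K + CC**-1) == v / (1 + K*CC), finite at CC = 0
    return params.v_KCa / (1.0 + params.K_KCa * CC)


def excitatory_conductance(I_Na: float, Ca: float, params: MembraneParams) -> float:
    """AMPA + NMDA conductance (nS).

    The AMPA term saturates in the magnitude of the sodium current (nA);
    the NMDA term carries a negative exponent on cytosolic calcium (uM),
    i.e. it decreases monotonically with Ca.
    """
    Ca = max(Ca, _CA_FLOOR)
    ampa_x = abs(I_Na) ** params.n_ex1
    ampa = params.v_ex1 * ampa_x / (params.K_ex1 + ampa_x)
    # v * Ca**-1 / (K + Ca**-1) == v / (1 + K*Ca)
    nmda = params.v_ex2 / (1.0 + params.K_ex2 * Ca)
    return ampa + nmda


def gaba_release(VIP: float, params: MembraneParams) -> float:
    """GABA concentration (nM) released as a saturating function of VIP."""
    _check_nonneg("VIP", VIP)
    return params.GABA_o + params.v_GABA * VIP / (params.K_GABA + VIP)


def chloride_in(MP: float, GABA: float, params: MembraneParams) -> float:
    """Intracellular chloride (mM): basal + Per-mRNA-controlled + GABA-gated.

    The GABA term carries a negative exponent, so chloride accumulation is
    maximal at low GABA; at GABA = 0 it takes its saturation value v_Cl2.
    """
    _check_nonneg("MP", MP)
    _check_nonneg("GABA", GABA)
    per_term = params.v_Cl1 * MP / (params.K_Cl1 + MP)
    if GABA == 0.0:
        gaba_term = params.v_Cl2  # limit of the negative-power saturation
    else:
        x = GABA ** params.n_Cl
        gaba_term = params.v_Cl2 * x / (params.K_Cl2 + x)
    return params.Cl_o + per_term + gaba_term


def nernst(X_ex: float, X_in: float, valence: int, temperature_c: float) -> float:
    """Nernst reversal potential (mV) for an ion of the given valence."""
    if X_ex <= 0 or X_in <= 0:
        raise ValueError("Nernst concentrations must be positive")
    if valence == 0:
        raise ValueError("valence must be nonzero")
    return rt_over_f(temperature_c) / valence * math.log(X_ex / X_in)


def permeability_K(BC: float, params: MembraneParams) -> float:
    """Relative potassium permeability; negative exponent on cytosolic
    BMAL1 makes P_K peak during the subjective night."""
    _check_nonneg("BC", BC)
    # v * BC**-2 / (K + BC**-2) == v / (1 + K*BC**2)
    return params.v_PK / (1.0 + params.K_PK * BC ** 2)


def resting_potential(
    P_K: float,
    Cl_in: float,
    Ca_in_uM: float,
    params: MembraneParams,
) -> float:
    """GHK resting potential (mV) including the divalent calcium term.

    The divalent extension of the GHK equation keeps the monovalent flux
    balance and adds a calcium flux with valence 2, which makes the
    equation implicit in the voltage:

        F(u) = P_K(K_i - K_o e^-u) + P_Na(Na_i - Na_o e^-u)
             + P_Cl(Cl_o - Cl_i e^-u)
             + 4 P_Ca (Ca_i - Ca_o e^-2u) / (1 + e^-u) = 0,   u = VF/RT

    solved by bracketed root finding.  In the limit P_Ca -> 0 this reduces
    exactly to the standard monovalent GHK equation.  Internal K+ and Na+
    are fixed by inverting the Nernst relation at the nominal reversal
    potentials.  Concentrations in mM (calcium converted from uM).
    """
    if P_K <= 0 or params.P_Na <= 0 or params.P_Cl <= 0:
        raise ValueError("monovalent permeabilities must be positive")
    if Cl_in <= 0 or Ca_in_uM <= 0:
        raise ValueError("ion concentrations must be positive")
    vt = rt_over_f(params.T)
    E_K = params.E_K_room * BODY_TO_ROOM
    E_Na = params.E_Na_room * BODY_TO_ROOM
    K_in = params.K_ex * math.exp(-E_K / vt)
    Na_in = params.Na_ex * math.exp(-E_Na / vt)
    Ca_in = Ca_in_uM * 1e-3   # mM
    Ca_ex = params.Ca_ex * 1e-3  # mM (table value is in uM)

    def flux_balance(u: float) -> float:
        eu = math.exp(-u)
        mono = (P_K * (K_in - params.K_ex * eu)
                + params.P_Na * (Na_in - params.Na_ex * eu)
                + params.P_Cl * (params.Cl_ex - Cl_in * eu))
        diva = 4.0 * params.P_Ca * (Ca_in - Ca_ex * eu * eu) / (1.0 + eu)
        return mono + diva

    # bracket in voltage: [-150, +50] mV covers any physiological solution
    lo, hi = -150.0 / vt, 50.0 / vt
    u = brentq(flux_balance, lo, hi, xtol=1e-12, rtol=1e-14)
    return u * vt


def membrane_resistance(V_rest: float, params: MembraneParams) -> float:
    """Input resistance R (GOhm) as a saturating function of |V_rest|.

    R = V_R * K_R / (|V_rest| - K_R): R rises as the membrane depolarizes
    toward K_R, so R peaks together with V_rest during the subjective day.
    The depolarization depth is floored at 2 mV so that transient
    excursions toward the law's pole saturate instead of diverging.
    """
    depth = max(abs(V_rest) - params.K_R, 2.0)
    return params.V_R * params.K_R / depth


def firing_rate(
    RI: float, V_reset: float, theta: float, tau_m: float
) -> float:
    """Firing rate (Hz) of the integrate-and-fire reduction.

    RI is the asymptotic voltage R* I* (mV).  Returns 0 for any
    sub-threshold drive (RI <= theta), never raising: a silent neuron.
    """
    if tau_m <= 0:
        raise ValueError("tau_m must be positive")
    if RI <= theta:
        return 0.0
    ratio = (RI - V_reset) / (RI - theta)
    if ratio <= 1.0:  # numerically degenerate: treat as silent
        return 0.0
    return 1.0 / (tau_m * math.log(ratio))


@dataclass(frozen=True)
class ElectroSnapshot:
    """All algebraic membrane quantities at one circadian time point."""

    g_K: float
    g_Na: float
    g_Ca: float
    g_KCa: float
    g_ex: float
    g_GABA: float
    g_L: float
    E_K: float
    E_Na: float
    E_Ca: float
    E_GABA: float
    E_L: float
    GABA: float
    Cl_in: float
    P_K: float
    V_rest: float
    R: float
    I_star: float
    R_star: float
    tau_m: float
    theta: float
    V_reset: float
    f_r: float
    I_K: float
    I_Na: float
    I_Ca: float
    I_KCa: float
    I_ex: float
    I_inhib: float


#: snapshot fields serialized into trajectory tables, in column order
SNAPSHOT_FIELDS: tuple[str, ...] = (
    "g_K", "g_Ca", "g_KCa", "g_ex", "g_L", "GABA", "Cl_in", "P_K",
    "E_Ca", "E_GABA", "V_rest", "R", "I_star", "R_star", "tau_m", "f_r",
    "I_K", "I_Na", "I_Ca", "I_KCa", "I_ex", "I_inhib",
)


def snapshot(
    MP: float,
    CC: float,
    BC: float,
    Ca_eff: float,
    VIP_eff: float,
    params: MembraneParams,
    *,
    nimodipine: bool = False,
    gaba_scale: float = 1.0,
    gaba_add: float = 0.0,
    I_app: float = 0.0,
) -> ElectroSnapshot:
    """Evaluate the full membrane snapshot from the slow state.

    Parameters
    ----------
    MP, CC, BC
        Per mRNA, cytosolic CRY and cytosolic BMAL1 (nM).
    Ca_eff
        Effective cytosolic calcium (uM), already output-scaled.
    VIP_eff
        VIP concentration acting on the membrane (nM); under VIP blockade
        this is zero while the VIP state keeps evolving.
    nimodipine
        L-type channel blockade: g_Ca forced to zero.
    gaba_scale, gaba_add
        Scale/offset applied to the released GABA before it gates the
        chloride equation (dose-response experiments).
    I_app
        Injected current (pA) added to the effective drive I*.
    """
    Ca_eff = max(Ca_eff, _CA_FLOOR)
    vt_body = params.T

    GABA = gaba_release(VIP_eff, params) * gaba_scale + gaba_add
    GABA = max(GABA, 0.0)
    Cl = chloride_in(MP, GABA, params)
    E_GABA = nernst(params.Cl_ex, Cl, -1, vt_body)
    E_K = params.E_K_room * BODY_TO_ROOM
    E_Na = params.E_Na_room * BODY_TO_ROOM
    E_L = params.E_L_room * BODY_TO_ROOM
    E_Ca = nernst(params.Ca_ex, Ca_eff, 2, vt_body)

    P_K = permeability_K(BC, params)
    V_rest = resting_potential(P_K, Cl, Ca_eff, params)
    R = membrane_resistance(V_rest, params)
    g_L = 1.0 / R

    g_K = conductance_K(MP, params)
    g_Ca = 0.0 if nimodipine else conductance_Ca(MP, params)
    g_KCa = conductance_KCa(CC, params)
    I_Na = params.g_Na * (V_rest - E_Na)          # pA
    g_ex = excitatory_conductance(I_Na * 1e-3, Ca_eff, params)  # |I_Na| in nA

    g_sum = (g_ex + params.g_GABA + params.g_Na + g_Ca + g_K + g_KCa + g_L)
    if not (g_sum > 0 and math.isfinite(g_sum)):
        raise FloatingPointError(f"total conductance degenerate: {g_sum}")
    I_star = (g_ex * params.E_ex + params.g_GABA * E_GABA
              + params.g_Na * E_Na + g_Ca * E_Ca
              + g_K * E_K + g_KCa * E_K + g_L * E_L
              + I_app)
    R_star = 1.0 / g_sum                           # GOhm
    tau_m = R_star * params.C_m                    # s
    theta = E_L + params.theta_offset
    V_reset = E_L + params.reset_offset
    f_r = firing_rate(R_star * I_star, V_reset, theta, tau_m)

    return ElectroSnapshot(
        g_K=g_K, g_Na=params.g_Na, g_Ca=g_Ca, g_KCa=g_KCa, g_ex=g_ex,
        g_GABA=params.g_GABA, g_L=g_L,
        E_K=E_K, E_Na=E_Na, E_Ca=E_Ca, E_GABA=E_GABA, E_L=E_L,
        GABA=GABA, Cl_in=Cl, P_K=P_K, V_rest=V_rest, R=R,
        I_star=I_star, R_star=R_star, tau_m=tau_m,
        theta=theta, V_reset=V_reset, f_r=f_r,
        I_K=g_K * (V_rest - E_K),
        I_Na=I_Na,
        I_Ca=g_Ca * (V_rest - E_Ca),
        I_KCa=g_KCa * (V_rest - E_K),
        I_ex=g_ex * (V_rest - params.E_ex),
        I_inhib=params.g_GABA * (V_rest - E_GABA),
    )
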