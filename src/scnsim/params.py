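"""Parameter sets for the single-cell SCN pacemaker-neuron model.

The model couples four layers:

* a 16-state circadian gene network (the classical interlocked
  Per/Cry/Bmal1 transcriptional loops, without the Rev-Erb branch),
* a two-pool intracellular calcium model (IP3- and ryanodine-sensitive
  stores plus membrane influx/efflux),
* an algebraic firing-rate-code electrophysiology layer (conductances,
  GHK resting potential, leaky integrate-and-fire rate reduction),
* a VIP/GABA/CREB signaling bridge closing the loop onto Per transcription.

Every parameter lives in one of four frozen dataclasses, grouped the same
way as the configuration file groups (``clock``, ``calcium``, ``membrane``,
``signaling``).  All clock rates are per hour; calcium is in uM; the
electrophysiology layer uses nS / mV / GOhm / nF so that the membrane time
constant comes out in seconds and firing rates in Hz.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Mapping

__all__ = [
    "ClockParams",
    "CalciumParams",
    "MembraneParams",
    "SignalParams",
    "Parameters",
    "INITIAL_STATE",
    "STATE_NAMES",
]


# Kelvin per Celsius offset and physical constants used by the Nernst/GHK
# computations (RT/F at 37 C in mV).
ZERO_C_IN_K = 273.15
BODY_T_C = 37.0
ROOM_T_C = 22.0
# Reversal potentials measured at room temperature are rescaled to body
# temperature with the absolute-temperature ratio, following the Nernst
# proportionality E ~ T.
BODY_TO_ROOM = (BODY_T_C + ZERO_C_IN_K) / (ROOM_T_C + ZERO_C_IN_K)


def rt_over_f(temperature_c: float = BODY_T_C) -> float:
    """RT/F in mV at the given temperature."""
    R = 8.31446  # J/(mol K)
    F = 96485.33  # C/mol
    return 1000.0 * R * (temperature_c + ZERO_C_IN_K) / F


@dataclass(frozen=True)
class ClockParams:
    """Rate constants of the 16-state Per/Cry/Bmal1 gene network.

    Names follow the standard mammalian-clock notation: ``v_s*`` are maximum
    transcription rates, ``v_m*`` maximum mRNA degradation rates, ``k_s*``
    translation rates, ``V_1..V_4`` (de)phosphorylation rates, ``v_d*``
    phospho-protein degradation rates, ``k_1..k_8`` transport and complex
    formation rates.  Units: nM/h for V/v rates, 1/h for first-order rates,
    1/(nM h) for the bimolecular rates k3 and k7, nM for Michaelis/threshold
    constants.

    Three values are retuned relative to the classical set: ``k1`` (nuclear
    import of the PER/CRY complex, 0.45/h), ``K_AP`` (activation threshold
    of Per transcription by nuclear BMAL1, 0.6 nM) and ``v_sP0`` (basal Per
    transcription rate, 1 nM/h; the CREB-dependent drive adds to it).
    """

    # transcription
    v_sP0: float = 1.0   # basal Per transcription rate, nM/h (retuned)
    v_sC: float = 1.1
    v_sB: float = 1.0
    K_AP: float = 0.6    # nM (retuned)
    K_AC: float = 0.6
    K_IB: float = 2.2
    n: float = 4.0       # Hill exponent, Per/Cry activation
    m: float = 2.0       # Hill exponent, Bmal1 autoinhibition
    # mRNA degradation
    v_mP: float = 1.1
    v_mC: float = 1.0
    v_mB: float = 0.8
    K_mP: float = 0.31
    K_mC: float = 0.4
    K_mB: float = 0.4
    k_dmp: float = 0.01
    k_dmc: float = 0.01
    k_dmb: float = 0.01
    # translation
    k_sP: float = 0.6
    k_sC: float = 1.6
    k_sB: float = 0.12
    # PER/CRY complex formation and shuttling
    k_1: float = 0.45    # PER/CRY cytosol -> nucleus, 1/h (retuned)
    k_2: float = 0.2
    k_3: float = 0.4
    k_4: float = 0.2
    # BMAL1 shuttling
    k_5: float = 0.4
    k_6: float = 0.2
    # inactive complex BN:PCN
    k_7: float = 0.5
    k_8: float = 0.1
    # phosphorylation / dephosphorylation
    V_1P: float = 0.4
    V_2P: float = 0.3
    V_1C: float = 0.6
    V_2C: float = 0.1
    V_1PC: float = 0.4
    V_2PC: float = 0.1
    V_3PC: float = 0.4
    V_4PC: float = 0.1
    V_1B: float = 0.5
    V_2B: float = 0.1
    V_3B: float = 0.5
    V_4B: float = 0.2
    K_p: float = 0.1
    K_dp: float = 0.1
    # degradation of phosphorylated proteins
    v_dPC: float = 0.7
    v_dCC: float = 0.7
    v_dPCC: float = 0.7
    v_dPCN: float = 0.7
    v_dBC: float = 0.5
    v_dBN: float = 0.6
    v_dIN: float = 0.8
    K_d: float = 0.3
    # nonspecific degradation
    k_dn: float = 0.01
    k_dnc: float = 0.12


@dataclass(frozen=True)
class CalciumParams:
    """Two-pool calcium model parameters.

    ``v_1``/``beta_IP3`` control the (constant) IP3-store release,
    ``V_M2``/``K_2``/``n`` the store uptake pump, ``V_M3``/``K_R``/``m``/
    ``K_A``/``p`` the calcium-induced calcium release from the ryanodine
    pool, ``k_f`` the passive store leak.  Membrane exchange is
    clock-modulated: efflux rate k(CC) (per uM per hour, acting on Ca**v)
    saturates in cytosolic CRY, influx v_o(BC) (uM/h) in cytosolic BMAL1.
    ``ca_scale`` multiplies the calcium signal seen by downstream consumers
    (reversal potential, NMDA conductance, kinase) without touching the
    internal store dynamics.
    """

    v_1: float = 0.0003      # uM/h, IP3-store release (held constant)
    beta_IP3: float = 0.5    # dimensionless IP3 saturation
    V_M2: float = 149.5      # uM/h, max store uptake
    K_2: float = 5.0         # uM
    n: float = 2.2           # uptake Hill exponent
    V_M3: float = 400.0      # uM/h, max store release
    K_R: float = 3.0         # uM, release threshold (store)
    m: float = 6.0           # release exponent (store)
    K_A: float = 0.67        # uM, activation threshold (cytosol)
    p: float = 4.2           # activation exponent (cytosol)
    k_f: float = 0.001       # 1/h, store leak
    v: float = 2.0           # efflux exponent on Ca
    v_kk: float = 3.3        # 1/(uM h), max efflux rate coefficient
    K_kk: float = 0.02       # nM**nkk, efflux saturation (lumped power)
    nkk: float = 0.1
    v_vo: float = 0.09       # uM/h, max influx
    K_vo: float = 4.5        # nM**nvo, influx saturation (lumped power)
    nvo: float = 4.5
    ca_scale: float = 1.0    # dimensionless output scaling


@dataclass(frozen=True)
class MembraneParams:
    """Electrophysiology parameters (conductances nS, potentials mV).

    Saturation constants written with fractional-power units in the source
    table (e.g. ``K_Ca`` in nM**2.2) are lumped constants: the denominator
    of the corresponding saturating form is ``K + x**n`` with ``x**n``
    carrying the same units.
    """

    # potassium (delayed rectifier); E_K measured at room temperature
    g_Ko: float = 9.7        # nS basal
    v_gk: float = 10.0       # nS max increment
    K_gk: float = 10.0       # nM (Per mRNA scale)
    E_K_room: float = -97.0  # mV at 22 C
    # sodium
    g_Na: float = 36.0       # nS
    E_Na_room: float = 45.0  # mV at 22 C
    # L-type calcium conductance, driven by Per mRNA
    v_Ca: float = 12.3       # nS
    K_Ca: float = 22.0       # nM**2.2 (lumped)
    n_Ca: float = 2.2
    # BK (calcium-activated potassium), driven by cytosolic CRY
    v_KCa: float = 3.0       # nS
    K_KCa: float = 0.16      # nM**-1 (lumped)
    n_KCa: float = -1.0
    # excitatory (AMPA + NMDA) conductance
    v_ex1: float = 105.0     # nS
    K_ex1: float = 574.05    # (nA)**2.5 (lumped; |I_Na| in nA)
    n_ex1: float = 2.5
    v_ex2: float = 4.4       # nS
    K_ex2: float = 1.0       # uM**-1 (lumped; Ca in uM)
    n_ex2: float = -1.0
    E_ex: float = 0.0        # mV
    # inhibitory (GABA_A / chloride)
    GABA_o: float = 0.2      # nM basal GABA
    v_GABA: float = 19.0     # nM max
    K_GABA: float = 3.0      # nM (VIP scale)
    g_GABA: float = 12.3     # nS
    Cl_o: float = 1.0        # mM basal intracellular chloride
    v_Cl1: float = 15.5      # mM, PER-controlled chloride release
    K_Cl1: float = 4.0       # nM
    v_Cl2: float = 19.0      # mM, GABA-controlled chloride release
    K_Cl2: float = 1.0       # nM**-0.2 (lumped)
    n_Cl: float = -0.2
    Cl_ex: float = 114.5     # mM extracellular chloride
    # leak
    E_L_room: float = -29.0  # mV at 22 C
    # GHK permeabilities and external concentrations
    P_Ca: float = 0.05
    P_Na: float = 0.036
    P_Cl: float = 0.3
    K_ex: float = 1.0        # mM external potassium
    Na_ex: float = 145.0     # mM external sodium
    Ca_ex: float = 5.0       # uM external calcium (see methods note)
    v_PK: float = 1.9        # max potassium permeability
    K_PK: float = 1.0        # nM**-2 (lumped)
    npk: float = -2.0
    # membrane resistance vs resting potential
    V_R: float = 0.41        # GOhm
    K_R: float = 34.0        # mV
    # integrate-and-fire reduction.  The firing threshold and reset sit
    # 20 and 4 mV above the cell's reference resting level, for which the
    # leakage reversal potential E_L (the passive resting potential) is
    # used; anchoring them to this fixed reference rather than to the
    # instantaneous GHK value keeps the firing-rate rhythm in phase with
    # the day-peaked conductance drive (see the methods note).
    C_m: float = 8.0         # nF (calibrated; see methods note)
    theta_offset: float = 20.0    # mV above the reference resting level
    reset_offset: float = 4.0     # mV above the reference resting level
    T: float = BODY_T_C      # C


@dataclass(frozen=True)
class SignalParams:
    """VIP release/depletion, kinase activation and phospho-CREB cycle.

    VIP production saturates in firing rate (Hz); depletion is a fractional
    power of VIP.  Kinase rate v_k is the sum of Michaelian calcium and VIP
    terms.  The CREB cycle is a phosphorylation/dephosphorylation pair with
    total CREB ``CB_T``; ``C_T``/``K_c`` convert phospho-CREB into the
    Per-transcription drive added to the basal rate v_sP0.
    """

    v_VIP: float = 0.5       # nM/h max VIP release
    K_VIP: float = 15.0      # Hz**1.9 (lumped)
    n_VIP: float = 1.9
    k_dVIP: float = 0.5      # nM**0.8/h depletion coefficient
    n_dVIP: float = 0.2
    V_MK: float = 5.0        # nM/h max Ca-induced kinase activation
    K_MK: float = 2.9        # uM
    V_beta: float = 2.0      # nM/h max VIP-induced kinase activation
    K_beta: float = 2.0      # nM (treated as nM; printed dimensionless)
    C_T: float = 1.6         # nM/h max CREB-dependent Per transcription
    K_c: float = 0.15        # nM, half-activation of the Per drive
    K_D: float = 0.08        # nM, Michaelis constant of CREB cycle
    CB_T: float = 0.12       # nM total CREB
    V_dCB: float = 0.6       # nM/h max CREB dephosphorylation


def _replace(obj, overrides: Mapping[str, Any]):
    unknown = set(overrides) - {f.name for f in dataclasses.fields(obj)}
    if unknown:
        raise KeyError(f"unknown parameter name(s): {sorted(unknown)}")
    for k, v in overrides.items():
        if not isinstance(v, (int, float)):
            raise TypeError(f"parameter {k!r} must be a number, got {v!r}")
        # every rate/threshold in the model is positive except signed
        # exponents and reversal potentials
        if k not in _SIGNED_OK and v <= 0:
            raise ValueError(f"parameter {k!r} must be positive, got {v}")
    return dataclasses.replace(obj, **overrides)


_SIGNED_OK = {
    "E_K_room", "E_Na_room", "E_L_room", "E_ex", "V_ref",
    "n_KCa", "n_ex2", "n_Cl", "npk",
}


@dataclass(frozen=True)
class Parameters:
    """The full model parameter set, grouped by layer."""

    clock: ClockParams = field(default_factory=ClockParams)
    calcium: CalciumParams = field(default_factory=CalciumParams)
    membrane: MembraneParams = field(default_factory=MembraneParams)
    signaling: SignalParams = field(default_factory=SignalParams)

    def with_overrides(
        self,
        clock: Mapping[str, Any] | None = None,
        calcium: Mapping[str, Any] | None = None,
        membrane: Mapping[str, Any] | None = None,
        signaling: Mapping[str, Any] | None = None,
    ) -> "Parameters":
        return Parameters(
            clock=_replace(self.clock, clock or {}),
            calcium=_replace(self.calcium, calcium or {}),
            membrane=_replace(self.membrane, membrane or {}),
            signaling=_replace(self.signaling, signaling or {}),
        )

    def to_dict(self) -> dict[str, dict[str, float]]:
        return {
            group: dataclasses.asdict(getattr(self, group))
            for group in ("clock", "calcium", "membrane", "signaling")
        }


# Canonical state ordering for all serialized vectors: calcium pair, the 16
# gene-network species, then the signaling pair.
STATE_NAMES: tuple[str, ...] = (
    "Ca", "Ca_store",
    "M_P", "M_C", "M_B",
    "P_C", "C_C", "P_CP", "C_CP",
    "PC_C", "PC_N", "PC_CP", "PC_NP",
    "B_C", "B_CP", "B_N", "B_NP", "I_N",
    "CB", "VIP",
)

# Nominal initial conditions (uM for the calcium pair, nM elsewhere).
INITIAL_STATE: dict[str, float] = {
    "Ca": 0.10, "Ca_store": 0.10,
    "M_P": 2.80, "M_C": 2.00, "M_B": 7.94,
    "P_C": 0.40, "C_C": 12.0, "P_CP": 0.13, "C_CP": 9.00,
    "PC_C": 1.26, "PC_N": 0.16, "PC_CP": 0.20, "PC_NP": 0.091,
    "B_C": 2.41, "B_CP": 0.48, "B_N": 1.94, "B_NP": 0.32, "I_N": 0.05,
    "CB": 0.12, "VIP": 0.00,
}
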