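"""16-state circadian gene network of a single SCN neuron.

The network is the classical mammalian Per/Cry/Bmal1 oscillator: CLOCK/BMAL1
(represented by nuclear BMAL1, B_N) activates Per and Cry transcription; the
PER/CRY complex shuttles to the nucleus and sequesters B_N into an inactive
complex I_N, closing the negative loop; B_N also represses its own mRNA,
closing the positive loop.  The Rev-Erb branch is omitted — it is not
required for sustained oscillation.

The only structural change relative to the classical network is the Per
transcription rate, which is not a constant: it is the basal rate v_sP0
plus a phospho-CREB-dependent activation supplied by the signaling layer,

    v_sP(t) = v_sP0 + C_T * CB / (K_c + CB)    [the ``per_drive`` argument
              is the full v_sP(t), in nM/h]

so electrical activity and calcium feed back onto gene expression.
This is the single place the coupled transcription rate is documented;
:func:`scnsim.signaling.per_transcription_rate` computes it.

State order (13 protein/complex species after the 3 mRNAs):
M_P, M_C, M_B, P_C, C_C, P_CP, C_CP, PC_C, PC_N, PC_CP, PC_NP,
B_C, B_CP, B_N, B_NP, I_N.
"""

from __future__ import annotations

import numpy as np

from .params import ClockParams

__all__ = ["CLOCK_STATE_NAMES", "clock_derivatives"]

CLOCK_STATE_NAMES: tuple[str, ...] = (
    "M_P", "M_C", "M_B",
    "P_C", "C_C", "P_CP", "C_CP",
    "PC_C", "PC_N", "PC_CP", "PC_NP",
    "B_C", "B_CP", "B_N", "B_NP", "I_N",
)


def clock_derivatives(
    state: np.ndarray, params: ClockParams, per_drive: float
) -> np.ndarray:
    """Instantaneous derivatives (nM/h) of the 16 gene-network species.

    Parameters
    ----------
    state
        The 16 concentrations in ``CLOCK_STATE_NAMES`` order, nM.
    params
        Clock rate constants.
    per_drive
        The full Per transcription rate v_sP (nM/h), basal plus
        CREB-dependent activation.  Must be non-negative.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (16,):
        raise ValueError(f"clock state must have 16 components, got {state.shape}")
    if np.any(state < 0):
        bad = CLOCK_STATE_NAMES[int(np.argmin(state))]
        raise ValueError(f"negative clock state component {bad}")
    if per_drive < 0:
        raise ValueError("per_drive must be non-negative")

    (MP, MC, MB, PC, CC, PCP, CCP,
     PCC, PCN, PCCP, PCNP, BC, BCP, BN, BNP, IN) = state
    p = params

    BNn = BN ** p.n
    BNm = BN ** p.m

    # mRNAs: Hill activation (Per, Cry) / repression (Bmal1), Michaelian
    # degradation plus nonspecific decay.
    dMP = (per_drive * BNn / (p.K_AP ** p.n + BNn)
           - p.v_mP * MP / (p.K_mP + MP) - p.k_dmp * MP)
    dMC = (p.v_sC * BNn / (p.K_AC ** p.n + BNn)
           - p.v_mC * MC / (p.K_mC + MC) - p.k_dmc * MC)
    dMB = (p.v_sB * p.K_IB ** p.m / (p.K_IB ** p.m + BNm)
           - p.v_mB * MB / (p.K_mB + MB) - p.k_dmb * MB)

    # cytosolic PER and CRY: translation, phosphorylation cycle, PER/CRY
    # complex formation/dissociation.
    dPC = (p.k_sP * MP - p.V_1P * PC / (p.K_p + PC)
           + p.V_2P * PCP / (p.K_dp + PCP)
           + p.k_4 * PCC - p.k_3 * PC * CC - p.k_dn * PC)
    dCC = (p.k_sC * MC - p.V_1C * CC / (p.K_p + CC)
           + p.V_2C * CCP / (p.K_dp + CCP)
           + p.k_4 * PCC - p.k_3 * PC * CC - p.k_dnc * CC)
    dPCP = (p.V_1P * PC / (p.K_p + PC) - p.V_2P * PCP / (p.K_dp + PCP)
            - p.v_dPC * PCP / (p.K_d + PCP) - p.k_dn * PCP)
    dCCP = (p.V_1C * CC / (p.K_p + CC) - p.V_2C * CCP / (p.K_dp + CCP)
            - p.v_dCC * CCP / (p.K_d + CCP) - p.k_dn * CCP)

    # PER/CRY complex, cytosolic and nuclear, with phosphorylation cycles,
    # nuclear shuttling (k_1 in, k_2 out) and sequestration of B_N.
    dPCC = (-p.V_1PC * PCC / (p.K_p + PCC)
            + p.V_2PC * PCCP / (p.K_dp + PCCP)
            - p.k_4 * PCC + p.k_3 * PC * CC
            + p.k_2 * PCN - p.k_1 * PCC - p.k_dn * PCC)
    dPCN = (-p.V_3PC * PCN / (p.K_p + PCN)
            + p.V_4PC * PCNP / (p.K_dp + PCNP)
            - p.k_2 * PCN + p.k_1 * PCC
            - p.k_7 * BN * PCN + p.k_8 * IN - p.k_dn * PCN)
    dPCCP = (p.V_1PC * PCC / (p.K_p + PCC)
             - p.V_2PC * PCCP / (p.K_dp + PCCP)
             - p.v_dPCC * PCCP / (p.K_d + PCCP) - p.k_dn * PCCP)
    dPCNP = (p.V_3PC * PCN / (p.K_p + PCN)
             - p.V_4PC * PCNP / (p.K_dp + PCNP)
             - p.v_dPCN * PCNP / (p.K_d + PCNP) - p.k_dn * PCNP)

    # BMAL1: translation, phosphorylation cycles, nuclear shuttling
    # (k_5 in, k_6 out) and sequestration into I_N.
    dBC = (p.k_sB * MB - p.V_1B * BC / (p.K_p + BC)
           + p.V_2B * BCP / (p.K_dp + BCP)
           - p.k_5 * BC + p.k_6 * BN - p.k_dn * BC)
    dBCP = (p.V_1B * BC / (p.K_p + BC) - p.V_2B * BCP / (p.K_dp + BCP)
            - p.v_dBC * BCP / (p.K_d + BCP) - p.k_dn * BCP)
    dBN = (-p.V_3B * BN / (p.K_p + BN) + p.V_4B * BNP / (p.K_dp + BNP)
           + p.k_5 * BC - p.k_6 * BN
           - p.k_7 * BN * PCN + p.k_8 * IN - p.k_dn * BN)
    dBNP = (p.V_3B * BN / (p.K_p + BN) - p.V_4B * BNP / (p.K_dp + BNP)
            - p.v_dBN * BNP / (p.K_d + BNP) - p.k_dn * BNP)

    # inactive nuclear complex BN:PCN
    dIN = (p.k_7 * BN * PCN - p.k_8 * IN
           - p.v_dIN * IN / (p.K_d + IN) - p.k_dn * IN)

    return np.array([dMP, dMC, dMB, dPC, dCC, dPCP, dCCP,
                     dPCC, dPCN, dPCCP, dPCNP, dBC, dBCP, dBN, dBNP, dIN])
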