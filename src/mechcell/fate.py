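"""Cell-fate subsystems: cyclin/Cdk relaxation oscillator, intrinsic +
extrinsic apoptosis, and the DNA-damage / p53-MDM2-WIP1 module.

The cycle module runs in dimensionless activity units and is integrated
deterministically in every cell (stochastic expression deregulates the
oscillator, so only cyclin D — the mitogenic input — is expression-coupled).
Ordered activation D -> E2F -> CycE -> CycA -> CycB -> Cdc20 produces one
division per relaxation loop; p21 inhibits Cdk activity and Chk1 blocks the
S->G2->M transition.

Apoptosis follows the extrinsic TRAIL -> C8 -> C3 -> cPARP route with the
C8 -> tBid -> Bax -> cytochrome-c mitochondrial amplification loop, and the
intrinsic route where unphosphorylated BIM and BAD (plus PUMA/NOXA) occupy
an anti-apoptotic BCL2 pool; free activated Bax forms pores ultrasensitively
and a C3a -> C8 positive feedback makes cPARP cleavage switch-like. Death is
latched when cPARP exceeds half of the PARP moiety.

DNA damage: etoposide produces double-strand lesions in proportion to
S-phase cyclin activity, ATM/ATR activate ultrasensitively, and the
p53-MDM2-WIP1 delayed negative feedback pulses while lesions persist.
"""

from __future__ import annotations

import numpy as np

from .network import S, NetworkParams

__all__ = ["cycle_rhs", "apoptosis_rhs", "damage_rhs", "phase_label",
           "s_phase_activity", "CYCLE_RESET"]


def _hill(x, K, n):
    xn = np.maximum(x, 0.0) ** n
    return xn / (K ** n + xn)


# G1 resting values the cycle module returns to after division
CYCLE_RESET = {"E2F": 0.0, "CycE": 0.0, "CycA": 0.0, "CycB": 0.0, "Cdc20": 0.0}


def cyclin_d_activity(y: np.ndarray, p: NetworkParams) -> np.ndarray:
    """Cyclin D/Cdk4-6 activity from cyclin D protein, inhibited by p21."""
    v = y[S["VOL"]]
    return (y[S["CycD"]] / (v * p.cycd_ref)) / (1.0 + y[S["p21"]] / p.K_p21_cycd)


def s_phase_activity(y: np.ndarray, p: NetworkParams) -> np.ndarray:
    """S-phase cyclin/Cdk2 activity (CycE + CycA, p21-inhibited)."""
    inhib = 1.0 / (1.0 + y[S["p21"]] / p.K_p21_cdk)
    return (y[S["CycE"]] + y[S["CycA"]]) * inhib


def cycle_rhs(y: np.ndarray, dy: np.ndarray, p: NetworkParams,
              cycd_drive=None) -> None:
    """Relaxation-oscillator ODEs for the cyclin sequence D->E->A->B.

    ``cycd_drive`` overrides the cyclin-D-derived drive (used by unit
    tests); by default it is computed from the CycD protein species.
    """
    d_act = cyclin_d_activity(y, p) if cycd_drive is None else cycd_drive
    inhib = 1.0 / (1.0 + y[S["p21"]] / p.K_p21_cdk)
    cyce_act = y[S["CycE"]] * inhib
    cyca_act = y[S["CycA"]] * inhib

    e2f, cyce, cyca = y[S["E2F"]], y[S["CycE"]], y[S["CycA"]]
    cycb, cdc20 = y[S["CycB"]], y[S["Cdc20"]]

    # E2F switches on with cyclin D activity and self-maintains through
    # CycE/Cdk2 (Rb hyperphosphorylation): the restriction point. Past it,
    # the cycle completes even if the mitogenic drive decays.
    e2f_drive = _hill(d_act, p.K_e2f, p.n_e2f) \
        + p.w_e2f_cyce * _hill(cyce_act, p.K_cyce_e2f, 4.0)
    dy[S["E2F"]] += p.k_e2f_on * e2f_drive * (1.0 - e2f) \
        - p.k_e2f_off * (1.0 + p.a_e2f_cyca * cyca_act) * e2f
    dy[S["CycE"]] += p.k_s_cyce * e2f \
        - p.k_d_cyce * (1.0 + p.a_cyce_cyca * cyca_act) * cyce
    # the CycA program requires prior CycE/Cdk2 activity (sequential
    # activation: E before A)
    dy[S["CycA"]] += p.k_s_cyca * e2f * _hill(cyce_act, 0.25, 2.0) \
        - p.k_d_cyca * (1.0 + p.a_cdc20_cyca * cdc20) * cyca
    chk_brake = 1.0 / (1.0 + y[S["Chk1a"]] / p.K_chk1)
    # p21 also inhibits cyclin B/Cdk1 loading. CycB accumulation is
    # autocatalytic (Cdc25-like positive feedback), giving the M-phase
    # trigger a robust all-or-none character.
    self_amp = p.cycb_auto_basal + (1.0 - p.cycb_auto_basal) \
        * _hill(cycb, p.K_cycb_auto, 4.0)
    dy[S["CycB"]] += p.k_s_cycb * _hill(cyca_act, p.K_cyca_b, p.n_cycb) \
        * self_amp * chk_brake * inhib \
        - p.k_d_cycb * (1.0 + p.a_cdc20_cycb * cdc20) * cycb
    dy[S["Cdc20"]] += p.k_cdc20_on * _hill(cycb, p.K_cycb_c20, p.n_cdc20) * (1.0 - cdc20) \
        - p.k_cdc20_off * cdc20

    # p21 and Chk1 (p53/damage inputs; intrinsic synthesis, not omics-coupled).
    # Strongly induced p21 resists degradation (arrest latch), so
    # damage-arrested cells stay arrested after p53 returns to baseline.
    p53_drive = _hill(y[S["p53"]] / p.K_p53_p21, 1.0, 4.0)
    p21 = y[S["p21"]]
    latch = 1.0 - p.p21_latch * _hill(p21, p.K_p21_latch, 4.0)
    dy[S["p21"]] += p.ks_p21_basal + p.ks_p21_p53 * p53_drive \
        - p.kd_p21 * p21 * latch
    dmg = y[S["ATMa"]] + y[S["ATRa"]]
    dy[S["Chk1a"]] += p.k_chk1_act * dmg * (1.0 - y[S["Chk1a"]]) \
        - p.k_chk1_deact * y[S["Chk1a"]]


def phase_label(y: np.ndarray, p: NetworkParams) -> np.ndarray:
    """Cell-cycle phase as a pure function of cyclin activities.

    Returns an integer array: 0=G0/G1, 1=S, 2=G2, 3=M."""
    s_act = s_phase_activity(y, p)
    b = y[S["CycB"]]
    phase = np.zeros(np.shape(y[S["CycB"]]), dtype=int)
    in_s = s_act >= p.s_phase_thresh
    phase = np.where(in_s & (y[S["CycA"]] <= y[S["CycE"]]), 1, phase)
    phase = np.where(in_s & (y[S["CycA"]] > y[S["CycE"]]), 2, phase)
    phase = np.where(b >= p.m_phase_thresh, 3, phase)
    return phase


def apoptosis_rhs(y: np.ndarray, dy: np.ndarray, p: NetworkParams,
                  trail_ng_ml: float = 0.0, akti_um: float = 0.0) -> None:
    """Extrinsic + intrinsic apoptosis fluxes."""
    from .signaling import inhibitor_factor
    fA = inhibitor_factor(akti_um, p.K_akti)
    v = y[S["VOL"]]
    # kinase drives are concentrations (amount / volume)
    erk_hat = y[S["ppERK"]] / (p.pperk_ref * v)
    akt_hat = y[S["ppAKT"]] / (p.akt_ref * v)

    # death receptor and initiator caspase
    dr_act = p.k_on_trail * trail_ng_ml * y[S["DR"]]
    dr_deact = p.k_off_trail * y[S["DRa"]]
    dy[S["DR"]] += -dr_act + dr_deact
    dy[S["DRa"]] += dr_act - dr_deact

    c8_act = (p.k_c8_dr * y[S["DRa"]] / (p.dr_ref * v) + p.c8_basal
              + p.k_c8_c3 * _hill(y[S["C3a"]] / (p.c3_ref * v), 0.3, 2.0)) * y[S["C8"]]
    c8_deact = p.k_c8a_deact * y[S["C8a"]]
    dy[S["C8"]] += -c8_act + c8_deact
    dy[S["C8a"]] += c8_act - c8_deact

    bid_cleave = p.k_bid_cleave * (y[S["C8a"]] / (p.c8_ref * v)) * y[S["Bid"]]
    tbid_rev = p.k_tbid_revert * y[S["tBid"]]
    dy[S["Bid"]] += -bid_cleave + tbid_rev
    dy[S["tBid"]] += bid_cleave - tbid_rev

    # BIM / BAD modification cycles (survival-kinase regulation)
    if p.bim_arm_enabled:
        bim_phos = p.k_bim_phos * erk_hat * y[S["BIM_u"]]
    else:
        bim_phos = 0.0 * y[S["BIM_u"]]
    bim_dephos = p.k_bim_dephos * y[S["BIM_p"]]
    dy[S["BIM_u"]] += -bim_phos + bim_dephos
    dy[S["BIM_p"]] += bim_phos - bim_dephos

    if p.bad_arm_enabled:
        bad_phos = (p.k_bad_phos_erk * erk_hat
                    + p.k_bad_phos_akt * akt_hat * fA) * y[S["BAD_u"]]
    else:
        bad_phos = 0.0 * y[S["BAD_u"]]
    bad_dephos = p.k_bad_dephos * y[S["BAD_p"]]
    dy[S["BAD_u"]] += -bad_phos + bad_dephos
    dy[S["BAD_p"]] += bad_phos - bad_dephos

    # BCL2 pool binding (mass conservation across all complexes)
    bcl2 = y[S["BCL2"]]
    k_on = p.k_on_bcl2 * bcl2 / (p.bcl2_ref * v)
    for ligand, cplx, k_off in (("BIM_u", "B_BIM", p.k_off_bcl2),
                                ("BAD_u", "B_BAD", p.k_off_bcl2),
                                ("PUMA", "B_PUMA", p.k_off_bcl2),
                                ("NOXA", "B_NOXA", p.k_off_bcl2),
                                ("aBax", "B_Bax", p.k_off_bcl2_bax)):
        on = k_on * y[S[ligand]]
        off = k_off * y[S[cplx]]
        dy[S[ligand]] += -on + off
        dy[S[cplx]] += on - off
        dy[S["BCL2"]] += -on + off

    # Bax activation by direct activators (tBid, free unphosphorylated BIM)
    activator = p.w_tbid_bax * y[S["tBid"]] + p.w_bim_bax * y[S["BIM_u"]] \
        + p.w_puma_bax * y[S["PUMA"]] + p.w_noxa_bax * y[S["NOXA"]]
    bax_act = p.k_bax_act * (activator / (p.act_ref * v)) * y[S["Bax"]]
    bax_deact = p.k_bax_deact * y[S["aBax"]]
    dy[S["Bax"]] += -bax_act + bax_deact
    dy[S["aBax"]] += bax_act - bax_deact

    # MOMP: ultrasensitive pore formation by free active Bax -> cytochrome c
    pore = _hill(y[S["aBax"]] / (p.bax_pore_ref * v), 1.0, p.n_pore)
    dy[S["CytC"]] += p.k_pore * pore * np.maximum(p.cytc_total * v - y[S["CytC"]], 0.0) \
        / (p.cytc_total * v) * p.cytc_ref * v - p.k_cytc_clear * y[S["CytC"]]

    # executioner caspase and PARP cleavage (snap action via C3a->C8 feedback)
    c3_act = (p.k_c3_c8 * y[S["C8a"]] / (p.c8_ref * v)
              + p.k_c3_cytc * _hill(y[S["CytC"]] / (p.cytc_ref * v), 1.0, p.n_c3)) * y[S["C3"]]
    c3_deact = p.k_c3a_deact * y[S["C3a"]]
    dy[S["C3"]] += -c3_act + c3_deact
    dy[S["C3a"]] += c3_act - c3_deact

    parp_cleave = p.k_parp_cleave * (y[S["C3a"]] / (p.c3_ref * v)) * y[S["PARP"]]
    dy[S["PARP"]] += -parp_cleave
    dy[S["cPARP"]] += parp_cleave


def damage_rhs(y: np.ndarray, dy: np.ndarray, p: NetworkParams,
               etoposide_um: float = 0.0, extra_dsb_rate=0.0,
               extra_ssb_rate=0.0, repair_enabled: bool = True) -> None:
    """Etoposide pharmacodynamics, lesion repair, ATM/ATR and p53 pulsing."""
    s_act = s_phase_activity(y, p)
    eto_hat = etoposide_um / p.eto_ref_um
    dsb_prod = p.k_dsb_eto * eto_hat * _hill(s_act, p.K_s_eto, p.n_s_eto) \
        + extra_dsb_rate
    ssb_prod = p.k_ssb_eto * eto_hat + extra_ssb_rate
    rep = 1.0 if repair_enabled else 0.0
    dy[S["DSB"]] += dsb_prod - rep * p.k_rep_dsb * p.brca2_scale \
        * y[S["DSB"]] / (p.K_rep + y[S["DSB"]])
    dy[S["SSB"]] += ssb_prod - rep * p.k_rep_ssb * p.msh6_scale \
        * y[S["SSB"]] / (p.K_rep + y[S["SSB"]])

    # ultrasensitive ATM/ATR activation, WIP1 feedback on ATM
    atm_on = p.k_atm_act * _hill(y[S["DSB"]], p.K_dsb_atm, p.n_atm) * (1.0 - y[S["ATMa"]])
    atm_off = p.k_atm_deact * (1.0 + p.a_wip1_atm * y[S["WIP1"]]) * y[S["ATMa"]]
    dy[S["ATMa"]] += atm_on - atm_off
    atr_on = p.k_atr_act * _hill(y[S["SSB"]], p.K_ssb_atr, p.n_atm) * (1.0 - y[S["ATRa"]])
    atr_off = p.k_atr_deact * y[S["ATRa"]]
    dy[S["ATRa"]] += atr_on - atr_off

    # p53-MDM2-WIP1 delayed negative feedback
    dmg = y[S["ATMa"]] + y[S["ATRa"]]
    p53 = y[S["p53"]]
    dy[S["p53"]] += p.ks_p53 * (1.0 + 2.0 * dmg) \
        - p.kd_p53 * y[S["MDM2"]] * p53 / (p.K_p53 + p53)
    dy[S["MDM2m"]] += p.ks_mdm2m * _hill(p53 / p.K_p53_m, 1.0, p.n_mdm2) \
        - p.kd_mdm2m * y[S["MDM2m"]]
    dy[S["MDM2"]] += p.ks_mdm2_basal + p.kt_mdm2 * y[S["MDM2m"]] \
        - p.kd_mdm2 * (1.0 + p.a_atm_mdm2 * dmg) * y[S["MDM2"]]
    dy[S["WIP1"]] += p.ks_wip1 * _hill(p53 / p.K_p53_w, 1.0, 2.0) \
        - p.kd_wip1 * y[S["WIP1"]]
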