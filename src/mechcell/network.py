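"""Reduced driver-network: species registry, rate constants, and the
coupling between the stochastic expression layer and the deterministic
signaling/fate ODEs.

The network keeps the architecture of the full-scale model — two exemplar
receptor classes feeding Ras/Raf/MEK/ERK and PI3K/PIP3/AKT with one
negative feedback per arm, Raf:MEK complex formation (sequestration),
mTOR/EIF4E translation control, FOXO shuttling, AP1/cMyc transcription
drives, a cyclin relaxation oscillator, an intrinsic+extrinsic apoptosis
module buffered by a BCL2 pool, and a p53-MDM2-WIP1 damage oscillator —
at ~80 species. Rate constants are this package's own calibration; they
are chosen so every deterministic relaxation rate stays below ~600/h
(non-stiff at the 15-s substep of the hybrid integrator).

State is a (n_species, n_cells) float array of molecules per cell
(activity-like species are normalized to [0, ~1]).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = ["SPECIES", "S", "n_species", "NetworkParams", "MOIETIES",
           "EXPRESSION_COUPLING", "moiety_total", "params_to_file",
           "params_from_file"]

# ---------------------------------------------------------------------------
# species registry

SPECIES: list[str] = [
    # EGFR-like receptor (dimerizing, ERK-biased, transient)
    "RE", "RE_L", "pRE", "pRE_i",
    # InsR/IGF1R-like receptor (AKT-biased, sustained)
    "RI", "pRI",
    # Ras
    "RasD", "RasT",
    # Raf isoforms, free and MEK-bound
    "CRaf", "aCRaf", "CRaf_MEK", "aCRaf_MEK",
    "BRaf", "aBRaf", "BRaf_MEK", "aBRaf_MEK",
    # MEK / ERK
    "MEK", "ppMEK", "ERK", "ppERK",
    # PI3K / AKT axis
    "PI3K", "aPI3K", "PIP2", "PIP3", "AKT", "ppAKT", "PTEN",
    # mTOR / EIF4E translation control
    "MTOR", "mTORa", "EIF4E", "EIF4E_BP", "BP1", "pBP1",
    # FOXO (nuclear active / phospho-cytoplasmic)
    "FOXO_n", "FOXO_c",
    # transcription factors & cyclin D protein
    "cFos", "cJun", "cMyc", "CycD",
    # cell-cycle module (deterministic, activity units)
    "E2F", "CycE", "CycA", "CycB", "Cdc20", "p21", "Chk1a",
    # DNA damage module
    "SSB", "DSB", "ATMa", "ATRa", "p53", "MDM2m", "MDM2", "WIP1",
    # apoptosis module
    "DR", "DRa", "C8", "C8a", "Bid", "tBid", "C3", "C3a",
    "PARP", "cPARP",
    "Bax", "aBax",
    "BCL2", "B_BIM", "B_BAD", "B_PUMA", "B_NOXA", "B_Bax",
    "BIM_u", "BIM_p", "BAD_u", "BAD_p", "PUMA", "NOXA", "CytC",
    # growth
    "RIB", "VOL",
]

S = {name: i for i, name in enumerate(SPECIES)}
n_species = len(SPECIES)

# conserved moieties: name -> list of (species, weight). Dimers carry two
# receptors. Checked by the conservation tests with expression fluxes off.
MOIETIES: dict[str, list[tuple[str, float]]] = {
    "RTK_E": [("RE", 1), ("RE_L", 1), ("pRE", 2), ("pRE_i", 2)],
    "RTK_I": [("RI", 1), ("pRI", 1)],
    "RAS": [("RasD", 1), ("RasT", 1)],
    "CRAF": [("CRaf", 1), ("aCRaf", 1), ("CRaf_MEK", 1), ("aCRaf_MEK", 1)],
    "BRAF": [("BRaf", 1), ("aBRaf", 1), ("BRaf_MEK", 1), ("aBRaf_MEK", 1)],
    "MEK": [("MEK", 1), ("ppMEK", 1), ("CRaf_MEK", 1), ("aCRaf_MEK", 1),
            ("BRaf_MEK", 1), ("aBRaf_MEK", 1)],
    "ERK": [("ERK", 1), ("ppERK", 1)],
    "PI3K": [("PI3K", 1), ("aPI3K", 1)],
    "PIP": [("PIP2", 1), ("PIP3", 1)],
    "AKT": [("AKT", 1), ("ppAKT", 1)],
    "PTEN": [("PTEN", 1)],
    "MTOR": [("MTOR", 1), ("mTORa", 1)],
    "EIF4E": [("EIF4E", 1), ("EIF4E_BP", 1)],
    "BP1": [("BP1", 1), ("pBP1", 1), ("EIF4E_BP", 1)],
    "FOXO": [("FOXO_n", 1), ("FOXO_c", 1)],
    "CFOS": [("cFos", 1)],
    "CJUN": [("cJun", 1)],
    "CMYC": [("cMyc", 1)],
    "CYCD": [("CycD", 1)],
    "DR": [("DR", 1), ("DRa", 1)],
    "C8": [("C8", 1), ("C8a", 1)],
    "BID": [("Bid", 1), ("tBid", 1)],
    "C3": [("C3", 1), ("C3a", 1)],
    "PARP": [("PARP", 1), ("cPARP", 1)],
    "BAX": [("Bax", 1), ("aBax", 1), ("B_Bax", 1)],
    "BCL2": [("BCL2", 1), ("B_BIM", 1), ("B_BAD", 1), ("B_PUMA", 1),
             ("B_NOXA", 1), ("B_Bax", 1)],
    "BIM": [("BIM_u", 1), ("BIM_p", 1), ("B_BIM", 1)],
    "BAD": [("BAD_u", 1), ("BAD_p", 1), ("B_BAD", 1)],
    "PUMA": [("PUMA", 1), ("B_PUMA", 1)],
    "NOXA": [("NOXA", 1), ("B_NOXA", 1)],
}


def moiety_total(y: np.ndarray, moiety: str) -> np.ndarray:
    """Total of a conserved moiety (sum across all forms, weighted)."""
    parts = MOIETIES[moiety]
    return sum(w * y[S[sp]] for sp, w in parts)


@dataclass
class CouplingEntry:
    """How one conglomerate's stochastic expression feeds the ODE layer."""

    conglomerate: str
    genes: list[str]  # member gene_ids in the tailored gene table
    newborn: str  # species receiving the synthesis flux
    moiety: str  # moiety whose forms share the gene's degradation rate
    # form-specific extra first-order decay, as multiples of the gene k_dp
    extra_decay: dict[str, float] = field(default_factory=dict)


# conglomerate -> coupling. Genes absent from an omics table still tailor
# (imputation), genes of the cycle/damage modules are intentionally NOT
# expression-coupled (stochastic expression deregulates the oscillator).
EXPRESSION_COUPLING: dict[str, CouplingEntry] = {c.conglomerate: c for c in [
    CouplingEntry("RTK_E", ["EGFR", "ERBB2"], "RE", "RTK_E",
                  extra_decay={"pRE_i": 25.0}),
    CouplingEntry("RTK_I", ["INSR", "IGF1R"], "RI", "RTK_I"),
    CouplingEntry("RAS", ["HRAS", "KRAS", "NRAS"], "RasD", "RAS"),
    CouplingEntry("CRAF", ["RAF1"], "CRaf", "CRAF"),
    CouplingEntry("BRAF", ["BRAF"], "BRaf", "BRAF"),
    CouplingEntry("MEK", ["MAP2K1", "MAP2K2"], "MEK", "MEK"),
    CouplingEntry("ERK", ["MAPK1", "MAPK3"], "ERK", "ERK"),
    CouplingEntry("PI3K", ["PIK3CA"], "PI3K", "PI3K"),
    CouplingEntry("PTEN", ["PTEN"], "PTEN", "PTEN"),
    CouplingEntry("AKT", ["AKT1", "AKT2"], "AKT", "AKT"),
    CouplingEntry("MTOR", ["MTOR"], "MTOR", "MTOR"),
    CouplingEntry("EIF4E", ["EIF4E"], "EIF4E", "EIF4E"),
    CouplingEntry("BP1", ["EIF4EBP1"], "BP1", "BP1"),
    CouplingEntry("FOXO", ["FOXO3"], "FOXO_n", "FOXO",
                  extra_decay={"FOXO_c": 3.0}),
    CouplingEntry("CFOS", ["FOS"], "cFos", "CFOS"),
    CouplingEntry("CJUN", ["JUN"], "cJun", "CJUN"),
    CouplingEntry("CMYC", ["MYC"], "cMyc", "CMYC"),
    CouplingEntry("CYCD", ["CCND1"], "CycD", "CYCD"),
    CouplingEntry("DR", ["TNFRSF10B"], "DR", "DR"),
    CouplingEntry("C8", ["CASP8"], "C8", "C8"),
    CouplingEntry("BID", ["BID"], "Bid", "BID"),
    CouplingEntry("C3", ["CASP3"], "C3", "C3"),
    CouplingEntry("PARP", ["PARP1"], "PARP", "PARP"),
    CouplingEntry("BAX", ["BAX"], "Bax", "BAX"),
    CouplingEntry("BCL2", ["BCL2"], "BCL2", "BCL2"),
    CouplingEntry("BIM", ["BCL2L11"], "BIM_u", "BIM",
                  extra_decay={"BIM_p": 3.0}),
    CouplingEntry("BAD", ["BAD"], "BAD_u", "BAD"),
    CouplingEntry("PUMA", ["BBC3"], "PUMA", "PUMA"),
    CouplingEntry("NOXA", ["PMAIP1"], "NOXA", "NOXA"),
]}

# genes tailored from omics but used only as static capacities (repair) or
# handled by the intrinsic synthesis of the cycle/damage modules
UNCOUPLED_GENES = ["TP53", "MDM2", "PPM1D", "CHEK1", "CCNE1", "CCNA2",
                   "CCNB1", "CDKN1A", "E2F1", "BRCA2", "MSH6", "MGMT"]


# ---------------------------------------------------------------------------
# parameters


@dataclass
class NetworkParams:
    """All rate constants of the reduced network (units: hours, molecules,
    nM for ligands, uM for drugs). Defaults are the shipped MCF10A-style
    calibration."""

    # --- receptors ---
    k_on_E: float = 1.0        # 1/(nM h) EGF binding
    k_off_E: float = 2.0       # 1/h
    k_dim: float = 25.0        # 1/h at RE_L = dim_ref
    dim_ref: float = 1.0e5
    k_dim_basal: float = 3.0e-4  # 1/h basal (ligand-free) activation
    k_undim: float = 0.3       # 1/h active dimer dissociation -> 2 RE
    k_int: float = 3.0         # 1/h internalization of active dimer
    k_rec: float = 0.4         # 1/h recycling pRE_i -> 2 RE
    k_on_I: float = 0.006      # 1/(nM h) insulin-class activation
    k_off_I: float = 0.6       # 1/h
    k_basal_I: float = 4.0e-4  # 1/h basal RI activation
    endo_signal_weight: float = 0.7  # pRE_i signaling efficiency vs pRE

    # --- Ras / Raf / MEK / ERK ---
    k_ras_act: float = 12.0    # 1/h at pRTK = rtk_ref
    rtk_ref: float = 2.0e4
    w_RI_ras: float = 0.02     # InsR-class weight onto Ras
    w_RE_pi3k: float = 0.2     # EGFR-class weight onto PI3K
    k_gap: float = 20.0        # 1/h RasGTP hydrolysis
    k_raf_act: float = 30.0    # 1/h at RasT = ras_ref (CRaf)
    k_raf_act_B: float = 60.0  # BRaf more active per molecule
    ras_ref: float = 3.0e4
    k_raf_deact: float = 10.0  # 1/h
    K_fb_erk: float = 1.0e5    # ppERK feedback on Raf activation
    n_fb_erk: float = 2.0
    k_on_RM: float = 30.0      # 1/h at MEK_free = mek_ref (Raf:MEK binding)
    mek_ref: float = 5.0e5
    k_off_RM: float = 10.0     # 1/h
    k_cat_RM: float = 60.0     # 1/h ppMEK production per active complex
    k_mek_dephos: float = 10.0
    k_cat_MEK: float = 60.0    # 1/h ERK phosphorylation at ppMEK = ppmek_ref
    ppmek_ref: float = 5.0e4
    k_erk_dephos: float = 12.0
    K_erk_sat: float = 1.0e5   # MEK->ERK saturation (ppERK output Raf-limited)
    K_meki: float = 0.05       # uM competitive factor K/(K+dose)

    # --- PI3K / AKT ---
    k_pi3k_act: float = 20.0   # 1/h at pRTK = rtk_ref_p
    rtk_ref_p: float = 2.0e4
    k_pi3k_deact: float = 10.0
    K_fb_akt: float = 0.6      # mTORa feedback on PI3K activation
    k_pip3: float = 30.0       # 1/h at aPI3K = pi3k_ref
    pi3k_ref: float = 2.5e4
    k_pten: float = 30.0       # 1/h at PTEN = pten_ref
    pten_ref: float = 1.2e5
    k_akt_act: float = 30.0    # 1/h at PIP3 = pip3_ref
    pip3_ref: float = 5.0e4
    k_akt_deact: float = 15.0
    K_akti: float = 0.05       # uM

    # --- mTOR / EIF4E / FOXO ---
    k_mtor_act: float = 6.0    # 1/h at ppAKT = akt_ref
    akt_ref: float = 1.2e5
    k_mtor_deact: float = 2.0
    k_bp1_phos: float = 30.0   # 1/h at mTORa fraction 1 (acts on free + bound)
    k_bp1_dephos: float = 2.0
    k_on_4ebp: float = 60.0    # 1/h at BP1 = bp1_ref
    bp1_ref: float = 8.0e4
    k_off_4ebp: float = 3.0
    k_foxo_phos: float = 8.0   # 1/h at ppAKT = akt_ref
    k_foxo_dephos: float = 1.0

    # --- transcription drives ---
    pperk_ref: float = 2.0e5   # normalization for ppERK-driven terms
    fos_induced_kbm: float = 400.0  # mRNA/(gene h) max induced cFos transcription
    n_fos: float = 2.0
    jun_erk_fold: float = 6.0
    jun_ap1_fold: float = 10.0
    K_ap1: float = 6.0e6       # cFos*cJun product scale (molecules^2)
    n_ap1: float = 2.0
    myc_akt_fold: float = 3.5  # shallow (n=1) cMyc translation boost by ppAKT
    cycd_ap1_fold: float = 20.0
    cycd_myc_fold: float = 0.8  # sustained cMyc arm of the cyclin D drive
    cycd_basal: float = 0.04   # basal fraction of max cyclin D drive
    K_myc: float = 9.0e4       # cMyc scale in the cyclin D AND gate
    myc_gate0: float = 0.7     # cMyc threshold of the AND gate
    myc_gate_width: float = 0.6
    bim_foxo_fold: float = 1.2
    foxo_ref_frac: float = 0.55  # basal nuclear FOXO fraction (normalization)
    p53_target_fold: float = 200.0  # PUMA/NOXA induction at p53_hat = 1
    a_p53_bcl2: float = 8.0    # p53 repression of BCL2 synthesis
    p53_ref: float = 1.0

    # --- cell cycle (activity units, ~20 h period at full drive) ---
    cycd_ref: float = 3.0e4    # CycD molecules at half-max Cdk4/6 activity
    K_p21_cycd: float = 0.5
    n_e2f: float = 4.0
    K_e2f: float = 0.5         # CycD activity at E2F switch
    k_e2f_on: float = 0.66
    w_e2f_cyce: float = 1.0    # CycE->E2F positive feedback (restriction point)
    K_cyce_e2f: float = 0.45
    k_e2f_off: float = 0.22
    a_e2f_cyca: float = 4.0    # CycA-driven E2F inactivation
    k_s_cyce: float = 0.17
    k_d_cyce: float = 0.075
    a_cyce_cyca: float = 2.5
    k_s_cyca: float = 0.095
    k_d_cyca: float = 0.055
    a_cdc20_cyca: float = 40.0
    k_s_cycb: float = 4.0
    n_cycb: float = 2.0
    K_cyca_b: float = 0.63     # CycA activity gating CycB synthesis
    k_d_cycb: float = 0.1
    cycb_auto_basal: float = 0.15  # basal fraction of CycB synthesis
    K_cycb_auto: float = 0.4   # CycB self-amplification midpoint
    a_cdc20_cycb: float = 60.0
    k_cdc20_on: float = 0.5
    n_cdc20: float = 6.0
    K_cycb_c20: float = 0.42
    k_cdc20_off: float = 0.2
    K_p21_cdk: float = 0.3     # p21 inhibition of CycE/CycA activity
    K_chk1: float = 0.25       # Chk1 brake on CycB synthesis
    s_phase_thresh: float = 0.5   # CycE+CycA activity marking S entry
    m_phase_thresh: float = 0.6
    div_frac_of_peak: float = 0.1
    g1_refractory_h: float = 6.0  # post-mitotic licensing delay

    # --- DNA damage / p53 ---
    k_dsb_eto: float = 6.5     # lesions/h at 100 uM etoposide, full S activity
    eto_ref_um: float = 100.0
    K_s_eto: float = 0.18      # S-phase cyclin activity at half-max damage
    n_s_eto: float = 2.0
    k_ssb_eto: float = 0.6
    k_rep_dsb: float = 5.0     # lesions/h max repair (BRCA2-like, saturating)
    K_rep: float = 0.3      # lesions at half-max repair
    k_rep_ssb: float = 2.0
    k_atm_act: float = 30.0
    n_atm: float = 4.0
    K_dsb_atm: float = 4.0     # lesions at half-max ATM activation
    k_atm_deact: float = 3.0
    a_wip1_atm: float = 0.5
    k_atr_act: float = 20.0
    K_ssb_atr: float = 8.0
    k_atr_deact: float = 3.0
    ks_p53: float = 0.29       # 1/h (activity units)
    kd_p53: float = 4.21       # 1/h at MDM2 = 1
    K_p53: float = 0.05
    ks_mdm2m: float = 1.98
    ks_mdm2_basal: float = 0.1
    n_mdm2: float = 4.0
    K_p53_m: float = 1.48
    kd_mdm2m: float = 0.67
    kt_mdm2: float = 4.47
    kd_mdm2: float = 1.12
    a_atm_mdm2: float = 0.0
    ks_wip1: float = 0.5
    K_p53_w: float = 1.5
    kd_wip1: float = 0.7
    ks_p21_p53: float = 6.0
    K_p53_p21: float = 1.1
    ks_p21_basal: float = 0.01
    kd_p21: float = 0.6
    p21_latch: float = 0.97    # max fractional block of p21 turnover
    K_p21_latch: float = 1.2   # p21 level where the arrest latch engages
    k_chk1_act: float = 4.0
    k_chk1_deact: float = 1.0

    # --- apoptosis ---
    k_on_trail: float = 0.01   # 1/(ng/mL h)
    k_off_trail: float = 0.3
    k_c8_dr: float = 3.0       # 1/h at DRa = dr_ref
    dr_ref: float = 1.0e4
    c8_basal: float = 8.0e-4   # 1/h basal C8 activation (starved-death knob)
    k_c8_c3: float = 1.5       # 1/h at C3a = c3_ref (feedback, snap action)
    k_c8a_deact: float = 0.3
    k_bid_cleave: float = 2.0  # 1/h at C8a = c8_ref
    c8_ref: float = 2.0e4
    k_tbid_revert: float = 0.3
    k_bax_act: float = 0.095   # 1/h at activator = act_ref
    act_ref: float = 3.0e4
    w_bim_bax: float = 1.0     # BIM_u as direct Bax activator
    w_puma_bax: float = 1.0    # free PUMA as direct Bax activator
    w_noxa_bax: float = 1.0    # free NOXA as direct Bax activator
    w_tbid_bax: float = 1.5
    k_bax_deact: float = 6.0
    k_on_bcl2: float = 25.0    # 1/h at BCL2_free = bcl2_ref
    bcl2_ref: float = 6.0e4
    k_off_bcl2: float = 3.0
    k_off_bcl2_bax: float = 1.5
    k_pore: float = 70.0       # 1/h max MOMP flux scale
    bax_pore_ref: float = 4.0e4
    n_pore: float = 2.0
    cytc_total: float = 1.0e5
    k_cytc_clear: float = 2.0
    k_c3_c8: float = 0.05      # 1/h at C8a = c8_ref (type I)
    k_c3_cytc: float = 40.0    # 1/h at CytC released = cytc_ref
    cytc_ref: float = 5.0e4
    n_c3: float = 2.0
    k_c3a_deact: float = 1.0
    k_parp_cleave: float = 30.0  # 1/h at C3a = c3_ref
    c3_ref: float = 5.0e4
    k_bim_phos: float = 10.0   # 1/h at ppERK = pperk_ref
    k_bim_dephos: float = 0.5
    k_bad_phos_erk: float = 5.0
    k_bad_phos_akt: float = 8.0
    k_bad_dephos: float = 0.5
    death_cparp_frac: float = 0.5
    bim_arm_enabled: bool = True   # ERK->BIM + FOXO->BIM regulation
    bad_arm_enabled: bool = True   # ERK/AKT->BAD regulation

    # --- growth / translation ---
    rib_ref: float = 6.0e6
    k_rib_turnover: float = float(np.log(1.5) / 20.0)
    rib_gain: float = 3.0
    K_s6k: float = 0.35        # mTORa fraction at half-max ribosome drive
    s6k_margin: float = 0.08   # dead-band above basal before growth engages
    theta_hill_k: float = 2.5e4
    theta_hill_n: float = 2.0
    theta_max: float = 2.0

    # repair capacities (set from proteomics at tailoring time)
    brca2_scale: float = 1.0
    msh6_scale: float = 1.0

    # fixed lipid pool (PIP2 + PIP3 moiety, not expression-coupled)
    pip_total: float = 1.0e5

    def copy(self) -> "NetworkParams":
        return dataclasses.replace(self)

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, bool):
                continue
            if isinstance(v, (int, float)):
                if not np.isfinite(v) or v < 0:
                    raise ValueError(f"parameter {f.name} must be finite and >= 0")


def params_to_file(params: NetworkParams, path) -> None:
    """Write the parameter set as 'key = value' lines."""
    with open(path, "w") as fh:
        fh.write("# mechcell reduced-network parameters (hours, molecules, nM, uM)\n")
        for f in dataclasses.fields(params):
            fh.write(f"{f.name} = {getattr(params, f.name)!r}\n")


def params_from_file(path) -> NetworkParams:
    """Read a 'key = value' parameter file; unknown keys are an error."""
    valid = {f.name: f.type for f in dataclasses.fields(NetworkParams)}
    kwargs = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed parameter line: {line!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in valid:
                raise KeyError(f"unknown network parameter {key!r}")
            kwargs[key] = (val == "True") if val in ("True", "False") else float(val)
    p = NetworkParams(**kwargs)
    p.validate()
    return p
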