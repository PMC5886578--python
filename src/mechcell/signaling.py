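"""Receptor -> ERK/AKT signaling layer of the reduced network.

Two exemplar receptor classes are modeled: an EGFR-like class (ligand
binding, dimerization, internalization and degradation-dominated
trafficking; ERK-biased, transient) and an InsR/IGF1R-like class
(AKT-biased, sustained). Downstream, mass-action futile cycles carry
pRTK -> Ras -> Raf -> ppMEK -> ppERK with ppERK->Raf negative feedback and
pRTK -> PI3K -> PIP3 -> ppAKT with mTOR->PI3K negative feedback. Raf binds
MEK in dead-end (inactive Raf) and productive (active Raf) complexes, which
is what makes MEK overexpression sequester Raf instead of amplifying ERK
output. Kinase inhibitors act as instantaneous competitive factors
K/(K+dose) on the target's catalytic rate.

All functions operate in-place on (n_species, n_cells) state/derivative
arrays using the `network.S` registry.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import curve_fit

from .network import S, NetworkParams

__all__ = ["receptor_rhs", "cascade_rhs", "transcription_drive", "fit_hill",
           "inhibitor_factor", "transformation_scan"]


def inhibitor_factor(dose_um: float, K_um: float) -> float:
    """Competitive inhibition factor K/(K+dose) applied to a catalytic rate."""
    if dose_um < 0:
        raise ValueError("inhibitor dose must be >= 0")
    return K_um / (K_um + dose_um)


def receptor_rhs(y: np.ndarray, dy: np.ndarray, p: NetworkParams,
                 egf_nM: float, ins_nM: float) -> None:
    """Ligand binding / dimerization / trafficking for both receptor classes."""
    if egf_nM < 0 or ins_nM < 0:
        raise ValueError("ligand doses must be >= 0")
    v = y[S["VOL"]]
    RE, RE_L, pRE, pRE_i = y[S["RE"]], y[S["RE_L"]], y[S["pRE"]], y[S["pRE_i"]]
    RI, pRI = y[S["RI"]], y[S["pRI"]]

    bind = p.k_on_E * egf_nM * RE
    unbind = p.k_off_E * RE_L
    dim = p.k_dim * RE_L * RE_L / (p.dim_ref * v)      # 2 RE_L -> pRE
    basal = 0.5 * p.k_dim_basal * RE                    # 2 RE -> pRE (slow)
    undim = p.k_undim * pRE                             # pRE -> 2 RE
    internal = p.k_int * pRE
    recyc = p.k_rec * pRE_i                             # pRE_i -> 2 RE

    dy[S["RE"]] += -bind + unbind - 2.0 * basal + 2.0 * undim + 2.0 * recyc
    dy[S["RE_L"]] += bind - unbind - 2.0 * dim
    dy[S["pRE"]] += dim + basal - undim - internal
    dy[S["pRE_i"]] += internal - recyc

    act_I = (p.k_on_I * ins_nM + p.k_basal_I) * RI
    deact_I = p.k_off_I * pRI
    dy[S["RI"]] += -act_I + deact_I
    dy[S["pRI"]] += act_I - deact_I


def _hill(x, K, n):
    xn = np.maximum(x, 0.0) ** n
    return xn / (K ** n + xn)


def cascade_rhs(y: np.ndarray, dy: np.ndarray, p: NetworkParams,
                meki_um: float = 0.0, akti_um: float = 0.0) -> None:
    """Ras/Raf/MEK/ERK and PI3K/AKT/mTOR/FOXO futile-cycle cascades."""
    fM = inhibitor_factor(meki_um, p.K_meki)
    fA = inhibitor_factor(akti_um, p.K_akti)
    v = y[S["VOL"]]

    pRE_sig = y[S["pRE"]] + p.endo_signal_weight * y[S["pRE_i"]]
    prtk_ras = pRE_sig + p.w_RI_ras * y[S["pRI"]]
    prtk_pi3k = p.w_RE_pi3k * pRE_sig + y[S["pRI"]]

    # catalytic drives are concentration-based (amount / volume), so cell
    # growth does not inflate signaling and division does not deflate it
    # Ras GDP/GTP cycle
    ras_act = p.k_ras_act * (prtk_ras / (p.rtk_ref * v)) * y[S["RasD"]]
    ras_deact = p.k_gap * y[S["RasT"]]
    dy[S["RasD"]] += -ras_act + ras_deact
    dy[S["RasT"]] += ras_act - ras_deact

    # Raf activation (free inactive Raf only; ppERK negative feedback).
    # Cooperative dependence on Ras-GTP keeps weak (insulin-class, basal)
    # inputs from leaking into the ERK arm.
    fb = 1.0 / (1.0 + (y[S["ppERK"]] / p.K_fb_erk) ** p.n_fb_erk)
    ras_rel = y[S["RasT"]] / (p.ras_ref * v)
    ras_drive = ras_rel ** 2 / (1.0 + ras_rel ** 2)
    mek_free = y[S["MEK"]]
    for iso, k_act in (("CRaf", p.k_raf_act), ("BRaf", p.k_raf_act_B)):
        i_free, a_free = S[iso], S["a" + iso]
        i_cplx, a_cplx = S[iso + "_MEK"], S["a" + iso + "_MEK"]
        act = k_act * ras_drive * fb * y[i_free]
        deact = p.k_raf_deact * y[a_free]
        deact_cplx = p.k_raf_deact * y[a_cplx]
        on_i = p.k_on_RM * (mek_free / (p.mek_ref * v)) * y[i_free]
        on_a = p.k_on_RM * (mek_free / (p.mek_ref * v)) * y[a_free]
        off_i = p.k_off_RM * y[i_cplx]
        off_a = p.k_off_RM * y[a_cplx]
        cat = p.k_cat_RM * y[a_cplx]  # aRaf:MEK -> aRaf + ppMEK
        dy[i_free] += -act + deact - on_i + off_i
        dy[a_free] += act - deact - on_a + off_a + cat
        dy[i_cplx] += on_i - off_i + deact_cplx
        dy[a_cplx] += on_a - off_a - cat - deact_cplx
        dy[S["MEK"]] += -on_i - on_a + off_i + off_a
        dy[S["ppMEK"]] += cat

    dy[S["MEK"]] += p.k_mek_dephos * y[S["ppMEK"]]
    dy[S["ppMEK"]] += -p.k_mek_dephos * y[S["ppMEK"]]

    # ERK activation; MEKi gates MEK catalytic activity. The reaction is
    # saturated in its ERK substrate, so ppERK output tracks upstream (Raf)
    # abundance rather than the large ERK pool.
    erk_sub = y[S["ERK"]] / (1.0 + y[S["ERK"]] / (p.K_erk_sat * v))
    erk_phos = p.k_cat_MEK * (y[S["ppMEK"]] / (p.ppmek_ref * v)) * fM * erk_sub
    erk_dephos = p.k_erk_dephos * y[S["ppERK"]]
    dy[S["ERK"]] += -erk_phos + erk_dephos
    dy[S["ppERK"]] += erk_phos - erk_dephos

    # PI3K/PIP3/AKT with mTOR-level negative feedback
    mtor_tot = y[S["MTOR"]] + y[S["mTORa"]]
    mtor_hat = y[S["mTORa"]] / np.maximum(mtor_tot, 1.0)
    fb_a = 1.0 / (1.0 + mtor_hat / p.K_fb_akt)
    pi_act = p.k_pi3k_act * (prtk_pi3k / (p.rtk_ref_p * v)) * fb_a * y[S["PI3K"]]
    pi_deact = p.k_pi3k_deact * y[S["aPI3K"]]
    dy[S["PI3K"]] += -pi_act + pi_deact
    dy[S["aPI3K"]] += pi_act - pi_deact

    pip_f = p.k_pip3 * (y[S["aPI3K"]] / (p.pi3k_ref * v)) * y[S["PIP2"]]
    pip_r = p.k_pten * (y[S["PTEN"]] / (p.pten_ref * v)) * y[S["PIP3"]]
    dy[S["PIP2"]] += -pip_f + pip_r
    dy[S["PIP3"]] += pip_f - pip_r

    akt_act = p.k_akt_act * (y[S["PIP3"]] / (p.pip3_ref * v)) * y[S["AKT"]]
    akt_deact = p.k_akt_deact * y[S["ppAKT"]]
    dy[S["AKT"]] += -akt_act + akt_deact
    dy[S["ppAKT"]] += akt_act - akt_deact

    # mTOR activity; AKTi gates AKT catalysis
    akt_hat = y[S["ppAKT"]] / (p.akt_ref * v)
    mt_act = p.k_mtor_act * akt_hat * fA * y[S["MTOR"]]
    mt_deact = p.k_mtor_deact * y[S["mTORa"]]
    dy[S["MTOR"]] += -mt_act + mt_deact
    dy[S["mTORa"]] += mt_act - mt_deact

    # EIF4E / 4EBP1: mTOR phosphorylates 4EBP1, releasing free EIF4E
    bp_phos_free = p.k_bp1_phos * mtor_hat * y[S["BP1"]]
    bp_phos_cplx = p.k_bp1_phos * mtor_hat * y[S["EIF4E_BP"]]
    bp_dephos = p.k_bp1_dephos * y[S["pBP1"]]
    bp_on = p.k_on_4ebp * (y[S["BP1"]] / (p.bp1_ref * v)) * y[S["EIF4E"]]
    bp_off = p.k_off_4ebp * y[S["EIF4E_BP"]]
    dy[S["BP1"]] += -bp_phos_free + bp_dephos - bp_on + bp_off
    dy[S["pBP1"]] += bp_phos_free + bp_phos_cplx - bp_dephos
    dy[S["EIF4E"]] += bp_phos_cplx - bp_on + bp_off
    dy[S["EIF4E_BP"]] += bp_on - bp_off - bp_phos_cplx

    # FOXO nuclear/cytoplasmic shuttling (AKT drives export)
    fx_out = p.k_foxo_phos * akt_hat * fA * y[S["FOXO_n"]]
    fx_in = p.k_foxo_dephos * y[S["FOXO_c"]]
    dy[S["FOXO_n"]] += -fx_out + fx_in
    dy[S["FOXO_c"]] += fx_out - fx_in


def transcription_drive(y: np.ndarray, p: NetworkParams,
                        akti_um: float = 0.0) -> dict:
    """Per-conglomerate transcription/translation multipliers.

    cFos transcription is induced by ppERK (additive rate, since its basal
    expression can be zero); cJun is driven by ppERK plus AP1 positive
    autoregulation (the source of AP1's sharp response to integrated ERK
    activity); cMyc translation is boosted by ppAKT with shallow n=1
    dependence; cyclin D transcription requires both arms (multiplicative
    AP1 x cMyc AND gate); BIM transcription follows nuclear FOXO; PUMA/NOXA
    follow p53.
    """
    fA = inhibitor_factor(akti_um, p.K_akti)
    v = y[S["VOL"]]
    erk_hat = y[S["ppERK"]] / (p.pperk_ref * v)
    akt_hat = y[S["ppAKT"]] / (p.akt_ref * v)

    ap1_act = y[S["cFos"]] * y[S["cJun"]] / (v * p.K_ap1)
    ap1_hat = _hill(ap1_act, 1.0, p.n_ap1)

    myc_hat = y[S["cMyc"]] / (v * p.K_myc)
    myc_gate = np.maximum(myc_hat - p.myc_gate0, 0.0) / p.myc_gate_width

    foxo_tot = y[S["FOXO_n"]] + y[S["FOXO_c"]]
    foxo_frac = y[S["FOXO_n"]] / np.maximum(foxo_tot, 1.0)

    p53_hat = _hill(y[S["p53"]] / p.p53_ref, 1.0, 4.0)

    bim_mult = np.ones_like(erk_hat)
    if p.bim_arm_enabled:
        bim_mult = 1.0 + p.bim_foxo_fold * np.maximum(
            foxo_frac - p.foxo_ref_frac, 0.0) / max(1.0 - p.foxo_ref_frac, 1e-9) \
            - 0.8 * np.maximum(p.foxo_ref_frac - foxo_frac, 0.0) / max(p.foxo_ref_frac, 1e-9)

    return {
        "k_bm_add": {"CFOS": p.fos_induced_kbm * _hill(erk_hat, 1.0, p.n_fos)},
        "k_bm_mult": {
            "CJUN": 1.0 + p.jun_erk_fold * _hill(erk_hat, 1.0, 1.0)
                    + p.jun_ap1_fold * ap1_hat,
            "CYCD": 1.0 + p.cycd_ap1_fold * ap1_hat * myc_gate
                    + p.cycd_myc_fold * myc_gate,
            "BIM": bim_mult,
            "PUMA": 1.0 + p.p53_target_fold * p53_hat,
            "NOXA": 1.0 + p.p53_target_fold * p53_hat,
            "BCL2": 1.0 / (1.0 + p.a_p53_bcl2 * p53_hat),
        },
        "k_bp_mult": {
            "CMYC": 1.0 + p.myc_akt_fold * fA * akt_hat / (1.0 + akt_hat),
        },
        "ap1_hat": ap1_hat,
        "myc_gate": myc_gate,
    }


# ---------------------------------------------------------------------------
# dose-response fitting


def fit_hill(doses, responses):
    """Least-squares Hill fit of a normalized dose-response curve.

    Returns (EC50, hill_coefficient). Needs >= 4 dose points with responses
    in [0, 1]; warns (but still fits) if the data are appreciably
    non-monotone.
    """
    doses = np.asarray(doses, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if len(doses) < 4:
        raise ValueError("need at least 4 dose points")
    if resp.min() < -1e-9 or resp.max() > 1.0 + 1e-9:
        raise ValueError("responses must be normalized to [0, 1]")
    order = np.argsort(doses)
    r_sorted = resp[order]
    if np.any(np.diff(r_sorted) < -0.05 * (r_sorted.max() - r_sorted.min() + 1e-12)):
        warnings.warn("dose-response is non-monotone beyond tolerance; "
                      "Hill fit returned anyway")

    def hill(d, rmax, ec50, n):
        return rmax * d ** n / (ec50 ** n + d ** n)

    pos = doses[doses > 0]
    ec0 = np.sqrt(pos.min() * pos.max()) if len(pos) else 1.0
    popt, _ = curve_fit(hill, doses, resp, p0=[max(resp.max(), 1e-6), ec0, 1.0],
                        bounds=([0, 1e-12, 0.1], [1.5, 1e12, 10.0]),
                        maxfev=20000)
    return float(popt[1]), float(popt[2])


# ---------------------------------------------------------------------------
# transformation scan


def transformation_scan(results, genes: dict[str, str], fold_change: float = 10.0,
                        n_cells: int = 30, duration_h: float = 24.0,
                        base_seed: int = 0):
    """Single-gene transformation-potential scan.

    For each gene, mRNA steady state is multiplied by ``fold_change``
    (oncogene) or divided (suppressor), rates re-derived, the average cell
    re-initialized, and the EGF+insulin percent-proliferating readout at
    ``duration_h`` recorded. Returns a list of (gene_id, percent, flag)
    sorted descending with the wild-type baseline included; variants whose
    re-initialization fails are flagged rather than dropped.

    ``results`` is an InitializedCellModel; ``genes`` maps gene_id to
    'oncogene' or 'suppressor'.
    """
    from . import simulate as sim  # local import: avoids a module cycle

    def readout(res, seed):
        pop = res.spawn_population(n_cells, base_seed=seed)
        cfg = sim.ExperimentConfig(
            population_size=n_cells, base_seed=seed,
            stimulus=sim.StimulusSpec(egf_ng_ml=20.0, insulin_ug_ml=10.0),
            duration_h=duration_h, readout_times=(duration_h,))
        _, summary = sim.run_experiment(pop, cfg, res)
        return summary.percent_proliferating[-1]

    rows = [("wild_type", readout(results, base_seed), "ok")]
    for gene, cls in genes.items():
        if cls not in ("oncogene", "suppressor"):
            raise ValueError(f"unknown classification {cls!r} for {gene}")
        factor = fold_change if cls == "oncogene" else 1.0 / fold_change
        try:
            variant = results.model.with_mrna_fold(gene, factor).fit(
                tolerance=results.report.tolerance,
                max_iter=results.report.max_iter)
            if not variant.report.converged:
                rows.append((gene, float("nan"), "init_not_converged"))
                continue
            rows.append((gene, readout(variant, base_seed), "ok"))
        except Exception as exc:  # noqa: BLE001 - variant failures are data
            rows.append((gene, float("nan"), f"failed: {exc}"))
    ok = [r for r in rows if r[2] == "ok"]
    bad = [r for r in rows if r[2] != "ok"]
    return sorted(ok, key=lambda r: -r[1]) + bad
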