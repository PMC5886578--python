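"""Model / Results objects.

`CellPopulationModel` is built from tailored gene records (or raw omics
tables) plus a network parameterization. Its `fit()` runs the average-cell
initialization: deterministic relaxation to a serum-starved steady state
with an outer loop rescaling each gene's effective translation rate until
every conglomerate's total conserved moiety matches its proteomics-derived
target. The returned `InitializedCellModel` carries the tailored system,
the average cell state, and an `InitializationReport`, and is the handle
for spawning stochastic populations and running experiments.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import omics as om
from . import signaling as sg
from . import expression as xp
from .network import (S, SPECIES, n_species, NetworkParams, MOIETIES,
                      EXPRESSION_COUPLING, CouplingEntry)

__all__ = ["TailoredSystem", "CellPopulationModel", "InitializedCellModel",
           "InitializationReport"]


class TailoredSystem:
    """Precomputed coupling between tailored gene records and the ODE layer."""

    def __init__(self, records: dict[str, om.GeneRecord], params: NetworkParams):
        self.params = params
        self.records = records
        self.couplings: list[CouplingEntry] = [
            EXPRESSION_COUPLING[c] for c in EXPRESSION_COUPLING]
        self.moieties = [c.moiety for c in self.couplings]

        gene_ids: list[str] = []
        self.cong_gene_slices: list[slice] = []
        self.newborn_idx: list[int] = []
        start = 0
        for c in self.couplings:
            members = [g for g in c.genes if g in records]
            gene_ids.extend(members)
            self.cong_gene_slices.append(slice(start, start + len(members)))
            self.newborn_idx.append(S[c.newborn])
            start += len(members)
        self.gene_ids = gene_ids
        self.n_genes = len(gene_ids)

        def arr(attr):
            return np.array([getattr(records[g], attr) for g in gene_ids], float)

        self.g_total = np.array([records[g].g_total for g in gene_ids], int)
        self.k_gac, self.k_gin = arr("k_gac"), arr("k_gin")
        self.k_bm, self.k_bp = arr("k_bm"), arr("k_bp")
        self.k_dm = np.array([records[g].k_dm for g in gene_ids])
        self.k_dp = np.array([records[g].k_dp for g in gene_ids])
        self.m_ss, self.p_ss = arr("m_ss"), arr("p_ss")
        self.g_active_ss = np.array([records[g].g_active_ss for g in gene_ids])
        self.k_bp_scale = np.ones(self.n_genes)  # initialization adjustment

        # silent-but-inducible genes (cFos-like: zero basal mRNA *and*
        # protein) get the cohort-median translation rate so induced
        # transcripts can actually be translated; knockouts (m_ss > 0,
        # k_bp forced to 0) are untouched.
        positive = self.k_bp[self.k_bp > 0]
        if len(positive):
            silent = (self.k_bp == 0) & (self.m_ss == 0) & (self.p_ss == 0) \
                & (self.g_total > 0)
            self.k_bp[silent] = float(np.median(positive))

        # per-conglomerate protein targets and degradation rates
        self.target_totals = np.array(
            [self.p_ss[sl].sum() for sl in self.cong_gene_slices])
        self._build_decay()
        self._build_moiety_arrays()

        self.translation = xp.TranslationControl(params.theta_hill_k,
                                                 params.theta_hill_n,
                                                 params.theta_max)
        # basal normalization (filled by set_basal during initialization)
        self.theta_basal = 1.0
        self.s6k_basal = 0.0
        self.basal_kbm_mult: dict[str, float] = {}
        self.basal_kbm_add: dict[str, float] = {}
        self.basal_kbp_mult: dict[str, float] = {}

    def _build_decay(self) -> None:
        """Per-species first-order decay rates.

        Every form of a coupled moiety decays at the member genes'
        abundance-weighted mean k_dp times any form-specific multiplier;
        hetero-complexes (shared by two moieties) decay at the mean of
        both parents' rates (degrading a complex destroys both proteins).
        """
        contributions: dict[int, list[float]] = {}
        for c, sl in zip(self.couplings, self.cong_gene_slices):
            w = self.p_ss[sl]
            kdp = self.k_dp[sl]
            k_eff = float(np.average(kdp, weights=w)) if w.sum() > 0 \
                else (float(kdp.mean()) if len(kdp) else 0.0)
            for sp, _weight in MOIETIES[c.moiety]:
                mult = c.extra_decay.get(sp, 1.0)
                contributions.setdefault(S[sp], []).append(k_eff * mult)
        self.decay_rates = np.zeros(n_species)
        for idx, vals in contributions.items():
            self.decay_rates[idx] = float(np.mean(vals))

    def _build_moiety_arrays(self) -> None:
        self.moiety_arrays = {}
        for m in self.moieties:
            idx = np.array([S[sp] for sp, _ in MOIETIES[m]], int)
            w = np.array([wt for _, wt in MOIETIES[m]], float)
            self.moiety_arrays[m] = (idx, w)

    # -- effective rates ---------------------------------------------------

    def _cong_of_gene(self):
        out = np.empty(self.n_genes, int)
        for ci, sl in enumerate(self.cong_gene_slices):
            out[sl] = ci
        return out

    def kbm_effective(self, drv: dict):
        """(k_bm multiplier-normalized, additive induced rate) per gene."""
        n_cols = np.shape(drv["ap1_hat"])[-1] if np.ndim(drv["ap1_hat"]) else 1
        kbm_eff = np.repeat(self.k_bm[:, None], n_cols, axis=1)
        kbm_add = np.zeros((self.n_genes, n_cols))
        if getattr(self, "_freeze_global", False):
            return kbm_eff, kbm_add
        for ci, c in enumerate(self.couplings):
            sl = self.cong_gene_slices[ci]
            mult = drv["k_bm_mult"].get(c.conglomerate)
            if mult is not None:
                base = self.basal_kbm_mult.get(c.conglomerate, 1.0)
                kbm_eff[sl] = self.k_bm[sl, None] * (np.asarray(mult) / base)
            add = drv["k_bm_add"].get(c.conglomerate)
            if add is not None:
                base = self.basal_kbm_add.get(c.conglomerate, 0.0)
                per_gene = np.maximum(np.asarray(add) - base, 0.0)
                kbm_add[sl] = per_gene  # induced rate per active gene copy
        return kbm_eff, kbm_add

    def kbp_multipliers(self, drv: dict):
        n_cols = np.shape(drv["ap1_hat"])[-1] if np.ndim(drv["ap1_hat"]) else 1
        mult = np.repeat(self.k_bp_scale[:, None], n_cols, axis=1)
        if getattr(self, "_freeze_global", False):
            return mult
        for ci, c in enumerate(self.couplings):
            m = drv["k_bp_mult"].get(c.conglomerate)
            if m is not None:
                base = self.basal_kbp_mult.get(c.conglomerate, 1.0)
                sl = self.cong_gene_slices[ci]
                mult[sl] = mult[sl] * (np.asarray(m) / base)
        return mult

    def set_basal(self, y_basal: np.ndarray) -> None:
        """Record the serum-starved operating point used to normalize the
        transcription/translation drives and the growth input."""
        y = y_basal.reshape(n_species, 1)
        p = self.params
        foxo_tot = float(y[S["FOXO_n"], 0] + y[S["FOXO_c"], 0])
        if foxo_tot > 0:
            p.foxo_ref_frac = float(y[S["FOXO_n"], 0]) / foxo_tot
        drv = sg.transcription_drive(y, p, 0.0)
        self.basal_kbm_mult = {k: float(np.ravel(v)[0])
                               for k, v in drv["k_bm_mult"].items()}
        self.basal_kbm_add = {k: float(np.ravel(v)[0])
                              for k, v in drv["k_bm_add"].items()}
        self.basal_kbp_mult = {k: float(np.ravel(v)[0])
                               for k, v in drv["k_bp_mult"].items()}
        self.theta_basal = float(xp.translation_theta(
            max(float(y[S["EIF4E"], 0] / y[S["VOL"], 0]), 0.0), self.translation))
        if self.theta_basal <= 0:
            self.theta_basal = 1.0
        mtor_tot = float(y[S["MTOR"], 0] + y[S["mTORa"], 0])
        self.s6k_basal = float(y[S["mTORa"], 0]) / max(mtor_tot, 1.0)

    # -- state construction -------------------------------------------------

    def initial_state(self) -> tuple[np.ndarray, np.ndarray]:
        """Average-cell pre-initialization state: proteomics totals in the
        unmodified forms, PTM forms and complexes zero."""
        y = np.zeros((n_species, 1))
        for ci, sl in enumerate(self.cong_gene_slices):
            y[self.newborn_idx[ci], 0] = self.p_ss[sl].sum()
        p = self.params
        # pre-bind BCL2 ligands near their binding equilibrium so the
        # all-free transient cannot trip the apoptosis switch
        for ligand, cplx in (("BIM_u", "B_BIM"), ("BAD_u", "B_BAD"),
                             ("PUMA", "B_PUMA"), ("NOXA", "B_NOXA")):
            free_bcl2 = max(float(y[S["BCL2"], 0]), 0.0)
            tot = float(y[S[ligand], 0])
            on = p.k_on_bcl2 * free_bcl2 / p.bcl2_ref
            bound = min(tot * on / (on + p.k_off_bcl2), 0.9 * free_bcl2)
            y[S[ligand], 0] = tot - bound
            y[S[cplx], 0] = bound
            y[S["BCL2"], 0] = free_bcl2 - bound
        y[S["PIP2"], 0] = p.pip_total
        y[S["p53"], 0] = p.ks_p53 / max(p.kd_p53, 1e-9)
        y[S["MDM2m"], 0] = 0.5
        y[S["MDM2"], 0] = 1.0
        y[S["p21"], 0] = p.ks_p21_basal / max(p.kd_p21, 1e-9)
        y[S["RIB"], 0] = p.rib_ref
        y[S["VOL"], 0] = 1.0
        mrna = self.m_ss.astype(float).copy()[:, None]
        return y, mrna


@dataclass
class InitializationReport:
    converged: bool
    iterations: int
    max_rel_error: float
    per_conglomerate_error: dict[str, float]
    basal_pperk_fraction: float
    basal_ppakt_fraction: float
    residual_drift: float
    non_cycling: bool
    non_apoptotic: bool
    tolerance: float = 0.01
    max_iter: int = 50
    worst_offenders: list = field(default_factory=list)


class CellPopulationModel:
    """Mechanistic model of a cell population, tailored by omics data.

    Parameters
    ----------
    records : dict[str, GeneRecord]
        Tailored per-gene expression parameters (from `omics.tailor_genes`).
    params : NetworkParams, optional
        Reduced-network rate constants; defaults to the shipped calibration.
    """

    def __init__(self, records: dict[str, om.GeneRecord],
                 params: NetworkParams | None = None):
        self.records = records
        self.params = (params or NetworkParams()).copy()

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_tables(cls, mrna: om.OmicsTable, protein: om.OmicsTable,
                    half_lives: pd.DataFrame, copies: pd.Series,
                    cmap: om.ConglomerateMap,
                    pool: om.PoolConstants | None = None,
                    params: NetworkParams | None = None,
                    k_gac: float = 2.0, k_gin: float = 2.0):
        records = om.tailor_genes(mrna, protein, half_lives, copies, cmap,
                                  pool=pool, k_gac=k_gac, k_gin=k_gin)
        return cls(records, params)

    @classmethod
    def from_parameter_frame(cls, frame: pd.DataFrame,
                             params: NetworkParams | None = None):
        return cls(om.records_from_frame(frame), params)

    # -- variants -----------------------------------------------------------

    def with_mrna_fold(self, gene_id: str, factor: float) -> "CellPopulationModel":
        """Variant with one gene's mRNA steady state scaled by ``factor``
        (protein target rescaled through the gene's protein-to-mRNA ratio,
        transcription/translation rates re-derived)."""
        if gene_id not in self.records:
            raise KeyError(f"gene {gene_id!r} not in model")
        records = dict(self.records)
        r = records[gene_id]
        ratio = r.p_ss / r.m_ss if r.m_ss > 0 else 0.0
        new = dataclasses.replace(r, m_ss=r.m_ss * factor,
                                  p_ss=r.m_ss * factor * ratio,
                                  k_bm=float("nan"), k_bp=float("nan"))
        records[gene_id] = om.compute_rate_constants(new)
        return CellPopulationModel(records, self.params)

    def retailored(self, new_mrna: om.OmicsTable,
                   knockouts: list[str] | None = None) -> "CellPopulationModel":
        return CellPopulationModel(om.retailor(self.records, new_mrna, knockouts),
                                   self.params)

    # -- fitting ------------------------------------------------------------

    def fit(self, tolerance: float = 0.01, max_iter: int = 50,
            relax_hours: float = 300.0, probe: bool = True,
            k_bp_scale=None) -> "InitializedCellModel":
        """Initialize the serum-starved average cell.

        Deterministic integration to steady state under zero stimulus; an
        outer loop rescales each gene's effective translation rate by
        (proteomics target)/(simulated conglomerate total) until the largest
        relative error is below ``tolerance``.
        """
        system = TailoredSystem(self.records, self.params)
        if k_bp_scale is not None:
            system.k_bp_scale = np.asarray(k_bp_scale, float).copy()
        y, mrna = system.initial_state()
        z = np.concatenate([y.ravel(), mrna.ravel()])

        converged = False
        iterations = 0
        errors = np.full(len(system.moieties), np.inf)
        for it in range(1, max_iter + 1):
            iterations = it
            system._freeze_global = (it == 1)
            z = self._relax(system, z, relax_hours if it <= 2 else 120.0)
            system._freeze_global = False
            yss = z[:n_species].reshape(n_species, 1)
            system.set_basal(yss[:, 0])
            totals = np.array([
                float((yss[idx_w[0]] * idx_w[1][:, None]).sum())
                for idx_w in (system.moiety_arrays[m] for m in system.moieties)])
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(system.target_totals > 0,
                                 system.target_totals / np.maximum(totals, 1e-12),
                                 1.0)
            errors = np.where(system.target_totals > 0,
                              np.abs(totals - system.target_totals)
                              / np.maximum(system.target_totals, 1e-12),
                              0.0)
            if errors.max() <= tolerance:
                converged = True
                break
            for ci, sl in enumerate(system.cong_gene_slices):
                system.k_bp_scale[sl] *= np.clip(ratio[ci], 0.2, 5.0) ** 0.7

        yss = z[:n_species].reshape(n_species, 1)
        mss = z[n_species:].reshape(system.n_genes, 1)
        dz = self._det_rhs(system, z)
        scale = np.maximum(np.abs(z), 1.0)
        drift = float(np.max(np.abs(dz) / scale))

        non_cycling, non_apoptotic = True, True
        if probe:
            z_probe = self._relax(system, z, 100.0, return_max=True)
            non_cycling = z_probe["cycb_max"] < 0.5 * self.params.K_cycb_c20
            parp_tot = max(z_probe["parp_tot"], 1.0)
            non_apoptotic = z_probe["cparp_max"] < 0.5 * parp_tot

        erk_tot = float(yss[S["ERK"], 0] + yss[S["ppERK"], 0])
        akt_tot = float(yss[S["AKT"], 0] + yss[S["ppAKT"], 0])
        report = InitializationReport(
            converged=converged and non_cycling and non_apoptotic,
            iterations=iterations,
            max_rel_error=float(errors.max()),
            per_conglomerate_error={m: float(e) for m, e in
                                    zip(system.moieties, errors)},
            basal_pperk_fraction=float(yss[S["ppERK"], 0]) / max(erk_tot, 1e-12),
            basal_ppakt_fraction=float(yss[S["ppAKT"], 0]) / max(akt_tot, 1e-12),
            residual_drift=drift,
            non_cycling=non_cycling, non_apoptotic=non_apoptotic,
            tolerance=tolerance, max_iter=max_iter,
            worst_offenders=sorted(zip(system.moieties, errors),
                                   key=lambda t: -t[1])[:5])
        return InitializedCellModel(self, system, yss[:, 0], mss[:, 0], report)

    # -- deterministic relaxation machinery ----------------------------------

    def _det_rhs(self, system: TailoredSystem, z: np.ndarray) -> np.ndarray:
        from .simulate import StimulusSpec, full_rhs
        stim = StimulusSpec()
        y = z[:n_species].reshape(n_species, 1)
        m = z[n_species:].reshape(system.n_genes, 1)
        dy = full_rhs(y, system, stim, m)
        drv = sg.transcription_drive(y, self.params, 0.0)
        kbm_eff, kbm_add = system.kbm_effective(drv)
        dm = (kbm_eff + kbm_add) * system.g_active_ss[:, None] \
            - system.k_dm[:, None] * m
        return np.concatenate([dy.ravel(), dm.ravel()])

    def _relax(self, system: TailoredSystem, z0: np.ndarray, hours: float,
               return_max: bool = False):
        def rhs(t, z):
            return self._det_rhs(system, z)
        if return_max:
            sol = solve_ivp(rhs, (0.0, hours), z0, method="LSODA",
                            rtol=1e-6, atol=1e-3, dense_output=False,
                            t_eval=np.linspace(0, hours, 201))
            ys = sol.y[:n_species]
            return {"cycb_max": float(ys[S["CycB"]].max()),
                    "cparp_max": float(ys[S["cPARP"]].max()),
                    "parp_tot": float(ys[S["PARP"], -1] + ys[S["cPARP"], -1])}
        sol = solve_ivp(rhs, (0.0, hours), z0, method="LSODA",
                        rtol=1e-6, atol=1e-3)
        if not sol.success:
            raise RuntimeError(f"steady-state relaxation failed: {sol.message}")
        return np.maximum(sol.y[:, -1], 0.0)


class InitializedCellModel:
    """Results object: tailored, initialized average cell.

    Carries the tailored system (gene arrays + network parameters), the
    average-cell steady state, and the initialization diagnostics. All
    population work (spawning, experiments, scans) hangs off this object.
    """

    def __init__(self, model: CellPopulationModel, system: TailoredSystem,
                 y_ss: np.ndarray, mrna_ss: np.ndarray,
                 report: InitializationReport):
        self.model = model
        self.system = system
        self.y_ss = y_ss
        self.mrna_ss = mrna_ss
        self.report = report

    @property
    def params(self) -> NetworkParams:
        return self.system.params

    @property
    def records(self) -> dict[str, om.GeneRecord]:
        return self.model.records

    # -- population work ----------------------------------------------------

    def spawn_population(self, n: int, base_seed: int = 0,
                         hours: float = 24.0, stochastic: bool = True,
                         window_s: float = 30.0, n_substeps: int = 2):
        """Spawn n cells by independent stochastic serum-starved pre-runs."""
        from .simulate import CellBatch, StimulusSpec, hybrid_step
        system = self.system
        y = np.repeat(self.y_ss[:, None], n, axis=1)
        if stochastic:
            rngs = np.random.default_rng(
                np.random.SeedSequence([int(base_seed) % (2 ** 31), 131]))
            g_tot = np.repeat(system.g_total[:, None], n, axis=1)
            pi_on = np.where(system.k_gac + system.k_gin > 0,
                             system.k_gac / np.maximum(system.k_gac + system.k_gin, 1e-12),
                             0.0)
            active = rngs.binomial(g_tot, pi_on[:, None])
            mrna = rngs.poisson(np.maximum(self.mrna_ss, 0.0)[:, None]
                                * np.ones((1, n)))
        else:
            active = np.repeat(np.round(system.g_active_ss)[:, None], n, axis=1
                               ).astype(np.int64)
            mrna = np.repeat(self.mrna_ss[:, None], n, axis=1)
        batch = CellBatch(y, active.astype(np.int64), mrna.astype(
            np.int64 if stochastic else float))
        if hours > 0:
            stim = StimulusSpec()
            dt = window_s / 3600.0
            rngs2 = np.random.default_rng(
                np.random.SeedSequence([int(base_seed) % (2 ** 31), 257]))
            for _ in range(int(round(hours / dt))):
                hybrid_step(batch, system, stim, dt, rngs2,
                            n_substeps=n_substeps,
                            deterministic=not stochastic)
        # pre-run events are history, not experiment readouts; cells that
        # died during the pre-run are dead at experiment start
        batch.t = 0.0
        batch.death_time[batch.dead] = 0.0
        batch.s_entry_time[:] = np.nan
        batch.cycb_peak[:] = 0.0
        batch.division_times = [[] for _ in range(n)]
        # quiescent cells must re-license replication origins on cycle
        # re-entry: same post-mitotic G1 delay, applied from stimulus start
        batch.g1_until[:] = self.system.params.g1_refractory_h
        return batch

    def simulate(self, config, population=None):
        """Spawn (if needed) and run one experiment; returns
        (recording, summary)."""
        from .simulate import run_experiment
        if population is None:
            population = self.spawn_population(
                config.population_size, base_seed=config.base_seed,
                stochastic=not config.deterministic,
                window_s=config.window_s, n_substeps=config.n_substeps)
        return run_experiment(population, config, self)

    # -- reporting ----------------------------------------------------------

    def parameter_frame(self) -> pd.DataFrame:
        frame = om.records_to_frame(self.records)
        scale = pd.Series(1.0, index=frame.index)
        for g, s in zip(self.system.gene_ids, self.system.k_bp_scale):
            scale[g] = s
        frame["k_bp_initialization_scale"] = scale
        return frame

    def summary(self) -> str:
        r = self.report
        lines = [
            "Initialized cell population model (serum-starved average cell)",
            "=" * 62,
            f"genes tailored: {len(self.records)}   "
            f"expression-coupled: {self.system.n_genes}",
            f"converged: {r.converged}   iterations: {r.iterations}   "
            f"max conglomerate error: {r.max_rel_error:.3%}",
            f"basal ppERK fraction: {r.basal_pperk_fraction:.3%}   "
            f"basal ppAKT fraction: {r.basal_ppakt_fraction:.3%}",
            f"residual drift: {r.residual_drift:.2e} /h   "
            f"non-cycling: {r.non_cycling}   non-apoptotic: {r.non_apoptotic}",
            "-" * 62,
            f"{'conglomerate':<14}{'target':>14}{'rel.err':>10}",
        ]
        sysm = self.system
        for m, tgt in zip(sysm.moieties, sysm.target_totals):
            lines.append(f"{m:<14}{tgt:>14.3g}{r.per_conglomerate_error[m]:>10.2%}")
        return "\n".join(lines)
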