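"""Simulation driver: hybrid time-stepping, experiments, and population
summaries.

Each exchange window (default 30 s) advances a population as:

1. stochastic step — telegraph gene switching, then mRNA birth/death with
   the gene state frozen (exact per-window propagators, vectorized across
   cells and genes);
2. deterministic step — fixed-step RK4 substeps of the full reduced-network
   ODE with mRNA counts held at their window values.

Cells are independent; each owns a counter-based RNG stream seeded
base_seed + cell_index. Dead cells are frozen at their death state. Events
(death, division, S-phase entry) are detected on the window grid.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from . import expression as xp
from . import fate as fl
from . import signaling as sg
from .network import S, SPECIES, n_species, NetworkParams, MOIETIES

__all__ = ["StimulusSpec", "ExperimentConfig", "CellBatch", "CellTrajectory",
           "PopulationSummary", "run_experiment", "summarize_population",
           "hybrid_step", "full_rhs", "write_trajectories_csv",
           "write_event_log_csv"]

EGF_KDA = 6.2        # molecular weights used to convert ng/mL doses to nM
INSULIN_KDA = 5.808


@dataclass(frozen=True)
class StimulusSpec:
    """Ligand, inhibitor and chemotherapy doses with application time."""

    egf_ng_ml: float = 0.0
    insulin_ug_ml: float = 0.0
    trail_ng_ml: float = 0.0
    etoposide_um: float = 0.0
    meki_um: float = 0.0
    akti_um: float = 0.0
    start_h: float = 0.0
    egf_kda: float = EGF_KDA
    insulin_kda: float = INSULIN_KDA

    @property
    def egf_nM(self) -> float:
        return self.egf_ng_ml / self.egf_kda
    @property
    def insulin_nM(self) -> float:
        return self.insulin_ug_ml * 1000.0 / self.insulin_kda

    def active(self, t: float) -> "StimulusSpec":
        return self if t >= self.start_h else StimulusSpec(
            egf_kda=self.egf_kda, insulin_kda=self.insulin_kda)


@dataclass(frozen=True)
class ExperimentConfig:
    """One virtual experiment on a spawned population."""

    population_size: int = 100
    base_seed: int = 0
    stimulus: StimulusSpec = field(default_factory=StimulusSpec)
    duration_h: float = 72.0
    save_stride_min: float = 6.0
    readout_times: tuple = (24.0, 48.0, 72.0)
    window_s: float = 30.0
    n_substeps: int = 2
    deterministic: bool = False
    proliferation_rule: str = "s_entry"  # or "divided"

    def __post_init__(self):
        if self.population_size < 1:
            raise ValueError("population_size must be >= 1")
        if self.duration_h <= 0:
            raise ValueError("duration must be > 0")


# ---------------------------------------------------------------------------
# population state


EXTENSIVE = np.ones(n_species, dtype=bool)
for _name in ("E2F", "CycE", "CycA", "CycB", "Cdc20", "p21", "Chk1a",
              "ATMa", "ATRa", "p53", "MDM2m", "MDM2", "WIP1", "VOL"):
    EXTENSIVE[S[_name]] = False
# lesions are split between daughters like molecules
EXTENSIVE[S["SSB"]] = True
EXTENSIVE[S["DSB"]] = True


@dataclass
class CellBatch:
    """Vectorized state of n cells (columns)."""

    y: np.ndarray            # (n_species, n)
    active: np.ndarray       # (n_genes, n) int promoter copies on
    mrna: np.ndarray         # (n_genes, n) counts (float in deterministic mode)
    t: float = 0.0
    dead: np.ndarray = None        # (n,) bool
    failed: np.ndarray = None      # (n,) bool, ODE failure
    death_time: np.ndarray = None
    s_entry_time: np.ndarray = None
    division_times: list = None    # list per cell
    cycb_peak: np.ndarray = None
    g1_until: np.ndarray = None    # licensing delay after division

    def __post_init__(self):
        n = self.y.shape[1]
        if self.dead is None:
            self.dead = np.zeros(n, dtype=bool)
        if self.failed is None:
            self.failed = np.zeros(n, dtype=bool)
        if self.death_time is None:
            self.death_time = np.full(n, np.nan)
        if self.s_entry_time is None:
            self.s_entry_time = np.full(n, np.nan)
        if self.division_times is None:
            self.division_times = [[] for _ in range(n)]
        if self.cycb_peak is None:
            self.cycb_peak = np.zeros(n)
        if self.g1_until is None:
            self.g1_until = np.zeros(n)

    @property
    def n_cells(self) -> int:
        return self.y.shape[1]

    def copy(self) -> "CellBatch":
        b = CellBatch(self.y.copy(), self.active.copy(), self.mrna.copy(),
                      t=self.t, dead=self.dead.copy(), failed=self.failed.copy(),
                      death_time=self.death_time.copy(),
                      s_entry_time=self.s_entry_time.copy(),
                      division_times=[list(d) for d in self.division_times],
                      cycb_peak=self.cycb_peak.copy(),
                      g1_until=self.g1_until.copy())
        return b


# ---------------------------------------------------------------------------
# composed deterministic RHS


def full_rhs(y: np.ndarray, system, stim: StimulusSpec,
             mrna: np.ndarray, expression_on: bool = True) -> np.ndarray:
    """Complete deterministic derivative of the network state.

    ``system`` is a mechcell.model.TailoredSystem carrying the tailored
    gene arrays and coupling; ``mrna`` the per-gene transcript counts held
    fixed during the window. With ``expression_on`` False all synthesis and
    degradation fluxes are disabled (pure signaling; moieties conserved).
    """
    p = system.params
    dy = np.zeros_like(y)
    sg.receptor_rhs(y, dy, p, stim.egf_nM, stim.insulin_nM)
    sg.cascade_rhs(y, dy, p, stim.meki_um, stim.akti_um)
    fl.cycle_rhs(y, dy, p)
    fl.apoptosis_rhs(y, dy, p, stim.trail_ng_ml, stim.akti_um)
    fl.damage_rhs(y, dy, p, stim.etoposide_um)

    # growth: ribosome synthesis follows the mTOR (p70S6K-like) drive
    mtor_tot = y[S["MTOR"]] + y[S["mTORa"]]
    s6k = y[S["mTORa"]] / np.maximum(mtor_tot, 1.0)
    if getattr(system, "_freeze_global", False):
        s6k = system.s6k_basal
    drive = np.maximum(s6k - system.s6k_basal - p.s6k_margin, 0.0) \
        / max(1.0 - system.s6k_basal - p.s6k_margin, 1e-9)
    drive = drive / (p.K_s6k + drive) * (1.0 + p.K_s6k)
    d_rib, d_vol = xp.growth_rhs(y[S["RIB"]], drive,
                                 xp.GrowthParams(p.rib_ref, p.k_rib_turnover,
                                                 p.rib_gain))
    dy[S["RIB"]] += d_rib
    dy[S["VOL"]] += d_vol  # volume slaved to ribosome content

    if expression_on:
        # protein synthesis into newborn species, first-order decay per form
        if getattr(system, "_freeze_global", False):
            theta_rel = 1.0
            ribf = 1.0
        else:
            # theta responds to free-EIF4E *concentration*
            theta = xp.translation_theta(
                np.maximum(y[S["EIF4E"]] / y[S["VOL"]], 0.0), system.translation)
            theta_rel = theta / system.theta_basal
            ribf = y[S["RIB"]] / p.rib_ref
        drv = sg.transcription_drive(y, p, stim.akti_um)
        kbp_mult = system.kbp_multipliers(drv)
        flux = system.k_bp[:, None] * kbp_mult * np.asarray(mrna, dtype=float)
        synth_per_gene = theta_rel * ribf * flux
        for ci, sp_idx in enumerate(system.newborn_idx):
            dy[sp_idx] += synth_per_gene[system.cong_gene_slices[ci]].sum(axis=0)
        dy -= system.decay_rates[:, None] * y
    return dy


def _deterministic_window(batch: CellBatch, system, stim: StimulusSpec,
                          dt: float, n_substeps: int, alive) -> None:
    """RK4 substeps over one window; updates batch.y in place (alive cells)."""
    h = dt / n_substeps
    y = batch.y
    m = batch.mrna
    for _ in range(n_substeps):
        k1 = full_rhs(y, system, stim, m)
        k2 = full_rhs(y + 0.5 * h * k1, system, stim, m)
        k3 = full_rhs(y + 0.5 * h * k2, system, stim, m)
        k4 = full_rhs(y + h * k3, system, stim, m)
        step = (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        y += np.where(alive[None, :], step, 0.0)
    np.maximum(y, 0.0, out=y)


def hybrid_step(batch: CellBatch, system, stim: StimulusSpec, dt: float,
                rngs, n_substeps: int = 2, deterministic: bool = False) -> None:
    """One exchange window: stochastic expression step, then ODE step."""
    alive = ~batch.dead & ~batch.failed
    p = system.params
    if deterministic:
        # gene state pinned at its mean, mRNA relaxed exactly toward its
        # conditional mean (hybrid-consistency mode)
        drv = sg.transcription_drive(batch.y, p, stim.active(batch.t).akti_um)
        kbm_eff, kbm_add = system.kbm_effective(drv)
        g_eff = system.g_active_ss[:, None]
        m_inf = np.where(system.k_dm[:, None] > 0,
                         (kbm_eff + kbm_add) * g_eff
                         / np.maximum(system.k_dm[:, None], 1e-12),
                         batch.mrna)
        decay = np.exp(-system.k_dm[:, None] * dt)
        new_m = m_inf + (batch.mrna - m_inf) * decay
        batch.mrna = np.where(alive[None, :], new_m, batch.mrna)
    else:
        drv = sg.transcription_drive(batch.y, p, stim.active(batch.t).akti_um)
        kbm_eff, kbm_add = system.kbm_effective(drv)
        new_active = xp.step_gene_switching(
            batch.active, system.g_total[:, None], system.k_gac[:, None],
            system.k_gin[:, None], dt, rngs)
        batch.active = np.where(alive[None, :], new_active, batch.active)
        birth = (kbm_eff + kbm_add) * batch.active
        # exact immigration-death propagator with frozen gene state
        kd = system.k_dm[:, None]
        surv_p = np.broadcast_to(np.exp(-kd * dt), batch.mrna.shape)
        mean_births = np.where(kd > 0, birth / np.maximum(kd, 1e-12)
                               * (1.0 - np.exp(-kd * dt)), birth * dt)
        survivors = rngs.binomial(batch.mrna.astype(np.int64), surv_p)
        births = rngs.poisson(np.maximum(mean_births, 0.0))
        batch.mrna = np.where(alive[None, :], survivors + births, batch.mrna)

    _deterministic_window(batch, system, stim.active(batch.t), dt,
                          n_substeps, alive)
    batch.t += dt
    # post-mitotic licensing: cycle species pinned at G1 reset
    holding = alive & (batch.t < batch.g1_until)
    if holding.any():
        for name, val in fl.CYCLE_RESET.items():
            batch.y[S[name]] = np.where(holding, val, batch.y[S[name]])
    _detect_events(batch, system, rngs, deterministic)


def _detect_events(batch: CellBatch, system, rngs, deterministic: bool) -> None:
    p = system.params
    y = batch.y
    alive = ~batch.dead & ~batch.failed

    bad = ~np.isfinite(y).all(axis=0)
    newly_failed = bad & alive
    if newly_failed.any():
        batch.failed |= newly_failed
        alive = ~batch.dead & ~batch.failed

    # death latch: cPARP exceeding half the PARP moiety
    parp_tot = y[S["PARP"]] + y[S["cPARP"]]
    dying = alive & (y[S["cPARP"]] > p.death_cparp_frac * np.maximum(parp_tot, 1.0))
    if dying.any():
        batch.dead |= dying
        batch.death_time[dying] = batch.t

    # S-phase entry (first crossing)
    s_act = fl.s_phase_activity(y, p)
    entering = alive & np.isnan(batch.s_entry_time) & (s_act >= p.s_phase_thresh)
    batch.s_entry_time[entering] = batch.t

    # division: cyclin B falls below 10% of its post-threshold peak
    batch.cycb_peak = np.where(alive, np.maximum(batch.cycb_peak, y[S["CycB"]]),
                               batch.cycb_peak)
    dividing = alive & (batch.cycb_peak > p.K_cycb_c20) \
        & (y[S["CycB"]] < p.div_frac_of_peak * batch.cycb_peak)
    if dividing.any():
        idx = np.where(dividing)[0]
        y[:, idx] = np.where(EXTENSIVE[:, None], 0.5 * y[:, idx], y[:, idx])
        y[S["VOL"], idx] *= 0.5
        for name, val in fl.CYCLE_RESET.items():
            y[S[name], idx] = val
        if deterministic:
            batch.mrna[:, idx] *= 0.5
        else:
            batch.mrna[:, idx] = rngs.binomial(
                batch.mrna[:, idx].astype(np.int64), 0.5)
        batch.cycb_peak[idx] = 0.0
        batch.g1_until[idx] = batch.t + p.g1_refractory_h
        for i in idx:
            batch.division_times[i].append(batch.t)


# ---------------------------------------------------------------------------
# trajectories and summaries


TRACKED_EXTRA = ["ppERK", "ppAKT", "cPARP", "CycB", "CycE", "CycA", "VOL", "RIB",
                 "FOXO_n", "p53", "p21", "DSB", "EIF4E", "C8a", "aBax", "CytC"]


class CellTrajectory:
    """Per-cell view into a recorded population run."""

    def __init__(self, times, data, columns, cell_index, death_time,
                 division_times, s_entry_time, failed):
        self.times = times
        self._data = data  # (n_save, n_cols, n_cells)
        self.columns = columns
        self.cell_index = cell_index
        self.death_time = death_time
        self.division_times = division_times
        self.s_entry_time = s_entry_time
        self.failed = failed

    def series(self, name: str) -> np.ndarray:
        return self._data[:, self.columns.index(name), self.cell_index]

    @property
    def fate_death(self) -> bool:
        return np.isfinite(self.death_time)


@dataclass
class PopulationSummary:
    readout_times: np.ndarray
    percent_dead: np.ndarray
    percent_proliferating: np.ndarray
    n_cells: int
    n_failed: int
    proliferation_rule: str = "s_entry"


class PopulationRecording:
    """Recorded run: moiety totals + tracked species over time, all cells."""

    def __init__(self, times, data, columns, batch: CellBatch):
        self.times = np.asarray(times)
        self.data = data
        self.columns = columns
        self.batch = batch

    def trajectory(self, i: int) -> CellTrajectory:
        b = self.batch
        return CellTrajectory(self.times, self.data, self.columns, i,
                              b.death_time[i], list(b.division_times[i]),
                              b.s_entry_time[i], bool(b.failed[i]))

    def trajectories(self) -> list:
        return [self.trajectory(i) for i in range(self.batch.n_cells)]


def _record_columns(system):
    return list(system.moieties) + TRACKED_EXTRA


def _snapshot(system, batch: CellBatch, out: np.ndarray) -> None:
    cols = 0
    for m in system.moieties:
        idx, w = system.moiety_arrays[m]
        out[cols] = (batch.y[idx] * w[:, None]).sum(axis=0)
        cols += 1
    for name in TRACKED_EXTRA:
        out[cols] = batch.y[S[name]]
        cols += 1


def run_experiment(population: CellBatch, config: ExperimentConfig, results
                   ) -> tuple[PopulationRecording, PopulationSummary]:
    """Advance a spawned population through a stimulus experiment.

    ``results`` is the InitializedCellModel providing the tailored system.
    Returns the recording (trajectories + events) and the summary at the
    configured readout times.
    """
    system = results.system
    batch = population.copy()
    batch.t = 0.0
    dt = config.window_s / 3600.0
    n_windows = int(round(config.duration_h / dt))
    stride = max(1, int(round(config.save_stride_min * 60.0 / config.window_s)))
    rngs = np.random.default_rng(
        np.random.SeedSequence([int(config.base_seed) % (2 ** 31), 977]))

    columns = _record_columns(system)
    n_save = n_windows // stride + 1
    data = np.empty((n_save, len(columns), batch.n_cells), dtype=np.float32)
    times = np.empty(n_save)
    _snapshot(system, batch, data[0])
    times[0] = 0.0
    k = 1
    for w in range(1, n_windows + 1):
        hybrid_step(batch, system, config.stimulus, dt, rngs,
                    n_substeps=config.n_substeps,
                    deterministic=config.deterministic)
        if w % stride == 0:
            _snapshot(system, batch, data[k])
            times[k] = batch.t
            k += 1
    recording = PopulationRecording(times[:k], data[:k], columns, batch)
    summary = summarize_population(recording, config.readout_times,
                                   config.proliferation_rule)
    return recording, summary


def summarize_population(recording: PopulationRecording, readout_times,
                         proliferation_rule: str = "s_entry",
                         control: PopulationSummary | None = None,
                         subtract_control: bool = False) -> PopulationSummary:
    """Percent dead / percent proliferating at the readout times.

    percent_dead counts death events at or before t over non-failed cells.
    Proliferation counts S-phase entry (rule 's_entry') or first division
    (rule 'divided') by t; with ``subtract_control`` the matched
    serum-starved control percentages are subtracted (clamped at 0).
    """
    if subtract_control and control is None:
        raise ValueError("control summary required when subtraction requested")
    b = recording.batch
    ok = ~b.failed
    n = int(ok.sum())
    if n == 0:
        raise ValueError("no usable cells (all failed)")
    readout_times = np.asarray(readout_times, dtype=float)
    dead_pct = np.array([100.0 * np.sum(ok & (b.death_time <= t)) / n
                         for t in readout_times])
    if proliferation_rule == "s_entry":
        ev = b.s_entry_time
        prol_pct = np.array([100.0 * np.sum(ok & (ev <= t)) / n
                             for t in readout_times])
    elif proliferation_rule == "divided":
        first_div = np.array([d[0] if d else np.inf for d in b.division_times])
        prol_pct = np.array([100.0 * np.sum(ok & (first_div <= t)) / n
                             for t in readout_times])
    else:
        raise ValueError(f"unknown proliferation rule {proliferation_rule!r}")
    if subtract_control:
        prol_pct = np.maximum(prol_pct - control.percent_proliferating, 0.0)
    return PopulationSummary(readout_times, dead_pct, prol_pct, n,
                             int(b.failed.sum()), proliferation_rule)


# ---------------------------------------------------------------------------
# text output


def write_trajectories_csv(recording: PopulationRecording, path,
                           species=None) -> None:
    """Long-format CSV: cell_id, time_h, species, amount."""
    species = species or recording.columns
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["cell_id", "time_h", "species", "amount"])
        for i in range(recording.batch.n_cells):
            traj = recording.trajectory(i)
            for name in species:
                vals = traj.series(name)
                for t, v in zip(recording.times, vals):
                    wr.writerow([i, f"{t:.4f}", name, f"{v:.6g}"])


def write_event_log_csv(recording: PopulationRecording, path) -> None:
    """Fate event log: cell_id, event in {death, division, s_entry}, time_h."""
    b = recording.batch
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["cell_id", "event", "time_h"])
        for i in range(b.n_cells):
            if np.isfinite(b.s_entry_time[i]):
                wr.writerow([i, "s_entry", f"{b.s_entry_time[i]:.4f}"])
            for t in b.division_times[i]:
                wr.writerow([i, "division", f"{t:.4f}"])
            if np.isfinite(b.death_time[i]):
                wr.writerow([i, "death", f"{b.death_time[i]:.4f}"])
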