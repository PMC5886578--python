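"""Simulation-driver tests: initialization contract, population spawning,
hybrid stepping, event bookkeeping, and population summaries."""

import numpy as np
import pytest

import mechcell as mc
from mechcell.network import S
from mechcell.simulate import (CellBatch, ExperimentConfig, PopulationSummary,
                               StimulusSpec, summarize_population)


class TestInitialization:
    def test_converges_within_tolerance(self, fitted):
        r = fitted.report
        assert r.converged
        assert r.max_rel_error <= r.tolerance

    def test_every_conglomerate_matches_proteomics_target(self, fitted):
        for m, err in fitted.report.per_conglomerate_error.items():
            assert err <= fitted.report.tolerance, m

    def test_refit_from_converged_state_is_cheap(self, fitted):
        """Re-running initialization on its own output converges in a
        couple of iterations (idempotence)."""
        model = fitted.model
        import mechcell.model as mm
        res2 = mm.CellPopulationModel(model.records, fitted.params).fit(
            probe=False, relax_hours=150.0,
            k_bp_scale=fitted.system.k_bp_scale)
        assert res2.report.converged
        assert res2.report.iterations <= 2

    def test_zero_stimulus_deterministic_run_stays_flat(self, fitted):
        cfg = ExperimentConfig(population_size=1, base_seed=0,
                               stimulus=StimulusSpec(), duration_h=24.0,
                               deterministic=True, save_stride_min=30.0,
                               readout_times=(24.0,))
        rec, summary = fitted.simulate(cfg)
        tr = rec.trajectory(0)
        for name in ("ERK", "AKT", "BCL2", "BIM", "RIB"):
            series = tr.series(name)
            assert abs(series[-1] - series[0]) / max(series[0], 1.0) < 0.05, name
        assert summary.percent_dead[-1] == 0.0


class TestSpawn:
    def test_deterministic_spawn_identical_to_average_cell(self, fitted):
        batch = fitted.spawn_population(1, base_seed=0, stochastic=False,
                                        hours=2.0)
        rel = np.abs(batch.y[:, 0] - fitted.y_ss) / np.maximum(
            np.abs(fitted.y_ss), 1.0)
        assert rel.max() < 0.05

    def test_same_seed_bit_identical(self, fitted):
        a = fitted.spawn_population(5, base_seed=11, hours=2.0)
        b = fitted.spawn_population(5, base_seed=11, hours=2.0)
        assert np.array_equal(a.y, b.y)
        assert np.array_equal(a.mrna, b.mrna)
        assert np.array_equal(a.active, b.active)

    def test_different_seeds_differ(self, fitted):
        a = fitted.spawn_population(3, base_seed=1, hours=2.0)
        b = fitted.spawn_population(3, base_seed=2, hours=2.0)
        assert not np.array_equal(a.mrna, b.mrna)

    def test_population_means_near_average_cell(self, fitted):
        """Stationary fluctuations are unbiased: the population mean of each
        protein stays within a few SE of the average-cell value."""
        batch = fitted.spawn_population(40, base_seed=3, hours=24.0)
        for name in ("ERK", "AKT", "BCL2"):
            idx, w = fitted.system.moiety_arrays[name]
            totals = (batch.y[idx] * w[:, None]).sum(axis=0)
            target = sum(wt * fitted.y_ss[i] for i, wt in zip(idx, w))
            se = totals.std(ddof=1) / np.sqrt(len(totals))
            assert abs(totals.mean() - target) < max(4 * se, 0.05 * target), name


class TestPopulationVariability:
    @pytest.fixture(scope="class")
    def starved_population(self, fitted):
        return fitted.spawn_population(60, base_seed=5, hours=24.0)

    def test_mrna_cv_exceeds_protein_cv(self, fitted, starved_population):
        """After the 24-h stochastic pre-run, transcript noise exceeds
        protein noise for expressed genes (slow protein turnover filters
        the mRNA fluctuations)."""
        batch = starved_population
        system = fitted.system
        wins = 0
        total = 0
        for ci, c in enumerate(system.couplings):
            sl = system.cong_gene_slices[ci]
            if system.m_ss[sl].sum() < 5:
                continue
            m = batch.mrna[sl].sum(axis=0).astype(float)
            idx, w = system.moiety_arrays[c.moiety]
            p = (batch.y[idx] * w[:, None]).sum(axis=0)
            if m.mean() <= 0 or p.mean() <= 0:
                continue
            cv_m = m.std() / m.mean()
            cv_p = p.std() / p.mean()
            total += 1
            if cv_m > cv_p:
                wins += 1
        assert total >= 10
        assert wins / total >= 0.9

    def test_low_abundance_transcripts_noisier(self, fitted,
                                               starved_population):
        batch = starved_population
        system = fitted.system
        means, cvs = [], []
        for gi in range(system.n_genes):
            m = batch.mrna[gi].astype(float)
            if m.mean() > 0.5:
                means.append(m.mean())
                cvs.append(m.std() / m.mean())
        means, cvs = np.array(means), np.array(cvs)
        lo = cvs[means < np.median(means)].mean()
        hi = cvs[means >= np.median(means)].mean()
        assert lo > hi

    def test_global_translation_couples_proteins_positively(self, fitted,
                                                            starved_population):
        """Shared EIF4E/ribosome control induces positive pairwise protein
        correlations across cells (median pairwise r > 0)."""
        batch = starved_population
        system = fitted.system
        mats = []
        for ci, c in enumerate(system.couplings):
            idx, w = system.moiety_arrays[c.moiety]
            p = (batch.y[idx] * w[:, None]).sum(axis=0)
            if p.mean() > 0:
                mats.append(p / p.mean())
        X = np.array(mats)
        corr = np.corrcoef(X)
        iu = np.triu_indices_from(corr, k=1)
        assert np.median(corr[iu]) > 0


class TestSummaries:
    def _recording(self, death_times, s_entry=None, n=None):
        n = n or len(death_times)

        class _B:
            pass

        b = _B()
        b.n_cells = n
        b.death_time = np.asarray(death_times, float)
        b.s_entry_time = np.asarray(
            s_entry if s_entry is not None else [np.nan] * n, float)
        b.division_times = [[] for _ in range(n)]
        b.failed = np.zeros(n, bool)

        class _R:
            pass

        r = _R()
        r.batch = b
        return r

    def test_counting_oracle(self):
        death = [48.0] * 3 + [np.nan] * 7
        rec = self._recording(death)
        s = summarize_population(rec, [24.0, 48.0, 72.0])
        assert list(s.percent_dead) == [0.0, 30.0, 30.0]

    def test_no_events_zero_everywhere(self):
        rec = self._recording([np.nan] * 5)
        s = summarize_population(rec, [24.0])
        assert s.percent_dead[0] == 0.0
        assert s.percent_proliferating[0] == 0.0

    def test_all_dead_at_time_zero(self):
        rec = self._recording([0.0] * 4)
        s = summarize_population(rec, [1.0, 24.0])
        assert list(s.percent_dead) == [100.0, 100.0]

    def test_death_curve_monotone(self):
        rec = self._recording([10.0, 20.0, 30.0, np.nan])
        s = summarize_population(rec, [5.0, 15.0, 25.0, 35.0])
        assert np.all(np.diff(s.percent_dead) >= 0)

    def test_control_subtraction_requires_control(self):
        rec = self._recording([np.nan] * 3)
        with pytest.raises(ValueError):
            summarize_population(rec, [24.0], subtract_control=True)

    def test_control_subtraction_clamps_at_zero(self):
        rec = self._recording([np.nan] * 4, s_entry=[10.0, np.nan, np.nan,
                                                    np.nan])
        control = PopulationSummary(np.array([24.0]), np.array([0.0]),
                                    np.array([80.0]), 4, 0)
        s = summarize_population(rec, [24.0], control=control,
                                 subtract_control=True)
        assert s.percent_proliferating[0] == 0.0


class TestHybridConsistency:
    def test_deterministic_window_matches_lsoda(self, fitted):
        """With stochasticity disabled the windowed RK4 path reproduces the
        adaptive (LSODA) trajectory of the same ODE system."""
        from scipy.integrate import solve_ivp
        from mechcell.network import n_species
        model = fitted.model
        system = fitted.system
        z0 = np.concatenate([fitted.y_ss, fitted.mrna_ss])
        stim_hours = 4.0

        # reference: LSODA on the full deterministic system under EGF
        import mechcell.signaling as sg
        from mechcell.simulate import StimulusSpec, full_rhs
        stim = StimulusSpec(egf_ng_ml=20.0)

        def rhs(t, z):
            y = z[:n_species].reshape(n_species, 1)
            m = z[n_species:].reshape(system.n_genes, 1)
            dy = full_rhs(y, system, stim, m)
            drv = sg.transcription_drive(y, system.params, 0.0)
            kbm_eff, kbm_add = system.kbm_effective(drv)
            dm = (kbm_eff + kbm_add) * system.g_active_ss[:, None] \
                - system.k_dm[:, None] * m
            return np.concatenate([dy.ravel(), dm.ravel()])

        ref = solve_ivp(rhs, (0, stim_hours), z0, method="LSODA", rtol=1e-8,
                        atol=1e-6).y[:, -1]

        cfg = ExperimentConfig(population_size=1, base_seed=0, stimulus=stim,
                               duration_h=stim_hours, deterministic=True,
                               save_stride_min=60.0, readout_times=(stim_hours,))
        rec, _ = fitted.simulate(cfg)
        y_win = rec.batch.y[:, 0]
        for name in ("ppERK", "ppAKT", "CycD", "BIM_u", "RIB"):
            i = S[name]
            denom = max(abs(ref[i]), 1.0)
            assert abs(y_win[i] - ref[i]) / denom < 0.05, name

    def test_halving_exchange_interval_small_effect(self, fitted):
        """Window-size artifact bound: halving the exchange interval moves
        deterministic 24-h protein outcomes by < 2%."""
        outs = []
        for window in (30.0, 15.0):
            cfg = ExperimentConfig(population_size=1, base_seed=0,
                                   stimulus=StimulusSpec(egf_ng_ml=20.0),
                                   duration_h=12.0, deterministic=True,
                                   window_s=window, save_stride_min=60.0,
                                   readout_times=(12.0,))
            rec, _ = fitted.simulate(cfg)
            idxs = [rec.columns.index(n) for n in ("ERK", "AKT", "BIM", "BCL2")]
            outs.append(rec.data[-1, idxs, 0])
        a, b = outs
        assert np.all(np.abs(a - b) / np.maximum(b, 1.0) < 0.02)


class TestDivisionBookkeeping:
    def test_division_halves_extensive_state(self, fitted):
        from mechcell.simulate import EXTENSIVE, _detect_events
        system = fitted.system
        n = 1
        y = np.repeat(fitted.y_ss[:, None], n, axis=1)
        y[S["CycB"], 0] = 0.01
        batch = CellBatch(y.copy(),
                          np.ones((system.n_genes, n), dtype=np.int64),
                          np.full((system.n_genes, n), 10.0))
        batch.cycb_peak[0] = 1.0  # past a super-threshold cyclin B peak
        rng = np.random.default_rng(0)
        vol_before = batch.y[S["VOL"], 0]
        rib_before = batch.y[S["RIB"], 0]
        _detect_events(batch, system, rng, deterministic=True)
        assert batch.division_times[0]
        assert batch.y[S["VOL"], 0] == pytest.approx(vol_before / 2)
        assert batch.y[S["RIB"], 0] == pytest.approx(rib_before / 2)
        assert np.all(batch.mrna == 5)
        assert batch.y[S["CycB"], 0] == 0.0

    def test_death_latch_freezes_cell(self, fitted):
        system = fitted.system
        y = np.repeat(fitted.y_ss[:, None], 1, axis=1)
        parp_tot = y[S["PARP"], 0] + y[S["cPARP"], 0]
        y[S["cPARP"], 0] = 0.9 * parp_tot
        y[S["PARP"], 0] = 0.1 * parp_tot
        batch = CellBatch(y, np.ones((system.n_genes, 1), dtype=np.int64),
                          np.full((system.n_genes, 1), 5, dtype=np.int64))
        from mechcell.simulate import hybrid_step
        rng = np.random.default_rng(0)
        hybrid_step(batch, system, StimulusSpec(), 30.0 / 3600.0, rng)
        assert batch.dead[0]
        t_death = batch.death_time[0]
        y_frozen = batch.y[:, 0].copy()
        for _ in range(5):
            hybrid_step(batch, system, StimulusSpec(egf_ng_ml=20.0),
                        30.0 / 3600.0, rng)
        assert batch.death_time[0] == t_death
        assert np.array_equal(batch.y[:, 0], y_frozen)
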