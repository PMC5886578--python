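"""Unit tests for omics tailoring: normalization, pool conversion, and
steady-state rate derivation."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import solve_ivp

from mechcell import omics as om


def table(values, species_class="mRNA", genes=None):
    arr = np.atleast_2d(np.asarray(values, float))
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    cols = [f"rep{j+1}" for j in range(arr.shape[1])]
    return om.OmicsTable(pd.DataFrame(arr, index=genes, columns=cols),
                         species_class)


class TestQuantileNormalize:
    def test_identical_columns_are_fixed_point(self):
        t = table([[1.0, 1.0], [5.0, 5.0], [2.0, 2.0]])
        out = om.quantile_normalize(t)
        pd.testing.assert_frame_equal(out.values, t.values)

    def test_anticorrelated_columns_by_rank(self):
        # columns (1,2,3) and (3,2,1): both sorted columns are (1,2,3), so
        # the common distribution is (1,2,3) and values are assigned back by
        # within-column rank, leaving this table unchanged (verified against
        # limma::normalizeQuantiles)
        t = table([[1.0, 3.0], [2.0, 2.0], [3.0, 1.0]])
        out = om.quantile_normalize(t).values.to_numpy()
        assert np.allclose(out[:, 0], [1.0, 2.0, 3.0])
        assert np.allclose(out[:, 1], [3.0, 2.0, 1.0])

    def test_matches_limma_reference_on_mixed_table(self):
        # frozen from limma::normalizeQuantiles on the same 4x3 input
        t = table([[4.0, 1.0, 6.0], [1.0, 3.0, 2.0],
                   [7.0, 2.0, 8.0], [2.0, 9.0, 1.0]])
        out = om.quantile_normalize(t).values.to_numpy()
        expected = np.array([[4.33333333, 1.0, 4.33333333],
                             [1.0, 4.33333333, 2.0],
                             [8.0, 2.0, 8.0],
                             [2.0, 8.0, 1.0]])
        assert np.allclose(out, expected)

    def test_column_value_multisets_identical(self):
        rng = np.random.default_rng(0)
        t = table(rng.lognormal(size=(20, 3)))
        out = om.quantile_normalize(t).values.to_numpy()
        for j in range(1, 3):
            assert np.allclose(np.sort(out[:, 0]), np.sort(out[:, j]))
        assert np.allclose(out.mean(axis=0), out.mean(axis=0)[0])

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        t = table(rng.lognormal(size=(15, 3)))
        once = om.quantile_normalize(t)
        twice = om.quantile_normalize(once)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_single_column_passthrough_warns(self):
        t = table([[1.0], [2.0]])
        with pytest.warns(UserWarning):
            out = om.quantile_normalize(t)
        pd.testing.assert_frame_equal(out.values, t.values)


class TestMoleculesPerCell:
    def test_single_gene_receives_whole_pool(self):
        t = table([[100.0], [0.0]], "protein")
        x = om.to_molecules_per_cell(t, om.PoolConstants())
        assert x.iloc[0] == pytest.approx(3.08e9)

    def test_direct_proportion(self):
        vals = [[10.0]] + [[990.0]]
        x = om.to_molecules_per_cell(table(vals, "mRNA"), om.PoolConstants())
        assert x.iloc[0] == pytest.approx(4000.0)

    def test_sum_equals_pool_and_scale_invariance(self):
        rng = np.random.default_rng(2)
        vals = rng.lognormal(size=(10, 2))
        pool = om.PoolConstants()
        x1 = om.to_molecules_per_cell(table(vals, "mRNA"), pool)
        x2 = om.to_molecules_per_cell(table(vals * 37.5, "mRNA"), pool)
        assert x1.sum() == pytest.approx(pool.total_mrna_per_cell)
        assert np.allclose(x1, x2)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            om.to_molecules_per_cell(table([[0.0], [0.0]]), om.PoolConstants())


class TestPoolArithmetic:
    def test_reported_mrna_total_from_bulk_rna(self):
        # 26 pg RNA, 3% mRNA, 2000-nt transcripts, 339.5 g/mol per nt
        mol = om.total_mrna_from_rna_mass(26.0, 0.03, 2000.0, 339.5)
        assert mol == pytest.approx(691_891, rel=2e-3)

    def test_linearity_in_rna_mass(self):
        a = om.total_mrna_from_rna_mass(26.0, 0.03, 2000.0, 339.5)
        b = om.total_mrna_from_rna_mass(52.0, 0.03, 2000.0, 339.5)
        assert b == pytest.approx(2 * a)

    def test_dimensional_analysis_oracle(self):
        # grams of mRNA -> moles -> molecules, step by step
        grams = 26.0e-12 * 0.03
        moles = grams / (2000.0 * 339.5)
        expected = moles * om.AVOGADRO
        got = om.total_mrna_from_rna_mass(26.0, 0.03, 2000.0, 339.5)
        assert got == pytest.approx(expected, rel=1e-3)

    def test_three_source_average_rounds_to_400k(self):
        out = om.pool_constant_from_sources([173_921, 360_000, 691_891], 1e5)
        assert out == 400_000

    def test_single_estimate_grid_one(self):
        assert om.pool_constant_from_sources([12345.0], 1.0) == 12345.0

    def test_symmetric_pair(self):
        assert om.pool_constant_from_sources([90.0, 110.0], 10.0) == 100.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            om.pool_constant_from_sources([], 1.0)


class TestRates:
    def test_half_life_closed_form(self):
        assert om.half_life_to_rate(math.log(2.0)) == pytest.approx(1.0)
        assert om.half_life_to_rate(9.0) == pytest.approx(0.0770, abs=1e-4)
        with pytest.raises(ValueError):
            om.half_life_to_rate(0.0)

    def test_decay_reaches_half_at_half_life(self):
        t_half = 7.3
        k = om.half_life_to_rate(t_half)
        sol = solve_ivp(lambda t, x: -k * x, (0, t_half), [100.0],
                        rtol=1e-10, atol=1e-12)
        assert sol.y[0, -1] == pytest.approx(50.0, rel=1e-6)

    @pytest.mark.parametrize("g,ka,ki,expected", [
        (2, 1.0, 1.0, 1.0),       # symmetric switching
        (3, 0.7, 0.0, 3.0),       # always-on limit
        (2, 0.5, 1.5, 0.5),
    ])
    def test_active_gene_steady_state(self, g, ka, ki, expected):
        assert om.steady_state_active_gene(g, ka, ki) == pytest.approx(expected)

    def test_active_gene_both_rates_zero_errors(self):
        with pytest.raises(ValueError):
            om.steady_state_active_gene(2, 0.0, 0.0)


class TestRateConstants:
    def test_silent_gene_gets_zero_rates(self):
        r = om.compute_rate_constants(om.GeneRecord("x", m_ss=0.0, p_ss=0.0))
        assert r.k_bm == 0.0 and r.k_bp == 0.0

    def test_transcription_rate_arithmetic(self):
        r = om.GeneRecord("x", g_total=2, k_gac=1.0, k_gin=1.0,
                          t_half_mrna=9.0, m_ss=17.0, p_ss=1000.0)
        out = om.compute_rate_constants(r)
        assert out.k_bm == pytest.approx(out.k_dm * 17.0 / 1.0)
        assert out.k_bm == pytest.approx(1.309, rel=1e-3)

    def test_deleted_gene_with_mrna_is_inconsistent(self):
        with pytest.raises(ValueError):
            om.compute_rate_constants(om.GeneRecord("x", g_total=0, m_ss=5.0))

    def test_steady_state_is_fixed_point_of_expression_odes(self):
        """Integrating dm/dt = k_bm g* - k_dm m, dp/dt = k_bp m - k_dp p from
        (m_ss, p_ss) with the derived rates must not drift (100 h)."""
        r = om.compute_rate_constants(om.GeneRecord(
            "x", g_total=2, k_gac=2.0, k_gin=2.0, t_half_mrna=9.0,
            t_half_protein=46.0, m_ss=120.0, p_ss=7.5e5))
        g_ss = r.g_active_ss

        def rhs(t, z):
            m, p = z
            return [r.k_bm * g_ss - r.k_dm * m, r.k_bp * m - r.k_dp * p]

        sol = solve_ivp(rhs, (0, 100.0), [r.m_ss, r.p_ss], rtol=1e-10,
                        atol=1e-10)
        assert abs(sol.y[0, -1] - r.m_ss) / r.m_ss < 1e-6
        assert abs(sol.y[1, -1] - r.p_ss) / r.p_ss < 1e-6


class TestConglomerates:
    def cmap(self):
        return om.ConglomerateMap({"ERK": ["MAPK1", "MAPK3"], "X": ["X1"]})

    def test_reported_erk_sum(self):
        out = om.aggregate_conglomerates(
            {"MAPK1": 746_463.0, "MAPK3": 76_314.0, "X1": 5.0}, self.cmap())
        assert out["ERK"] == pytest.approx(822_777.0)

    def test_singleton_identity_and_conservation(self):
        per_gene = {"MAPK1": 3.0, "MAPK3": 4.0, "X1": 11.0}
        out = om.aggregate_conglomerates(per_gene, self.cmap())
        assert out["X"] == 11.0
        assert sum(out.values()) == pytest.approx(sum(per_gene.values()))

    def test_unmapped_gene_errors_with_name(self):
        with pytest.raises(KeyError, match="UNKNOWN"):
            om.aggregate_conglomerates({"UNKNOWN": 1.0}, self.cmap())

    def test_gene_in_two_conglomerates_rejected(self):
        with pytest.raises(ValueError):
            om.ConglomerateMap({"A": ["g1"], "B": ["g1"]})


class TestRetailor:
    def base(self):
        genes = ["A", "B", "PTEN"]
        mrna = table([[100.0], [300.0], [600.0]], "mRNA", genes)
        prot = table([[1.0], [2.0], [7.0]], "protein", genes)
        hl = pd.DataFrame({"t_half_mrna_h": [9.0] * 3,
                           "t_half_protein_h": [46.0] * 3}, index=genes)
        copies = pd.Series([2, 2, 2], index=genes)
        cmap = om.ConglomerateMap({g: [g] for g in genes})
        return om.tailor_genes(mrna, prot, hl, copies, cmap), genes

    def test_identity_retailor_is_noop(self):
        base, genes = self.base()
        new = om.retailor(base, table([[100.0], [300.0], [600.0]], "mRNA",
                                      genes), [])
        for g in genes:
            assert new[g].m_ss == pytest.approx(base[g].m_ss)
            assert new[g].p_ss == pytest.approx(base[g].p_ss)
            assert new[g].k_bp == pytest.approx(base[g].k_bp)

    def test_knockout_zeroes_translation(self):
        base, genes = self.base()
        new = om.retailor(base, table([[100.0], [300.0], [600.0]], "mRNA",
                                      genes), ["PTEN"])
        assert new["PTEN"].k_bp == 0.0
        # protein decays to < 1% of base within 5 half-lives without synthesis
        k = new["PTEN"].k_dp
        sol = solve_ivp(lambda t, p: [-k * p[0]], (0, 5 * 46.0),
                        [base["PTEN"].p_ss], rtol=1e-8)
        assert sol.y[0, -1] < 0.05 * base["PTEN"].p_ss

    def test_protein_tracks_mrna_under_fixed_ratio(self):
        # pool renormalization changes every share, but p_ss/m_ss is held at
        # the base context ratio, so p_new/p_old == m_new/m_old exactly
        base, genes = self.base()
        new = om.retailor(base, table([[200.0], [300.0], [600.0]], "mRNA",
                                      genes), [])
        for g in genes:
            assert new[g].p_ss / base[g].p_ss == pytest.approx(
                new[g].m_ss / base[g].m_ss)

    def test_unknown_knockout_errors(self):
        base, genes = self.base()
        with pytest.raises(KeyError):
            om.retailor(base, table([[1.0], [1.0], [1.0]], "mRNA", genes),
                        ["NOPE"])


class TestNormalizationProperties:
    """Property-based checks of the normalization pipeline."""

    from hypothesis import given, settings, strategies as st

    @staticmethod
    def _table_from(values):
        import numpy as _np
        arr = _np.array(values, float)
        return table(arr)

    @given(st.lists(st.lists(st.floats(min_value=0.0, max_value=1e6,
                                       allow_nan=False, allow_infinity=False),
                             min_size=2, max_size=4),
                    min_size=2, max_size=12).filter(
                        lambda rows: len({len(r) for r in rows}) == 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_quantile_normalize_idempotent_and_multiset_equal(self, rows):
        import numpy as np
        t = table(np.array(rows, float))
        once = om.quantile_normalize(t)
        twice = om.quantile_normalize(once)
        assert np.allclose(once.values.to_numpy(), twice.values.to_numpy())
        out = once.values.to_numpy()
        for j in range(1, out.shape[1]):
            assert np.allclose(np.sort(out[:, 0]), np.sort(out[:, j]))

    @given(st.lists(st.floats(min_value=1e-6, max_value=1e6,
                              allow_nan=False, allow_infinity=False),
                    min_size=2, max_size=20),
           st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_pool_conversion_scale_invariant_and_conserving(self, vals, c):
        import numpy as np
        pool = om.PoolConstants()
        t1 = table(np.array(vals)[:, None])
        t2 = table(c * np.array(vals)[:, None])
        x1 = om.to_molecules_per_cell(t1, pool)
        x2 = om.to_molecules_per_cell(t2, pool)
        assert np.allclose(x1, x2, rtol=1e-9)
        assert x1.sum() == pytest.approx(pool.total_mrna_per_cell)
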