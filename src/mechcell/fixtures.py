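"""Synthetic-data generation: omics tables, half-life tables, copy-number
tables, the conglomerate map, and canned experiment configurations.

The generator emulates the model's data inputs: per-gene linear abundance
measurements (UMI-count-like for mRNA, iBAQ-like for protein) in three
replicates with mean-preserving log-normal noise, anchored so that the full
tailoring pipeline recovers a set of literature-reported molecules-per-cell
values exactly in the noiseless limit. A single BULK row absorbs the rest
of the whole-cell pools so that the anchored genes land on their absolute
copy numbers after pool normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import EXPRESSION_COUPLING, UNCOUPLED_GENES
from .omics import ConglomerateMap, OmicsTable, PoolConstants

__all__ = ["FixtureSpec", "make_omics_fixture", "make_conglomerate_map",
           "make_experiment_configs", "DEFAULT_GENOME"]


# gene -> (protein molecules/cell, mRNA molecules/cell,
#          mRNA half-life h, protein half-life h, copies)
# Protein abundances for ERK/AKT/MEK isoforms, Raf isoforms, cMyc/cFos/cJun
# and BAD/BCL2 are the reported MCF10A copy numbers; the remainder are
# order-of-magnitude-realistic choices for this cell type.
DEFAULT_GENOME: dict[str, tuple[float, float, float, float, int]] = {
    # receptors
    "EGFR":     (9.0e4, 60.0, 6.0, 12.0, 2),
    "ERBB2":    (3.0e4, 25.0, 6.0, 12.0, 2),
    "INSR":     (4.0e4, 25.0, 8.0, 16.0, 2),
    "IGF1R":    (2.0e4, 15.0, 8.0, 16.0, 2),
    # Ras/Raf/MEK/ERK
    "HRAS":     (5.0e4, 30.0, 9.0, 46.0, 2),
    "KRAS":     (4.0e4, 25.0, 9.0, 46.0, 2),
    "NRAS":     (3.0e4, 20.0, 9.0, 46.0, 2),
    "RAF1":     (2.9e4, 20.0, 9.0, 40.0, 2),
    "BRAF":     (2.8e3, 4.0, 9.0, 40.0, 2),
    "MAP2K1":   (147250.0, 60.0, 9.0, 46.0, 2),
    "MAP2K2":   (377540.0, 120.0, 9.0, 46.0, 2),
    "MAPK1":    (746463.0, 220.0, 9.0, 46.0, 2),
    "MAPK3":    (76314.0, 40.0, 9.0, 46.0, 2),
    # PI3K/AKT axis
    "PIK3CA":   (5.0e4, 30.0, 9.0, 30.0, 2),
    "PTEN":     (1.2e5, 80.0, 9.0, 30.0, 2),
    "AKT1":     (74762.0, 50.0, 9.0, 36.0, 2),
    "AKT2":     (81476.0, 50.0, 9.0, 36.0, 2),
    "MTOR":     (6.0e4, 30.0, 9.0, 30.0, 2),
    "EIF4E":    (1.0e5, 60.0, 9.0, 30.0, 2),
    "EIF4EBP1": (8.0e4, 50.0, 9.0, 20.0, 2),
    "FOXO3":    (4.0e4, 30.0, 6.0, 12.0, 2),
    # immediate-early / TFs
    "FOS":      (0.0, 0.0, 0.25, 2.0, 2),
    "JUN":      (3.0e3, 6.0, 0.4, 2.0, 2),
    "MYC":      (4.8e4, 50.0, 0.5, 1.0, 2),
    "CCND1":    (4.0e3, 10.0, 0.5, 0.8, 2),
    # apoptosis
    "TNFRSF10B": (1.0e4, 10.0, 6.0, 12.0, 2),
    "CASP8":    (2.0e4, 15.0, 9.0, 30.0, 2),
    "BID":      (6.0e4, 30.0, 9.0, 40.0, 2),
    "CASP3":    (5.0e4, 25.0, 9.0, 30.0, 2),
    "PARP1":    (1.0e6, 300.0, 9.0, 46.0, 2),
    "BAX":      (1.0e5, 50.0, 9.0, 40.0, 2),
    "BCL2":     (6.1e4, 40.0, 6.0, 20.0, 2),
    "BCL2L11":  (2.0e4, 12.0, 3.0, 8.0, 2),
    "BAD":      (1.4e4, 15.0, 6.0, 20.0, 2),
    "BBC3":     (2.0e3, 3.0, 1.5, 4.0, 2),
    "PMAIP1":   (2.0e3, 3.0, 1.5, 4.0, 2),
    # cycle / damage module genes (tailored but not expression-coupled)
    "TP53":     (2.0e4, 20.0, 9.0, 0.5, 2),
    "MDM2":     (1.0e4, 10.0, 2.0, 0.5, 2),
    "PPM1D":    (5.0e3, 5.0, 2.0, 2.0, 2),
    "CHEK1":    (1.0e4, 10.0, 9.0, 10.0, 2),
    "CCNE1":    (2.0e3, 4.0, 2.0, 2.0, 2),
    "CCNA2":    (1.0e3, 3.0, 2.0, 2.0, 2),
    "CCNB1":    (1.0e3, 3.0, 2.0, 2.0, 2),
    "CDKN1A":   (5.0e3, 8.0, 1.0, 1.0, 2),
    "E2F1":     (1.0e3, 3.0, 1.0, 2.0, 2),
    "BRCA2":    (1.0e4, 8.0, 9.0, 20.0, 2),
    "MSH6":     (1.0e4, 8.0, 9.0, 20.0, 2),
    "MGMT":     (1.0e4, 8.0, 9.0, 20.0, 2),
}


@dataclass
class FixtureSpec:
    """Configuration of the synthetic omics generator."""

    genome: dict = field(default_factory=lambda: dict(DEFAULT_GENOME))
    n_replicates: int = 3
    noise_cv: float = 0.2       # log-normal replicate CV, mean-preserving
    seed: int = 0
    pool: PoolConstants = field(default_factory=PoolConstants)
    measurement_scale_mrna: float = 0.05    # arbitrary linear unit (UMI-like)
    measurement_scale_protein: float = 1e-4  # arbitrary linear unit (iBAQ-like)


def _replicates(x: np.ndarray, n_rep: int, cv: float,
                rng: np.random.Generator) -> np.ndarray:
    if cv <= 0:
        return np.repeat(x[:, None], n_rep, axis=1)
    sigma = np.sqrt(np.log1p(cv ** 2))
    noise = rng.lognormal(-0.5 * sigma ** 2, sigma, size=(len(x), n_rep))
    return x[:, None] * noise


def make_omics_fixture(spec: FixtureSpec | None = None):
    """Generate (copies, mRNA table, protein table, half-life table).

    The noiseless expectation of each table, run through quantile
    normalization and pool conversion, reproduces the anchored
    molecules-per-cell values exactly (a BULK row absorbs the remainder of
    each pool). Deterministic for a given seed.
    """
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(spec.seed)
    genes = list(spec.genome)
    p_target = np.array([spec.genome[g][0] for g in genes], float)
    m_target = np.array([spec.genome[g][1] for g in genes], float)
    if (p_target < 0).any() or (m_target < 0).any():
        raise ValueError("anchored abundances must be non-negative")
    m_bulk = spec.pool.total_mrna_per_cell - m_target.sum()
    p_bulk = spec.pool.total_protein_per_cell - p_target.sum()
    if m_bulk < 0 or p_bulk < 0:
        raise ValueError("anchored abundances exceed the whole-cell pool")
    index = genes + ["BULK"]
    m_all = np.append(m_target, m_bulk) * spec.measurement_scale_mrna
    p_all = np.append(p_target, p_bulk) * spec.measurement_scale_protein

    cols = [f"rep{i + 1}" for i in range(spec.n_replicates)]
    mrna = OmicsTable(pd.DataFrame(
        _replicates(m_all, spec.n_replicates, spec.noise_cv, rng),
        index=index, columns=cols), "mRNA")
    protein = OmicsTable(pd.DataFrame(
        _replicates(p_all, spec.n_replicates, spec.noise_cv, rng),
        index=index, columns=cols), "protein")

    half_lives = pd.DataFrame(
        {"t_half_mrna_h": [spec.genome[g][2] for g in genes] + [9.0],
         "t_half_protein_h": [spec.genome[g][3] for g in genes] + [46.0]},
        index=index)
    copies = pd.Series([spec.genome[g][4] for g in genes] + [2],
                       index=index, dtype=int)
    return copies, mrna, protein, half_lives


def make_conglomerate_map(genome: dict | None = None) -> ConglomerateMap:
    """Conglomerate map over the fixture gene set (ERK=MAPK1+MAPK3, ...)."""
    genome = genome or DEFAULT_GENOME
    mapping: dict[str, list[str]] = {}
    for cong, entry in EXPRESSION_COUPLING.items():
        members = [g for g in entry.genes if g in genome]
        if members:
            mapping[cong] = members
    for g in UNCOUPLED_GENES:
        if g in genome:
            mapping[g] = [g]
    if "BULK" not in mapping:
        mapping["BULK"] = ["BULK"]
    return ConglomerateMap(mapping)


def make_experiment_configs(population_size: int = 100, base_seed: int = 0):
    """Canned experiment configurations for the reported scenarios.

    Doses: EGF 20 ng/mL, insulin 10 ug/mL, MEKi/AKTi 10 uM, etoposide
    100 uM, TRAIL ladder 2-300 ng/mL.
    """
    from .simulate import ExperimentConfig, StimulusSpec

    def cfg(stim, duration=72.0, **kw):
        return ExperimentConfig(population_size=population_size,
                                base_seed=base_seed, stimulus=stim,
                                duration_h=duration, **kw)

    gf = dict(egf_ng_ml=20.0, insulin_ug_ml=10.0)
    configs = {
        "serum_starved": cfg(StimulusSpec(), 72.0),
        "egf": cfg(StimulusSpec(egf_ng_ml=20.0), 24.0, readout_times=(24.0,)),
        "insulin": cfg(StimulusSpec(insulin_ug_ml=10.0), 24.0,
                       readout_times=(24.0,)),
        "egf_insulin": cfg(StimulusSpec(**gf), 72.0),
        "egf_insulin_meki": cfg(StimulusSpec(**gf, meki_um=10.0), 72.0),
        "egf_insulin_akti": cfg(StimulusSpec(**gf, akti_um=10.0), 72.0),
        "egf_insulin_meki_akti": cfg(StimulusSpec(**gf, meki_um=10.0,
                                                  akti_um=10.0), 72.0),
        "etoposide": cfg(StimulusSpec(etoposide_um=100.0), 72.0),
        "egf_insulin_etoposide": cfg(StimulusSpec(**gf, etoposide_um=100.0),
                                     72.0),
    }
    for dose in (2.0, 10.0, 50.0, 100.0, 300.0):
        configs[f"trail_{dose:g}"] = cfg(
            StimulusSpec(trail_ng_ml=dose), 24.0, readout_times=(5.0, 24.0))
    return configs
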