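"""mechcell: omics-tailored hybrid stochastic-deterministic simulation of
single-cell proliferation and death driven by the ERK/AKT pan-cancer driver
network."""

from .omics import (OmicsTable, PoolConstants, GeneRecord, ConglomerateMap,
                    quantile_normalize, to_molecules_per_cell,
                    total_mrna_from_rna_mass, pool_constant_from_sources,
                    half_life_to_rate, steady_state_active_gene,
                    compute_rate_constants, aggregate_conglomerates,
                    tailor_genes, retailor)
from .network import NetworkParams, SPECIES, S, MOIETIES, moiety_total
from .model import CellPopulationModel, InitializedCellModel, InitializationReport
from .simulate import (StimulusSpec, ExperimentConfig, PopulationSummary,
                       run_experiment, summarize_population)
from .fixtures import (FixtureSpec, make_omics_fixture, make_conglomerate_map,
                       make_experiment_configs, DEFAULT_GENOME)
from .analysis import (FeatureMatrix, FateReport, build_features, label_cells,
                       lasso_select, train_and_roc, correlation_screen,
                       lhs_degradation_sensitivity)
from .signaling import fit_hill, transformation_scan

__version__ = "0.1.0"

__all__ = [n for n in dir() if not n.startswith("_")]


def default_model(seed: int = 0, noise_cv: float = 0.0,
                  params: NetworkParams | None = None) -> CellPopulationModel:
    """Convenience: the MCF10A-style model tailored from the synthetic
    omics fixture (noiseless by default, so anchors are exact)."""
    import warnings as _w
    spec = FixtureSpec(seed=seed, noise_cv=noise_cv)
    copies, mrna, protein, half_lives = make_omics_fixture(spec)
    cmap = make_conglomerate_map(spec.genome)
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        return CellPopulationModel.from_tables(mrna, protein, half_lives,
                                               copies, cmap, pool=spec.pool,
                                               params=params)
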