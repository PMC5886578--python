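"""Omics tailoring: convert gene-level abundance tables into per-gene
molecules-per-cell values and steady-state transcription/translation rate
constants.

The expression model for each gene is the telegraph + linear birth/death
system

    dm/dt  = k_bm * g_active - k_dm * m
    dp/dt  = k_bp * m        - k_dp * p
    dg*/dt = k_gac * g_inactive - k_gin * g_active

with steady states  g*_ss = k_gac * g_total / (k_gac + k_gin),
k_bm = k_dm * m_ss / g*_ss  and  k_bp = k_dp * p_ss / m_ss.

Linear measurement units (UMI counts, iBAQ scores) are converted to
molecules per cell by assigning each gene its share of a fixed whole-cell
pool (400,000 mRNAs; 3.08e9 proteins by default).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "OmicsTable",
    "PoolConstants",
    "GeneRecord",
    "ConglomerateMap",
    "AVOGADRO",
    "quantile_normalize",
    "collapse_replicates",
    "to_molecules_per_cell",
    "total_mrna_from_rna_mass",
    "pool_constant_from_sources",
    "half_life_to_rate",
    "steady_state_active_gene",
    "compute_rate_constants",
    "aggregate_conglomerates",
    "tailor_genes",
    "retailor",
]

AVOGADRO = 6.02214076e23


@dataclass(frozen=True)
class OmicsTable:
    """Gene-level linear abundance measurements, one column per replicate.

    ``values`` is indexed by gene_id; units are arbitrary but linearly
    proportional to molecule numbers (A_i = alpha * X_i).
    """

    values: pd.DataFrame
    species_class: str  # "mRNA" or "protein"

    def __post_init__(self) -> None:
        if self.species_class not in ("mRNA", "protein"):
            raise ValueError(f"unknown species_class {self.species_class!r}")
        if self.values.shape[1] < 1:
            raise ValueError("need at least one replicate column")
        if self.values.index.has_duplicates:
            raise ValueError("gene_ids must be unique")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("abundances must be non-negative")

    @property
    def n_replicates(self) -> int:
        return self.values.shape[1]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)


@dataclass(frozen=True)
class PoolConstants:
    """Whole-cell molecule pools used to scale linear measurements."""

    total_mrna_per_cell: float = 400_000.0
    total_protein_per_cell: float = 3.08e9
    ribosomes_per_cell: float = 6.0e6

    def __post_init__(self) -> None:
        for name in ("total_mrna_per_cell", "total_protein_per_cell", "ribosomes_per_cell"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    def pool_for(self, species_class: str) -> float:
        return {
            "mRNA": self.total_mrna_per_cell,
            "protein": self.total_protein_per_cell,
        }[species_class]


@dataclass
class GeneRecord:
    """Per-gene expression parameters of the tailored model."""

    gene_id: str
    g_total: int = 2
    k_gac: float = 2.0  # 1/h
    k_gin: float = 2.0  # 1/h
    t_half_mrna: float = 9.0  # h
    t_half_protein: float = 46.0  # h
    m_ss: float = 0.0  # molecules/cell
    p_ss: float = 0.0  # molecules/cell
    k_bm: float = float("nan")  # mRNA/(active gene * h)
    k_bp: float = float("nan")  # protein/(mRNA * h)
    conglomerate_id: str = ""

    @property
    def k_dm(self) -> float:
        return half_life_to_rate(self.t_half_mrna)

    @property
    def k_dp(self) -> float:
        return half_life_to_rate(self.t_half_protein)

    @property
    def g_active_ss(self) -> float:
        return steady_state_active_gene(self.g_total, self.k_gac, self.k_gin)


class ConglomerateMap:
    """Total mapping gene_id -> conglomerate (lumped model species).

    Functionally redundant gene products are summed into a single model
    species, e.g. ERK = MAPK1 + MAPK3.
    """

    def __init__(self, mapping: dict[str, list[str]]):
        self._by_conglomerate = {c: list(genes) for c, genes in mapping.items()}
        self._by_gene: dict[str, str] = {}
        for cong, genes in self._by_conglomerate.items():
            for g in genes:
                if g in self._by_gene:
                    raise ValueError(f"gene {g!r} mapped to more than one conglomerate")
                self._by_gene[g] = cong

    def conglomerate_of(self, gene_id: str) -> str:
        return self._by_gene[gene_id]

    def genes_of(self, conglomerate_id: str) -> list[str]:
        return list(self._by_conglomerate[conglomerate_id])

    @property
    def conglomerates(self) -> list[str]:
        return list(self._by_conglomerate)

    @property
    def genes(self) -> list[str]:
        return list(self._by_gene)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_gene

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ConglomerateMap":
        """Build from a two-column table (gene_id, conglomerate_id)."""
        mapping: dict[str, list[str]] = {}
        for gene, cong in zip(frame.iloc[:, 0], frame.iloc[:, 1]):
            mapping.setdefault(str(cong), []).append(str(gene))
        return cls(mapping)

    def to_frame(self) -> pd.DataFrame:
        rows = [(g, c) for g, c in self._by_gene.items()]
        return pd.DataFrame(rows, columns=["gene_id", "conglomerate_id"])


# ---------------------------------------------------------------------------
# operations


def quantile_normalize(table: OmicsTable) -> OmicsTable:
    """Quantile-normalize replicate columns.

    Each column's sorted values are replaced by the row-wise mean of all
    sorted columns; values are assigned back by within-column rank, so after
    normalization every column holds the identical value multiset.
    Single-column tables pass through with a warning. Idempotent.
    """
    vals = table.values
    if vals.shape[1] < 2:
        warnings.warn("quantile normalization needs >=2 replicates; passing through")
        return table
    arr = vals.to_numpy(dtype=float)
    order = np.argsort(arr, axis=0, kind="stable")
    ranks = np.empty_like(order)
    n = arr.shape[0]
    rows = np.arange(n)
    for j in range(arr.shape[1]):
        ranks[order[:, j], j] = rows
    mean_sorted = np.sort(arr, axis=0).mean(axis=1)
    out = mean_sorted[ranks]
    return OmicsTable(pd.DataFrame(out, index=vals.index, columns=vals.columns),
                      table.species_class)


def collapse_replicates(table: OmicsTable) -> pd.Series:
    """Collapse replicate columns to one value per gene (arithmetic mean)."""
    return table.values.mean(axis=1)


def to_molecules_per_cell(table: OmicsTable, pool: PoolConstants) -> pd.Series:
    """Convert linear abundances A_i to absolute copies per cell X_i.

    Because A_i = alpha * X_i with one unknown scale per table,
    A_i / sum(A) = X_i / sum(X), so X_i is the gene's share of the fixed
    whole-cell pool for its species class. The output sums exactly to the
    pool constant.
    """
    a = collapse_replicates(table)
    total = float(a.sum())
    if total <= 0:
        raise ValueError("all-zero abundance table: shares are undefined")
    return a / total * pool.pool_for(table.species_class)


def total_mrna_from_rna_mass(total_rna_pg: float, mrna_fraction: float,
                             mean_transcript_nt: float,
                             nt_mass_g_per_mol: float) -> float:
    """Estimate total mRNA molecules per cell from bulk RNA mass.

    molecules = pg*1e-12 * fraction / (nt * g/mol per nt) * N_A.
    With typical mammalian values (26 pg, 3% mRNA, 2000 nt, 339.5 g/mol)
    this gives ~6.9e5 molecules per cell.
    """
    for name, v in (("total_rna_pg", total_rna_pg), ("mrna_fraction", mrna_fraction),
                    ("mean_transcript_nt", mean_transcript_nt),
                    ("nt_mass_g_per_mol", nt_mass_g_per_mol)):
        if v <= 0:
            raise ValueError(f"{name} must be > 0")
    grams = total_rna_pg * 1e-12 * mrna_fraction
    mol = grams / (mean_transcript_nt * nt_mass_g_per_mol)
    return mol * AVOGADRO


def pool_constant_from_sources(estimates: list[float], rounding_grid: float) -> float:
    """Average independent pool-size estimates, rounded to a grid multiple."""
    if len(estimates) == 0:
        raise ValueError("need at least one estimate")
    if rounding_grid <= 0:
        raise ValueError("rounding_grid must be > 0")
    mean = float(np.mean(estimates))
    return round(mean / rounding_grid) * rounding_grid


def half_life_to_rate(t_half: float) -> float:
    """First-order rate constant k = ln2 / t_half (1/h)."""
    if t_half <= 0:
        raise ValueError("half-life must be > 0")
    return math.log(2.0) / t_half


def steady_state_active_gene(g_total: float, k_gac: float, k_gin: float) -> float:
    """Mean active gene copies of the telegraph process,
    g*_ss = k_gac * g_total / (k_gin + k_gac)."""
    if k_gac + k_gin <= 0:
        raise ValueError("k_gac + k_gin must be > 0")
    if k_gac < 0 or k_gin < 0:
        raise ValueError("switching rates must be non-negative")
    return k_gac * g_total / (k_gin + k_gac)


def compute_rate_constants(record: GeneRecord) -> GeneRecord:
    """Fill k_bm and k_bp from the steady-state balance.

    k_bm = k_dm * m_ss / g*_ss ; k_bp = k_dp * p_ss / m_ss. Deleted genes
    (g_total = 0) get k_bm = 0; silent genes (m_ss = 0) get k_bm = k_bp = 0.
    """
    if record.m_ss > 0 and record.g_total == 0:
        raise ValueError(
            f"gene {record.gene_id}: m_ss > 0 with zero gene copies is inconsistent")
    if record.g_total == 0 or record.m_ss == 0:
        k_bm = 0.0
        k_bp = 0.0 if record.m_ss == 0 else record.k_dp * record.p_ss / record.m_ss
        if record.m_ss == 0 and record.p_ss > 0:
            # protein present with no transcript: frozen pool, no synthesis
            k_bp = 0.0
        return replace(record, k_bm=k_bm, k_bp=k_bp)
    g_ss = record.g_active_ss
    k_bm = record.k_dm * record.m_ss / g_ss
    k_bp = record.k_dp * record.p_ss / record.m_ss
    return replace(record, k_bm=k_bm, k_bp=k_bp)


def aggregate_conglomerates(per_gene: dict[str, float] | pd.Series,
                            cmap: ConglomerateMap) -> dict[str, float]:
    """Sum per-gene amounts into conglomerate totals; conserves the total."""
    if isinstance(per_gene, pd.Series):
        per_gene = per_gene.to_dict()
    unmapped = [g for g in per_gene if g not in cmap]
    if unmapped:
        raise KeyError(f"genes missing from conglomerate map: {sorted(unmapped)}")
    out: dict[str, float] = {}
    for g, v in per_gene.items():
        c = cmap.conglomerate_of(g)
        out[c] = out.get(c, 0.0) + float(v)
    return out


# ---------------------------------------------------------------------------
# pipeline


def tailor_genes(mrna: OmicsTable, protein: OmicsTable,
                 half_lives: pd.DataFrame, copies: pd.Series,
                 cmap: ConglomerateMap,
                 pool: PoolConstants | None = None,
                 k_gac: float = 2.0, k_gin: float = 2.0) -> dict[str, GeneRecord]:
    """Full PREP pipeline: normalize, convert to molecules per cell, and
    derive per-gene rate constants.

    Quantile normalization is applied per species class. Genes present in
    only one of the two tables are imputed via the cohort-median
    protein-to-mRNA ratio (with a warning). ``half_lives`` needs columns
    t_half_mrna_h / t_half_protein_h indexed by gene_id; ``copies`` is an
    integer Series indexed by gene_id.
    """
    pool = pool or PoolConstants()
    m_mol = to_molecules_per_cell(quantile_normalize(mrna), pool)
    p_mol = to_molecules_per_cell(quantile_normalize(protein), pool)

    genes = sorted(set(m_mol.index) | set(p_mol.index))
    with np.errstate(divide="ignore", invalid="ignore"):
        both = [g for g in genes if g in m_mol.index and g in p_mol.index
                and m_mol[g] > 0 and p_mol[g] > 0]
        ratios = np.array([p_mol[g] / m_mol[g] for g in both])
    median_ratio = float(np.median(ratios)) if len(ratios) else 1.0

    records: dict[str, GeneRecord] = {}
    for g in genes:
        if g in m_mol.index:
            m = float(m_mol[g])
        else:
            p_tmp = float(p_mol[g])
            m = p_tmp / median_ratio
            warnings.warn(f"gene {g}: no mRNA measurement; imputed from "
                          "cohort-median protein-to-mRNA ratio")
        if g in p_mol.index:
            p = float(p_mol[g])
        else:
            p = m * median_ratio
            warnings.warn(f"gene {g}: no protein measurement; imputed from "
                          "cohort-median protein-to-mRNA ratio")
        g_total = int(copies.get(g, 2))
        if g_total == 0:
            m = 0.0
        hl = half_lives.loc[g] if g in half_lives.index else None
        rec = GeneRecord(
            gene_id=g,
            g_total=g_total,
            k_gac=k_gac,
            k_gin=k_gin,
            t_half_mrna=float(hl["t_half_mrna_h"]) if hl is not None else 9.0,
            t_half_protein=float(hl["t_half_protein_h"]) if hl is not None else 46.0,
            m_ss=m,
            p_ss=p,
            conglomerate_id=cmap.conglomerate_of(g) if g in cmap else g,
        )
        records[g] = compute_rate_constants(rec)
    return records


def retailor(base: dict[str, GeneRecord], new_mrna: OmicsTable,
             knockouts: list[str] | None = None,
             pool: PoolConstants | None = None) -> dict[str, GeneRecord]:
    """Re-tailor an existing parameter set to a new cellular context.

    mRNA-derived quantities are recomputed from ``new_mrna``; protein steady
    states are recomputed from the base context's gene-specific
    protein-to-mRNA ratios; knockout genes get k_bp = 0 (protein synthesis
    removed). All other parameters are kept.
    """
    knockouts = knockouts or []
    for g in knockouts:
        if g not in base:
            raise KeyError(f"knockout gene {g!r} not in model")
    pool = pool or PoolConstants()
    m_mol = to_molecules_per_cell(quantile_normalize(new_mrna), pool)
    out: dict[str, GeneRecord] = {}
    for g, rec in base.items():
        new = replace(rec)
        if g in m_mol.index:
            m_new = float(m_mol[g])
            ratio = rec.p_ss / rec.m_ss if rec.m_ss > 0 else 0.0
            new = replace(new, m_ss=m_new, p_ss=m_new * ratio, k_bm=float("nan"),
                          k_bp=float("nan"))
        new = compute_rate_constants(new)
        if g in knockouts:
            new = replace(new, k_bp=0.0, p_ss=0.0)
        out[g] = new
    return out


def records_to_frame(records: dict[str, GeneRecord]) -> pd.DataFrame:
    """Flatten GeneRecords into the tailored-parameter table (TSV-ready)."""
    rows = []
    for g, r in records.items():
        rows.append(dict(gene_id=g, g_total=r.g_total, k_gac=r.k_gac, k_gin=r.k_gin,
                         t_half_mrna_h=r.t_half_mrna, t_half_protein_h=r.t_half_protein,
                         m_ss=r.m_ss, p_ss=r.p_ss, k_dm=r.k_dm, k_dp=r.k_dp,
                         k_bm=r.k_bm, k_bp=r.k_bp, conglomerate_id=r.conglomerate_id))
    return pd.DataFrame(rows).set_index("gene_id")


def records_from_frame(frame: pd.DataFrame) -> dict[str, GeneRecord]:
    records = {}
    for g, row in frame.iterrows():
        records[str(g)] = GeneRecord(
            gene_id=str(g), g_total=int(row["g_total"]), k_gac=float(row["k_gac"]),
            k_gin=float(row["k_gin"]), t_half_mrna=float(row["t_half_mrna_h"]),
            t_half_protein=float(row["t_half_protein_h"]), m_ss=float(row["m_ss"]),
            p_ss=float(row["p_ss"]), k_bm=float(row["k_bm"]), k_bp=float(row["k_bp"]),
            conglomerate_id=str(row["conglomerate_id"]))
    return records
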