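# Methods

This note documents the model behind `mechcell`: what is simulated, how the
omics tailoring works, which design choices were genuinely open and how they
were resolved, what the synthetic-data generator does and does not emulate,
and the numerical machinery. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Scope and architecture

The package simulates single epithelial cells in which stochastic gene
expression feeds a deterministic mechanistic network of the major cancer
driver pathways, and asks population-level questions: what fraction of
cells dies or divides under a stimulus, and how predictable each cell's
fate is from its protein levels. The network is a *reduced* re-expression
of a much larger class of mass-action models: it keeps the architecture —
receptor activation and trafficking, Ras/Raf/MEK/ERK and PI3K/AKT futile
cycles with one negative feedback per arm, Raf:MEK complex formation,
mTOR/EIF4E translation control, AP1/cMyc transcription drives, a cyclin
oscillator, an intrinsic/extrinsic apoptosis module and a p53 DNA-damage
module — at roughly 80 species instead of ~1,200. All rate constants are
this package's own calibration against population-level behavior
(serum-starved death rate, inhibitor-induced death kinetics, the etoposide
plateau, ~20-h cycle timing); they are not literature rate constants.

## Omics tailoring (the PREP stage)

Gene-level linear measurements (three replicates of UMI-count-like mRNA
and iBAQ-like protein intensities) are quantile-normalized per species
class, replicates collapsed by arithmetic mean, and converted to molecules
per cell by assigning each gene its share of fixed whole-cell pools:
400,000 mRNAs and 3.08x10^9 proteins (the mRNA pool is the grid-rounded
average of three independent literature-style estimates, one of which is
derived from 26 pg total RNA x 3% mRNA / (2000 nt x 339.5 g/mol) x N_A).
Degradation rates come from gene-specific half-lives (k = ln2/t_half);
transcription and translation rates follow from the steady-state balance
k_bm = k_dm m_ss / g*_ss and k_bp = k_dp p_ss / m_ss, with
g*_ss = k_gac g_tot/(k_gac+k_gin). A single promoter switching rate pair
(k_gac = k_gin = 2/h) is used for all genes; it gives a mean active
fraction of 0.5 and makes switching observable at the 30-s exchange
interval. Functionally redundant products are summed into conglomerates
(ERK = MAPK1+MAPK3, AKT = AKT1+AKT2, ...). Genes measured in only one
modality are imputed through the cohort-median protein-to-mRNA ratio. A
gene with zero basal mRNA *and* protein but positive copy number (the
cFos case) receives the cohort-median translation rate so that induced
transcripts can be translated; knockouts (translation rate forced to zero)
are untouched by this rule.

Re-tailoring to a new cellular context swaps the mRNA table, recomputes
protein targets through the base context's gene-specific protein-to-mRNA
ratios, re-derives rates, and zeroes the translation rate of knockout
genes (the PTEN-null scenario).

## Average-cell initialization

Initialization integrates the deterministic system to its serum-starved
steady state and then rescales each gene's effective translation rate by
(proteomics target)/(simulated conglomerate total) until the largest
relative error is below 1% (default; up to 50 iterations). The rescaling
is damped (ratio^0.7, clipped to [0.2, 5]) because global translation
control couples all genes. The first relaxation pass runs with the
transcription-factor multipliers and the global translation/growth inputs
frozen at their neutral values; the basal operating point recorded from
that pass (basal free-EIF4E, basal mTOR fraction, basal nuclear-FOXO
fraction, basal multiplier values) then normalizes all drives so the
tailored rates remain a fixed point of the full system. Convergence also
requires a non-cycling (no cyclin B excursion in a 100-h probe) and
non-apoptotic (cPARP below half the PARP pool) steady state. Basal
caspase-8 activity is an explicit configuration knob: it sets the
serum-starved death rate and is the parameter a user would retune for a
context where basal death is known to differ.

The basal state is a genuine steady state of the deterministic system
except for slow cPARP turnover: serum-starved cells sit at a sub-lethal
cleaved-PARP equilibrium whose level varies from cell to cell, and the
upper tail of that distribution drifts across the 50% death threshold over
tens of hours. This is the model's account of the steady basal attrition
of starved populations; it is deliberate, not a convergence failure.

## Hybrid stochastic–deterministic stepping

Every 30-s window (configurable), each cell advances in two stages:

1. *Stochastic expression.* Promoter copies flip with the exact two-state
   matrix-exponential transition probabilities over the window; mRNA counts
   are updated with the exact immigration–death propagator (binomial
   survival x Poisson births) with the gene state frozen within the
   window. These propagators equal event-by-event SSA in distribution at
   the window boundaries — the only points the hybrid scheme reads — and
   vectorize across cells and genes; an event-driven SSA is retained as the
   independent oracle in the test suite.
2. *Deterministic dynamics.* The full network ODE advances by fixed-step
   RK4 (two 15-s substeps by default) with mRNA held at its window value.
   All rate constants are kept below ~600/h so the explicit step is
   stable; halving the exchange interval changes 24-h protein outcomes by
   under 2% (tested). Catalytic drives are concentration-based
   (amount/volume), so growth does not inflate signaling and division does
   not deflate it.

Deterministic single-cell work (initialization, deterministic experiments)
uses adaptive LSODA on the same right-hand side, giving a dual-route
numerical consistency check (tested against the windowed path).

Population runs draw from one counter-based stream seeded by the
experiment's base seed; identical seeds give bit-identical populations.
Dead cells are frozen. Division fires when cyclin B falls below 10% of a
super-threshold peak; volume, ribosomes, proteins and lesions halve (mRNA
splits binomially), gene copies are retained, and the cycle module resets
to G1. Events are detected on the window grid, not the save stride.

## The reduced network: choices that were genuinely open

* **Receptors.** Two exemplar classes: an EGFR-like class (ligand binding,
  dimerization, internalization with degradation-dominated trafficking —
  hence transient, ERK-biased signaling) and an InsR/IGF1R-like class
  (no down-regulation — sustained, AKT-biased). Doses in ng/mL or ug/mL
  are converted to nM with molecular weights carried as data on the
  stimulus object (EGF 6.2 kDa, insulin 5.808 kDa; 10 ug/mL insulin is
  1721 nM).
* **Raf–MEK sequestration.** MEK binds both inactive and active Raf;
  Ras-GTP activates only free Raf. MEK in excess therefore traps Raf in
  dead-end complexes, which is why MEK overexpression raises Raf:MEK
  complexes without raising time-averaged ppERK (tested).
* **ERK output is Raf-limited.** The MEK→ERK reaction is saturated in its
  ERK substrate, so ppERK tracks upstream (Raf) abundance rather than the
  very large ERK pool. This reproduces the observed contrast that
  initial Raf levels carry information about stochastic proliferation
  while total-ERK levels do not.
* **Cyclin D drive.** Transcription requires both arms multiplicatively
  (AP1 x cMyc AND gate: either kinase inhibitor abolishes cycling), with
  AP1's sharpness coming from cJun positive autoregulation and a weaker
  sustained cMyc term carrying the prolonged-AKT synergy of EGF+insulin.
* **Cell cycle.** The module runs in activity units, deterministically in
  every cell, and is not coupled to stochastic expression (coupling it
  deregulates the oscillator); cyclin D protein is the single expression-
  coupled input. Three mechanisms make the module robust rather than a
  smooth oscillator, each with a standard biological reading: a CycE→E2F
  positive feedback (the restriction point — commitment survives decay of
  a transient mitogen pulse), an autocatalytic CycB trigger (Cdc25-like
  positive feedback giving an all-or-none mitotic burst), and a
  post-mitotic/licensing G1 hold (cycle species pinned at the G1 reset for
  `g1_refractory_h` = 6 h after division and on re-entry from quiescence).
  Together these give a first division ~20 h after full stimulation.
* **Apoptosis.** Free activated Bax forms pores ultrasensitively; a
  thresholded C3a→C8 positive feedback produces the switch-like cPARP
  spike; death latches at cPARP > 50% of the PARP moiety (the spike is
  switch-like, so the exact fraction is not critical). BIM and PUMA (and,
  more weakly, NOXA) act as direct Bax activators as well as BCL2 ligands;
  BAD is a pure sensitizer. ERK phosphorylates BIM (faster degradation of
  the phospho-form), ERK and AKT phosphorylate BAD, and AKT exports FOXO
  from the nucleus, shutting down BIM transcription — the two "arms" whose
  knockouts the test suite compares (BIM dominance).
* **DNA damage.** Etoposide produces double-strand lesions in proportion
  to S-phase cyclin activity (no cycling, no damage), ATM/ATR activate
  with Hill coefficient 4, and p53 relaxes through a delayed MDM2 negative
  feedback whose parameterization was selected for a sustained limit cycle
  (period ~5.7 h, constant amplitude) robust across the ATM activity
  range. p53 induces PUMA/NOXA steeply (n = 4 relative to baseline p53),
  represses BCL2 synthesis, and induces p21. Induced p21 resists
  degradation above a threshold (an arrest latch), so damage-arrested
  cells stay arrested after p53 returns to baseline — this is what makes
  etoposide killing plateau rather than consume the whole population,
  and why p21 loss sensitizes.

## The synthetic-data generator

`mechcell.fixtures` emulates the model's data inputs so the whole pipeline
runs without downloads: three-replicate linear abundance tables with
mean-preserving log-normal replicate noise (CV 0.2 by default), half-life
and copy-number tables, the conglomerate map, and canned experiment
configurations at the standard doses (EGF 20 ng/mL, insulin 10 ug/mL,
MEKi/AKTi 10 uM, etoposide 100 uM, TRAIL 2–300 ng/mL). A single BULK row
absorbs the remainder of each whole-cell pool so that the ~48 modeled
genes land exactly on their anchored molecules-per-cell values after pool
normalization; the anchors include the reported copy numbers for the
ERK/MEK/AKT isoforms, the Raf isoforms, cMyc/cFos/cJun and BAD/BCL2.
Unanchored abundances and mRNA copy numbers are order-of-magnitude
choices for this cell type, fixed once; half-lives default to 9 h (mRNA)
and 46 h (protein) with shorter values for immediate-early genes.

What the generator does *not* emulate: sequencing-level artifacts (UMI
collisions, batch effects), genome-scale breadth (only the modeled genes
plus BULK), inter-replicate structure beyond independent log-normal noise,
and any real biological covariation between genes. Consequently, passing
tests demonstrate that the pipeline and the reduced network behave as
specified under these idealized inputs — not that the calibration would
transfer unchanged to real RNA-seq/proteomics tables.

## Fate-analysis pipeline

Predictors are conserved-moiety totals (the sum of a protein across all
modification states and complexes), at t = 0 or trapezoid-averaged over
8-h/40-h windows clipped to each cell's lifetime. Labels are death before
40 h (death experiments) or division within 30 h (proliferation; the
percent-proliferating readout itself uses cumulative S-phase entry by the
readout time minus the matched serum-starved control, clamped at zero).
Feature selection is L1 regression on z-scored predictors with seeded,
class-stratified 5-fold cross-validation; classification is a linear SVM
standardized by the training split, scored by held-out ROC/AUC (trapezoid
integration; verified to equal the Mann–Whitney rank statistic). The
degradation-rate sensitivity analysis draws Latin-hypercube normal samples
around each protein half-life in log10 space with sigma = log10(3.16) — a
half-decade, putting the bulk of draws within ~2–4-fold of the original
values (a linear-space option exists); each set is re-initialized (failing
sets are recorded as discarded) and simulated under the inhibitor
combination.

## Problem sizes and tolerances

Shipped defaults: 30-s exchange window with two RK4 substeps; trajectory
saving at 6-min stride (30-min in the long population experiments);
initialization tolerance 1%, LSODA at rtol 1e-6 / atol 1e-3. The test
suite uses populations of 30–40 cells for qualitative population
properties and the stated sizes (100 or 400 cells) for the headline
quantities; the acceptance script runs the full-size experiments.

## Known limitations

* Protein degradation is deterministic; fluctuations from low-abundance
  degradation machinery are not represented.
* Two receptor classes stand in for the nine RTK families; trafficking
  parameters are class-level, not receptor-specific.
* The cycle and damage modules use intrinsic synthesis in activity units;
  their genes are tailored but (except cyclin D) not expression-coupled.
* The division decision in the reduced model is dominated by
  transcription-factor burst noise during the induction window; initial
  Raf totals therefore carry the right *contrast* (predictive while total
  ERK and AKT sit at chance) but a weaker absolute signal than a
  full-scale model would give.
* Cells are independent — no paracrine or contact effects — and there is
  no checkpoint/restart or distributed execution.
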