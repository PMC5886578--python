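"""Hybrid stochastic gene-expression layer.

Gene switching (two-state telegraph promoter) and mRNA birth/death are
stochastic and advanced window-by-window with the *exact* transition
propagators of their continuous-time Markov chains, so the state sampled at
each window boundary has exactly the SSA law there:

* telegraph: each copy flips with the 2-state matrix-exponential
  probabilities over dt;
* mRNA (gene state frozen within the window): survivors are binomial with
  survival probability exp(-k_dm dt), births are Poisson with mean
  k_bm * g * (1 - exp(-k_dm dt)) / k_dm (the immigration-death propagator).

Protein dynamics are deterministic (dp/dt = theta * k_bp * m - k_dp * p,
scaled by ribosome availability), with a global translation multiplier
theta(free EIF4E) shared by all genes. Event-driven SSA implementations are
kept as independent oracles for tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ExpressionState",
    "TranslationControl",
    "telegraph_transition_probs",
    "step_gene_switching",
    "step_mrna",
    "translation_theta",
    "protein_rhs",
    "growth_rhs",
    "ssa_telegraph",
    "ssa_birth_death",
    "GrowthParams",
]

RIBOSOMES_REF = 6.0e6  # average-cell ribosome pool (molecules)


@dataclass
class TranslationControl:
    """Hill control of global translation by free EIF4E.

    theta = theta_max * E^n / (K^n + E^n); theta(0)=0, theta->theta_max.
    The engine rescales theta by its serum-starved basal value so tailored
    translation rates remain a fixed point at basal.
    """

    hill_k: float = 4.0e4  # molecules free EIF4E at half-max
    hill_n: float = 2.0
    theta_max: float = 2.0

    def theta(self, free_eif4e):
        return translation_theta(free_eif4e, self)


def translation_theta(free_eif4e, control: TranslationControl):
    """Evaluate the EIF4E translation multiplier (monotone, saturating)."""
    e = np.asarray(free_eif4e, dtype=float)
    if np.any(e < 0):
        raise ValueError("free EIF4E must be non-negative")
    en = e ** control.hill_n
    return control.theta_max * en / (control.hill_k ** control.hill_n + en)


@dataclass
class GrowthParams:
    """Ribosome synthesis / volume growth parameters.

    The ribosome pool relaxes toward rib_ref * (1 + gain * drive) with rate
    k_turnover; at full mitogenic drive (drive=1, gain=3,
    k_turnover=ln(1.5)/20) the pool doubles in ~20 h. Volume is slaved to
    ribosome content: V = rib / rib_ref.
    """

    rib_ref: float = RIBOSOMES_REF
    k_turnover: float = float(np.log(1.5) / 20.0)  # 1/h
    gain: float = 3.0


def growth_rhs(ribosomes, drive, params: GrowthParams | None = None):
    """d(ribosomes)/dt and d(volume)/dt for mitogenic drive in [0, 1]."""
    p = params or GrowthParams()
    target = p.rib_ref * (1.0 + p.gain * np.clip(drive, 0.0, 1.0))
    d_rib = p.k_turnover * (target - np.asarray(ribosomes, dtype=float))
    d_vol = d_rib / p.rib_ref
    return d_rib, d_vol


@dataclass
class ExpressionState:
    """Per-cell stochastic expression state (per-gene arrays).

    Arrays have shape (..., n_genes) where the leading axes index cells.
    """

    active_copies: np.ndarray  # int
    mrna: np.ndarray  # int
    protein: np.ndarray  # float, molecules
    free_eif4e: float | np.ndarray = 4.0e4
    ribosomes: float | np.ndarray = RIBOSOMES_REF
    volume: float | np.ndarray = 1.0

    def copy(self) -> "ExpressionState":
        return ExpressionState(self.active_copies.copy(), self.mrna.copy(),
                               self.protein.copy(), np.copy(self.free_eif4e),
                               np.copy(self.ribosomes), np.copy(self.volume))


def telegraph_transition_probs(k_gac: float, k_gin: float, dt: float):
    """Exact 2-state CTMC transition probabilities over dt.

    Returns (p_on_given_on, p_on_given_off)."""
    lam = k_gac + k_gin
    if lam == 0:
        return 1.0, 0.0
    pi_on = k_gac / lam
    decay = np.exp(-lam * dt)
    return pi_on + (1.0 - pi_on) * decay, pi_on * (1.0 - decay)


def step_gene_switching(active, g_total, k_gac, k_gin, dt: float,
                        rng: np.random.Generator):
    """Advance telegraph promoter copies by dt (exact propagator).

    Each of the g_total copies flips independently; the new active count is
    Binomial(active, P(on|on)) + Binomial(g_total - active, P(on|off)).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    active = np.asarray(active)
    g_total = np.asarray(g_total)
    # vectorized over per-gene rates
    lam = np.asarray(k_gac, dtype=float) + np.asarray(k_gin, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pi_on = np.where(lam > 0, np.asarray(k_gac, dtype=float) / np.where(lam > 0, lam, 1.0), 0.0)
    decay = np.exp(-lam * dt)
    p_on_on = pi_on + (1.0 - pi_on) * decay
    p_on_off = pi_on * (1.0 - decay)
    stay = rng.binomial(active, np.broadcast_to(p_on_on, active.shape))
    gain = rng.binomial(g_total - active, np.broadcast_to(p_on_off, active.shape))
    return stay + gain


def step_mrna(mrna, active, k_bm, k_dm, dt: float, rng: np.random.Generator,
              k_bm_scale=1.0):
    """Advance mRNA counts by dt with the gene state frozen (exact propagator).

    Survivors ~ Binomial(m, e^{-k_dm dt}); births ~ Poisson of the
    immigration-death window mean. ``k_bm_scale`` carries transcription-factor
    multipliers from the signaling layer.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    m = np.asarray(mrna)
    kd = np.asarray(k_dm, dtype=float)
    birth_rate = np.asarray(k_bm, dtype=float) * np.asarray(k_bm_scale, dtype=float) \
        * np.asarray(active, dtype=float)
    surv_p = np.exp(-kd * dt)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_births = np.where(kd > 0, birth_rate / np.where(kd > 0, kd, 1.0)
                               * (1.0 - surv_p), birth_rate * dt)
    survivors = rng.binomial(m, np.broadcast_to(surv_p, m.shape))
    births = rng.poisson(np.broadcast_to(mean_births, m.shape))
    return survivors + births


def protein_rhs(protein, mrna, k_bp, k_dp, theta=1.0, ribosome_factor=1.0):
    """Deterministic protein flux: dp/dt = theta * rib * k_bp * m - k_dp * p."""
    synth = np.asarray(theta, dtype=float) * np.asarray(ribosome_factor, dtype=float) \
        * np.asarray(k_bp, dtype=float) * np.asarray(mrna, dtype=float)
    return synth - np.asarray(k_dp, dtype=float) * np.asarray(protein, dtype=float)


# ---------------------------------------------------------------------------
# event-driven SSA oracles (reference implementations, used in tests)


def ssa_telegraph(active0: int, g_total: int, k_gac: float, k_gin: float,
                  t_end: float, rng: np.random.Generator) -> int:
    """Event-by-event simulation of g_total independent telegraph copies."""
    active = int(active0)
    t = 0.0
    while True:
        a_rate = k_gac * (g_total - active)
        i_rate = k_gin * active
        total = a_rate + i_rate
        if total == 0:
            return active
        t += rng.exponential(1.0 / total)
        if t > t_end:
            return active
        if rng.random() < a_rate / total:
            active += 1
        else:
            active -= 1


def ssa_birth_death(m0: int, birth_rate: float, k_dm: float, t_end: float,
                    rng: np.random.Generator) -> int:
    """Event-by-event simulation of constant-birth linear-death mRNA counts."""
    m = int(m0)
    t = 0.0
    while True:
        total = birth_rate + k_dm * m
        if total == 0:
            return m
        t += rng.exponential(1.0 / total)
        if t > t_end:
            return m
        if rng.random() < birth_rate / total:
            m += 1
        else:
            m -= 1
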