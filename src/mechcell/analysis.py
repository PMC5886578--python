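"""Stochastic-fate predictability pipeline.

Features are per-cell conserved-moiety totals (sum across all forms of a
protein), either at t=0 or trapezoid time-averaged over a window clipped to
the cell's lifetime. A lasso (L1) regression with 5-fold cross-validation
reduces the feature set; a standardized linear max-margin classifier (SVM)
is trained on half the cells and evaluated by ROC/AUC on a held-out half.
Also provides the per-protein correlation screen against time-to-death and
the Latin-hypercube sensitivity analysis over protein degradation rates.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LassoCV
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = ["FeatureMatrix", "FateReport", "build_features", "label_cells",
           "lasso_select", "train_and_roc", "roc_auc_trapezoid",
           "correlation_screen", "lhs_degradation_sensitivity"]

FEATURE_MODES = ("initial", "mean_8h", "mean_40h", "until_death")
_MODE_WINDOW = {"mean_8h": 8.0, "mean_40h": 40.0, "until_death": np.inf}


@dataclass
class FeatureMatrix:
    """Cells x moiety-total features with binary fate labels."""

    X: np.ndarray
    labels: np.ndarray      # bool
    feature_names: list[str]
    cell_ids: np.ndarray
    mode: str = "initial"

    def subset(self, names) -> "FeatureMatrix":
        idx = [self.feature_names.index(n) for n in names]
        return FeatureMatrix(self.X[:, idx], self.labels, list(names),
                             self.cell_ids, self.mode)


@dataclass
class FateReport:
    selected_features: list[str]
    classifier: str
    roc_fpr: list[float]
    roc_tpr: list[float]
    auc: float
    n_train: int
    n_valid: int
    feature_names: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)


def label_cells(recording, rule: str = "death_before_40h",
                threshold_h: float | None = None) -> np.ndarray:
    """Binary fate labels.

    'death_before_40h': death event before 40 h (early vs late death);
    'divided_30h': first division within the 30-h time course.
    """
    b = recording.batch
    if rule == "death_before_40h":
        thr = 40.0 if threshold_h is None else threshold_h
        return np.isfinite(b.death_time) & (b.death_time < thr)
    if rule == "divided_30h":
        thr = 30.0 if threshold_h is None else threshold_h
        first = np.array([d[0] if d else np.inf for d in b.division_times])
        return first <= thr
    raise ValueError(f"unknown label rule {rule!r}")


def build_features(recording, mode: str, labels: np.ndarray,
                   features: list[str] | None = None) -> FeatureMatrix:
    """Per-cell moiety-total features for the requested averaging mode.

    Time averages use the trapezoid rule over the saved grid restricted to
    [0, min(window, death time)]; a cell whose window contains fewer than
    two saved points is excluded with a warning.
    """
    if mode not in FEATURE_MODES:
        raise ValueError(f"unknown mode {mode!r}")
    names = features or list(recording.columns)
    cols = [recording.columns.index(n) for n in names]
    times = recording.times
    data = recording.data  # (n_save, n_cols, n_cells)
    b = recording.batch
    n = b.n_cells
    keep, rows = [], []
    for i in range(n):
        if b.failed[i]:
            continue
        if mode == "initial":
            rows.append(data[0, cols, i])
            keep.append(i)
            continue
        t_end = min(_MODE_WINDOW[mode],
                    b.death_time[i] if np.isfinite(b.death_time[i]) else np.inf,
                    times[-1])
        mask = times <= t_end + 1e-9
        if mask.sum() < 2:
            warnings.warn(f"cell {i}: averaging window too short; excluded")
            continue
        t = times[mask]
        avg = np.trapezoid(data[mask][:, cols, i], t, axis=0) / (t[-1] - t[0])
        rows.append(avg)
        keep.append(i)
    keep = np.array(keep, int)
    return FeatureMatrix(np.array(rows, float), np.asarray(labels)[keep],
                         names, keep, mode)


def lasso_select(features: FeatureMatrix, cv_folds: int = 5,
                 seed: int = 0) -> list[tuple[str, float]]:
    """L1-regularized selection of fate-predictive moiety totals.

    The binary label is regressed on z-scored predictors with the penalty
    chosen by stratified 5-fold CV; returns (name, coefficient) for nonzero
    coefficients sorted by |coefficient|.
    """
    y = features.labels.astype(float)
    if len(np.unique(y)) < 2:
        raise ValueError("labels are single-class; lasso selection undefined")
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need >= 2 cells per class")
    X = features.X
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (X - mu) / sd
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(Z, y))
    lasso = LassoCV(cv=folds, random_state=seed, max_iter=5000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lasso.fit(Z, y)
    coefs = lasso.coef_
    ranked = sorted(((features.feature_names[j], float(c))
                     for j, c in enumerate(coefs) if c != 0.0),
                    key=lambda t: -abs(t[1]))
    return ranked


def roc_auc_trapezoid(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by trapezoid integration over all score thresholds (tie-averaged)."""
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    return float(np.trapezoid(tpr, fpr))


def mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-statistic AUC (P(score_pos > score_neg), ties counted half)."""
    pos = scores[labels.astype(bool)]
    neg = scores[~labels.astype(bool)]
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[:len(pos)].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def train_and_roc(features: FeatureMatrix, train_n: int = 200,
                  valid_n: int = 200, seed: int = 0) -> FateReport:
    """Standardized linear SVM + held-out ROC/AUC.

    Cells are split train_n/valid_n at random (disjoint); predictors are
    z-scored with the training split's mean/SD; the classifier's continuous
    decision score on the held-out split yields the ROC curve and AUC.
    If a class is missing from the training split the split is resampled
    with a warning.
    """
    n = len(features.labels)
    if n < train_n + valid_n:
        raise ValueError(f"need >= {train_n + valid_n} labeled cells, have {n}")
    rng = np.random.default_rng(seed)
    for attempt in range(50):
        perm = rng.permutation(n)
        tr, va = perm[:train_n], perm[train_n:train_n + valid_n]
        if (len(np.unique(features.labels[tr])) == 2
                and len(np.unique(features.labels[va])) == 2):
            break
        warnings.warn("class missing from split; resampling")
    else:
        raise ValueError("could not build a two-class train/validation split")

    Xtr, ytr = features.X[tr], features.labels[tr].astype(int)
    Xva, yva = features.X[va], features.labels[va].astype(int)
    mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    clf = SVC(kernel="linear", C=1.0)
    clf.fit((Xtr - mu) / sd, ytr)
    scores = clf.decision_function((Xva - mu) / sd)
    fpr, tpr, _ = roc_curve(yva, scores, drop_intermediate=False)
    auc = roc_auc_trapezoid(scores, np.asarray(yva))
    return FateReport(selected_features=list(features.feature_names),
                      classifier="standardized linear max-margin (SVM)",
                      roc_fpr=list(map(float, fpr)),
                      roc_tpr=list(map(float, tpr)),
                      auc=auc, n_train=len(tr), n_valid=len(va),
                      feature_names=list(features.feature_names))


def correlation_screen(features: FeatureMatrix, time_to_death: np.ndarray,
                       n_perm: int = 200, seed: int = 0) -> pd.DataFrame:
    """Pearson correlation of each feature with time-to-death, with a
    permutation p-value (dead cells only)."""
    rng = np.random.default_rng(seed)
    ttd = np.asarray(time_to_death)[features.cell_ids]
    ok = np.isfinite(ttd)
    rows = []
    for j, name in enumerate(features.feature_names):
        x = features.X[ok, j]
        y = ttd[ok]
        if x.std() == 0 or len(x) < 3:
            rows.append((name, np.nan, np.nan))
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        null = np.array([np.corrcoef(x, rng.permutation(y))[0, 1]
                         for _ in range(n_perm)])
        pval = float((np.sum(np.abs(null) >= abs(r)) + 1) / (n_perm + 1))
        rows.append((name, r, pval))
    return pd.DataFrame(rows, columns=["feature", "pearson_r", "perm_p"])


def lhs_degradation_sensitivity(model, n_sets: int, sd: float = 3.16,
                                seed: int = 0, n_cells: int = 25,
                                readouts=(24.0, 48.0, 72.0),
                                log_space: bool = True,
                                duration_h: float = 72.0) -> pd.DataFrame:
    """Latin-hypercube sensitivity of inhibitor-induced death to protein
    degradation rates.

    Each protein half-life is perturbed by an LHS-normal draw centered on
    the original value; sd=3.16 in log10 space corresponds to the typical
    ~2-4-fold bulk spread (a linear-space option is provided). Each set is
    re-initialized (failing sets are recorded as discarded) and simulated
    under EGF+insulin+MEKi+AKTi; death percentages at the readouts and the
    across-set dispersion summary are returned.
    """
    from scipy.stats import norm, qmc
    from .simulate import ExperimentConfig, StimulusSpec

    if n_sets < 2:
        raise ValueError("n_sets must be >= 2")
    genes = list(model.records)
    sampler = qmc.LatinHypercube(d=len(genes), seed=seed)
    u = sampler.random(n_sets)
    z = norm.ppf(u)
    base = np.array([model.records[g].t_half_protein for g in genes])
    if log_space:
        sigma = np.log10(sd)
        t_half = base[None, :] * 10.0 ** (sigma * z)
    else:
        t_half = np.maximum(base[None, :] + sd * z, 1e-3)

    rows = []
    for k in range(n_sets):
        records = {}
        for j, g in enumerate(genes):
            r = model.records[g]
            records[g] = dataclasses.replace(r, t_half_protein=float(t_half[k, j]),
                                             k_bm=float("nan"), k_bp=float("nan"))
        from .omics import compute_rate_constants
        records = {g: compute_rate_constants(r) for g, r in records.items()}
        variant = type(model)(records, model.params)
        try:
            res = variant.fit(max_iter=20, probe=False)
        except Exception:
            rows.append({"set": k, "status": "discarded",
                         **{f"death_{int(t)}h": np.nan for t in readouts}})
            continue
        if not res.report.converged and res.report.max_rel_error > 0.10:
            rows.append({"set": k, "status": "discarded",
                         **{f"death_{int(t)}h": np.nan for t in readouts}})
            continue
        cfg = ExperimentConfig(
            population_size=n_cells, base_seed=seed + 7919 * k,
            stimulus=StimulusSpec(egf_ng_ml=20.0, insulin_ug_ml=10.0,
                                  meki_um=10.0, akti_um=10.0),
            duration_h=duration_h, readout_times=tuple(readouts))
        _, summary = res.simulate(cfg)
        rows.append({"set": k, "status": "ok",
                     **{f"death_{int(t)}h": summary.percent_dead[i]
                        for i, t in enumerate(readouts)}})
    out = pd.DataFrame(rows)
    if (out["status"] == "ok").sum() == 0:
        raise RuntimeError("all parameter sets failed initialization")
    return out
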