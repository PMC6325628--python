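"""Assay-discrimination layer: correlation-based feature selection and
repeated cross-validated SVM-RBF performance reporting.

The classifier report is the machine twin of a performance-table row:
retained-feature count, AUC mean ± std over repeated stratified 5-fold
partitions, and accuracy / sensitivity / specificity in percent.  The
(C, gamma) hyperparameter grid defaults to 21 log-spaced C values in
[1e-5, 1e5] and 10 log-spaced gamma values in [1e-3, 10]; the grid point is
chosen by an inner 3-fold cross-validated AUC inside each training split so
the held-out fold never informs model selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

DEFAULT_C_GRID = np.logspace(-5, 5, 21)
DEFAULT_GAMMA_GRID = np.logspace(-3, 1, 10)


# ---------------------------------------------------------------------------
# feature selection

def select_features_by_correlation(table: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Iteratively drop one member of the most-correlated feature pair until
    every pairwise |Pearson r| is below `threshold`.

    The dropped member is the one with the larger mean |r| against all
    remaining features; ties resolve to the later column.  Constant features
    count as |r| = 0 against everything (with a warning).  Column order of
    the survivors is preserved.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    cols = list(table.columns)
    if len(cols) < 2:
        return table.copy()
    X = table.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("feature table contains NaNs")
    sd = X.std(axis=0)
    if (sd == 0).any():
        logger.warning("constant feature(s) %s treated as uncorrelated",
                       [c for c, s in zip(cols, sd) if s == 0])
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.nan_to_num(np.abs(corr), nan=0.0)
    np.fill_diagonal(corr, 0.0)

    alive = list(range(len(cols)))
    while len(alive) > 1:
        sub = corr[np.ix_(alive, alive)]
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[i, j] < threshold:
            break
        mean_i = sub[i].sum() / (len(alive) - 1)
        mean_j = sub[j].sum() / (len(alive) - 1)
        # drop the more globally redundant member; tie -> later column
        drop = j if mean_j >= mean_i else i
        del alive[drop]
    return table.iloc[:, alive].copy()


# ---------------------------------------------------------------------------
# SVM-RBF repeated cross-validation

@dataclass
class ClassifierReport:
    comparison: str
    features_after_selection: int
    auc_mean: float
    auc_std: float
    accuracy: float      # percent
    sensitivity: float   # percent, true-positive rate of the positive class
    specificity: float   # percent
    folds: int
    repeats: int
    seed: int
    c_grid: np.ndarray = field(repr=False, default=None)
    gamma_grid: np.ndarray = field(repr=False, default=None)
    auc_per_repeat: np.ndarray = field(repr=False, default=None)


def _zscore_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return mu, sd


def _select_grid_point(
    X: np.ndarray, y: np.ndarray, c_grid, gamma_grid, inner_folds: int, rs: int
) -> tuple[float, float]:
    """Inner-CV AUC over the grid; ties resolve to the first grid point."""
    if len(c_grid) == 1 and len(gamma_grid) == 1:
        return float(c_grid[0]), float(gamma_grid[0])
    n_splits = min(inner_folds, int(np.bincount(y).min()))
    n_splits = max(n_splits, 2)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=rs)
    splits = list(skf.split(X, y))
    best_auc, best = -np.inf, (float(c_grid[0]), float(gamma_grid[0]))
    for C in c_grid:
        for gamma in gamma_grid:
            scores, truths = [], []
            for tr, te in splits:
                mu, sd = _zscore_fit(X[tr])
                clf = SVC(C=C, gamma=gamma, kernel="rbf")
                clf.fit((X[tr] - mu) / sd, y[tr])
                scores.append(clf.decision_function((X[te] - mu) / sd))
                truths.append(y[te])
            auc = roc_auc_score(np.concatenate(truths), np.concatenate(scores))
            if auc > best_auc:
                best_auc, best = auc, (float(C), float(gamma))
    return best


def evaluate_classifier(
    table: pd.DataFrame,
    labels,
    positive: str,
    folds: int = 5,
    repeats: int = 200,
    c_grid=None,
    gamma_grid=None,
    seed: int = 0,
    inner_folds: int = 3,
    comparison: str | None = None,
) -> ClassifierReport:
    """Repeated stratified k-fold SVM-RBF evaluation.

    Per repeat: a fresh stratified partition; per training split: features
    z-scored on the training data, the (C, gamma) grid point picked by inner
    cross-validated AUC, the model refit and scored on the held-out fold.
    The per-repeat AUC pools all held-out decision values; the report gives
    its mean ± std over repeats, and accuracy / sensitivity / specificity
    from the pooled hard predictions.  Deterministic under `seed`.
    """
    X = table.to_numpy(dtype=float)
    y_raw = np.asarray(labels)
    classes = np.unique(y_raw)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes.tolist()}")
    if positive not in classes:
        raise ValueError(f"positive class {positive!r} not among {classes.tolist()}")
    y = (y_raw == positive).astype(int)
    if np.bincount(y).min() < folds:
        raise ValueError("each class needs at least `folds` members")
    c_grid = np.atleast_1d(DEFAULT_C_GRID if c_grid is None else np.asarray(c_grid, dtype=float))
    gamma_grid = np.atleast_1d(DEFAULT_GAMMA_GRID if gamma_grid is None else np.asarray(gamma_grid, dtype=float))

    rng = np.random.default_rng(seed)
    aucs = np.empty(repeats)
    accs = np.empty(repeats)
    sens = np.empty(repeats)
    spec = np.empty(repeats)
    for rep in range(repeats):
        rs = int(rng.integers(0, 2**31 - 1))
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rs)
        scores = np.empty(len(y))
        preds = np.empty(len(y), dtype=int)
        for tr, te in skf.split(X, y):
            C, gamma = _select_grid_point(X[tr], y[tr], c_grid, gamma_grid, inner_folds, rs)
            mu, sd = _zscore_fit(X[tr])
            clf = SVC(C=C, gamma=gamma, kernel="rbf")
            clf.fit((X[tr] - mu) / sd, y[tr])
            Z = (X[te] - mu) / sd
            scores[te] = clf.decision_function(Z)
            preds[te] = clf.predict(Z)
        aucs[rep] = roc_auc_score(y, scores)
        accs[rep] = (preds == y).mean()
        sens[rep] = (preds[y == 1] == 1).mean()
        spec[rep] = (preds[y == 0] == 0).mean()
    return ClassifierReport(
        comparison=comparison or f"{positive} vs rest",
        features_after_selection=X.shape[1],
        auc_mean=float(aucs.mean()),
        auc_std=float(aucs.std()),
        accuracy=float(100.0 * accs.mean()),
        sensitivity=float(100.0 * sens.mean()),
        specificity=float(100.0 * spec.mean()),
        folds=folds,
        repeats=repeats,
        seed=seed,
        c_grid=c_grid,
        gamma_grid=gamma_grid,
        auc_per_repeat=aucs,
    )


def choose_selection_threshold(
    table: pd.DataFrame,
    labels,
    positive: str,
    candidate_thresholds=(0.75, 0.8, 0.85, 0.9),
    **eval_kwargs,
) -> tuple[float, dict[float, ClassifierReport]]:
    """Pick the correlation-selection threshold maximising mean AUC.

    Runs selection + evaluation per candidate; ties resolve to the smaller
    threshold.  Returns the winner and the full per-candidate report map.
    """
    candidates = sorted(candidate_thresholds)
    if not candidates:
        raise ValueError("need at least one candidate threshold")
    reports: dict[float, ClassifierReport] = {}
    for thr in candidates:
        selected = select_features_by_correlation(table, thr)
        reports[thr] = evaluate_classifier(selected, labels, positive, **eval_kwargs)
    best = max(candidates, key=lambda t: (reports[t].auc_mean, -t))
    return best, reports
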