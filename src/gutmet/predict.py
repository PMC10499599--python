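"""IR prediction benchmarking: mRMR feature selection, random-forest AUC over
feature counts, and explained variance of cytokines.

mRMR is the classic greedy scheme: the first feature maximises relevance to
the label, each subsequent feature maximises relevance minus mean redundancy
with the already-selected set.  Relevance and redundancy use the Gaussian
mutual-information surrogate MI = -0.5*ln(1 - rho^2) with Spearman rho, so
the selection is invariant to strictly monotone feature transforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, train_test_split

__all__ = [
    "PredictionParams",
    "mrmr_select",
    "rf_auc",
    "auc_over_k",
    "explained_variance",
]


@dataclass(frozen=True)
class PredictionParams:
    k_grid: tuple = tuple(range(5, 55, 5))
    test_fraction_classif: float = 0.25  # 3:1 train:test
    test_fraction_regress: float = 0.20  # 4:1 train:test
    cv_folds: int = 10
    n_trees: int = 500
    n_repeats: int = 20
    tune_mtry: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


def _mi_surrogate(x: np.ndarray, y: np.ndarray) -> float:
    rho = stats.spearmanr(x, y).statistic
    if not np.isfinite(rho):
        return 0.0
    rho = min(abs(rho), 0.999999)
    return -0.5 * np.log(1.0 - rho**2)


def mrmr_select(X: pd.DataFrame, y, k: int) -> list:
    """Greedy minimum-redundancy maximum-relevance selection of k features.

    Expects features already square-root transformed where the analysis
    convention requires it.  Constant features have zero relevance and are
    never picked before informative ones.
    """
    if k > X.shape[1]:
        warnings.warn("k exceeds feature count; clipping", stacklevel=2)
        k = X.shape[1]
    y = np.asarray(y, dtype=float)
    cols = list(X.columns)
    relevance = {c: _mi_surrogate(X[c].to_numpy(), y) for c in cols}
    selected = [max(cols, key=lambda c: (relevance[c], -cols.index(c)))]
    red_cache: dict[tuple, float] = {}

    def redundancy(c: str, s: str) -> float:
        key = (c, s) if c < s else (s, c)
        if key not in red_cache:
            red_cache[key] = _mi_surrogate(X[c].to_numpy(), X[s].to_numpy())
        return red_cache[key]

    while len(selected) < k:
        best, best_score = None, -np.inf
        for c in cols:
            if c in selected:
                continue
            score = relevance[c] - np.mean([redundancy(c, s) for s in selected])
            if score > best_score + 1e-15:
                best, best_score = c, score
        selected.append(best)
    return selected


def _forest(params: PredictionParams, seed: int, n_features: int) -> RandomForestClassifier:
    return RandomForestClassifier(n_estimators=params.n_trees, random_state=seed)


def rf_auc(X: pd.DataFrame, y, params: PredictionParams = PredictionParams()) -> list:
    """Held-out AUCs of random-forest classifiers over repeated stratified splits.

    Each repeat draws a stratified 3:1 train/test split, optionally tunes the
    per-split feature count by cross-validation on the training set, fits the
    forest, scores the test samples and computes AUC by the rank
    (Mann-Whitney) formulation.
    """
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) != 2:
        raise ValueError("rf_auc requires a binary label")
    aucs = []
    p = X.shape[1]
    for r in range(params.n_repeats):
        seed = params.seed + 1000 * r
        Xtr, Xte, ytr, yte = train_test_split(
            X, y, test_size=params.test_fraction_classif, stratify=y, random_state=seed
        )
        clf = RandomForestClassifier(n_estimators=params.n_trees, random_state=seed)
        if params.tune_mtry and p > 2:
            grid = sorted({max(1, int(np.sqrt(p) / 2)), max(1, int(np.sqrt(p))),
                           max(1, min(p, int(2 * np.sqrt(p))))})
            folds = min(params.cv_folds, int(np.bincount(ytr).min()))
            if folds >= 2:
                search = GridSearchCV(clf, {"max_features": grid}, cv=folds, scoring="roc_auc")
                search.fit(Xtr, ytr)
                clf = search.best_estimator_
            else:
                clf.fit(Xtr, ytr)
        else:
            clf.fit(Xtr, ytr)
        scores = clf.predict_proba(Xte)[:, 1]
        aucs.append(float(roc_auc_score(yte, scores)))
    return aucs


def auc_over_k(datasets: dict, y, params: PredictionParams = PredictionParams(),
               sqrt_transform: bool = True) -> pd.DataFrame:
    """AUC distributions per omics layer and feature count.

    ``datasets`` maps layer name to a sample-aligned DataFrame.  For each
    layer and each k in ``k_grid``, features are selected by mRMR on the
    square-root-transformed data and forests are fit/scored ``n_repeats``
    times.  Returns a long-format frame (layer, k, repeat, auc).
    """
    rows = []
    for layer, df in datasets.items():
        Xs = np.sqrt(df.clip(lower=0)) if sqrt_transform else df
        for k in params.k_grid:
            if k > df.shape[1]:
                warnings.warn(f"{layer}: k={k} exceeds {df.shape[1]} features; clipped",
                              stacklevel=2)
            feats = mrmr_select(Xs, y, min(k, df.shape[1]))
            aucs = rf_auc(df.loc[:, feats], y, params)
            rows.extend((layer, k, r, a) for r, a in enumerate(aucs))
    return pd.DataFrame(rows, columns=["layer", "k", "repeat", "auc"])


def explained_variance(X: pd.DataFrame, y_cytokine,
                       params: PredictionParams = PredictionParams()) -> float:
    """Held-out R^2 of a random-forest regression, clipped at zero.

    The target should be log10-transformed and scaled upstream.  R^2 follows
    the definition 1 - sum((test - pred)^2) / sum((test - mean(test))^2) on
    the held-out split; negative values are reported as 0.
    """
    y = np.asarray(y_cytokine, dtype=float)
    Xtr, Xte, ytr, yte = train_test_split(
        X, y, test_size=params.test_fraction_regress, random_state=params.seed
    )
    if np.var(yte) == 0:
        warnings.warn("zero-variance test targets: R^2 undefined", stacklevel=2)
        return float("nan")
    reg = RandomForestRegressor(n_estimators=params.n_trees, random_state=params.seed)
    if params.tune_mtry and X.shape[1] > 2:
        p = X.shape[1]
        grid = sorted({max(1, p // 3), max(1, int(np.sqrt(p))), p})
        search = GridSearchCV(reg, {"max_features": grid}, cv=min(params.cv_folds, len(ytr)))
        search.fit(Xtr, ytr)
        reg = search.best_estimator_
    else:
        reg.fit(Xtr, ytr)
    pred = reg.predict(Xte)
    r2 = r_squared(yte, pred)
    return max(0.0, r2)


def r_squared(test: np.ndarray, pred: np.ndarray) -> float:
    """R^2 = 1 - sum((test - pred)^2) / sum((test - mean(test))^2)."""
    test = np.asarray(test, dtype=float)
    pred = np.asarray(pred, dtype=float)
    denom = np.sum((test - test.mean()) ** 2)
    if denom == 0:
        return float("nan")
    return float(1.0 - np.sum((test - pred) ** 2) / denom)
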