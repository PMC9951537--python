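"""Random-forest learners with grid-search fivefold CV, and performance metrics.

Model selection follows the study protocol: the classifier is selected by mean
cross-validated accuracy (maximized), the regressors by mean cross-validated
RMSE (minimized), over an explicit hyperparameter grid with fivefold CV. For
the classifier, SMOTE oversampling is applied inside each training fold only —
never before splitting — so validation folds contain no synthetic points.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold

from .dataset import LabeledDataset
from .resampling import SmoteConfig, balance_training_fold

#: Conventional RF search ranges; fully exposed so callers can shrink or grow.
DEFAULT_CLASSIFIER_GRID = {
    "n_estimators": [100, 300, 500],
    "max_depth": [None, 16, 32],
    "max_features": ["sqrt", 0.3],
}
DEFAULT_REGRESSOR_GRID = dict(DEFAULT_CLASSIFIER_GRID)


@dataclass(frozen=True)
class HyperGrid:
    """Named candidate lists; the Cartesian product is searched in declared order."""

    params: dict

    def __post_init__(self):
        if not self.params or any(len(v) == 0 for v in self.params.values()):
            raise ValueError("grid must be non-empty with non-empty candidate lists")

    def candidates(self):
        keys = list(self.params)
        for combo in itertools.product(*(self.params[k] for k in keys)):
            yield dict(zip(keys, combo))


@dataclass(frozen=True)
class ClassifierMetrics:
    acc: float
    auroc: Optional[float]
    mcc: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    confusion: tuple  # (TP, FP, TN, FN)
    undefined: tuple = ()  # names of metrics undefined on this input


@dataclass(frozen=True)
class RegressorMetrics:
    rmse: float
    r2: Optional[float]
    n: int
    undefined: tuple = ()


def make_model(task: str, params: dict, seed: int):
    cls = {"classification": RandomForestClassifier, "regression": RandomForestRegressor}[task]
    return cls(random_state=int(seed) % (2**31), n_jobs=1, **params)


def grid_search_cv(dataset: LabeledDataset, grid: HyperGrid, task: str, folds: int = 5,
                   smote: SmoteConfig | None = None, seed: int = 0):
    """Exhaustive grid search with fivefold CV; returns (best_params, best_score).

    Classification: stratified folds, score = mean fold accuracy (higher wins);
    regression: shuffled unstratified folds, score = mean fold RMSE on log10
    LD50 (lower wins). Ties go to the earlier candidate in grid order. Fully
    deterministic given ``seed``.
    """
    if task not in ("classification", "regression"):
        raise ValueError(f"unknown task {task!r}")
    rng = np.random.default_rng(seed)
    cv_seed = int(rng.integers(2**31))
    model_seed = int(rng.integers(2**31))
    if task == "classification":
        n_neg, n_pos = dataset.class_counts
        if min(n_neg, n_pos) < folds:
            raise ValueError(f"each class needs >= {folds} members for {folds}-fold CV")
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=cv_seed)
        split_iter = list(splitter.split(dataset.X, dataset.y_label))
    else:
        if len(dataset) < folds:
            raise ValueError(f"need >= {folds} rows for {folds}-fold CV")
        splitter = KFold(n_splits=folds, shuffle=True, random_state=cv_seed)
        split_iter = list(splitter.split(dataset.X))

    best_params, best_score = None, None
    for params in grid.candidates():
        fold_scores = []
        for fold_i, (tr, va) in enumerate(split_iter):
            train = dataset.subset(tr)
            if task == "classification" and smote is not None:
                fold_cfg = SmoteConfig(smote.k_neighbors, smote.target_ratio,
                                       seed=(smote.seed * folds + fold_i) % (2**31))
                train = balance_training_fold(train, fold_cfg)
            model = make_model(task, params, model_seed)
            if task == "classification":
                model.fit(train.X, train.y_label)
                fold_scores.append(float(np.mean(model.predict(dataset.X[va]) == dataset.y_label[va])))
            else:
                model.fit(train.X, train.y_log)
                resid = model.predict(dataset.X[va]) - dataset.y_log[va]
                fold_scores.append(float(np.sqrt(np.mean(resid**2))))
        score = float(np.mean(fold_scores))
        better = (
            best_score is None
            or (task == "classification" and score > best_score)
            or (task == "regression" and score < best_score)
        )
        if better:
            best_params, best_score = params, score
    return best_params, best_score


def compute_classifier_metrics(scores, labels, threshold: float = 0.5) -> ClassifierMetrics:
    """ACC/AUROC/MCC/PPV/NPV and the confusion counts at a score threshold.

    AUROC is rank-based concordance (ties count 1/2); MCC uses the standard
    confusion-matrix formula and is 0 when any marginal is zero. On a
    single-class label vector AUROC and MCC are reported as undefined (None)
    with an explicit flag rather than raising.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    n = tp + fp + tn + fn
    acc = (tp + tn) / n
    undefined = []

    if len(np.unique(labels)) < 2:
        auroc = None
        mcc = None
        undefined += ["auroc", "mcc"]
    else:
        auroc = float(roc_auc_score(labels, scores))
        num = tp * tn - fp * fn
        den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        mcc = float(num / np.sqrt(den)) if den > 0 else 0.0
    ppv = tp / (tp + fp) if (tp + fp) > 0 else None
    npv = tn / (tn + fn) if (tn + fn) > 0 else None
    if ppv is None:
        undefined.append("ppv")
    if npv is None:
        undefined.append("npv")
    return ClassifierMetrics(acc=float(acc), auroc=auroc, mcc=mcc, ppv=ppv, npv=npv,
                             confusion=(tp, fp, tn, fn), undefined=tuple(undefined))


def compute_regressor_metrics(pred, truth) -> RegressorMetrics:
    """RMSE and R^2 (1 - SSres/SStot); R^2 flagged undefined on constant truth."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape or pred.size == 0:
        raise ValueError("pred and truth must be equal-length, non-empty")
    rmse = float(np.sqrt(np.mean((pred - truth) ** 2)))
    ss_tot = float(np.sum((truth - truth.mean()) ** 2))
    if ss_tot == 0:
        return RegressorMetrics(rmse=rmse, r2=None, n=pred.size, undefined=("r2",))
    r2 = 1.0 - float(np.sum((pred - truth) ** 2)) / ss_tot
    return RegressorMetrics(rmse=rmse, r2=r2, n=pred.size)


def rank_correlations(pred, truth) -> tuple:
    """(Pearson r, Spearman r on mid-ranks); (None, None) on constant input."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.size < 3 or pred.shape != truth.shape:
        raise ValueError("need >= 3 aligned values")
    if np.ptp(pred) == 0 or np.ptp(truth) == 0:
        return None, None
    return float(stats.pearsonr(pred, truth).statistic), float(stats.spearmanr(pred, truth).statistic)
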