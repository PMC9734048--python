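"""Importance-ranked predictive models from region-wise flexibility.

Two tasks mirror the analysis design: classification (patient vs control
from node flexibilities) and regression (symptom severity).  A gradient-
boosted tree ensemble is fit once on the full training cohort to rank
features by their share of total split gain; the top-N feature prefixes
(N = 1..R) are then evaluated with repeated stratified (classification) or
plain (regression) k-fold cross-validation, and the prefix with the best
mean metric is selected.  A held-out cohort provides the independent test.

The default recipe computes the ranking on all training rows before
cross-validating the prefix curve.  This is the simple, literal protocol; it
lets the ranking see all training labels, so the CV curve is optimistically
biased (see the README).  A nested variant that re-ranks inside every
training fold is available via ``nested=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold
from xgboost import XGBClassifier, XGBRegressor

from .errors import ConfigurationError, DegenerateModelError
from .synthetic import GROUP_ADHD, MED_TREATED

__all__ = [
    "DEFAULT_XGB_PARAMS",
    "FeatureSelectionResult",
    "rank_importance",
    "top_n_search",
    "evaluate_model",
    "prepare_cohort_features",
]

#: Fixed, seeded ensemble settings used everywhere unless overridden.
DEFAULT_XGB_PARAMS = {
    "n_estimators": 100,
    "max_depth": 3,
    "learning_rate": 0.3,
    "subsample": 1.0,
    "colsample_bytree": 1.0,
    "tree_method": "hist",
    "n_jobs": 1,
    "verbosity": 0,
}


@dataclass
class FeatureSelectionResult:
    """Ranking, top-N performance curve and metrics of one search."""

    ranking: list[str]
    scores: np.ndarray
    candidate_ns: np.ndarray
    curve: np.ndarray
    best_n: int
    selected: list[str]
    cv_metrics: dict
    test_metrics: dict | None = None
    task: str = "classify"
    seed: int = 0
    nested: bool = False
    params: dict = field(default_factory=dict)


def _make_model(task: str, seed: int, params: dict | None):
    merged = dict(DEFAULT_XGB_PARAMS)
    if params:
        merged.update(params)
    if task == "classify":
        return XGBClassifier(random_state=seed, **merged)
    if task == "regress":
        return XGBRegressor(random_state=seed, **merged)
    raise ConfigurationError(f"unknown task {task!r}")


def _validate_xy(x: pd.DataFrame, y: np.ndarray, task: str) -> None:
    if x.isna().any().any() or not np.all(np.isfinite(y)):
        raise ValueError("missing values in features or target")
    if task == "classify":
        if np.unique(y).size < 2:
            raise DegenerateModelError("classification needs at least 2 classes")
    elif np.unique(y).size < 2:
        raise DegenerateModelError("regression target is constant")


def rank_importance(
    x: pd.DataFrame,
    y,
    task: str = "classify",
    seed: int = 0,
    params: dict | None = None,
) -> tuple[list[str], np.ndarray]:
    """Rank features by normalized total split-gain importance.

    One ensemble is fit on all provided rows; the importance of a feature is
    its share of the total split gain (nonnegative, summing to 1).  Features
    never used in a split score 0.  Ties, including all-zero scores, are
    broken by column order, so the result is deterministic given ``seed``.
    """
    x = pd.DataFrame(x)
    y = np.asarray(y)
    _validate_xy(x, y, task)
    model = _make_model(task, seed, params)
    model.fit(x.to_numpy(), y)
    booster = model.get_booster()
    gain = booster.get_score(importance_type="total_gain")
    scores = np.array(
        [gain.get(f"f{j}", 0.0) for j in range(x.shape[1])], dtype=float
    )
    total = scores.sum()
    if total > 0:
        scores = scores / total
    order = np.argsort(-scores, kind="stable")
    return [x.columns[j] for j in order], scores[order]


def _cv_splits(y, task, n_folds, rep_seed):
    if task == "classify":
        counts = np.bincount(y.astype(int))
        if counts[counts > 0].min() < n_folds:
            raise ConfigurationError(
                f"smallest class has {counts[counts > 0].min()} members, fewer "
                f"than n_folds={n_folds}; reduce n_folds or add subjects"
            )
        cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=rep_seed)
    else:
        cv = KFold(n_splits=n_folds, shuffle=True, random_state=rep_seed)
    return cv


def _pooled_cv_predictions(x, y, task, n_folds, rep_seed, model_seed, params, ranking=None, n_top=None):
    """Out-of-fold predictions pooled over one k-fold split.

    With ``ranking``/``n_top``, feature selection is redone *inside* each
    training fold (nested variant): ``ranking`` is ignored and recomputed.
    """
    cv = _cv_splits(y, task, n_folds, rep_seed)
    pred = np.empty(y.size)
    score = np.empty(y.size)  # decision scores for AUC (classification)
    for train, test in cv.split(x, y if task == "classify" else None):
        xtr, xte = x.iloc[train], x.iloc[test]
        if n_top is not None:
            if ranking is None:  # nested: rank within the fold
                fold_rank, _ = rank_importance(xtr, y[train], task, model_seed, params)
            else:
                fold_rank = ranking
            cols = fold_rank[:n_top]
            xtr, xte = xtr[cols], xte[cols]
        model = _make_model(task, model_seed, params)
        model.fit(xtr.to_numpy(), y[train])
        if task == "classify":
            pred[test] = model.predict(xte.to_numpy())
            score[test] = model.predict_proba(xte.to_numpy())[:, 1]
        else:
            pred[test] = model.predict(xte.to_numpy())
            score[test] = pred[test]
    return pred, score


def _r2(y_true, y_pred) -> float:
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    ss_tot = float(np.sum((y_true - np.mean(y_true)) ** 2))
    return 1.0 - ss_res / ss_tot


def _classification_metrics(y_true, y_pred, y_score) -> dict:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    out = {
        "accuracy": (tp + tn) / y_true.size,
        "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
        "specificity": tn / (tn + fp) if tn + fp else np.nan,
    }
    out["auc"] = float(roc_auc_score(y_true, y_score))
    return out


def top_n_search(
    x: pd.DataFrame,
    y,
    task: str = "classify",
    n_folds: int = 10,
    n_repeats: int = 10,
    seed: int = 0,
    candidate_ns=None,
    params: dict | None = None,
    nested: bool = False,
    ranking: list[str] | None = None,
) -> FeatureSelectionResult:
    """Choose the best top-N feature prefix by repeated k-fold CV.

    For each candidate N the top-N ranked features are evaluated with
    ``n_repeats`` independent k-fold CVs; the curve records the mean metric
    (pooled accuracy for classification, pooled R^2 for regression) and
    ``best_n`` is the smallest N attaining the maximum.  Full classification
    metrics (accuracy, sensitivity, specificity, AUC with ADHD as the
    positive class) or R^2 are then reported at ``best_n``.
    """
    x = pd.DataFrame(x)
    y = np.asarray(y).astype(float if task == "regress" else int)
    _validate_xy(x, y, task)
    if y.size < n_folds:
        raise ConfigurationError("need at least n_folds subjects")
    scores = None
    if ranking is None and not nested:
        ranking, scores = rank_importance(x, y, task, seed, params)
    elif ranking is not None:
        missing = set(x.columns) - set(ranking)
        if missing:
            raise ConfigurationError(f"ranking does not cover features: {missing}")
        scores = np.full(len(ranking), np.nan)
    if candidate_ns is None:
        candidate_ns = np.arange(1, x.shape[1] + 1)
    candidate_ns = np.asarray(candidate_ns, dtype=int)
    rep_seeds = np.random.SeedSequence(seed).generate_state(n_repeats, np.uint32)
    rep_seeds = (rep_seeds % (2**31 - 1)).astype(int)

    curve = np.empty(candidate_ns.size)
    for idx, n_top in enumerate(candidate_ns):
        rep_metric = np.empty(n_repeats)
        for rep in range(n_repeats):
            pred, score = _pooled_cv_predictions(
                x, y, task, n_folds, rep_seeds[rep], seed, params,
                ranking=None if nested else ranking, n_top=int(n_top),
            )
            if task == "classify":
                rep_metric[rep] = float(np.mean(pred == y))
            else:
                rep_metric[rep] = _r2(y, pred)
        curve[idx] = rep_metric.mean()
    best_idx = int(np.argmax(curve))  # argmax takes the first (smallest N) tie
    best_n = int(candidate_ns[best_idx])

    # full metric set at the selected prefix, averaged over repeats
    per_rep = []
    for rep in range(n_repeats):
        pred, score = _pooled_cv_predictions(
            x, y, task, n_folds, rep_seeds[rep], seed, params,
            ranking=None if nested else ranking, n_top=best_n,
        )
        if task == "classify":
            per_rep.append(_classification_metrics(y, pred, score))
        else:
            per_rep.append({"r2": _r2(y, pred)})
    cv_metrics = {
        k: float(np.mean([m[k] for m in per_rep])) for k in per_rep[0]
    }
    if nested:
        ranking, scores = rank_importance(x, y, task, seed, params)
    return FeatureSelectionResult(
        ranking=list(ranking),
        scores=np.asarray(scores, dtype=float),
        candidate_ns=candidate_ns,
        curve=curve,
        best_n=best_n,
        selected=list(ranking[:best_n]),
        cv_metrics=cv_metrics,
        task=task,
        seed=seed,
        nested=nested,
        params=dict(params or {}),
    )


def evaluate_model(
    selected: list[str],
    x_train: pd.DataFrame,
    y_train,
    x_test: pd.DataFrame,
    y_test,
    task: str = "classify",
    seed: int = 0,
    params: dict | None = None,
) -> dict:
    """Fit on the training cohort only and score the independent test set.

    Classification reports accuracy, sensitivity (cases positive),
    specificity and rank-based AUC from predicted scores; regression reports
    R^2 = 1 - SS_res / SS_tot on the test targets.
    """
    x_train, x_test = pd.DataFrame(x_train), pd.DataFrame(x_test)
    for name, frame in (("train", x_train), ("test", x_test)):
        missing = set(selected) - set(frame.columns)
        if missing:
            raise ConfigurationError(f"{name} set lacks features: {missing}")
    y_train = np.asarray(y_train)
    y_test = np.asarray(y_test)
    _validate_xy(x_train[selected], y_train, task)
    model = _make_model(task, seed, params)
    model.fit(x_train[selected].to_numpy(), y_train)
    if task == "classify":
        pred = model.predict(x_test[selected].to_numpy())
        score = model.predict_proba(x_test[selected].to_numpy())[:, 1]
        return _classification_metrics(y_test, pred, score)
    pred = model.predict(x_test[selected].to_numpy())
    return {"r2": _r2(y_test, pred)}


def prepare_cohort_features(
    node_features: pd.DataFrame,
    subjects: pd.DataFrame,
    task: str = "classify",
    exclude_female: bool = True,
    exclude_medicated: bool = True,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Apply the training-cohort exclusions and build (X, y).

    The default recipe drops female subjects and medicated patients before
    model training (sex imbalance and the medication-linked shift in
    flexibility would otherwise confound the models).  Classification
    targets are 1 for the patient group, 0 for controls; regression targets
    are the severity scores.
    """
    sub = subjects.loc[node_features.index]
    keep = pd.Series(True, index=sub.index)
    if exclude_female:
        keep &= sub["sex"] != "F"
    if exclude_medicated:
        keep &= ~((sub["group"] == GROUP_ADHD) & (sub["medication"] == MED_TREATED))
    x = node_features.loc[keep]
    sub = sub.loc[keep]
    if task == "classify":
        y = (sub["group"] == GROUP_ADHD).to_numpy().astype(int)
    else:
        y = sub["severity"].to_numpy(dtype=float)
    return x, y
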