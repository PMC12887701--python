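"""Pathway-restricted supervised evaluation.

A pluggable classifier suite is scored with stratified k-fold
cross-validation on six metrics (AUC, accuracy, F1, precision, recall,
Cohen's kappa), models are ranked by summed metric ranks, and gene
importances are extracted from the top models (intrinsic where available,
permutation fallback otherwise) and aggregated with inverse-position
weights.

Preprocessing (per-gene Z-score, low-variance drop, ANOVA-F selection at
P < 0.01) is fitted inside each training fold by default to avoid leakage;
``paper_faithful=True`` fits it once on the full data instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import (ExtraTreesClassifier, GradientBoostingClassifier,
                              RandomForestClassifier)
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (accuracy_score, cohen_kappa_score, f1_score,
                             precision_score, recall_score, roc_auc_score)
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

log = logging.getLogger(__name__)

METRICS = ("auc", "accuracy", "f1", "precision", "recall", "kappa")


@dataclass
class ModelMetrics:
    model: str
    auc: float
    accuracy: float
    f1: float
    precision: float
    recall: float
    kappa: float

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRICS}


@dataclass
class ImportanceVector:
    model: str
    importances: pd.Series  # gene -> non-negative weight, sums to 1
    method: str  # intrinsic | permutation


class EmptyFeatureSetError(ValueError):
    pass


class Preprocessor:
    """Z-score + low-variance drop + ANOVA-F selection, fit/transform style.

    If fewer than ``min_features`` genes pass the F-test P threshold, the
    selection falls back to the ``fallback_k`` smallest-P genes (logged).
    """

    def __init__(self, var_eps: float = 1e-8, f_alpha: float = 0.01,
                 min_features: int = 2, fallback_k: int = 10):
        self.var_eps = var_eps
        self.f_alpha = f_alpha
        self.min_features = min_features
        self.fallback_k = fallback_k
        self.genes_: list[str] | None = None
        self.mean_: pd.Series | None = None
        self.sd_: pd.Series | None = None

    def fit(self, X: pd.DataFrame, y: np.ndarray) -> "Preprocessor":
        """X: samples x genes."""
        var = X.var(axis=0, ddof=1)
        keep = var[var >= self.var_eps].index
        if len(keep) == 0:
            raise EmptyFeatureSetError("empty feature set: all genes near-constant")
        Xv = X[keep]
        y = np.asarray(y)
        g0, g1 = Xv[y == 0], Xv[y == 1]
        fstat, pvals = stats.f_oneway(g0.to_numpy(), g1.to_numpy(), axis=0)
        pvals = pd.Series(pvals, index=keep)
        selected = pvals[pvals < self.f_alpha].index
        if len(selected) < self.min_features:
            selected = pvals.nsmallest(min(self.fallback_k, len(pvals))).index
            log.info("ANOVA-F selection kept < %d genes; falling back to the "
                     "%d smallest-P genes", self.min_features, len(selected))
        self.genes_ = list(selected)
        self.mean_ = X[self.genes_].mean(axis=0)
        self.sd_ = X[self.genes_].std(axis=0, ddof=1)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if self.genes_ is None:
            raise RuntimeError("Preprocessor not fitted")
        return (X[self.genes_] - self.mean_) / self.sd_

    def fit_transform(self, X: pd.DataFrame, y: np.ndarray) -> pd.DataFrame:
        return self.fit(X, y).transform(X)


def preprocess(matrix: pd.DataFrame, labels: pd.Series,
               var_eps: float = 1e-8, f_alpha: float = 0.01) -> pd.DataFrame:
    """One-shot preprocessing of a genes x samples matrix.

    Returns the samples x genes feature matrix after Z-scoring, variance
    filtering, and ANOVA-F selection.
    """
    X = matrix.T.loc[labels.index]
    return Preprocessor(var_eps=var_eps, f_alpha=f_alpha).fit_transform(
        X, labels.to_numpy())


def default_model_suite(seed: int = 0, n_estimators: int = 100) -> dict:
    """The required default classifier suite (classical tiers only)."""
    return {
        "logistic_regression": LogisticRegression(max_iter=2000, C=1.0),
        "knn": KNeighborsClassifier(n_neighbors=5),
        "svc": SVC(kernel="rbf", C=1.0, random_state=seed),
        "random_forest": RandomForestClassifier(
            n_estimators=n_estimators, random_state=seed),
        "extra_trees": ExtraTreesClassifier(
            n_estimators=n_estimators, random_state=seed),
        "gradient_boosting": GradientBoostingClassifier(
            n_estimators=n_estimators, random_state=seed),
    }


def _scores_for_auc(model, X: pd.DataFrame) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


def fold_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                 y_score: np.ndarray) -> dict[str, float]:
    return {
        "auc": float(roc_auc_score(y_true, y_score)),
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "f1": float(f1_score(y_true, y_pred, zero_division=0)),
        "precision": float(precision_score(y_true, y_pred, zero_division=0)),
        "recall": float(recall_score(y_true, y_pred, zero_division=0)),
        "kappa": float(cohen_kappa_score(y_true, y_pred)),
    }


def crossval_evaluate(matrix: pd.DataFrame, labels: pd.Series,
                      models: dict | None = None, k: int = 10, seed: int = 0,
                      var_eps: float = 1e-8, f_alpha: float = 0.01,
                      paper_faithful: bool = False) -> list[ModelMetrics]:
    """Stratified k-fold CV of each model; metrics are fold-averaged.

    ``matrix`` is genes x samples.  ``k`` is lowered (with a log message)
    when a class has fewer than ``k`` members.
    """
    if models is None:
        models = default_model_suite(seed)
    y = labels.to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("crossval_evaluate: labels contain a single class")
    k_eff = min(k, int(counts.min()))
    if k_eff < k:
        log.info("k lowered from %d to %d (min class count)", k, k_eff)
    X_all = matrix.T.loc[labels.index]

    global_prep = None
    if paper_faithful:
        global_prep = Preprocessor(var_eps=var_eps, f_alpha=f_alpha).fit(X_all, y)

    skf = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed)
    results = []
    for name, template in models.items():
        per_fold: list[dict[str, float]] = []
        for train_idx, test_idx in skf.split(X_all, y):
            X_tr, X_te = X_all.iloc[train_idx], X_all.iloc[test_idx]
            y_tr, y_te = y[train_idx], y[test_idx]
            prep = global_prep or Preprocessor(
                var_eps=var_eps, f_alpha=f_alpha).fit(X_tr, y_tr)
            model = clone_model(template)
            model.fit(prep.transform(X_tr), y_tr)
            X_te_t = prep.transform(X_te)
            per_fold.append(fold_metrics(
                y_te, model.predict(X_te_t), _scores_for_auc(model, X_te_t)))
        means = {m: float(np.mean([f[m] for f in per_fold])) for m in METRICS}
        results.append(ModelMetrics(model=name, **means))
    return results


def clone_model(model):
    from sklearn.base import clone
    return clone(model)


def composite_rank(metrics: list[ModelMetrics]) -> pd.Series:
    """Sum of per-metric ranks (1 = best, ties averaged); lower is better.

    Invariant to metric ordering and to the order of the input models.
    """
    if len(metrics) < 2:
        raise ValueError("composite_rank requires >= 2 models")
    df = pd.DataFrame({m.model: m.as_dict() for m in metrics}).T
    ranks = df.apply(lambda col: stats.rankdata(-col.to_numpy(), method="average"),
                     axis=0, result_type="broadcast")
    return ranks.sum(axis=1).sort_values(kind="mergesort")


def top_models(metrics: list[ModelMetrics], n: int = 5) -> list[str]:
    composite = composite_rank(metrics)
    # stable tie-break by model name
    order = sorted(composite.index, key=lambda m: (composite[m], m))
    return order[:n]


def extract_importance(model, X: pd.DataFrame, y: np.ndarray,
                       method: str = "auto", name: str | None = None,
                       seed: int = 0, n_repeats: int = 20) -> ImportanceVector:
    """Per-gene importance from a fitted model, normalized to sum 1.

    ``auto`` uses intrinsic scores (|coefficients| or impurity-based split
    gain) when the model exposes them, otherwise permutation importance
    (negatives clipped to 0).  An all-zero vector is replaced by a uniform
    one so the sum-to-one invariant holds.
    """
    name = name or type(model).__name__
    if method == "auto":
        method = ("intrinsic" if hasattr(model, "coef_")
                  or hasattr(model, "feature_importances_") else "permutation")
    if method == "intrinsic":
        if hasattr(model, "feature_importances_"):
            raw = np.asarray(model.feature_importances_, dtype=float)
        elif hasattr(model, "coef_"):
            raw = np.abs(np.asarray(model.coef_, dtype=float)).ravel()
        else:
            log.info("model %s exposes no intrinsic importances; "
                     "using permutation fallback", name)
            method = "permutation"
    if method == "permutation":
        res = permutation_importance(model, X, y, n_repeats=n_repeats,
                                     random_state=seed)
        raw = np.clip(res.importances_mean, 0.0, None)
    total = raw.sum()
    values = raw / total if total > 0 else np.full(len(raw), 1.0 / len(raw))
    return ImportanceVector(model=name,
                            importances=pd.Series(values, index=X.columns),
                            method=method)


def weighted_importance(vectors: list[ImportanceVector]) -> pd.Series:
    """Aggregate top-model importances with inverse-position weights.

    The vector at top-5 position r (1-based, input order) gets weight 1/r;
    genes absent from a model's feature set contribute importance 0 there.
    """
    if not vectors:
        raise ValueError("weighted_importance: no importance vectors")
    if len(vectors) > 5:
        raise ValueError("weighted_importance accepts at most 5 vectors")
    genes = sorted(set().union(*(set(v.importances.index) for v in vectors)))
    acc = pd.Series(0.0, index=genes)
    total_w = 0.0
    for r, v in enumerate(vectors, start=1):
        w = 1.0 / r
        acc = acc.add(w * v.importances.reindex(genes, fill_value=0.0))
        total_w += w
    return acc / total_w


@dataclass
class PathwayEvaluation:
    dataset: str
    pathway: str
    metrics: list[ModelMetrics]
    composite: pd.Series
    importances: dict[str, ImportanceVector] = field(default_factory=dict)


def evaluate_pathway(matrix: pd.DataFrame, labels: pd.Series, genes,
                     dataset: str = "", pathway: str = "",
                     models: dict | None = None, k: int = 10,
                     seed: int = 0, top_n: int = 5) -> PathwayEvaluation:
    """CV-evaluate the suite on a pathway-restricted expression matrix and
    extract importances from the top-ranked models (fitted on the full,
    globally preprocessed data)."""
    present = [g for g in genes if g in matrix.index]
    if not present:
        raise EmptyFeatureSetError(f"no pathway genes present in dataset {dataset!r}")
    sub = matrix.loc[present]
    metrics = crossval_evaluate(sub, labels, models=models, k=k, seed=seed)
    composite = composite_rank(metrics)
    suite = models if models is not None else default_model_suite(seed)

    y = labels.to_numpy()
    X_all = sub.T.loc[labels.index]
    prep = Preprocessor().fit(X_all, y)
    X_t = prep.transform(X_all)
    importances = {}
    for name in top_models(metrics, n=top_n):
        model = clone_model(suite[name])
        model.fit(X_t, y)
        importances[name] = extract_importance(model, X_t, y, name=name, seed=seed)
    return PathwayEvaluation(dataset=dataset, pathway=pathway, metrics=metrics,
                             composite=composite, importances=importances)
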