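"""SMOTE-balanced stratified cross-validation over seven classifier families.

The evaluation protocol is 5-fold stratified CV (optionally repeated over
several shuffle seeds).  Inside every training fold, and only there:

1. feature selection is re-run (``selection_scope='per_fold'``, the default)
   so test subjects never influence the selected set;
2. the minority class is SMOTE-upsampled to parity — each synthetic point is
   ``x + lam * (x_nn - x)`` with lam ~ U(0, 1) and ``x_nn`` one of the
   ``k = min(3, minority - 1)`` nearest minority neighbours (Euclidean);
3. hyperparameters are grid-searched to maximize mean F1 (nested inner
   3-fold in ``strict`` mode; across the outer folds themselves in ``paper``
   mode, the simpler non-nested protocol).

Distance-based models (KNN, SVM, LR) see train-fold-standardized features;
tree models and naive Bayes consume raw features.  Per-subject out-of-fold
P(Y=1) probabilities are retained: they are the raw material of the
compensatory-reserve report.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .select import SelectionConfig, select_features

logger = logging.getLogger(__name__)

ALL_CLASSIFIERS = ("KNN", "RF", "ET", "SVM", "DT", "NB", "LR")
_SCALED = {"KNN", "SVM", "LR"}

METRICS = ("accuracy", "precision", "recall", "f1", "roc_auc", "aupr")


def default_grids() -> Dict[str, List[dict]]:
    """Small published-default hyperparameter grids (repository defaults)."""
    def expand(**axes):
        keys = list(axes)
        return [dict(zip(keys, vals)) for vals in itertools.product(*axes.values())]

    return {
        "KNN": expand(n_neighbors=[3, 5, 7, 9]),
        "RF": expand(n_estimators=[200, 500], max_depth=[None, 5, 10]),
        "ET": expand(n_estimators=[200, 500], max_depth=[None, 5, 10]),
        "SVM": expand(C=[0.1, 1.0, 10.0]),
        "DT": expand(max_depth=[None, 3, 5]),
        "NB": [{}],
        "LR": expand(C=[0.1, 1.0, 10.0]),
    }


def _make_estimator(name: str, params: dict, seed: int):
    if name == "KNN":
        est = KNeighborsClassifier(**params)
    elif name == "RF":
        est = RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    elif name == "ET":
        est = ExtraTreesClassifier(random_state=seed, n_jobs=1, **params)
    elif name == "SVM":
        est = SVC(kernel="rbf", gamma="scale", probability=True, random_state=seed, **params)
    elif name == "DT":
        est = DecisionTreeClassifier(random_state=seed, **params)
    elif name == "NB":
        est = GaussianNB(**params)
    elif name == "LR":
        est = LogisticRegression(max_iter=2000, random_state=seed, **params)
    else:
        raise ValueError(f"unknown classifier {name!r}")
    if name in _SCALED:
        return Pipeline([("scale", StandardScaler()), ("clf", est)])
    return est


@dataclass(frozen=True)
class CvConfig:
    folds: int = 5
    smote_k_cap: int = 3
    classifiers: Tuple[str, ...] = ALL_CLASSIFIERS
    grids: Optional[Mapping[str, List[dict]]] = None
    repeat_seeds: Tuple[int, ...] = (0, 1, 2, 3, 4)
    inner_folds: int = 3
    mode: str = "strict"  # 'strict' = nested tuning, 'paper' = tuned on the outer folds

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        unknown = set(self.classifiers) - set(ALL_CLASSIFIERS)
        if unknown:
            raise ValueError(f"unknown classifier(s) {sorted(unknown)}")
        if self.mode not in ("strict", "paper"):
            raise ValueError("mode must be 'strict' or 'paper'")

    def grid_for(self, name: str) -> List[dict]:
        grids = self.grids if self.grids is not None else default_grids()
        grid = grids.get(name, [{}])
        if not grid:
            raise ValueError(f"empty hyperparameter grid for {name}")
        return grid


def smote_balance(
    X: np.ndarray, y: np.ndarray, seed: int, k_cap: int = 3
) -> Tuple[np.ndarray, np.ndarray]:
    """Upsample the minority class to parity by k-NN interpolation.

    Majority rows are untouched; original rows come first in the output.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("SMOTE requires exactly two classes in y")
    if counts[0] == counts[1]:
        return X.copy(), y.copy()
    minority = classes[np.argmin(counts)]
    X_min = X[y == minority]
    n_min = len(X_min)
    if n_min < 2:
        raise ValueError("SMOTE needs at least 2 minority samples to interpolate")
    k = min(k_cap, n_min - 1)
    n_new = int(counts.max() - n_min)
    # +1 neighbour because each point is its own nearest neighbour
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min)
    _, nbr = nn.kneighbors(X_min)
    rng = np.random.default_rng(seed)
    base = rng.integers(0, n_min, size=n_new)
    pick = rng.integers(1, k + 1, size=n_new)  # skip column 0 (self)
    lam = rng.uniform(0.0, 1.0, size=n_new)
    anchors = X_min[base]
    partners = X_min[nbr[base, pick]]
    synthetic = anchors + lam[:, None] * (partners - anchors)
    X_out = np.vstack([X, synthetic])
    y_out = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])
    return X_out, y_out


def compute_metrics(
    y_true: np.ndarray, y_pred: np.ndarray, y_prob: Optional[np.ndarray] = None
) -> Dict[str, Optional[float]]:
    """Standard binary metrics with positive class Y=1.

    ROC-AUC / AUPR are None (reported missing, not 0) when y_true is
    single-class; precision is 0 when nothing is predicted positive.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0 or y_true.size != y_pred.size:
        raise ValueError("y_true and y_pred must be non-empty and aligned")
    out: Dict[str, Optional[float]] = {
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "precision": float(precision_score(y_true, y_pred, zero_division=0)),
        "recall": float(recall_score(y_true, y_pred, zero_division=0)),
        "f1": float(f1_score(y_true, y_pred, zero_division=0)),
        "roc_auc": None,
        "aupr": None,
    }
    if y_pred.sum() == 0 and y_true.sum() > 0:
        logger.warning("no positive predictions: precision reported as 0")
    if y_prob is not None and len(np.unique(y_true)) == 2:
        out["roc_auc"] = float(roc_auc_score(y_true, y_prob))
        out["aupr"] = float(average_precision_score(y_true, y_prob))
    return out


@dataclass
class EvalReport:
    """Cross-validation outcome: metrics and out-of-fold probabilities."""

    per_classifier: Dict[str, Dict[str, Tuple[float, float]]]
    pooled: Dict[str, Tuple[float, float]]
    oof_probabilities: Dict[str, Dict[int, Dict[str, float]]]  # clf -> repeat -> subject -> P(Y=1)
    fold_metrics: Dict[str, List[Dict[str, Optional[float]]]]
    selected_per_fold: Dict[Tuple[int, int], List[str]]
    labels: Dict[str, int]

    def mean_oof_probability(self, subject_id: str) -> float:
        """P(Y=1) for one subject, averaged over classifiers and repeats."""
        vals = [
            reps[r][subject_id]
            for reps in self.oof_probabilities.values()
            for r in reps
            if subject_id in reps[r]
        ]
        if not vals:
            raise KeyError(f"no out-of-fold probability for subject {subject_id!r}")
        return float(np.mean(vals))


def _mean_sd(values: Sequence[float]) -> Tuple[float, float]:
    arr = np.asarray([v for v in values if v is not None], dtype=float)
    if arr.size == 0:
        return (np.nan, np.nan)
    return float(arr.mean()), float(arr.std())


def _tune_strict(name, grid, Xb, yb, inner_folds, seed) -> dict:
    """Best params by mean F1 over an inner stratified CV on the balanced train set."""
    if len(grid) == 1:
        return grid[0]
    n_splits = min(inner_folds, int(np.bincount(yb.astype(int)).min()))
    inner = StratifiedKFold(n_splits=max(2, n_splits), shuffle=True, random_state=seed)
    best, best_f1 = grid[0], -1.0
    for params in grid:
        f1s = []
        for tr, va in inner.split(Xb, yb):
            est = _make_estimator(name, params, seed)
            est.fit(Xb[tr], yb[tr])
            f1s.append(f1_score(yb[va], est.predict(Xb[va]), zero_division=0))
        mean_f1 = float(np.mean(f1s))
        if mean_f1 > best_f1:
            best, best_f1 = params, mean_f1
    return best


def run_cv(
    features: pd.DataFrame,
    labels: Sequence[int],
    config: CvConfig = CvConfig(),
    selection: Optional[SelectionConfig] = None,
    selection_scope: str = "per_fold",
    feature_builder: Optional[Callable[[List[str]], pd.DataFrame]] = None,
) -> EvalReport:
    """Cross-validated evaluation of the selected-feature classifiers.

    ``features`` is a numeric subjects x p frame indexed by subject id;
    ``labels`` the aligned 0/1 vector.  With ``selection`` given and
    ``selection_scope='per_fold'`` the hybrid filter is re-run on each
    training fold; ``'global'`` selects once on all rows (the single-pass
    protocol); ``selection=None`` uses all columns as-is.

    ``feature_builder``, when given, recomputes the feature table per outer
    fold from the training subject ids only (used for per-fold healthy
    templates, removing the control self-reference of a globally built
    template); it must return a frame covering at least the same subjects.
    """
    y = np.asarray(labels, dtype=int)
    if len(y) != len(features):
        raise ValueError("labels must align with feature rows")
    counts = np.bincount(y, minlength=2)
    if counts.min() < config.folds:
        raise ValueError(
            f"need >= {config.folds} subjects per class for {config.folds}-fold stratified CV, "
            f"got {counts.tolist()}"
        )
    if selection_scope not in ("per_fold", "global"):
        raise ValueError("selection_scope must be 'per_fold' or 'global'")
    global_cols: Optional[List[str]] = None
    if selection is not None and selection_scope == "global":
        global_cols = select_features(features, y, selection).selected

    subjects = list(features.index)
    fold_metrics: Dict[str, List[Dict[str, Optional[float]]]] = {c: [] for c in config.classifiers}
    oof: Dict[str, Dict[int, Dict[str, float]]] = {c: {} for c in config.classifiers}
    selected_per_fold: Dict[Tuple[int, int], List[str]] = {}

    for rep_seed in config.repeat_seeds:
        skf = StratifiedKFold(n_splits=config.folds, shuffle=True, random_state=rep_seed)
        prepared = []
        for fold_i, (tr, te) in enumerate(skf.split(features, y)):
            assert len(set(tr) & set(te)) == 0  # leakage guard: disjoint folds
            if feature_builder is not None:
                fold_features = feature_builder([subjects[i] for i in tr]).loc[subjects]
            else:
                fold_features = features
            X_tr_df, y_tr = fold_features.iloc[tr], y[tr]
            if selection is not None and selection_scope == "per_fold":
                cols = select_features(X_tr_df, y_tr, selection).selected
            elif global_cols is not None:
                cols = global_cols
            else:
                cols = list(features.columns)
            selected_per_fold[(rep_seed, fold_i)] = cols
            smote_seed = int((rep_seed * 1009 + fold_i) % 2**31)
            Xb, yb = smote_balance(
                X_tr_df[cols].to_numpy(dtype=float), y_tr, seed=smote_seed, k_cap=config.smote_k_cap
            )
            prepared.append(
                dict(fold=fold_i, te=te, Xb=Xb, yb=yb,
                     X_te=fold_features.iloc[te][cols].to_numpy(dtype=float), y_te=y[te],
                     te_subjects=[subjects[i] for i in te])
            )

        for name in config.classifiers:
            grid = config.grid_for(name)
            rep_oof = oof[name].setdefault(int(rep_seed), {})
            if config.mode == "strict":
                for prep in prepared:
                    seed = int((rep_seed * 7919 + prep["fold"]) % 2**31)
                    params = _tune_strict(name, grid, prep["Xb"], prep["yb"], config.inner_folds, seed)
                    est = _make_estimator(name, params, seed)
                    est.fit(prep["Xb"], prep["yb"])
                    prob = est.predict_proba(prep["X_te"])[:, list(est.classes_).index(1)]
                    pred = est.predict(prep["X_te"])
                    fold_metrics[name].append(compute_metrics(prep["y_te"], pred, prob))
                    rep_oof.update(zip(prep["te_subjects"], prob.astype(float)))
            else:  # paper-faithful: tune on the outer folds themselves
                evals = []
                for params in grid:
                    rows = []
                    for prep in prepared:
                        seed = int((rep_seed * 7919 + prep["fold"]) % 2**31)
                        est = _make_estimator(name, params, seed)
                        est.fit(prep["Xb"], prep["yb"])
                        prob = est.predict_proba(prep["X_te"])[:, list(est.classes_).index(1)]
                        pred = est.predict(prep["X_te"])
                        rows.append((compute_metrics(prep["y_te"], pred, prob),
                                     dict(zip(prep["te_subjects"], prob.astype(float)))))
                    mean_f1 = float(np.mean([m["f1"] for m, _ in rows]))
                    evals.append((mean_f1, rows))
                _, rows = max(evals, key=lambda e: e[0])
                for m, probs in rows:
                    fold_metrics[name].append(m)
                    rep_oof.update(probs)

    per_classifier = {
        name: {metric: _mean_sd([fm[metric] for fm in fms]) for metric in METRICS}
        for name, fms in fold_metrics.items()
    }
    pooled = {
        metric: _mean_sd([per_classifier[name][metric][0] for name in config.classifiers])
        for metric in METRICS
    }
    return EvalReport(
        per_classifier=per_classifier,
        pooled=pooled,
        oof_probabilities=oof,
        fold_metrics=fold_metrics,
        selected_per_fold=selected_per_fold,
        labels=dict(zip(subjects, y.tolist())),
    )
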