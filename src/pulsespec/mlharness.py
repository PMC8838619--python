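"""Cross-validated classification of the 40 spectral indices.

Eight classifier families (SVM, MLP, GNB, DT, RF, LR, LDA, KNN) are trained
on subject-level feature vectors with stratified threefold cross-validation.
Per fold the harness reports accuracy (percent), sensitivity (recall on the
positive class, AD = "1"), specificity (recall on the negative class), a
rank-based ROC AUC of the predicted probabilities, and the 2x2 confusion
table; fold metrics are averaged arithmetically. Features are z-scored with
statistics fit on the training folds only (the classifiers include
scale-sensitive methods, so scaling is on by default but can be disabled).

External (test-cohort) predictions come from a single model refit on the
full training table; SVM probabilities use Platt sigmoid calibration of the
decision values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import FeatureMismatchError, ValidationError
from .spectral import FEATURE_NAMES
from .utils import spawn_seed

__all__ = [
    "METHODS",
    "DEFAULT_HYPERPARAMETERS",
    "ModelSpec",
    "FoldResult",
    "CVReport",
    "SubjectPrediction",
    "make_folds",
    "run_cv",
    "predict_external",
    "average_fold_metrics",
]

#: Reference hyperparameters per method; ModelSpec accepts only these keys.
DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "SVM": {
        "C": 1.0,
        "kernel": "rbf",
        "gamma": "auto",
        "tol": 1e-4,
        "max_iter": -1,
        "class_weight": None,
    },
    "MLP": {
        "hidden_layer_sizes": 100,
        "solver": "adam",
        "alpha": 1e-4,
        "batch_size": "auto",
        "max_iter": 200,
        "learning_rate_init": 0.001,
    },
    "GNB": {"priors": None},
    "DT": {
        "criterion": "gini",
        "splitter": "best",
        "max_depth": None,
        "min_samples_split": 2,
        "min_samples_leaf": 1,
        "min_weight_fraction_leaf": 0.0,
        "max_features": None,
        "max_leaf_nodes": None,
        # accepted for config fidelity; 0.0 was the no-op default of a
        # since-removed sklearn parameter and is not forwarded
        "min_impurity_split": 0.0,
    },
    "RF": {
        "n_estimators": 100,
        "criterion": "gini",
        "max_depth": None,
        "min_samples_split": 2,
        "min_samples_leaf": 1,
        "min_weight_fraction_leaf": 0.0,
        "max_features": None,
        "max_leaf_nodes": None,
    },
    "LR": {"penalty": "l2", "solver": "lbfgs", "class_weight": None},
    "LDA": {"solver": "svd", "shrinkage": None, "priors": None},
    "KNN": {"n_neighbors": 5, "weights": "uniform", "algorithm": "auto", "n_jobs": None},
}

METHODS = tuple(DEFAULT_HYPERPARAMETERS)

_DROP_KEYS = {"min_impurity_split"}


@dataclass(frozen=True)
class ModelSpec:
    """A classifier family plus hyperparameter overrides.

    Hyperparameter keys are restricted to the reference set for the method;
    anything else raises :class:`ValidationError`.
    """

    method: str
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.method not in DEFAULT_HYPERPARAMETERS:
            raise ValidationError(
                f"unknown method {self.method!r}; choose from {sorted(METHODS)}"
            )
        allowed = set(DEFAULT_HYPERPARAMETERS[self.method])
        unknown = set(self.hyperparameters) - allowed
        if unknown:
            raise ValidationError(
                f"hyperparameters {sorted(unknown)} not allowed for {self.method}; "
                f"allowed: {sorted(allowed)}"
            )

    def resolved(self) -> dict:
        params = dict(DEFAULT_HYPERPARAMETERS[self.method])
        params.update(self.hyperparameters)
        return params

    def build(self, seed: int = 0):
        """Construct the sklearn estimator; ``seed`` fixes any stochastic fit."""
        p = {k: v for k, v in self.resolved().items() if k not in _DROP_KEYS}
        if self.method == "SVM":
            return SVC(probability=True, random_state=seed, **p)
        if self.method == "MLP":
            hidden = p.pop("hidden_layer_sizes")
            if isinstance(hidden, int):
                hidden = (hidden,)
            return MLPClassifier(hidden_layer_sizes=hidden, random_state=seed, **p)
        if self.method == "GNB":
            return GaussianNB(**p)
        if self.method == "DT":
            return DecisionTreeClassifier(random_state=seed, **p)
        if self.method == "RF":
            return RandomForestClassifier(random_state=seed, **p)
        if self.method == "LR":
            if p.get("penalty") == "l2":
                p.pop("penalty")  # sklearn default; passing it explicitly is deprecated
            return LogisticRegression(random_state=seed, max_iter=1000, **p)
        if self.method == "LDA":
            return LinearDiscriminantAnalysis(**p)
        if self.method == "KNN":
            return KNeighborsClassifier(**p)
        raise AssertionError("unreachable")


@dataclass
class FoldResult:
    """Held-out metrics of one cross-validation fold.

    ``confusion`` is ``[[TN, FP], [FN, TP]]`` with class 1 = AD; it may be
    ``None`` when a result is reconstructed from reported metrics alone.
    """

    fold_index: int
    accuracy_pct: float
    sensitivity: float
    specificity: float
    auc: float
    confusion: list | None = None

    def __post_init__(self):
        if self.confusion is not None:
            (tn, fp), (fn, tp) = self.confusion
            total = tn + fp + fn + tp
            acc = 100.0 * (tn + tp) / total
            if abs(acc - self.accuracy_pct) > 0.5:
                raise ValidationError(
                    f"accuracy {self.accuracy_pct} inconsistent with confusion table ({acc:.2f})"
                )


def average_fold_metrics(folds: list[FoldResult]) -> dict[str, float]:
    """Arithmetic means of the per-fold metrics."""
    return {
        "accuracy_pct": float(np.mean([f.accuracy_pct for f in folds])),
        "sensitivity": float(np.mean([f.sensitivity for f in folds])),
        "specificity": float(np.mean([f.specificity for f in folds])),
        "auc": float(np.mean([f.auc for f in folds])),
    }


@dataclass
class CVReport:
    model: ModelSpec
    folds: list[FoldResult]
    seed: int

    @property
    def avg_accuracy_pct(self) -> float:
        return average_fold_metrics(self.folds)["accuracy_pct"]

    @property
    def avg_sensitivity(self) -> float:
        return average_fold_metrics(self.folds)["sensitivity"]

    @property
    def avg_specificity(self) -> float:
        return average_fold_metrics(self.folds)["specificity"]

    @property
    def avg_auc(self) -> float:
        return average_fold_metrics(self.folds)["auc"]

    def to_dict(self, ndigits: int = 2) -> dict:
        """Serializable summary; percentages and proportions to ``ndigits``."""
        return {
            "model": self.model.method,
            "hyperparameters": {
                k: v for k, v in self.model.resolved().items() if v is not None
            },
            "seed": self.seed,
            "folds": [
                {
                    "fold_index": f.fold_index,
                    "accuracy_pct": round(f.accuracy_pct, ndigits),
                    "sensitivity": round(f.sensitivity, ndigits),
                    "specificity": round(f.specificity, ndigits),
                    "auc": round(f.auc, ndigits),
                    "confusion": f.confusion,
                }
                for f in self.folds
            ],
            "avg_accuracy_pct": round(self.avg_accuracy_pct, ndigits),
            "avg_sensitivity": round(self.avg_sensitivity, ndigits),
            "avg_specificity": round(self.avg_specificity, ndigits),
            "avg_auc": round(self.avg_auc, ndigits),
        }


@dataclass
class SubjectPrediction:
    subject_id: str
    probability_ad: float
    mmse: int
    cohort: str


def make_folds(labels, k: int = 3, seed: int = 0) -> np.ndarray:
    """Subject-level stratified partition into k near-equal folds.

    Within each class, subjects are shuffled and dealt round-robin into the
    folds, with the starting fold rotated per class so fold sizes stay within
    one of each other. Deterministic under ``seed``. Raises if any class has
    fewer than k members.
    """
    labels = np.asarray(labels)
    if k < 2:
        raise ValidationError("k must be >= 2")
    classes = np.unique(labels)
    rng = np.random.default_rng(seed)
    fold = np.empty(len(labels), dtype=int)
    for ci, cls in enumerate(classes):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < k:
            raise ValidationError(
                f"class {cls!r} has {len(idx)} subjects, fewer than k = {k}"
            )
        perm = rng.permutation(idx)
        fold[perm] = (np.arange(len(perm)) + ci) % k
    return fold


def _feature_matrix(features: pd.DataFrame) -> np.ndarray:
    missing = [c for c in FEATURE_NAMES if c not in features.columns]
    if missing:
        raise FeatureMismatchError(f"feature table lacks columns: {missing}")
    X = features[FEATURE_NAMES].to_numpy(dtype=float)
    bad = ~np.isfinite(X).all(axis=1)
    if bad.any():
        offenders = list(features.index[bad])
        raise ValidationError(
            f"non-finite features for subjects {offenders}; imputation refused"
        )
    return X


def run_cv(
    features: pd.DataFrame,
    model: ModelSpec,
    seed: int = 0,
    *,
    k: int = 3,
    positive_label: str = "AD",
    standardize: bool = True,
) -> CVReport:
    """Stratified k-fold cross-validation on a binary-labeled feature table.

    ``features`` must carry a ``group`` column; subjects with
    ``group == positive_label`` form class 1. Standardization statistics are
    computed on the training folds only.
    """
    if "group" not in features.columns:
        raise ValidationError("features table must have a 'group' column")
    X = _feature_matrix(features)
    y = (features["group"] == positive_label).to_numpy(dtype=int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValidationError("both classes must be present for cross-validation")
    folds = make_folds(y, k=k, seed=seed)

    fold_results = []
    for f in range(k):
        train, test = folds != f, folds == f
        X_train, X_test = X[train], X[test]
        if standardize:
            scaler = StandardScaler().fit(X_train)
            X_train, X_test = scaler.transform(X_train), scaler.transform(X_test)
        estimator = model.build(seed=spawn_seed(seed, f))
        estimator.fit(X_train, y[train])
        proba = estimator.predict_proba(X_test)[:, list(estimator.classes_).index(1)]
        predicted = estimator.predict(X_test)
        tn, fp, fn, tp = confusion_matrix(y[test], predicted, labels=[0, 1]).ravel()
        fold_results.append(
            FoldResult(
                fold_index=f + 1,
                accuracy_pct=100.0 * (tn + tp) / (tn + fp + fn + tp),
                sensitivity=tp / (tp + fn) if (tp + fn) else float("nan"),
                specificity=tn / (tn + fp) if (tn + fp) else float("nan"),
                auc=float(roc_auc_score(y[test], proba)),
                confusion=[[int(tn), int(fp)], [int(fn), int(tp)]],
            )
        )
    return CVReport(model=model, folds=fold_results, seed=seed)


def predict_external(
    test_features: pd.DataFrame,
    model: ModelSpec,
    train_features: pd.DataFrame,
    seed: int = 0,
    *,
    positive_label: str = "AD",
    standardize: bool = True,
) -> list[SubjectPrediction]:
    """Fit once on the full training table, return AD probabilities for the
    test cohorts.

    ``test_features`` must provide the 40 feature columns plus ``group``
    (cohort label) and ``mmse`` columns.
    """
    for col in ("group", "mmse"):
        if col not in test_features.columns:
            raise ValidationError(f"test features must have a {col!r} column")
    X_train = _feature_matrix(train_features)
    y_train = (train_features["group"] == positive_label).to_numpy(dtype=int)
    X_test = _feature_matrix(test_features)
    if standardize:
        scaler = StandardScaler().fit(X_train)
        X_train, X_test = scaler.transform(X_train), scaler.transform(X_test)
    estimator = model.build(seed=spawn_seed(seed, 0xE))
    estimator.fit(X_train, y_train)
    proba = estimator.predict_proba(X_test)[:, list(estimator.classes_).index(1)]
    return [
        SubjectPrediction(
            subject_id=str(sid),
            probability_ad=float(p),
            mmse=int(row_mmse),
            cohort=str(row_group),
        )
        for sid, p, row_mmse, row_group in zip(
            test_features.index, proba, test_features["mmse"], test_features["group"]
        )
    ]
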