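"""Final classifiers, cross-validated evaluation metrics, and consensus.

Linear SVM and k-NN (Euclidean) are trained on the receptor feature space
against each of the two negative groups (inferred and known), evaluated by
unstratified 10-fold cross-validation with confusion counts summed across
test folds, and the four resulting models vote on unlabeled receptors: a
receptor is predicted metabolic only when all four call it positive.

Two metric variants are provided. ``variant='paper'`` uses
sensitivity = TP/(TP+FN) and specificity = TN/(TN+FN);
``variant='standard'`` uses the conventional specificity TN/(TN+FP).
Accuracy and MCC are identical between variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "ClassifierSpec",
    "compute_metrics",
    "make_classifier",
    "cross_validate",
    "select_knn_k",
    "tune_svm_cost",
    "fit_final_models",
    "consensus_predict",
    "evaluate_label_sets",
]


@dataclass
class ConfusionCounts:
    """TP/TN/FP/FN summed across cross-validation test folds."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name, v in vars(self).items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    """Sensitivity/specificity/accuracy/MCC plus the misclassified ids.

    Metrics with a zero denominator are NaN (reported as undefined).
    """

    sensitivity: float
    specificity: float
    accuracy: float
    mcc: float
    variant: str
    counts: ConfusionCounts
    fp_ids: list = field(default_factory=list)
    fn_ids: list = field(default_factory=list)

    def rounded(self, ndigits: int = 2) -> dict:
        return {
            k: (round(getattr(self, k), ndigits) if np.isfinite(getattr(self, k)) else None)
            for k in ("sensitivity", "specificity", "accuracy", "mcc")
        }

    def to_dict(self) -> dict:
        return {
            "counts": vars(self.counts),
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "mcc": self.mcc,
            "variant": self.variant,
            "fp_ids": list(self.fp_ids),
            "fn_ids": list(self.fn_ids),
        }


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def compute_metrics(
    counts: ConfusionCounts,
    variant: str = "paper",
    fp_ids=(),
    fn_ids=(),
) -> MetricsReport:
    """Derive sensitivity, specificity, accuracy and MCC from counts."""
    if variant not in ("paper", "standard"):
        raise ValueError(f"unknown metric variant {variant!r}")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    sensitivity = _safe_div(tp, tp + fn)
    specificity = _safe_div(tn, tn + fn) if variant == "paper" else _safe_div(tn, tn + fp)
    accuracy = _safe_div(tp + tn, counts.total)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = _safe_div(tp * tn - fp * fn, np.sqrt(denom)) if denom > 0 else float("nan")
    return MetricsReport(
        sensitivity=sensitivity,
        specificity=specificity,
        accuracy=accuracy,
        mcc=mcc,
        variant=variant,
        counts=counts,
        fp_ids=sorted(fp_ids),
        fn_ids=sorted(fn_ids),
    )


@dataclass(frozen=True)
class ClassifierSpec:
    """Which base classifier to use and its hyperparameters."""

    method: str  # 'linear_svm' | 'knn'
    svm_cost: float = 1.0
    knn_k: int = 5

    def __post_init__(self) -> None:
        if self.method not in ("linear_svm", "knn"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.method == "linear_svm" and self.svm_cost <= 0:
            raise ValueError("svm_cost must be positive")
        if self.method == "knn" and self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")


def make_classifier(spec: ClassifierSpec):
    if spec.method == "linear_svm":
        return SVC(kernel="linear", C=spec.svm_cost)
    # brute-force Euclidean k-NN; vote ties resolve to the first class
    # (negative), distance ties to the lowest row index — deterministic
    return KNeighborsClassifier(
        n_neighbors=spec.knn_k, metric="euclidean", algorithm="brute"
    )


def cross_validate(
    features: pd.DataFrame,
    labels: pd.Series,
    spec: ClassifierSpec,
    n_folds: int = 10,
    rng_seed: int = 0,
    max_refolds: int = 20,
) -> tuple[ConfusionCounts, list, list]:
    """Unstratified k-fold CV; returns summed counts and FP/FN id lists.

    Folds are a seeded random partition. If any training fold is
    single-class, the partition is redrawn with an incremented seed (the
    event is logged).
    """
    ids = features.index
    y = labels.loc[ids].to_numpy(dtype=int)
    X = features.to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    n_folds = min(n_folds, len(ids))

    seed = rng_seed
    for _ in range(max_refolds):
        kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        splits = list(kf.split(X))
        if all(len(np.unique(y[tr])) == 2 for tr, _ in splits):
            break
        logger.warning("single-class training fold at seed %d; refolding", seed)
        seed += 1
    else:
        raise RuntimeError("could not build folds with both classes in every training set")

    pred = np.empty_like(y)
    for tr, te in splits:
        clf = make_classifier(spec)
        clf.fit(X[tr], y[tr])
        pred[te] = clf.predict(X[te])
    tp = int(np.sum((y == 1) & (pred == 1)))
    tn = int(np.sum((y == 0) & (pred == 0)))
    fp = int(np.sum((y == 0) & (pred == 1)))
    fn = int(np.sum((y == 1) & (pred == 0)))
    fp_ids = ids[(y == 0) & (pred == 1)].tolist()
    fn_ids = ids[(y == 1) & (pred == 0)].tolist()
    return ConfusionCounts(tp, tn, fp, fn), fp_ids, fn_ids


def _cv_error(features, labels, spec, n_folds, rng_seed) -> float:
    counts, _, _ = cross_validate(features, labels, spec, n_folds, rng_seed)
    return (counts.fp + counts.fn) / counts.total


def select_knn_k(
    features: pd.DataFrame,
    labels: pd.Series,
    k_grid=range(1, 11),
    n_folds: int = 10,
    rng_seed: int = 0,
) -> int:
    """Pick the LARGEST k attaining the minimal CV error rate."""
    k_grid = list(k_grid)
    if not k_grid:
        raise ValueError("empty k grid")
    n = len(features)
    n_folds_eff = min(n_folds, n)
    min_train = n - int(np.ceil(n / n_folds_eff))  # smallest training fold
    errors = {}
    for k in k_grid:
        if k > min_train:
            continue
        errors[k] = _cv_error(features, labels, ClassifierSpec("knn", knn_k=k), n_folds, rng_seed)
    if not errors:
        raise ValueError("no feasible k in the grid")
    best = min(errors.values())
    return max(k for k, e in errors.items() if e == best)


def tune_svm_cost(
    features: pd.DataFrame,
    labels: pd.Series,
    cost_grid=None,
    n_folds: int = 10,
    rng_seed: int = 0,
) -> float:
    """Pick the cost minimizing CV error; ties go to the SMALLEST cost
    (largest-margin preference)."""
    if cost_grid is None:
        cost_grid = [2.0**e for e in range(-5, 6)]
    cost_grid = sorted(cost_grid)
    if not cost_grid:
        raise ValueError("empty cost grid")
    best_cost, best_err = None, None
    for c in cost_grid:
        err = _cv_error(features, labels, ClassifierSpec("linear_svm", svm_cost=c), n_folds, rng_seed)
        if best_err is None or err < best_err:
            best_cost, best_err = c, err
    return best_cost


def _binary_labels(features, positives, negatives) -> tuple[pd.DataFrame, pd.Series]:
    ids = [r for r in features.index if r in positives or r in negatives]
    y = pd.Series([1 if r in positives else 0 for r in ids], index=ids)
    return features.loc[ids], y


def evaluate_label_sets(
    features: pd.DataFrame,
    positives,
    negative_groups: dict,
    n_folds: int = 10,
    rng_seed: int = 0,
    variant: str = "paper",
    tune: bool = True,
) -> dict:
    """Tune, cross-validate and report both classifiers per negative group.

    Returns ``{group: {'linear_svm': MetricsReport, 'knn': MetricsReport,
    'svm_cost': c, 'knn_k': k}}``.
    """
    out = {}
    positives = frozenset(positives)
    for group, negatives in negative_groups.items():
        X, y = _binary_labels(features, positives, frozenset(negatives))
        cost = tune_svm_cost(X, y, n_folds=n_folds, rng_seed=rng_seed) if tune else 1.0
        k = select_knn_k(X, y, n_folds=n_folds, rng_seed=rng_seed) if tune else 5
        result = {"svm_cost": cost, "knn_k": k}
        for method, spec in [
            ("linear_svm", ClassifierSpec("linear_svm", svm_cost=cost)),
            ("knn", ClassifierSpec("knn", knn_k=k)),
        ]:
            counts, fp_ids, fn_ids = cross_validate(X, y, spec, n_folds, rng_seed)
            result[method] = compute_metrics(counts, variant, fp_ids, fn_ids)
        out[group] = result
    return out


def fit_final_models(
    features: pd.DataFrame,
    positives,
    negative_groups: dict,
    specs: dict | None = None,
    n_folds: int = 10,
    rng_seed: int = 0,
    tune: bool = True,
) -> dict:
    """Fit one SVM and one k-NN per negative group on ALL labeled data.

    Returns ``{(method, group): fitted classifier}`` for the 2 x 2 grid.
    """
    models = {}
    positives = frozenset(positives)
    for group, negatives in negative_groups.items():
        X, y = _binary_labels(features, positives, frozenset(negatives))
        if specs and group in specs:
            cost, k = specs[group]["svm_cost"], specs[group]["knn_k"]
        elif tune:
            cost = tune_svm_cost(X, y, n_folds=n_folds, rng_seed=rng_seed)
            k = select_knn_k(X, y, n_folds=n_folds, rng_seed=rng_seed)
        else:
            cost, k = 1.0, 5
        for method, spec in [
            ("linear_svm", ClassifierSpec("linear_svm", svm_cost=cost)),
            ("knn", ClassifierSpec("knn", knn_k=min(k, len(y)))),
        ]:
            clf = make_classifier(spec)
            clf.fit(X.to_numpy(dtype=float), y.to_numpy())
            models[(method, group)] = clf
    return models


def consensus_predict(
    features_unlabeled: pd.DataFrame, models: dict
) -> tuple[frozenset, pd.DataFrame]:
    """Predict metabolic receptors by unanimous vote of the trained models.

    Returns the set of receptors every model classifies positive, and a
    votes table with one column per model plus the vote count and the
    consensus flag.
    """
    if not models:
        raise ValueError("no trained models supplied")
    for key, clf in models.items():
        if not hasattr(clf, "classes_"):
            raise ValueError(f"model {key} is not trained")
    if features_unlabeled.empty:
        return frozenset(), pd.DataFrame(
            columns=[f"{m}_{g}" for m, g in models] + ["votes", "consensus"]
        )
    votes = pd.DataFrame(index=features_unlabeled.index)
    X = features_unlabeled.to_numpy(dtype=float)
    for (method, group), clf in models.items():
        votes[f"{method}_{group}"] = (clf.predict(X) == 1).astype(int)
    votes["votes"] = votes.sum(axis=1)
    votes["consensus"] = votes["votes"] == len(models)
    return frozenset(votes.index[votes["consensus"]]), votes
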