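"""Positive-unlabeled bagging with linear SVMs.

Supervised training needs negatives, but for receptor function only a
small positive set is known; everything else is unlabeled. PU bagging
turns this into an ensemble vote: each round draws a bootstrap sample of
unlabeled points as provisional negatives, trains a linear SVM of the
positives against them, and classifies the out-of-bag (OOB) unlabeled
points. A point's positive rate is the fraction of positive OOB votes it
received over all rounds; high rates nominate new positives, high negative
rates (1 - rate) nominate confident negatives.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted, check_X_y

from .containers import LabelSet

__all__ = ["PUBaggingClassifier", "pu_bagging", "derive_labels"]


class PUBaggingClassifier(BaseEstimator):
    """Bagged linear-SVM positive-unlabeled scorer.

    ``fit(X, y)`` takes ``y`` with 1 for known positives and 0 for
    unlabeled points. Each of ``n_iterations`` rounds bootstraps
    ``sample_size`` unlabeled points (with replacement, default
    ``= number of positives``) as provisional negatives, trains
    ``SVC(kernel='linear', C=C)``, and records a binary vote (or the
    decision margin when ``score='margin'``) for every OOB unlabeled
    point.

    Fitted attributes
    -----------------
    oob_positive_rate_ : ndarray
        Mean positive OOB vote per point; NaN for positives and for
        unlabeled points with fewer than ``min_oob`` OOB appearances.
    oob_count_ : ndarray
        Number of OOB appearances per point.
    """

    def __init__(
        self,
        n_iterations: int = 100,
        sample_size: int | None = None,
        C: float = 1.0,
        min_oob: int = 10,
        score: str = "vote",
        random_state: int | None = None,
    ):
        self.n_iterations = n_iterations
        self.sample_size = sample_size
        self.C = C
        self.min_oob = min_oob
        self.score = score
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.score not in ("vote", "margin"):
            raise ValueError(f"unknown score mode {self.score!r}")
        pos_idx = np.flatnonzero(y == 1)
        unl_idx = np.flatnonzero(y == 0)
        if len(pos_idx) < 2:
            raise ValueError("need >= 2 positive examples")
        if len(unl_idx) == 0:
            raise ValueError("need at least one unlabeled example")
        k = self.sample_size if self.sample_size is not None else len(pos_idx)
        rng = np.random.default_rng(self.random_state)

        vote_sum = np.zeros(X.shape[0])
        oob_count = np.zeros(X.shape[0], dtype=int)
        y_train_pos = np.ones(len(pos_idx), dtype=int)
        for _ in range(self.n_iterations):
            boot = rng.choice(unl_idx, size=k, replace=True)
            oob = np.setdiff1d(unl_idx, boot)
            if len(oob) == 0:
                continue
            Xtr = np.vstack([X[pos_idx], X[boot]])
            ytr = np.concatenate([y_train_pos, np.zeros(len(boot), dtype=int)])
            clf = SVC(kernel="linear", C=self.C)
            clf.fit(Xtr, ytr)
            if self.score == "vote":
                votes = (clf.predict(X[oob]) == 1).astype(float)
            else:
                votes = clf.decision_function(X[oob])
            vote_sum[oob] += votes
            oob_count[oob] += 1

        rates = np.full(X.shape[0], np.nan)
        defined = oob_count >= max(self.min_oob, 1)
        rates[defined] = vote_sum[defined] / oob_count[defined]
        if not defined[unl_idx].any():
            warnings.warn(
                "no unlabeled point accumulated enough OOB appearances; "
                "all rates undefined", stacklevel=2,
            )
        self.oob_positive_rate_ = rates
        self.oob_count_ = oob_count
        self.oob_score_sum_ = vote_sum
        return self

    def predict_proba_oob(self) -> np.ndarray:
        check_is_fitted(self, "oob_positive_rate_")
        return self.oob_positive_rate_


def pu_bagging(
    features: pd.DataFrame,
    seed_positives,
    unlabeled=None,
    t: int = 100,
    k: int | None = None,
    rng_seed: int | None = None,
    min_oob: int = 10,
    C: float = 1.0,
    score: str = "vote",
) -> pd.DataFrame:
    """Run PU bagging on a receptor feature matrix.

    Parameters follow the ensemble description: ``t`` rounds, bootstrap
    size ``k`` (default = number of seed positives). ``unlabeled``
    defaults to every feature row not in ``seed_positives``. Returns a
    DataFrame indexed by receptor with ``oob_count``, ``oob_score_sum``
    and ``positive_rate`` (NaN where undefined).
    """
    seed_positives = [r for r in seed_positives if r in features.index]
    if unlabeled is None:
        unlabeled = [r for r in features.index if r not in set(seed_positives)]
    ids = list(seed_positives) + [r for r in unlabeled if r not in set(seed_positives)]
    X = features.loc[ids].to_numpy(dtype=float)
    y = np.array([1] * len(seed_positives) + [0] * (len(ids) - len(seed_positives)))
    est = PUBaggingClassifier(
        n_iterations=t, sample_size=k, C=C, min_oob=min_oob, score=score,
        random_state=rng_seed,
    ).fit(X, y)
    out = pd.DataFrame(
        {
            "oob_count": est.oob_count_,
            "oob_score_sum": est.oob_score_sum_,
            "positive_rate": est.oob_positive_rate_,
        },
        index=pd.Index(ids, name="receptor"),
    )
    return out.loc[ids[len(seed_positives):]]


def derive_labels(
    rates: pd.DataFrame,
    pos_threshold: float = 0.7,
    neg_threshold: float = 0.8,
    accept_list=None,
    seed_positives=(),
    known_negatives=(),
) -> LabelSet:
    """Threshold PU rates into a four-way label set.

    Candidate positives have ``positive_rate > pos_threshold`` and must
    appear in ``accept_list`` (the stand-in for independent verification;
    ``None`` accepts all). Inferred negatives have
    ``1 - positive_rate > neg_threshold``. Seed positives are always
    positive; known negatives are kept out of the inferred set. Points
    with undefined rates stay unlabeled.
    """
    for name, th in (("pos_threshold", pos_threshold), ("neg_threshold", neg_threshold)):
        if not 0.5 < th <= 1.0:
            raise ValueError(f"{name} must be in (0.5, 1], got {th}")
    seed_positives = frozenset(seed_positives)
    known_negatives = frozenset(known_negatives) - seed_positives
    accept = None if accept_list is None else frozenset(accept_list)

    rate = rates["positive_rate"]
    defined = rate.notna()
    high = frozenset(rates.index[defined & (rate > pos_threshold)])
    low = frozenset(rates.index[defined & ((1.0 - rate) > neg_threshold)])

    candidates = high if accept is None else (high & accept)
    positives = seed_positives | (candidates - known_negatives)
    negatives_inferred = low - positives - known_negatives
    unlabeled = (frozenset(rates.index) | seed_positives) - positives - negatives_inferred - known_negatives
    return LabelSet(
        positives=positives,
        negatives_inferred=negatives_inferred,
        negatives_known=known_negatives,
        unlabeled=unlabeled,
    )
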