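"""Feature ranking by recursive feature elimination with a linear SVM.

SVM-RFE (Guyon et al.) trains a linear SVM, scores each surviving
feature by its squared weight, discards the lowest-scoring feature(s),
and repeats until no feature is left; the importance ranking is the
reverse of the removal order.  For multi-class problems the classifier
is the one-vs-one ensemble of binary machines (libsvm's scheme) and a
feature's criterion is the sum of its squared weight over all binary
machines.

Determinism contract: the libsvm solver is deterministic for a fixed
dataset, the criterion is permutation-invariant over samples, and ties
are broken by removing the feature with the larger flat index first, so
two runs with identical inputs and settings produce identical rankings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted, check_X_y

DEFAULT_COST = 1.0
DEFAULT_STEP = 1
DEFAULT_TOP_K = 120


@dataclass(frozen=True)
class IterationRecord:
    """Features removed in one RFE iteration, worst first."""

    removed: tuple[int, ...]
    criteria: tuple[float, ...]


@dataclass
class RankedFeatures:
    """SVM-RFE importance ordering of feature indices.

    ``order`` lists flat feature indices most-important first and is a
    permutation of ``range(n_features)``; ``elimination_log`` holds one
    record per RFE iteration and reconstructs ``order`` exactly
    (reversed concatenation of the removal sequence).
    """

    order: np.ndarray
    elimination_log: list[IterationRecord]
    settings: dict = field(default_factory=dict)
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        d = len(self.order)
        if sorted(self.order) != list(range(d)):
            raise ValueError("order is not a permutation of the feature indices")

    def top_k(self, k: int) -> np.ndarray:
        if not 1 <= k <= len(self.order):
            raise ValueError(f"k={k} outside [1, {len(self.order)}]")
        return self.order[:k]

    def to_frame(self) -> pd.DataFrame:
        names = (
            self.feature_names
            if self.feature_names is not None
            else [str(i) for i in range(len(self.order))]
        )
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.order) + 1),
                "feature_index": self.order,
                "feature_name": [names[i] for i in self.order],
            }
        )


def _validate_labels(y: np.ndarray, min_class_size: int = 2) -> None:
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes, got 1")
    if counts.min() < min_class_size:
        bad = classes[counts < min_class_size].tolist()
        raise ValueError(
            f"every class needs >= {min_class_size} samples; offending: {bad}"
        )


def _rfe_order(
    X: np.ndarray, y: np.ndarray, cost: float, step: int
) -> tuple[np.ndarray, list[IterationRecord]]:
    n_features = X.shape[1]
    remaining = np.arange(n_features)
    removal_sequence: list[int] = []
    log: list[IterationRecord] = []
    while remaining.size:
        svc = SVC(kernel="linear", C=cost)
        svc.fit(X[:, remaining], y)
        criteria = np.square(svc.coef_).sum(axis=0)
        n_drop = min(step, remaining.size)
        # ascending criterion; ties resolved toward the larger flat index
        order = np.lexsort((-remaining, criteria))
        drop = order[:n_drop]
        log.append(
            IterationRecord(
                removed=tuple(int(remaining[i]) for i in drop),
                criteria=tuple(float(criteria[i]) for i in drop),
            )
        )
        removal_sequence.extend(int(remaining[i]) for i in drop)
        remaining = np.delete(remaining, drop)
    return np.asarray(removal_sequence[::-1], dtype=int), log


def rank_features_rfe(
    features: pd.DataFrame | np.ndarray,
    labels,
    cost: float = DEFAULT_COST,
    step: int = DEFAULT_STEP,
    min_class_size: int = 2,
) -> RankedFeatures:
    """Rank all features by SVM-RFE importance, most-important first.

    ``step`` features are eliminated per iteration (1 is Guyon's
    original schedule; larger values trade ranking resolution for
    speed).  Requires >= 2 classes with >= ``min_class_size`` samples
    each.
    """
    if step < 1:
        raise ValueError(f"step must be >= 1, got {step}")
    if cost <= 0:
        raise ValueError(f"cost must be positive, got {cost}")
    names = (
        list(features.columns) if isinstance(features, pd.DataFrame) else None
    )
    X, y = check_X_y(np.asarray(features, dtype=float), np.asarray(labels))
    _validate_labels(y, min_class_size)
    order, log = _rfe_order(X, y, cost, step)
    return RankedFeatures(
        order=order,
        elimination_log=log,
        settings={"cost": cost, "step": step, "n_features": X.shape[1]},
        feature_names=names,
    )


def select_top_k(
    ranked: RankedFeatures, features: pd.DataFrame, k: int
) -> pd.DataFrame:
    """Sub-matrix of the ``k`` highest-ranked columns, rows untouched."""
    idx = ranked.top_k(k)
    if isinstance(features, pd.DataFrame):
        return features.iloc[:, idx]
    return np.asarray(features)[:, idx]


class SVMRFESelector(SelectorMixin, BaseEstimator):
    """Scikit-learn selector wrapping linear SVM-RFE.

    Parameters
    ----------
    n_features_to_select:
        How many top-ranked features :meth:`transform` keeps (the
        operating point of the published pipeline is 120).
    cost:
        Soft-margin penalty C of the linear SVM used for ranking.
    step:
        Features eliminated per RFE iteration.
    min_class_size:
        Smallest class size accepted by :meth:`fit`; lowered to 1 by
        the jackknife when singleton classes are explicitly allowed.

    Attributes
    ----------
    ranking_order_:
        Permutation of feature indices, most important first.
    ranking_:
        Strict 1-based rank per feature (1 = most important).
    elimination_log_:
        Per-iteration removal records.
    support_:
        Boolean mask of the selected top-k features.
    """

    def __init__(
        self,
        n_features_to_select: int = DEFAULT_TOP_K,
        cost: float = DEFAULT_COST,
        step: int = DEFAULT_STEP,
        min_class_size: int = 2,
    ):
        self.n_features_to_select = n_features_to_select
        self.cost = cost
        self.step = step
        self.min_class_size = min_class_size

    def fit(self, X, y) -> "SVMRFESelector":
        ranked = rank_features_rfe(
            X, y, cost=self.cost, step=self.step,
            min_class_size=self.min_class_size,
        )
        d = len(ranked.order)
        k = self.n_features_to_select
        if not 1 <= k <= d:
            raise ValueError(f"n_features_to_select={k} outside [1, {d}]")
        self.n_features_in_ = d
        self.ranking_order_ = ranked.order
        self.elimination_log_ = ranked.elimination_log
        self.ranked_ = ranked
        ranking = np.empty(d, dtype=int)
        ranking[ranked.order] = np.arange(1, d + 1)
        self.ranking_ = ranking
        support = np.zeros(d, dtype=bool)
        support[ranked.order[:k]] = True
        self.support_ = support
        return self

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_
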