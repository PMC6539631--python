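"""Linear-SVM classification and jackknife (leave-one-out) evaluation.

Performance is reported per subcellular location ``j`` as

    Sens_j = TP_j / (TP_j + FN_j)
    Spec_j = TN_j / (TN_j + FP_j)
    MCC_j  = (TP_j TN_j - FP_j FN_j)
             / sqrt((TP_j+FP_j)(TP_j+FN_j)(TN_j+FP_j)(TN_j+FN_j))

with overall accuracy OA = sum_j TP_j / n, all derived from one
aggregated confusion matrix of the jackknife run.  Any metric whose
denominator is zero is reported as 0 and flagged, so sweep tables stay
total.

Two evaluation modes are provided.  In ``paper`` mode the RFE ranking
and top-k selection are computed once on the full dataset before the
leave-one-out loop — a single ranked list per dataset, from which top-K
curves can be drawn, at the price of selection leakage into each fold.
``leak_free`` mode recomputes ranking and selection inside every fold on
the n-1 training samples and is the honest protocol for new
applications.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import LeaveOneOut, cross_val_predict
from sklearn.pipeline import Pipeline
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .encoding import PopmTrigramEncoder
from .selection import DEFAULT_COST, DEFAULT_STEP, DEFAULT_TOP_K, SVMRFESelector

MODES = ("paper", "leak_free")


@dataclass(frozen=True)
class ConfusionMatrix:
    """C x C count matrix; rows are true classes, columns predictions."""

    counts: np.ndarray
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        c = len(self.class_names)
        if self.counts.shape != (c, c):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{c} class names"
            )
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.class_names), columns=list(self.class_names)
        )


@dataclass
class EvaluationReport:
    """Aggregated confusion matrix with per-class Sens/Spec/MCC and OA."""

    confusion: ConfusionMatrix
    per_class: pd.DataFrame  # columns: sens, spec, mcc, n, zero_denominator
    oa: float
    settings: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "class_names": list(self.confusion.class_names),
            "confusion": self.confusion.counts.tolist(),
            "per_class": {
                cls: {
                    "sens": float(row["sens"]),
                    "spec": float(row["spec"]),
                    "mcc": float(row["mcc"]),
                    "n": int(row["n"]),
                    "zero_denominator": bool(row["zero_denominator"]),
                }
                for cls, row in self.per_class.iterrows()
            },
            "oa": float(self.oa),
            "settings": self.settings,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    def to_text(self) -> str:
        """Human-readable table: Location, Sens %, Spec %, MCC, OA %."""
        lines = [
            f"{'Location':<12}{'Sens (%)':>10}{'Spec (%)':>10}{'MCC':>8}",
        ]
        for cls, row in self.per_class.iterrows():
            lines.append(
                f"{cls:<12}{100 * row['sens']:>10.1f}"
                f"{100 * row['spec']:>10.1f}{row['mcc']:>8.3f}"
            )
        lines.append(f"{'OA (%)':<12}{100 * self.oa:>10.1f}")
        return "\n".join(lines)


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return num / den, False


def compute_metrics(confusion: ConfusionMatrix) -> EvaluationReport:
    """Per-class Sens/Spec/MCC and OA from a confusion matrix.

    TP/FN/FP/TN for class ``j`` come from the one-vs-rest collapse of
    the matrix; zero-denominator metrics are 0 with the
    ``zero_denominator`` flag set.
    """
    counts = confusion.counts.astype(np.int64)
    total = counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    rows = []
    for j, cls in enumerate(confusion.class_names):
        tp = counts[j, j]
        fn = counts[j, :].sum() - tp
        fp = counts[:, j].sum() - tp
        tn = total - tp - fn - fp
        sens, f1 = _safe_div(tp, tp + fn)
        spec, f2 = _safe_div(tn, tn + fp)
        mcc_den = float((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        mcc, f3 = _safe_div(float(tp * tn - fp * fn), np.sqrt(mcc_den))
        rows.append(
            {
                "sens": sens,
                "spec": spec,
                "mcc": mcc,
                "n": int(tp + fn),
                "zero_denominator": f1 or f2 or f3,
            }
        )
    per_class = pd.DataFrame(rows, index=list(confusion.class_names))
    oa = float(np.trace(counts) / total)
    return EvaluationReport(confusion=confusion, per_class=per_class, oa=oa)


def _class_order(labels: np.ndarray) -> list:
    """Distinct labels in first-appearance order."""
    seen: dict = {}
    for lab in labels:
        seen.setdefault(lab, None)
    return list(seen)


def train_svm(features, labels, cost: float = DEFAULT_COST) -> SVC:
    """Fit a linear-kernel one-vs-one SVM (libsvm)."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.size == 0:
        raise ValueError("empty feature matrix")
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes to train")
    return SVC(kernel="linear", C=cost).fit(X, y)


def _validate_jackknife_inputs(y: np.ndarray, allow_singletons: bool) -> None:
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if not allow_singletons and counts.min() < 2:
        bad = classes[counts < 2].tolist()
        raise ValueError(
            f"classes with a single member have no same-class training "
            f"example in their fold: {bad} (pass allow_singletons=True "
            f"to override)"
        )


def jackknife_evaluate(
    features,
    labels,
    k: int = DEFAULT_TOP_K,
    mode: str = "paper",
    cost: float = DEFAULT_COST,
    step: int = DEFAULT_STEP,
    seed: int = 0,
    allow_singletons: bool = False,
    ranked=None,
) -> EvaluationReport:
    """Leave-one-out evaluation of the top-``k`` tri-gram SVM.

    ``mode='paper'`` ranks features once on the full matrix before the
    loop; ``mode='leak_free'`` re-ranks inside each fold.  ``ranked``
    may pass a precomputed :class:`~popmgram.selection.RankedFeatures`
    to reuse in paper mode (e.g. during a top-K sweep).  Fold order is
    the dataset order; the pipeline is deterministic, so identical
    inputs give identical reports.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and labels disagree on sample count")
    _validate_jackknife_inputs(y, allow_singletons)
    class_names = _class_order(y)
    if X.shape[0] < len(class_names) + 1:
        raise ValueError("need at least one more sample than classes")

    min_class_size = 1 if allow_singletons else 2
    if mode == "paper":
        if ranked is None:
            selector = SVMRFESelector(
                n_features_to_select=k, cost=cost, step=step,
                min_class_size=min_class_size,
            ).fit(X, y)
            Xk = selector.transform(X)
        else:
            Xk = X[:, ranked.top_k(k)]
        pred = cross_val_predict(
            SVC(kernel="linear", C=cost), Xk, y, cv=LeaveOneOut()
        )
    else:
        pipe = Pipeline(
            [
                ("select", SVMRFESelector(n_features_to_select=k, cost=cost,
                                          step=step, min_class_size=1)),
                ("svm", SVC(kernel="linear", C=cost)),
            ]
        )
        pred = cross_val_predict(pipe, X, y, cv=LeaveOneOut())

    counts = _sk_confusion(y, pred, labels=class_names)
    report = compute_metrics(
        ConfusionMatrix(counts=counts, class_names=tuple(map(str, class_names)))
    )
    report.settings = {
        "k": k,
        "cost": cost,
        "step": step,
        "mode": mode,
        "seed": seed,
        "n_samples": int(X.shape[0]),
    }
    return report


def sweep_top_k(
    features,
    labels,
    k_values=tuple(range(10, 301, 10)),
    mode: str = "paper",
    cost: float = DEFAULT_COST,
    step: int = DEFAULT_STEP,
    seed: int = 0,
) -> pd.DataFrame:
    """Jackknife OA as a function of the number of selected features.

    Returns a ``(k, oa)`` table; ``.attrs['best_k']`` holds the argmax
    (smallest k on ties).  In paper mode the ranking is computed once
    and reused across the whole grid, mirroring a single ranked list
    per dataset.
    """
    k_values = list(k_values)
    if not k_values:
        raise ValueError("empty k grid")
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    ranked = None
    if mode == "paper":
        from .selection import rank_features_rfe

        ranked = rank_features_rfe(X, y, cost=cost, step=step)
    rows = []
    for k in k_values:
        report = jackknife_evaluate(
            X, y, k=k, mode=mode, cost=cost, step=step, seed=seed, ranked=ranked
        )
        rows.append({"k": k, "oa": report.oa})
    table = pd.DataFrame(rows)
    best = table.loc[table["oa"].idxmax()]  # idxmax takes the first max
    table.attrs["best_k"] = int(best["k"])
    return table


class PopmTrigramClassifier(ClassifierMixin, BaseEstimator):
    """End-to-end subcellular-location predictor.

    Chains the POPM tri-gram encoder, SVM-RFE top-k selection and a
    linear one-vs-one SVM into a single scikit-learn estimator whose
    ``X`` is a list of residue strings.

    Parameters
    ----------
    k: number of top-ranked tri-gram features kept (default 120).
    cost: linear-SVM penalty C shared by the ranking and the final
        classifier.
    step: RFE elimination step.
    standardize: z-score the tri-gram features before selection.
    """

    def __init__(
        self,
        k: int = DEFAULT_TOP_K,
        cost: float = DEFAULT_COST,
        step: int = DEFAULT_STEP,
        standardize: bool = False,
    ):
        self.k = k
        self.cost = cost
        self.step = step
        self.standardize = standardize

    def fit(self, X, y) -> "PopmTrigramClassifier":
        self.encoder_ = PopmTrigramEncoder(standardize=self.standardize).fit(X)
        features = self.encoder_.transform(X)
        self.selector_ = SVMRFESelector(
            n_features_to_select=self.k, cost=self.cost, step=self.step
        ).fit(features, y)
        self.svm_ = train_svm(
            self.selector_.transform(features), y, cost=self.cost
        )
        self.classes_ = self.svm_.classes_
        return self

    def predict(self, X):
        check_is_fitted(self, "svm_")
        features = self.encoder_.transform(X)
        return self.svm_.predict(self.selector_.transform(features))

    def decision_function(self, X):
        check_is_fitted(self, "svm_")
        features = self.encoder_.transform(X)
        return self.svm_.decision_function(self.selector_.transform(features))
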