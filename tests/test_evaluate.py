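"""Confusion-matrix metrics, jackknife evaluation and the top-K sweep."""

import numpy as np
import pandas as pd
import pytest
from sklearn.svm import SVC

from popmgram.evaluate import (
    ConfusionMatrix,
    PopmTrigramClassifier,
    compute_metrics,
    jackknife_evaluate,
    sweep_top_k,
    train_svm,
)


def tally_oracle(counts: np.ndarray, j: int) -> tuple[int, int, int, int]:
    """Independent one-vs-rest tally: expand the confusion matrix into
    (true, pred) pairs and count TP/FN/FP/TN for class j by brute force."""
    pairs = [
        (t, p)
        for t in range(counts.shape[0])
        for p in range(counts.shape[1])
        for _ in range(counts[t, p])
    ]
    tp = sum(1 for t, p in pairs if t == j and p == j)
    fn = sum(1 for t, p in pairs if t == j and p != j)
    fp = sum(1 for t, p in pairs if t != j and p == j)
    tn = sum(1 for t, p in pairs if t != j and p != j)
    return tp, fn, fp, tn


def test_hand_computed_binary_case():
    # TP=8, FN=2, TN=85, FP=5
    cm = ConfusionMatrix(
        counts=np.array([[8, 2], [5, 85]]), class_names=("pos", "neg")
    )
    report = compute_metrics(cm)
    row = report.per_class.loc["pos"]
    assert row["sens"] == pytest.approx(0.800)
    assert row["spec"] == pytest.approx(85 / 90)
    assert row["mcc"] == pytest.approx(670 / np.sqrt(13 * 10 * 90 * 87))
    assert report.oa == pytest.approx(93 / 100)


def test_perfect_diagonal_limit():
    cm = ConfusionMatrix(
        counts=np.diag([5, 7, 9]), class_names=("a", "b", "c")
    )
    report = compute_metrics(cm)
    assert (report.per_class[["sens", "spec", "mcc"]] == 1.0).all().all()
    assert report.oa == 1.0
    assert not report.per_class["zero_denominator"].any()


def test_degenerate_all_into_one_class():
    # balanced 10+10, everything predicted as the first class
    cm = ConfusionMatrix(
        counts=np.array([[10, 0], [10, 0]]), class_names=("a", "b")
    )
    report = compute_metrics(cm)
    a = report.per_class.loc["a"]
    assert a["sens"] == 1.0 and a["spec"] == 0.0 and a["mcc"] == 0.0
    assert a["zero_denominator"]
    b = report.per_class.loc["b"]
    assert b["sens"] == 0.0 and b["zero_denominator"]


def test_metrics_agree_with_tally_oracle_on_random_matrices():
    rng = np.random.default_rng(11)
    for _ in range(50):
        c = int(rng.integers(2, 7))
        counts = rng.integers(0, 41, size=(c, c))
        if counts.sum() == 0:
            counts[0, 0] = 1
        cm = ConfusionMatrix(
            counts=counts, class_names=tuple(f"c{i}" for i in range(c))
        )
        report = compute_metrics(cm)
        assert report.oa == pytest.approx(np.trace(counts) / counts.sum())
        for j, cls in enumerate(cm.class_names):
            tp, fn, fp, tn = tally_oracle(counts, j)
            row = report.per_class.loc[cls]
            if tp + fn:
                assert row["sens"] == pytest.approx(tp / (tp + fn))
            if tn + fp:
                assert row["spec"] == pytest.approx(tn / (tn + fp))
            den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
            if den:
                assert row["mcc"] == pytest.approx(
                    (tp * tn - fp * fn) / np.sqrt(den)
                )


def test_empty_confusion_rejected():
    cm = ConfusionMatrix(counts=np.zeros((2, 2), dtype=int), class_names=("a", "b"))
    with pytest.raises(ValueError, match="empty"):
        compute_metrics(cm)


def test_train_svm_separable_cases(small_features):
    X4 = np.array([[0.0, 0], [0, 1], [10, 0], [10, 1]])
    y4 = ["a", "a", "b", "b"]
    assert train_svm(X4, y4).score(X4, y4) == 1.0
    features, labels = small_features
    svc = train_svm(features.values, labels)
    assert svc.score(features.values, labels) >= 0.95
    with pytest.raises(ValueError):
        train_svm(X4, ["a"] * 4)
    with pytest.raises(ValueError):
        train_svm(np.empty((0, 3)), [])


def test_jackknife_confusion_totals_and_determinism(small_features):
    features, labels = small_features
    kwargs = dict(k=50, mode="paper", step=200, seed=0)
    a = jackknife_evaluate(features, labels, **kwargs)
    assert a.confusion.total == len(labels)
    assert list(a.confusion.class_names) == ["A", "B", "C"]
    b = jackknife_evaluate(features, labels, **kwargs)
    np.testing.assert_array_equal(a.confusion.counts, b.confusion.counts)
    assert a.to_dict() == b.to_dict()


def test_jackknife_separable_perfect_both_modes(small_features):
    features, labels = small_features
    paper = jackknife_evaluate(features, labels, k=50, mode="paper", step=500)
    leak_free = jackknife_evaluate(
        features, labels, k=50, mode="leak_free", step=500
    )
    assert paper.oa >= 0.95
    # leakage cannot be required on an easy problem
    assert leak_free.oa >= paper.oa - 0.05


def test_jackknife_rejects_singleton_classes(small_features):
    features, labels = small_features
    labels = np.array(labels, dtype=object).copy()
    labels[0] = "lonely"
    with pytest.raises(ValueError, match="lonely"):
        jackknife_evaluate(features, labels, k=10, step=500)
    report = jackknife_evaluate(
        features, labels, k=10, step=500, allow_singletons=True
    )
    assert report.confusion.total == len(labels)


def test_jackknife_rejects_bad_mode(small_features):
    features, labels = small_features
    with pytest.raises(ValueError, match="mode"):
        jackknife_evaluate(features, labels, mode="bootstrap")


def test_sweep_returns_curve_and_best_k(small_features):
    features, labels = small_features
    table = sweep_top_k(features, labels, k_values=[20, 120], step=500)
    assert list(table["k"]) == [20, 120]
    assert ((table["oa"] >= 0) & (table["oa"] <= 1)).all()
    assert table.attrs["best_k"] in (20, 120)
    with pytest.raises(ValueError, match="empty"):
        sweep_top_k(features, labels, k_values=[])


def test_report_serialization_roundtrip(small_features):
    features, labels = small_features
    report = jackknife_evaluate(features, labels, k=30, step=500)
    data = report.to_dict()
    assert data["oa"] == report.oa
    assert set(data["per_class"]) == {"A", "B", "C"}
    text = report.to_text()
    assert "OA (%)" in text and "Location" in text


def test_end_to_end_classifier_memorizes_separable(small_dataset):
    seqs = [r.sequence for r in small_dataset.records]
    labels = small_dataset.label_array()
    clf = PopmTrigramClassifier(k=50, step=500).fit(seqs, labels)
    assert list(clf.predict(seqs)) == list(labels)
    assert set(clf.classes_) == {"A", "B", "C"}
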