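"""Metric correctness against hand-coded confusion-table arithmetic and
closed forms, plus distributional sanity properties."""

import itertools
import math

import numpy as np
import pytest
from sklearn.metrics import matthews_corrcoef

from ifselect import (
    acc,
    confusion,
    evaluate,
    macro_f1,
    mcc,
    weighted_f1,
    weighted_f1_classic,
)


# ---------------------------------------------------------------------------
# independent oracle: plain-python confusion-table arithmetic

def oracle_metrics(true, pred, classes):
    n = len(true)
    tp = {c: sum(1 for t, p in zip(true, pred) if t == c and p == c)
          for c in classes}
    fp = {c: sum(1 for t, p in zip(true, pred) if t != c and p == c)
          for c in classes}
    fn = {c: sum(1 for t, p in zip(true, pred) if t == c and p != c)
          for c in classes}
    w = {c: (tp[c] + fn[c]) / n for c in classes}
    prec = {c: tp[c] / (tp[c] + fp[c]) if tp[c] + fp[c] else 0.0
            for c in classes}
    rec = {c: tp[c] / (tp[c] + fn[c]) if tp[c] + fn[c] else 0.0
           for c in classes}
    pw = sum(w[c] * prec[c] for c in classes)
    rw = sum(w[c] * rec[c] for c in classes)
    wf1 = 2 * pw * rw / (pw + rw) if pw + rw else 0.0
    f1 = {c: (2 * prec[c] * rec[c] / (prec[c] + rec[c])
              if prec[c] + rec[c] else 0.0) for c in classes}
    present = [c for c in classes if tp[c] + fp[c] + fn[c] > 0]
    mf1 = sum(f1[c] for c in present) / len(present) if present else 0.0
    a = sum(1 for t, p in zip(true, pred) if t == p) / n
    return wf1, mf1, a


def oracle_mcc_indicator(true, pred, classes):
    n = len(true)
    X = [[1.0 if t == c else 0.0 for c in classes] for t in true]
    Y = [[1.0 if p == c else 0.0 for c in classes] for p in pred]
    mx = [sum(col) / n for col in zip(*X)]
    my = [sum(col) / n for col in zip(*Y)]
    cxy = sum((X[i][k] - mx[k]) * (Y[i][k] - my[k])
              for i in range(n) for k in range(len(classes)))
    cxx = sum((X[i][k] - mx[k]) ** 2
              for i in range(n) for k in range(len(classes)))
    cyy = sum((Y[i][k] - my[k]) ** 2
              for i in range(n) for k in range(len(classes)))
    if cxx == 0 or cyy == 0:
        return 0.0
    return cxy / math.sqrt(cxx * cyy)


CLASSES = ["a", "b", "c"]


def test_confusion_counts_by_hand():
    s = confusion(["a", "a", "b"], ["a", "b", "b"], ["a", "b"])
    assert s.tp.tolist() == [1, 1]
    assert s.fn.tolist() == [1, 0]
    assert s.fp.tolist() == [0, 1]
    assert s.n == 3


def test_confusion_perfect_and_single_class():
    s = confusion(["a", "b"], ["a", "b"], ["a", "b"])
    assert s.fp.sum() == 0 and s.fn.sum() == 0
    s1 = confusion(["a", "a"], ["a", "a"], ["a", "b"])
    assert s1.w.tolist() == [1.0, 0.0]


def test_confusion_errors():
    with pytest.raises(ValueError, match="length"):
        confusion(["a"], ["a", "b"], ["a", "b"])
    with pytest.raises(ValueError, match="class_names"):
        confusion(["a"], ["z"], ["a", "b"])


def test_weighted_f1_six_sample_example():
    true = ["a", "a", "a", "b", "b", "c"]
    pred = ["a", "a", "b", "b", "c", "c"]
    s = confusion(true, pred, CLASSES)
    expected, _, _ = oracle_metrics(true, pred, CLASSES)
    assert weighted_f1(s) == pytest.approx(expected)
    assert weighted_f1(s) == pytest.approx(12 / 17)  # frozen from the oracle


def test_weighted_f1_majority_predictor_closed_form():
    true = ["a"] * 5 + ["b"] * 5
    pred = ["a"] * 10
    s = confusion(true, pred, ["a", "b"])
    # weighted precision 0.25, weighted recall 0.5 -> harmonic mean 1/3
    assert weighted_f1(s) == pytest.approx(1 / 3)


def test_weighted_f1_perfect_is_one():
    true = ["a", "b", "b", "c", "c", "c"]
    s = confusion(true, true, CLASSES)
    assert weighted_f1(s) == pytest.approx(1.0)
    assert macro_f1(s) == pytest.approx(1.0)


def test_weighted_f1_differs_from_classic_variant():
    true = ["a"] * 8 + ["b"] * 2
    pred = ["a"] * 6 + ["b"] * 2 + ["b", "a"]
    s = confusion(true, pred, ["a", "b"])
    assert weighted_f1(s) != pytest.approx(weighted_f1_classic(s))


def test_acc_basics():
    assert acc(["a", "b"], ["b", "a"]) == 0.0
    assert acc(["a", "b"], ["a", "b"]) == 1.0


def test_macro_equals_weighted_average_for_balanced_classes():
    rng = np.random.default_rng(0)
    true = ["a"] * 30 + ["b"] * 30 + ["c"] * 30
    pred = rng.choice(CLASSES, size=90).tolist()
    s = confusion(true, pred, CLASSES)
    assert macro_f1(s) == pytest.approx(weighted_f1_classic(s))
    # equal weights collapse the weighted precision/recall to macro averages
    assert np.dot(s.w, s.precision()) == pytest.approx(s.precision().mean())


def test_mcc_binary_matches_closed_form_exhaustively():
    for tp, tn, fp, fn in itertools.product(range(6), repeat=4):
        true = ["p"] * (tp + fn) + ["n"] * (tn + fp)
        pred = (["p"] * tp + ["n"] * fn + ["n"] * tn + ["p"] * fp)
        if not true:
            continue
        got = mcc(true, pred, ["n", "p"])
        denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        expected = ((tp * tn - fp * fn) / math.sqrt(denom)) if denom else 0.0
        assert got == pytest.approx(expected, abs=1e-12), (tp, tn, fp, fn)


def test_mcc_specific_binary_table():
    tp, tn, fp, fn = 45, 40, 10, 5
    true = ["p"] * (tp + fn) + ["n"] * (tn + fp)
    pred = ["p"] * tp + ["n"] * fn + ["n"] * tn + ["p"] * fp
    expected = (tp * tn - fp * fn) / math.sqrt(
        (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    )
    assert mcc(true, pred, ["n", "p"]) == pytest.approx(expected)


def test_mcc_cyclic_shift_is_negative():
    true = (CLASSES * 20)
    shift = {"a": "b", "b": "c", "c": "a"}
    pred = [shift[t] for t in true]
    got = mcc(true, pred, CLASSES)
    assert got < 0
    assert got == pytest.approx(oracle_mcc_indicator(true, pred, CLASSES))


def test_mcc_matches_sklearn_on_random_multiclass_draws(rng):
    for _ in range(200):
        n = int(rng.integers(4, 40))
        true = rng.choice(CLASSES, size=n).tolist()
        pred = rng.choice(CLASSES, size=n).tolist()
        got = mcc(true, pred, CLASSES)
        assert got == pytest.approx(
            matthews_corrcoef(true, pred), abs=1e-10
        )


def test_metric_bounds_on_random_draws(rng):
    for _ in range(300):
        n = int(rng.integers(2, 30))
        true = rng.choice(CLASSES, size=n).tolist()
        pred = rng.choice(CLASSES, size=n).tolist()
        rep = evaluate(true, pred, CLASSES)
        assert 0.0 <= rep.weighted_f1 <= 1.0
        assert 0.0 <= rep.macro_f1 <= 1.0
        assert 0.0 <= rep.acc <= 1.0
        assert -1.0 <= rep.mcc <= 1.0


def test_permutation_null_centers_near_zero(rng):
    true = ["a"] * 30 + ["b"] * 40 + ["c"] * 50
    mccs, f1s = [], []
    chance = sum((np.array([30, 40, 50]) / 120) ** 2)
    for _ in range(300):
        pred = rng.permutation(true).tolist()
        mccs.append(mcc(true, pred, CLASSES))
        f1s.append(weighted_f1(confusion(true, pred, CLASSES)))
    assert abs(np.mean(mccs)) < 0.02
    assert abs(np.mean(f1s) - chance) < 0.02


def test_degenerate_all_wrong_single_column():
    # constant prediction of a class absent from truth
    got = mcc(["a", "a"], ["b", "b"], ["a", "b"])
    assert got == 0.0
    s = confusion(["a", "a"], ["b", "b"], ["a", "b"])
    assert weighted_f1(s) == 0.0
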