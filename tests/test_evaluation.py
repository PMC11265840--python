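"""Evaluation metrics against independent oracles."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import rankdata

from her2pss.evaluation import (
    GROUPINGS,
    adjacent_pair_accuracy,
    averaged_confident_probs,
    confusion_matrix,
    grouped_roc_auc,
    overall_accuracy,
    per_class_specificity,
)
from her2pss.inference import make_record


# -- confusion matrix ------------------------------------------------------


def test_perfect_predictions_diagonal():
    true = ["0", "1+", "2+", "3+", "2+"]
    cm = confusion_matrix(true, true)
    assert np.all(cm == np.diag(np.diag(cm)))
    assert overall_accuracy(cm) == 1.0


def test_single_misclassification():
    cm = confusion_matrix(["2+"], ["3+"])
    assert cm[2, 3] == 1 and cm.sum() == 1
    assert overall_accuracy(cm) == 0.0


def test_confusion_matrix_matches_nested_loop_tally(rng):
    true = rng.integers(0, 4, 200)
    pred = rng.integers(0, 4, 200)
    cm = confusion_matrix(true, pred)
    brute = np.zeros((4, 4), dtype=int)
    for t, p in zip(true, pred):
        brute[t, p] += 1
    np.testing.assert_array_equal(cm, brute)


def test_length_mismatch_rejected():
    with pytest.raises(ValueError):
        confusion_matrix(["0", "1+"], ["0"])


# -- specificity -----------------------------------------------------------


def _specificity_oracle(cm):
    """One-vs-rest binarize-and-count, independent of the marginal formula."""
    total = cm.sum()
    out = []
    for i in range(4):
        tn = fp = 0
        for t in range(4):
            for p in range(4):
                if t != i and p != i:
                    tn += cm[t, p]
                if t != i and p == i:
                    fp += cm[t, p]
        out.append(tn / (tn + fp) if (tn + fp) else np.nan)
    return np.array(out)


def test_perfect_specificity():
    cm = np.diag([5, 6, 7, 8])
    np.testing.assert_allclose(per_class_specificity(cm), np.ones(4))


def test_all_predicted_class0_balanced_truth():
    cm = np.zeros((4, 4), dtype=int)
    cm[:, 0] = 10
    spec = per_class_specificity(cm)
    assert spec[0] == 0.0
    np.testing.assert_allclose(spec[1:], 1.0)


def test_specificity_matches_binarization_oracle(rng):
    for _ in range(100):
        cm = rng.integers(0, 20, (4, 4))
        got = per_class_specificity(cm)
        want = _specificity_oracle(cm)
        np.testing.assert_allclose(got, want, rtol=1e-12)


def test_specificity_marginal_identity(rng):
    """TP + FP + FN + TN == total for every class."""
    cm = rng.integers(0, 30, (4, 4))
    total = cm.sum()
    for i in range(4):
        tp = cm[i, i]
        fp = cm[:, i].sum() - tp
        fn = cm[i, :].sum() - tp
        tn = total - tp - fp - fn
        assert tp + fp + fn + tn == total


def test_degenerate_specificity_flagged():
    cm = np.zeros((4, 4), dtype=int)
    cm[1, 1] = 4  # every core truly class 1+: no true negatives for class 1+
    with pytest.warns(RuntimeWarning):
        spec = per_class_specificity(cm)
    assert np.isnan(spec[1])


# -- adjacent-pair accuracy ------------------------------------------------


def test_pair_accuracy_trivial_cases():
    true = ["0", "1+", "0", "1+"]
    assert adjacent_pair_accuracy(true, true, (0, 1)) == 1.0
    pred = ["1+", "2+", "1+", "2+"]
    assert adjacent_pair_accuracy(["0"] * 4, pred, (0, 1)) == 0.0


def test_pair_accuracy_out_of_pair_prediction_is_error():
    true = ["1+", "1+", "2+", "2+", "2+", "1+", "2+", "1+", "2+", "1+"]
    pred = ["1+", "2+", "2+", "3+", "2+", "1+", "2+", "1+", "0", "1+"]
    # manual tally: correct iff pred == true; "3+" and "0" are errors
    correct = sum(t == p for t, p in zip(true, pred))
    assert adjacent_pair_accuracy(true, pred, (1, 2)) == pytest.approx(correct / 10)


def test_pair_accuracy_non_adjacent_rejected():
    with pytest.raises(ValueError):
        adjacent_pair_accuracy(["0"], ["0"], (0, 2))


def test_pair_accuracy_empty_subset_flagged():
    with pytest.warns(RuntimeWarning):
        out = adjacent_pair_accuracy(["3+"], ["3+"], (0, 1))
    assert np.isnan(out)


def test_pair_subsets_partition(rng):
    """Each core's true label belongs to 1 or 2 adjacent pairs; subset
    sizes add up accordingly."""
    true = rng.integers(0, 4, 100)
    sizes = [
        int(np.isin(true, [a, a + 1]).sum()) for a in (0, 1, 2)
    ]
    counts = np.bincount(true, minlength=4)
    assert sizes[0] == counts[0] + counts[1]
    assert sizes[1] == counts[1] + counts[2]
    assert sizes[2] == counts[2] + counts[3]
    assert sum(sizes) == len(true) + counts[1] + counts[2]


# -- averaged confident probabilities --------------------------------------


def test_averaged_probs_k1_is_most_confident():
    recs = [
        make_record(1, [0.4, 0.3, 0.2, 0.1]),
        make_record(2, [0.9, 0.05, 0.03, 0.02]),
    ]
    np.testing.assert_allclose(
        averaged_confident_probs(recs, 1), recs[1].probs, atol=1e-12
    )


def test_averaged_probs_identical_records():
    p = [0.2, 0.3, 0.4, 0.1]
    recs = [make_record(i, p) for i in range(4)]
    np.testing.assert_allclose(averaged_confident_probs(recs, 3), p, atol=1e-12)


def test_averaged_probs_top2_mean_and_simplex_noop():
    recs = [
        make_record(1, [0.7, 0.1, 0.1, 0.1]),    # margin 0.6
        make_record(2, [0.4, 0.3, 0.2, 0.1]),    # margin 0.1
        make_record(3, [0.05, 0.85, 0.05, 0.05]),  # margin 0.8
    ]
    want = np.mean([recs[2].probs, recs[0].probs], axis=0)
    got = averaged_confident_probs(recs, 2)
    np.testing.assert_allclose(got, want, atol=1e-12)
    assert got.sum() == pytest.approx(1.0, abs=1e-9)


def test_averaged_probs_empty_rejected():
    with pytest.raises(ValueError):
        averaged_confident_probs([], 1)


# -- ROC / AUC -------------------------------------------------------------


def _auc_oracle(y, score):
    """Mann-Whitney U with midrank ties, divided by n_pos * n_neg."""
    ranks = rankdata(score)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2
    return u / (n_pos * n_neg)


def _probs_from_scores(score):
    """Embed a positive-class score for grouping '012_vs_3'."""
    p = np.zeros((len(score), 4))
    p[:, 3] = score
    p[:, 0] = 1 - score
    return p


def test_roc_perfect_separation():
    true = ["0"] * 5 + ["3+"] * 5
    score = np.r_[np.linspace(0.0, 0.2, 5), np.linspace(0.8, 1.0, 5)]
    roc = grouped_roc_auc(true, _probs_from_scores(score), "012_vs_3")
    assert roc.auc == pytest.approx(1.0)
    assert roc.fpr[0] == 0.0 and roc.tpr[0] == 0.0
    assert roc.fpr[-1] == 1.0 and roc.tpr[-1] == 1.0


def test_roc_identical_scores_chance():
    true = ["0"] * 6 + ["3+"] * 6
    score = np.full(12, 0.5)
    roc = grouped_roc_auc(true, _probs_from_scores(score), "012_vs_3")
    assert roc.auc == pytest.approx(0.5)


def test_auc_equals_mann_whitney_u(rng):
    """Trapezoid AUC equals the rank-based U statistic to 1e-12, including
    tied scores, for every grouping."""
    for _ in range(100):
        n = int(rng.integers(8, 30))
        true = rng.integers(0, 4, n)
        if len(np.unique(true)) < 2:
            continue
        raw = rng.random((n, 4)) * rng.choice([1, 1, 4])
        raw = np.round(raw, 1) + 1e-9  # induce ties
        probs = raw / raw.sum(axis=1, keepdims=True)
        for grouping, positive in GROUPINGS.items():
            y = np.isin(true, list(positive))
            if y.all() or not y.any():
                continue
            roc = grouped_roc_auc([str(t) if t else "0" for t in true], probs, grouping)
            score = probs[:, sorted(positive)].sum(axis=1)
            assert roc.auc == pytest.approx(_auc_oracle(y, score), abs=1e-12)


def test_roc_monotone_curves(rng):
    true = rng.integers(0, 4, 40)
    raw = rng.random((40, 4))
    probs = raw / raw.sum(axis=1, keepdims=True)
    roc = grouped_roc_auc(true, probs, "01_vs_23")
    assert np.all(np.diff(roc.fpr) >= 0)
    assert np.all(np.diff(roc.tpr) >= 0)


def test_roc_single_class_rejected():
    with pytest.raises(ValueError):
        grouped_roc_auc(["0", "0"], np.full((2, 4), 0.25), "0_vs_rest")
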