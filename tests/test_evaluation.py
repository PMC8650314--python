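"""Metrics, ROC/PRC sweeps, and stratified K-fold cross-validation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hormobind import (ConfusionCounts, GaussianNaiveBayes, SyntheticSpec,
                       confusion, generate_dataset, kfold_cv, metrics,
                       prc_points, roc_points, stratified_folds)


def test_confusion_direct_count():
    y_true = [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]
    y_pred = [1, 1, 1, 0, 0, 0, 0, 0, 0, 1]
    c = confusion(y_true, y_pred, positive=1)
    assert (c.TP, c.FN, c.TN, c.FP) == (3, 2, 4, 1)
    assert c.total == 10


def test_confusion_degenerate_cases():
    c = confusion([1, 0], [1, 0])
    assert (c.TP, c.TN, c.FP, c.FN) == (1, 1, 0, 0)
    c = confusion([1, 0, 0], [1, 1, 1])
    assert c.TN == 0 and c.FN == 0
    with pytest.raises(ValueError, match="two distinct"):
        confusion([0, 1, 2], [0, 1, 2])


def test_metrics_hand_computed():
    """TP=3 FN=2 TN=4 FP=1 → SN .6, SP .8, ACC .7, prec .75, F1 2/3,
    MCC 10/sqrt(600)."""
    m = metrics(ConfusionCounts(TP=3, FP=1, TN=4, FN=2))
    assert m["SN"] == pytest.approx(0.6)
    assert m["SP"] == pytest.approx(0.8)
    assert m["ACC"] == pytest.approx(0.7)
    assert m["precision"] == pytest.approx(0.75)
    assert m["F1"] == pytest.approx(2 * 0.75 * 0.6 / (0.75 + 0.6))
    assert m["MCC"] == pytest.approx(10 / np.sqrt(600))


def test_metrics_perfect_and_no_skill():
    perfect = metrics(ConfusionCounts(5, 0, 5, 0))
    assert perfect["ACC"] == perfect["MCC"] == perfect["F1"] == 1.0
    none = metrics(ConfusionCounts(1, 1, 1, 1))
    assert none["ACC"] == 0.5 and none["MCC"] == 0.0


def test_metrics_zero_denominator_conventions():
    m = metrics(ConfusionCounts(TP=0, FP=0, TN=3, FN=2))
    assert m["precision"] == 0.0 and m["F1"] == 0.0 and m["MCC"] == 0.0
    with pytest.raises(ValueError):
        metrics(ConfusionCounts(0, 0, 0, 0))


def test_metrics_match_sklearn_on_random_tables(rng):
    """500 random confusion tables against sklearn's formulas."""
    from sklearn.metrics import f1_score, matthews_corrcoef, precision_score
    for _ in range(500):
        tp, fp, tn, fn = rng.integers(0, 20, size=4)
        if tp + fp + tn + fn == 0:
            continue
        y_true = [1] * (tp + fn) + [0] * (tn + fp)
        y_pred = [1] * tp + [0] * fn + [0] * tn + [1] * fp
        m = metrics(ConfusionCounts(int(tp), int(fp), int(tn), int(fn)))
        assert m["MCC"] == pytest.approx(
            matthews_corrcoef(y_true, y_pred), abs=1e-10)
        assert m["precision"] == pytest.approx(
            precision_score(y_true, y_pred, zero_division=0), abs=1e-10)
        assert m["F1"] == pytest.approx(
            f1_score(y_true, y_pred, zero_division=0), abs=1e-10)


def test_label_swap_symmetry(rng):
    """Swapping the positive class exchanges SN and SP; ACC and |MCC|
    are unchanged."""
    y_true = rng.integers(0, 2, size=40)
    y_pred = rng.integers(0, 2, size=40)
    m1 = metrics(confusion(y_true, y_pred, positive=1))
    m0 = metrics(confusion(y_true, y_pred, positive=0))
    assert m1["SN"] == pytest.approx(m0["SP"])
    assert m1["SP"] == pytest.approx(m0["SN"])
    assert m1["ACC"] == pytest.approx(m0["ACC"])
    assert abs(m1["MCC"]) == pytest.approx(abs(m0["MCC"]))


# ---------------------------------------------------------------------------
# ROC / PRC
# ---------------------------------------------------------------------------

def auroc_pair_oracle(y_true, scores):
    """Mann–Whitney concordance with ties counted 1/2."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores)
    pos = scores[y_true == 1]
    neg = scores[y_true == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def test_roc_hand_example():
    points, auroc = roc_points([1, 0, 1, 0], [0.9, 0.8, 0.4, 0.3], positive=1)
    assert auroc == pytest.approx(0.75)
    assert tuple(points[0]) == (0.0, 0.0)
    assert tuple(points[-1]) == (1.0, 1.0)


def test_roc_perfect_and_all_ties():
    _, auroc = roc_points([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1])
    assert auroc == 1.0
    _, auroc = roc_points([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5])
    assert auroc == 0.5


@settings(max_examples=60, deadline=None)
@given(st.lists(st.tuples(st.integers(0, 1),
                          st.sampled_from([0.1, 0.25, 0.5, 0.75, 0.9])),
                min_size=4, max_size=50))
def test_auroc_equals_pair_counting_oracle(pairs):
    """Trapezoidal AUROC equals Mann–Whitney concordance, ties as 1/2."""
    y = np.array([p[0] for p in pairs])
    s = np.array([p[1] for p in pairs])
    if y.min() == y.max():
        return
    _, auroc = roc_points(y, s)
    assert auroc == pytest.approx(auroc_pair_oracle(y, s), abs=1e-10)


def test_prc_hand_example():
    points, auprc = prc_points([1, 0, 1, 0], [0.9, 0.8, 0.4, 0.3])
    expected = [(0.5, 1.0), (0.5, 0.5), (1.0, 2 / 3), (1.0, 0.5)]
    np.testing.assert_allclose(points, expected, atol=1e-12)
    assert auprc == pytest.approx(5 / 6)


def test_prc_perfect_separation():
    _, auprc = prc_points([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1])
    assert auprc == 1.0


def test_prc_requires_positives():
    with pytest.raises(ValueError):
        prc_points([0, 0, 0], [0.1, 0.2, 0.3])
    with pytest.raises(ValueError):
        roc_points([1, 1], [0.1, 0.2])


def test_prc_matches_sklearn_average_precision(rng):
    """Step-rule AUPRC equals sklearn's average_precision_score."""
    from sklearn.metrics import average_precision_score
    for _ in range(20):
        y = rng.integers(0, 2, size=30)
        if y.sum() in (0, 30):
            continue
        s = rng.random(30).round(2)  # ties likely
        _, auprc = prc_points(y, s)
        assert auprc == pytest.approx(average_precision_score(y, s),
                                      abs=1e-10)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def test_stratified_fold_arithmetic():
    """20 samples (10/10), K=10 → folds of 2, one per class."""
    y = np.array([1] * 10 + [0] * 10)
    a = stratified_folds(y, K=10, seed=0)
    for k in range(10):
        fold = y[a == k]
        assert fold.size == 2
        assert fold.sum() == 1


def test_folds_partition_and_determinism():
    y = np.array([1] * 13 + [0] * 17)
    a1 = stratified_folds(y, K=5, seed=7)
    a2 = stratified_folds(y, K=5, seed=7)
    np.testing.assert_array_equal(a1, a2)
    assert sorted(np.unique(a1)) == list(range(5))
    assert np.bincount(a1).sum() == 30
    assert not np.array_equal(a1, stratified_folds(y, K=5, seed=8))


def test_fold_count_exceeding_class_size():
    y = np.array([1] * 3 + [0] * 20)
    with pytest.raises(ValueError, match="smallest class"):
        stratified_folds(y, K=5, seed=0)


@pytest.fixture(scope="module")
def small_benchmark():
    return generate_dataset(SyntheticSpec(n_pos=30, n_neg=30,
                                          length_range=(50, 120),
                                          delta=0.8, seed=11))


def test_kfold_cv_report_structure(small_benchmark):
    rep = kfold_cv(small_benchmark, encoder="kmer", encoder_params={"k": 2},
                   m=50, K=5, seed=3)
    assert rep.pooled_counts.total == 60
    assert len(rep.fold_counts) == 5
    assert sum(c.total for c in rep.fold_counts) == 60
    assert set(rep.pooled) == {"SN", "SP", "ACC", "precision", "F1", "MCC"}
    assert 0.0 <= rep.auroc <= 1.0 and 0.0 <= rep.auprc <= 1.0
    assert rep.config["m"] == 50 and rep.config["K"] == 5


def test_kfold_cv_deterministic_under_seed(small_benchmark):
    rep1 = kfold_cv(small_benchmark, encoder="kmer", encoder_params={"k": 2},
                    m=50, K=5, seed=3)
    rep2 = kfold_cv(small_benchmark, encoder="kmer", encoder_params={"k": 2},
                    m=50, K=5, seed=3)
    assert rep1.to_json() == rep2.to_json()


def test_kfold_cv_separable_benchmark_accurate(small_benchmark):
    """K=2 on a separable synthetic benchmark reaches pooled ACC >= 0.9."""
    rep = kfold_cv(small_benchmark, encoder="kmer", encoder_params={"k": 2},
                   m=100, K=2, seed=42)
    assert rep.pooled["ACC"] >= 0.9


def test_kfold_cv_selection_modes_differ_in_config(small_benchmark):
    rep = kfold_cv(small_benchmark, encoder="kmer", encoder_params={"k": 1},
                   m=10, selection_mode="pre-cv", K=3, seed=1)
    assert rep.config["selection_mode"] == "pre-cv"
    with pytest.raises(ValueError):
        kfold_cv(small_benchmark, selection_mode="bogus")


def test_kfold_cv_classifier_contract(small_benchmark):
    """Any fit/predict_proba/predict object plugs into the CV loop."""
    class PriorOnly:
        def fit(self, X, y):
            self.class_labels, counts = np.unique(y, return_counts=True)
            self.p = counts / counts.sum()
            return self

        def predict_proba(self, X):
            return np.tile(self.p, (len(X), 1))

        def predict(self, X):
            return np.full(len(X), self.class_labels[np.argmax(self.p)])

    rep = kfold_cv(small_benchmark, encoder="kmer", encoder_params={"k": 1},
                   m=None, classifier_factory=PriorOnly, K=3, seed=0)
    assert 0.4 <= rep.pooled["ACC"] <= 0.6  # balanced prior-only guessing
    assert rep.auroc == pytest.approx(0.5)
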