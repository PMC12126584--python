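"""Metric implementations vs hand-counted examples and independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import (
    average_precision_score,
    balanced_accuracy_score,
    f1_score,
    roc_auc_score,
)

from pdmotor import metrics as M


def _pred(y, scores, **kw):
    return M.PredictionSet(np.asarray(y), np.asarray(scores, float), **kw)


def _onehot(labels, k):
    return np.eye(k)[np.asarray(labels)]


def _random_pred(rng, n=50, k=2):
    y = rng.integers(0, k, n)
    while len(np.unique(y)) < k:
        y = rng.integers(0, k, n)
    return _pred(y, M.softmax(rng.normal(size=(n, k))))


class TestBalancedAccuracy:
    def test_perfect(self):
        p = _pred([0, 1, 2], _onehot([0, 1, 2], 3))
        assert M.balanced_accuracy(p) == 1.0

    def test_constant_binary_prediction_is_half(self):
        p = _pred([0, 0, 0, 1], _onehot([0, 0, 0, 0], 2))
        assert M.balanced_accuracy(p) == 0.5

    def test_hand_counted(self):
        p = _pred([0, 0, 1, 1, 1], _onehot([0, 1, 1, 1, 0], 2))
        assert M.balanced_accuracy(p) == pytest.approx((0.5 + 2 / 3) / 2)

    def test_matches_sklearn_on_fuzz(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = _random_pred(rng, k=int(rng.integers(2, 5)))
            assert M.balanced_accuracy(p) == pytest.approx(
                balanced_accuracy_score(p.y_true, p.y_pred), abs=1e-12)


class TestAveragePrecision:
    def test_perfect_ranking(self):
        p = _pred([0, 0, 1, 1], [[0.9, 0.1], [0.8, 0.2], [0.3, 0.7], [0.2, 0.8]])
        assert M.average_precision(p, 1) == 1.0

    def test_positive_ranked_last_of_two(self):
        p = _pred([0, 1], [[0.4, 0.6], [0.6, 0.4]])
        assert M.average_precision(p, 1) == pytest.approx(0.5)

    def test_constant_scores_give_prevalence(self):
        y = [0] * 7 + [1] * 3
        p = _pred(y, np.tile([0.5, 0.5], (10, 1)))
        assert M.average_precision(p, 1) == pytest.approx(0.3)

    def test_no_positives_rejected(self):
        p = _pred([0, 0], np.tile([0.5, 0.5], (2, 1)))
        with pytest.raises(ValueError):
            M.average_precision(p, 1)

    def test_matches_sklearn_on_fuzz(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            p = _random_pred(rng)
            assert M.average_precision(p, 1) == pytest.approx(
                average_precision_score(p.y_true, p.scores[:, 1]), abs=1e-12)

    def test_map_of_random_scores_near_mean_prevalence(self):
        rng = np.random.default_rng(2)
        y = rng.choice(3, size=4000, p=[0.6, 0.3, 0.1])
        p = _pred(y, M.softmax(rng.normal(size=(4000, 3))))
        prevalences = np.bincount(y) / len(y)
        # AP of a random ranker concentrates near the class prevalence
        assert M.mean_ap(p) == pytest.approx(prevalences.mean(), abs=0.03)


class TestF1:
    def test_perfect(self):
        p = _pred([0, 1, 1], _onehot([0, 1, 1], 2))
        assert M.f1_macro(p) == 1.0

    def test_half_precision_half_recall(self):
        # class 1: P = R = 0.5 -> F1 = 0.5; class 0: P = R = 0.5 as well
        p = _pred([0, 1, 0, 1], _onehot([1, 0, 0, 1], 2))
        assert M.f1_macro(p) == pytest.approx(0.5)

    def test_absent_class_scores_zero(self):
        p = _pred([0, 0], _onehot([0, 0], 2))
        assert M.f1_macro(p) == pytest.approx(0.5)  # class 1: 0 by convention

    def test_matches_sklearn_on_fuzz(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = _random_pred(rng, k=3)
            assert M.f1_macro(p) == pytest.approx(
                f1_score(p.y_true, p.y_pred, average="macro",
                         labels=range(3), zero_division=0), abs=1e-12)


def _pairwise_auroc_oracle(y, scores):
    """Brute-force one-vs-one AUROC: average over pairs of directed AUROCs."""
    import itertools

    def directed(y_bin, s):
        pos, neg = s[y_bin == 1], s[y_bin == 0]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        return wins / (len(pos) * len(neg))

    vals = []
    for i, j in itertools.combinations(range(scores.shape[1]), 2):
        mask = (y == i) | (y == j)
        yi = (y[mask] == i).astype(int)
        vals.append(0.5 * (directed(yi, scores[mask, i])
                           + directed(1 - yi, scores[mask, j])))
    return float(np.mean(vals))


class TestAuroc:
    def test_perfect_separation(self):
        p = _pred([0, 0, 1, 1], [[0.9, 0.1], [0.8, 0.2], [0.3, 0.7], [0.1, 0.9]])
        assert M.auroc(p) == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 10_000)
        p = _pred(y, M.softmax(rng.normal(size=(10_000, 2))))
        n1, n0 = y.sum(), (1 - y).sum()
        se = np.sqrt((n1 + n0 + 1) / (12 * n1 * n0))
        assert abs(M.auroc(p) - 0.5) < 3 * se

    def test_multiclass_matches_pairwise_oracle(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 3, 50)
        scores = M.softmax(rng.normal(size=(50, 3)))
        p = _pred(y, scores)
        assert M.auroc(p) == pytest.approx(_pairwise_auroc_oracle(y, scores), abs=1e-12)

    def test_multiclass_matches_sklearn_ovo(self):
        rng = np.random.default_rng(6)
        y = rng.integers(0, 4, 120)
        scores = M.softmax(rng.normal(size=(120, 4)))
        p = _pred(y, scores)
        assert M.auroc(p) == pytest.approx(
            roc_auc_score(y, scores, multi_class="ovo", average="macro"), abs=1e-12)


class TestMamae:
    def test_perfect(self):
        p = _pred([0, 1, 2], _onehot([0, 1, 2], 3))
        assert M.mamae(p) == 0.0

    def test_hand_counted(self):
        p = _pred([0, 0, 2], _onehot([2, 0, 2], 3))
        assert M.mamae(p) == pytest.approx(0.5)

    def test_always_predicting_zero_on_four_balanced_classes(self):
        p = _pred([0, 1, 2, 3], _onehot([0, 0, 0, 0], 4))
        assert M.mamae(p) == pytest.approx(1.5)

    def test_printed_form_divides_by_n(self):
        p = _pred([0, 0, 2], _onehot([2, 0, 2], 3))
        assert M.mamae(p, as_printed=True) == pytest.approx((1.0 + 0.0) / 3)


class TestSoftmaxAndLoss:
    def test_symmetric(self):
        assert np.allclose(M.softmax(np.array([0.0, 0.0])), [0.5, 0.5])

    def test_one_zero(self):
        e = np.e
        assert np.allclose(M.softmax(np.array([1.0, 0.0])),
                           [e / (e + 1), 1 / (e + 1)])

    def test_shift_invariance(self):
        x = np.array([[0.3, -1.2, 2.0]])
        assert np.allclose(M.softmax(x), M.softmax(x + 123.4))

    def test_rows_sum_to_one_under_extremes(self):
        x = np.array([[1e8, 0.0, -1e8]])
        s = M.softmax(x)
        assert np.isfinite(s).all() and s.sum() == pytest.approx(1.0)

    def test_cross_entropy_values(self):
        assert M.categorical_cross_entropy(_onehot([1], 2), _onehot([1], 2)) == (
            pytest.approx(0.0, abs=1e-9))
        uniform4 = np.full((1, 4), 0.25)
        assert M.categorical_cross_entropy(_onehot([2], 4), uniform4) == (
            pytest.approx(np.log(4)))
        uniform2 = np.full((1, 2), 0.5)
        assert M.categorical_cross_entropy(_onehot([0], 2), uniform2) == (
            pytest.approx(np.log(2)))


class TestConfusion:
    def test_perfect_is_diagonal(self):
        p = _pred([0, 1, 2, 2], _onehot([0, 1, 2, 2], 3))
        assert np.array_equal(M.confusion(p), np.diag([1, 1, 2]))

    def test_single_column_for_constant_prediction(self):
        p = _pred([0, 1, 2], _onehot([1, 1, 1], 3))
        mat = M.confusion(p)
        assert mat[:, [0, 2]].sum() == 0 and mat[:, 1].sum() == 3

    def test_row_sums_conserved(self):
        rng = np.random.default_rng(7)
        p = _random_pred(rng, n=40, k=3)
        assert np.array_equal(M.confusion(p).sum(axis=1),
                              np.bincount(p.y_true, minlength=3))


class TestReliability:
    def test_on_diagonal_mass_is_zero(self):
        p = _pred(np.ones(100, int), np.tile([0.0, 1.0], (100, 1)))
        assert M.smece(p) == pytest.approx(0.0, abs=1e-6)

    def test_anti_calibrated_is_one(self):
        p = _pred(np.zeros(100, int), np.tile([0.0, 1.0], (100, 1)))
        assert M.smece(p) == pytest.approx(1.0, abs=1e-6)

    def test_calibrated_simulation_is_small(self):
        rng = np.random.default_rng(8)
        f = rng.uniform(size=20_000)
        y = (rng.uniform(size=20_000) < f).astype(int)
        p = _pred(y, np.column_stack([1 - f, f]))
        assert M.smece(p) < 0.02

    def test_curve_bounds_and_bandwidth(self):
        rng = np.random.default_rng(9)
        f = rng.uniform(size=500)
        y = (rng.uniform(size=500) < 0.3).astype(int)
        curve = M.reliability(_pred(y, np.column_stack([1 - f, f])))
        assert curve.bandwidth > 0
        assert np.all((curve.smoothed >= 0) & (curve.smoothed <= 1))
        assert np.all(curve.density >= 0)

    def test_multiclass_rejected(self):
        p = _pred([0, 1, 2], _onehot([0, 1, 2], 3))
        with pytest.raises(ValueError):
            M.reliability(p)


@settings(max_examples=200, deadline=None)
@given(data=st.data())
def test_bounded_metrics_stay_in_range(data):
    """Fuzzed prediction sets keep every bounded metric inside its range."""
    k = data.draw(st.integers(2, 5))
    n = data.draw(st.integers(k, 40))
    rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
    y = rng.integers(0, k, n)
    y[:k] = np.arange(k)  # every class present
    p = _pred(y, M.softmax(rng.normal(size=(n, k)) * 3))
    assert 0.0 <= M.balanced_accuracy(p) <= 1.0
    assert 0.0 <= M.accuracy(p) <= 1.0
    assert 0.0 <= M.mean_ap(p) <= 1.0
    assert 0.0 <= M.f1_macro(p) <= 1.0
    assert 0.0 <= M.auroc(p) <= 1.0
    assert M.mamae(p) >= 0.0


def test_evaluate_report_fields():
    rng = np.random.default_rng(10)
    y = rng.integers(0, 2, 60)
    y[:2] = [0, 1]
    p = _pred(y, M.softmax(rng.normal(size=(60, 2))))
    report = M.evaluate(p)
    assert report.smece is not None and report.mamae is None
    d = report.to_dict()
    assert set(d) >= {"accuracy", "balanced_accuracy", "map", "f1_macro",
                      "auroc", "confusion", "smece"}
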