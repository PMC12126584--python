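import numpy as np
import pytest

from pdmotor import metrics as M
from pdmotor.error_analysis import (
    TaskErrorTable,
    binarize_tremor,
    expected_counts,
    flag_deviations,
    magnitude_series,
    magnitude_stats,
    misclassification_summary,
    observed_counts,
    sample_entropy,
    welch_band_power,
    welch_psd,
)
from pdmotor.simulate import default_task_catalog, synthesize_signal


class TestExpectedCounts:
    def test_single_task_expected_equals_observed_totals(self):
        observed = np.array([[[3.0, 1.0], [2.0, 4.0]]])  # (1 task, 2, 2)
        table = expected_counts(TaskErrorTable(["t"], ["0", "1"], observed))
        assert np.allclose(table.expected, observed)

    def test_two_task_hand_example(self):
        """Equal task shares at y: E = half of the column total."""
        K = 2
        observed = np.zeros((2, K, K))
        # for y=0: task A has 10 samples, task B has 10 -> shares 0.5/0.5
        observed[0, 0, 0] = 7.0
        observed[0, 1, 0] = 3.0
        observed[1, 0, 0] = 5.0
        observed[1, 1, 0] = 5.0
        observed[:, 1, 1] = 2.0  # some true-class-1 mass in both tasks
        table = expected_counts(TaskErrorTable(["A", "B"], ["0", "1"], observed))
        # sum_k O[k, yhat=1, y=0] = 8, share of A = 10/20
        assert table.expected[0, 1, 0] == pytest.approx(4.0)
        assert table.expected[1, 1, 0] == pytest.approx(4.0)

    def test_conservation_on_fuzzed_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            t, k = rng.integers(1, 6), rng.integers(2, 5)
            observed = rng.poisson(3.0, size=(t, k, k)).astype(float)
            table = expected_counts(
                TaskErrorTable([f"t{i}" for i in range(t)],
                               [str(c) for c in range(k)], observed))
            assert np.allclose(table.expected.sum(axis=0),
                               observed.sum(axis=0), atol=1e-9)

    def test_empty_true_class_warns_and_zeroes(self):
        observed = np.zeros((2, 2, 2))
        observed[:, :, 0] = 1.0  # class "1" never occurs as ground truth
        with pytest.warns(UserWarning, match="no samples"):
            table = expected_counts(TaskErrorTable(["A", "B"], ["0", "1"], observed))
        assert np.all(table.expected[:, :, 1] == 0)


class TestFlagDeviations:
    def _table(self, o, e):
        observed = np.zeros((2, 2, 2))
        expected = np.zeros((2, 2, 2))
        observed[0, 1, 0], expected[0, 1, 0] = o, e
        return TaskErrorTable(["A", "B"], ["0", "1"], observed, expected)

    def test_large_ratio_flagged(self):
        flags = flag_deviations(self._table(216, 100))
        assert len(flags) == 1 and flags[0].task == "A"

    def test_small_ratio_not_flagged(self):
        assert flag_deviations(self._table(12, 11)) == []

    def test_low_expected_count_not_flagged(self):
        assert flag_deviations(self._table(15, 5)) == []

    def test_underrepresentation_also_flagged(self):
        assert len(flag_deviations(self._table(100, 216))) == 1


class TestBinarizeTremor:
    def test_zero_is_absent(self):
        assert binarize_tremor(np.array([0]))[0] == 0

    def test_three_is_present(self):
        assert binarize_tremor(np.array([3]))[0] == 1

    def test_vector(self):
        assert binarize_tremor(np.array([0, 1, 4])).tolist() == [0, 1, 1]


class TestMagnitudeStats:
    def test_constant_axes(self):
        acc = np.vstack([np.full(100, 2.5), np.zeros(100), np.zeros(100)])
        assert np.allclose(magnitude_series(acc), 2.5)
        assert magnitude_stats(acc, 50.0).sd == 0.0

    def test_axis_permutation_invariance(self):
        rng = np.random.default_rng(0)
        acc = rng.normal(size=(3, 200))
        assert np.allclose(magnitude_series(acc), magnitude_series(acc[[2, 0, 1]]))

    def test_bradykinetic_pair_has_lower_sd(self):
        profile = default_task_catalog()[11]
        for seed in range(3):
            sds = {
                b: magnitude_stats(
                    synthesize_signal(profile, 0, b, False, 20, 50, seed=seed),
                    50.0, compute_entropy=False).sd
                for b in (False, True)
            }
            assert sds[True] < sds[False]


class TestWelchBandPower:
    def test_pure_tone_peak_location(self):
        t = np.arange(2000) / 50.0
        freqs, psd = welch_psd(np.sin(2 * np.pi * 5.0 * t), 50.0)
        assert freqs[np.argmax(psd)] == pytest.approx(5.0, abs=0.2)

    def test_white_noise_beats_out_of_band_tone(self):
        rng = np.random.default_rng(1)
        noise = rng.normal(size=4000)
        tone = np.sqrt(2) * np.sin(2 * np.pi * 10.0 * np.arange(4000) / 50.0)
        assert welch_band_power(noise, 50.0) > welch_band_power(tone, 50.0)

    def test_zero_signal(self):
        assert welch_band_power(np.zeros(1000), 50.0) == 0.0

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            welch_band_power(np.zeros(1000), 50.0, band=(20.0, 30.0))


def _sampen_oracle(x, m, r):
    """O(N^2) direct template matching with Chebyshev distance."""
    n = len(x)

    def count(mm):
        total = 0
        for i in range(n - m):
            for j in range(i + 1, n - m):
                if max(abs(x[i + d] - x[j + d]) for d in range(mm)) <= r:
                    total += 1
        return total

    B, A = count(m), count(m + 1)
    return float("inf") if (A == 0 or B == 0) else -np.log(A / B)


class TestSampleEntropy:
    def test_constant_series_is_zero(self):
        assert sample_entropy(np.full(50, 1.3)) == 0.0

    def test_noise_exceeds_sinusoid(self):
        rng = np.random.default_rng(2)
        noise = rng.normal(size=2000)
        tone = np.sin(2 * np.pi * 2.0 * np.arange(2000) / 50.0)
        assert sample_entropy(noise) > sample_entropy(tone)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        for n in (50, 120, 200):
            x = rng.normal(size=n)
            r = 0.2 * x.std()
            assert sample_entropy(x, 2, r) == pytest.approx(
                _sampen_oracle(x, 2, r), abs=1e-9)

    def test_no_matches_returns_inf_with_warning(self):
        x = np.arange(10.0)  # strictly increasing, tiny tolerance
        with pytest.warns(UserWarning):
            assert sample_entropy(x, 2, r=1e-12) == np.inf

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            sample_entropy(np.zeros(3), m=2)


def test_band_power_separates_tremor_presence(easy_tremor_recordings):
    """Tremor-positive recordings show higher 4-6 Hz band power (3 S.E.)."""
    pos, neg = [], []
    for rec in easy_tremor_recordings:
        mag = magnitude_series(rec.acc)
        power = welch_band_power(mag - mag.mean(), rec.fs_hz)
        (pos if rec.tremor >= 1 else neg).append(power)
    pos, neg = np.array(pos), np.array(neg)
    se = np.sqrt(pos.var() / len(pos) + neg.var() / len(neg))
    assert pos.mean() - neg.mean() > 3 * se


def test_misclassification_summary_round_trip():
    rng = np.random.default_rng(4)
    n = 600
    y = rng.integers(0, 2, n)
    tasks = np.where(rng.uniform(size=n) < 0.5, "drawing", "walking")
    # force false positives to concentrate on drawing
    scores = np.where((y == 0) & (tasks == "drawing") & (rng.uniform(size=n) < 0.8),
                      0.9, 0.1)
    scores = np.where(y == 1, rng.uniform(size=n), scores)
    pred = M.PredictionSet(y, np.column_stack([1 - scores, scores]))
    frame = misclassification_summary(pred, tasks)
    assert set(frame.columns) == {"task", "y_pred", "y_true", "observed", "expected"}
    fp = frame[(frame.y_pred == "1") & (frame.y_true == "0")]
    assert "drawing" in set(fp.task)


def test_observed_counts_totals():
    y = np.array([0, 0, 1, 1])
    pred = M.PredictionSet(y, np.eye(2)[[0, 1, 1, 0]])
    table = observed_counts(pred, np.array(["a", "a", "b", "b"]))
    assert table.observed.sum() == 4
    assert table.observed[0].sum() == 2  # task a
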