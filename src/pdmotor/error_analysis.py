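"""Task-level misclassification analysis and signal-level explanations.

If a classifier's errors were uniformly distributed across motor tasks,
the observed error count for each (task, predicted class, true class)
cell would match an expected count computed from the task's share of all
samples at that true class:

    E[t, yhat, y] = ( sum_i O[t, i, y] / sum_k sum_i O[k, i, y] )
                    * sum_k O[k, yhat, y]

Cells whose observed/expected ratio is at least 1.4 in either direction
(with both counts >= 10) flag task-specific error patterns.  Signal-level
explanations use the magnitude of the acceleration series: its standard
deviation (a power proxy), its Welch power spectral density and 4-6 Hz
tremor-band power, and its sample entropy (complexity of short noisy
physiological signals).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .metrics import PredictionSet

TREMOR_BAND = (4.0, 6.0)


@dataclass
class TaskErrorTable:
    """Observed (and optionally expected) counts by task x predicted x true."""

    tasks: list[str]
    class_names: list[str]
    observed: np.ndarray  # (n_tasks, K_pred, K_true)
    expected: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=float)
        K = len(self.class_names)
        if self.observed.shape != (len(self.tasks), K, K):
            raise ValueError("observed counts must have shape (tasks, K, K)")
        if np.any(self.observed < 0):
            raise ValueError("counts must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ti, task in enumerate(self.tasks):
            for pi, p in enumerate(self.class_names):
                for yi, y in enumerate(self.class_names):
                    rows.append(
                        {
                            "task": task, "y_pred": p, "y_true": y,
                            "observed": self.observed[ti, pi, yi],
                            "expected": (None if self.expected is None
                                         else self.expected[ti, pi, yi]),
                        }
                    )
        return pd.DataFrame(rows)


def observed_counts(pred: PredictionSet, tasks: np.ndarray,
                    task_order: list[str] | None = None) -> TaskErrorTable:
    """Tally O[t, yhat, y] from a prediction set and per-window task names."""
    tasks = np.asarray(tasks)
    names = task_order or sorted(set(tasks.tolist()))
    index = {t: i for i, t in enumerate(names)}
    K = pred.n_classes
    observed = np.zeros((len(names), K, K))
    y_pred = pred.y_pred
    for t, p, y in zip(tasks, y_pred, pred.y_true):
        observed[index[t], p, y] += 1
    return TaskErrorTable(list(names), list(pred.class_names), observed)


def expected_counts(table: TaskErrorTable) -> TaskErrorTable:
    """Expected counts under task-uniform misclassification.

    A true class with zero samples overall yields zero expected counts for
    that class (with a warning).
    """
    O = table.observed
    per_task_true = O.sum(axis=1)          # (T, K_true): all samples of y in task t
    per_true = per_task_true.sum(axis=0)   # (K_true,)
    totals = O.sum(axis=0)                 # (K_pred, K_true)
    expected = np.zeros_like(O)
    for y in range(O.shape[2]):
        if per_true[y] == 0:
            warnings.warn(
                f"no samples with true class {table.class_names[y]!r}; "
                "expected counts set to 0"
            )
            continue
        share = per_task_true[:, y] / per_true[y]          # (T,)
        expected[:, :, y] = share[:, None] * totals[None, :, y]
    return TaskErrorTable(list(table.tasks), list(table.class_names), O, expected)


@dataclass
class FlaggedCell:
    task: str
    y_pred: str
    y_true: str
    observed: float
    expected: float


def flag_deviations(table: TaskErrorTable, min_ratio: float = 1.4,
                    min_count: float = 10.0) -> list[FlaggedCell]:
    """Cells where observed and expected differ by >= 40 % with both >= 10."""
    if table.expected is None:
        table = expected_counts(table)
    flags = []
    for ti, task in enumerate(table.tasks):
        for pi, p in enumerate(table.class_names):
            for yi, y in enumerate(table.class_names):
                o = table.observed[ti, pi, yi]
                e = table.expected[ti, pi, yi]
                if o < min_count or e < min_count:
                    continue
                if max(o, e) / min(o, e) >= min_ratio:
                    flags.append(FlaggedCell(task, p, y, o, e))
    return flags


def binarize_tremor(labels: np.ndarray) -> np.ndarray:
    """Ordinal severity -> presence: 0 absent, >= 1 present."""
    return (np.asarray(labels) >= 1).astype(int)


@dataclass
class SignalSummary:
    magnitude: np.ndarray
    sd: float
    sample_entropy: float
    psd_freqs: np.ndarray = field(repr=False, default=None)
    psd: np.ndarray = field(repr=False, default=None)
    band_power: float = 0.0


def magnitude_series(acc: np.ndarray) -> np.ndarray:
    acc = np.atleast_2d(np.asarray(acc, dtype=float))
    return np.sqrt((acc**2).sum(axis=0))


def welch_psd(series: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    nperseg = min(256, len(series))
    return sps.welch(series, fs=fs, window="hann", nperseg=nperseg,
                     noverlap=nperseg // 2)


def welch_band_power(series: np.ndarray, fs: float,
                     band: tuple[float, float] = TREMOR_BAND) -> float:
    """Trapezoidal integral of the Welch PSD over ``band``."""
    if band[1] > fs / 2:
        raise ValueError(f"band {band} exceeds Nyquist ({fs / 2} Hz)")
    freqs, psd = welch_psd(series, fs)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if mask.sum() < 2:
        return float(psd[mask].sum())
    return float(np.trapezoid(psd[mask], freqs[mask]))


def sample_entropy(series: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """SampEn(m, r) = -ln(A/B) with Chebyshev distance, self-matches excluded.

    B counts template pairs of length m within tolerance r, A the pairs
    still within tolerance at length m + 1.  Default r = 0.2 * S.D.
    Returns +inf (with a warning) when no length-(m+1) pair matches.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n <= m + 1:
        raise ValueError(f"series too short for m={m}")
    if r is None:
        r = 0.2 * float(np.std(x))

    def _count(mm: int) -> int:
        templates = np.lib.stride_tricks.sliding_window_view(x, mm)[: n - m]
        # pairwise Chebyshev distances; count i < j within tolerance
        d = np.abs(templates[:, None, :] - templates[None, :, :]).max(axis=2)
        within = d <= r
        return int((np.triu(within, k=1)).sum())

    B = _count(m)
    A = _count(m + 1)
    if B == 0 or A == 0:
        warnings.warn("sample entropy undefined (no matching templates); returning inf")
        return float("inf")
    return float(-np.log(A / B))


def magnitude_stats(acc: np.ndarray, fs: float, m: int = 2,
                    compute_entropy: bool = True) -> SignalSummary:
    """Magnitude S.D., tremor-band power, PSD and sample entropy."""
    mag = magnitude_series(acc)
    if len(mag) < 2:
        raise ValueError("need at least 2 samples")
    freqs, psd = welch_psd(mag, fs)
    return SignalSummary(
        magnitude=mag,
        sd=float(np.std(mag)),
        sample_entropy=sample_entropy(mag, m=m) if compute_entropy else float("nan"),
        psd_freqs=freqs,
        psd=psd,
        band_power=welch_band_power(mag, fs),
    )


def misclassification_summary(pred: PredictionSet, tasks: np.ndarray,
                              min_ratio: float = 1.4,
                              min_count: float = 10.0) -> pd.DataFrame:
    """Flagged task/prediction cells as a tidy frame (may be empty)."""
    table = expected_counts(observed_counts(pred, tasks))
    flags = flag_deviations(table, min_ratio=min_ratio, min_count=min_count)
    return pd.DataFrame(
        [
            {"task": f.task, "y_pred": f.y_pred, "y_true": f.y_true,
             "observed": f.observed, "expected": f.expected}
            for f in flags
        ],
        columns=["task", "y_pred", "y_true", "observed", "expected"],
    )
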