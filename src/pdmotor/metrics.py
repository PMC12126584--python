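"""Evaluation metrics and calibration analysis.

Implements the scalar metrics used throughout the pipeline:

* balanced accuracy (BA) — mean per-class recall; 0.5 is the binary
  random-classifier expectation,
* average precision, AP = sum_i (R_i - R_{i-1}) P_i over descending score
  thresholds with R_{-1} = 0 (non-interpolated), and its one-vs-rest mean
  (mAP),
* macro F1 (one-vs-rest),
* AUROC — rank statistic for binary tasks; unweighted one-vs-one pair
  average for multiclass, which is less sensitive to class imbalance than
  one-vs-rest,
* MAMAE — macro-averaged mean absolute error for ordinal tasks: equal-weight
  mean over classes of the per-class mean |yhat - y|,
* softmax with max-subtraction,
* smoothed expected calibration error (smECE) from a Gaussian-kernel
  reliability curve with a self-consistent (fixed-point) bandwidth.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata


@dataclass
class PredictionSet:
    """Per-window class scores with ground truth; input to every metric."""

    y_true: np.ndarray  # (N,) int class indices
    scores: np.ndarray  # (N, K) probabilities or raw likelihoods
    class_names: list[str] | None = None
    is_proba: bool = True

    def __post_init__(self) -> None:
        self.y_true = np.asarray(self.y_true, dtype=int)
        self.scores = np.atleast_2d(np.asarray(self.scores, dtype=float))
        if self.scores.shape[0] != self.y_true.shape[0]:
            raise ValueError("scores and y_true disagree on sample count")
        if self.class_names is None:
            self.class_names = [str(k) for k in range(self.scores.shape[1])]
        if self.is_proba:
            sums = self.scores.sum(axis=1)
            if len(sums) and not np.allclose(sums, 1.0, atol=1e-6):
                raise ValueError("probability rows must sum to 1")

    @property
    def n_classes(self) -> int:
        return self.scores.shape[1]

    @property
    def y_pred(self) -> np.ndarray:
        # argmax with first-index tie-break
        return np.argmax(self.scores, axis=1)

    def as_probabilities(self) -> "PredictionSet":
        if self.is_proba:
            return self
        return PredictionSet(self.y_true, softmax(self.scores),
                             list(self.class_names), is_proba=True)


def softmax(likelihoods: np.ndarray) -> np.ndarray:
    """Row-wise softmax with max-subtraction for numerical stability."""
    x = np.atleast_2d(np.asarray(likelihoods, dtype=float))
    if not np.all(np.isfinite(x)):
        raise ValueError("softmax input must be finite")
    z = x - x.max(axis=1, keepdims=True)
    e = np.exp(z)
    out = e / e.sum(axis=1, keepdims=True)
    return out if np.asarray(likelihoods).ndim > 1 else out[0]


def categorical_cross_entropy(y_onehot: np.ndarray, probs: np.ndarray,
                              eps: float = 1e-12) -> float:
    """Mean per-sample categorical cross-entropy -sum_c y_c log(p_c)."""
    y = np.atleast_2d(y_onehot)
    p = np.clip(np.atleast_2d(probs), eps, 1.0)
    return float(-(y * np.log(p)).sum(axis=1).mean())


def confusion(pred: PredictionSet) -> np.ndarray:
    """Confusion counts, rows = true class, columns = predicted class."""
    K = pred.n_classes
    mat = np.zeros((K, K), dtype=int)
    np.add.at(mat, (pred.y_true, pred.y_pred), 1)
    return mat


def accuracy(pred: PredictionSet) -> float:
    return float(np.mean(pred.y_pred == pred.y_true))


def balanced_accuracy(pred: PredictionSet) -> float:
    """Mean of the per-class recalls over classes present in y_true."""
    recalls = []
    present = np.unique(pred.y_true)
    if len(present) == 0:
        raise ValueError("empty prediction set")
    for c in present:
        mask = pred.y_true == c
        recalls.append(np.mean(pred.y_pred[mask] == c))
    return float(np.mean(recalls))


def per_class_recall(pred: PredictionSet, c: int) -> float:
    mask = pred.y_true == c
    if not mask.any():
        raise ValueError(f"class {pred.class_names[c]!r} has no true samples")
    return float(np.mean(pred.y_pred[mask] == c))


def average_precision(pred: PredictionSet, positive_class: int = 1) -> float:
    """AP = sum_i (R_i - R_{i-1}) P_i over descending unique thresholds."""
    y = (pred.y_true == positive_class).astype(int)
    s = pred.scores[:, positive_class]
    n_pos = y.sum()
    if n_pos == 0:
        raise ValueError("average precision undefined without positive samples")
    thresholds = np.unique(s)[::-1]
    ap = 0.0
    r_prev = 0.0
    for thr in thresholds:
        sel = s >= thr
        tp = y[sel].sum()
        precision = tp / sel.sum()
        recall = tp / n_pos
        ap += (recall - r_prev) * precision
        r_prev = recall
    return float(ap)


def mean_ap(pred: PredictionSet) -> float:
    """Unweighted mean of one-vs-rest per-class APs."""
    aps = [average_precision(pred, c) for c in range(pred.n_classes)
           if np.any(pred.y_true == c)]
    if not aps:
        raise ValueError("no class with positive samples")
    return float(np.mean(aps))


def f1_macro(pred: PredictionSet) -> float:
    """One-vs-rest F1 = 2PR/(P+R) per class, unweighted mean; 0 when P+R=0."""
    f1s = []
    for c in range(pred.n_classes):
        tp = np.sum((pred.y_pred == c) & (pred.y_true == c))
        fp = np.sum((pred.y_pred == c) & (pred.y_true != c))
        fn = np.sum((pred.y_pred != c) & (pred.y_true == c))
        if tp + fp + fn == 0:
            f1s.append(0.0)
            continue
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1s.append(2 * precision * recall / (precision + recall)
                   if precision + recall else 0.0)
    return float(np.mean(f1s))


def _binary_auroc(scores_pos: np.ndarray, y_bin: np.ndarray) -> float:
    """Mann-Whitney rank AUROC with midrank tie handling."""
    n_pos = int(y_bin.sum())
    n_neg = len(y_bin) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs both classes present")
    ranks = rankdata(scores_pos)
    return float((ranks[y_bin == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auroc(pred: PredictionSet) -> float:
    """Binary: rank AUROC.  Multiclass: unweighted one-vs-one pair average.

    For each unordered class pair (i, j) the two directed AUROCs (score of i
    against truth i-vs-j, and of j against j-vs-i) are averaged over the
    samples belonging to the pair; pairs missing a class are skipped with a
    warning.
    """
    p = pred.as_probabilities()
    if p.n_classes == 2:
        return _binary_auroc(p.scores[:, 1], (p.y_true == 1).astype(int))
    pair_scores = []
    for i, j in itertools.combinations(range(p.n_classes), 2):
        mask = (p.y_true == i) | (p.y_true == j)
        if not (np.any(p.y_true == i) and np.any(p.y_true == j)):
            warnings.warn(f"AUROC pair ({i},{j}) skipped: class absent from y_true")
            continue
        y_i = (p.y_true[mask] == i).astype(int)
        a_ij = _binary_auroc(p.scores[mask, i], y_i)
        a_ji = _binary_auroc(p.scores[mask, j], 1 - y_i)
        pair_scores.append(0.5 * (a_ij + a_ji))
    if not pair_scores:
        raise ValueError("no valid class pair for AUROC")
    return float(np.mean(pair_scores))


def mamae(pred: PredictionSet, as_printed: bool = False) -> float:
    """Macro-averaged mean absolute error on ordinal integer classes.

    Default: equal-weight mean over classes of the per-class mean
    |yhat - y|.  ``as_printed=True`` divides the class sum by N instead of
    the class count (an alternative normalization of the same sum).
    """
    errors = np.abs(pred.y_pred - pred.y_true).astype(float)
    present = np.unique(pred.y_true)
    per_class = [errors[pred.y_true == c].mean() for c in present]
    if as_printed:
        return float(np.sum(per_class) / len(pred.y_true))
    return float(np.mean(per_class))


# ---------------------------------------------------------------------------
# Calibration: smoothed ECE with self-consistent Gaussian bandwidth


@dataclass
class ReliabilityCurve:
    f_grid: np.ndarray        # predicted-probability grid in [0, 1]
    smoothed: np.ndarray      # kernel estimate of E[y | f]
    density: np.ndarray       # kernel density of predictions on the grid
    bandwidth: float
    smece: float


_N_BINS = 4096


def _bin_masses(f: np.ndarray, values: np.ndarray, n_bins: int) -> np.ndarray:
    idx = np.clip((f * n_bins).astype(int), 0, n_bins - 1)
    return np.bincount(idx, weights=values, minlength=n_bins)


def _smooth(mass: np.ndarray, sigma: float, n_bins: int) -> np.ndarray:
    # mode="reflect" realizes the Gaussian kernel folded at the [0,1]
    # boundaries (half-sample-symmetric images, matching bin centers)
    from scipy.ndimage import gaussian_filter1d

    return gaussian_filter1d(mass, sigma * n_bins, mode="reflect", truncate=6.0)


def _smece_at(sigma: float, residual_mass: np.ndarray, n: int,
              n_bins: int) -> float:
    return float(np.abs(_smooth(residual_mass, sigma, n_bins)).sum() / n)


def reliability(pred_binary: PredictionSet, n_bins: int = _N_BINS,
                sigma_bounds: tuple[float, float] = (1e-3, 1.0),
                tol: float = 1e-4) -> ReliabilityCurve:
    """Reliability curve and smECE for a binary task.

    Predicted probabilities are binned onto a fine grid; the miscalibration
    at bandwidth sigma is the total absolute mass of the Gaussian-smoothed
    residual (y - f) histogram, with reflection at the [0,1] boundaries.
    The reported smECE uses the self-consistent bandwidth sigma* with
    smECE_{sigma*} = sigma*, found by bisection (smECE_sigma is
    non-increasing in sigma, so the map has a unique crossing; the search
    is clamped to ``sigma_bounds``).
    """
    p = pred_binary.as_probabilities()
    if p.n_classes != 2:
        raise ValueError("reliability analysis is defined for binary tasks")
    f = p.scores[:, 1]
    y = (p.y_true == 1).astype(float)
    n = len(f)
    residual_mass = _bin_masses(f, y - f, n_bins)

    lo, hi = sigma_bounds
    if _smece_at(lo, residual_mass, n, n_bins) <= lo:
        sigma = lo
    elif _smece_at(hi, residual_mass, n, n_bins) >= hi:
        sigma = hi
    else:
        a, b = lo, hi
        while b - a > tol:
            mid = 0.5 * (a + b)
            if _smece_at(mid, residual_mass, n, n_bins) > mid:
                a = mid
            else:
                b = mid
        sigma = 0.5 * (a + b)

    smece_value = _smece_at(sigma, residual_mass, n, n_bins)
    count_mass = _bin_masses(f, np.ones(n), n_bins)
    y_mass = _bin_masses(f, y, n_bins)
    den = _smooth(count_mass, sigma, n_bins)
    num = _smooth(y_mass, sigma, n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        smoothed = np.where(den > 1e-300, num / np.maximum(den, 1e-300), 0.0)
    smoothed = np.clip(smoothed, 0.0, 1.0)
    grid = (np.arange(n_bins) + 0.5) / n_bins
    density = den / n * n_bins  # per unit predicted probability
    return ReliabilityCurve(grid, smoothed, density, sigma, smece_value)


def smece(pred_binary: PredictionSet) -> float:
    return reliability(pred_binary).smece


# ---------------------------------------------------------------------------


@dataclass
class MetricReport:
    """All scalar metrics for one evaluated model run."""

    accuracy: float
    balanced_accuracy: float
    ap_per_class: dict[str, float]
    map: float
    f1_macro: float
    auroc: float
    confusion: list[list[int]]
    mamae: float | None = None
    smece: float | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
            "ap_per_class": self.ap_per_class,
            "map": self.map,
            "f1_macro": self.f1_macro,
            "auroc": self.auroc,
            "confusion": self.confusion,
            "mamae": self.mamae,
            "smece": self.smece,
            **self.extras,
        }


def evaluate(pred: PredictionSet, ordinal: bool | None = None) -> MetricReport:
    """Compute the full metric suite for one prediction set.

    ``ordinal`` controls whether MAMAE is reported (default: multiclass
    tasks are treated as ordinal, matching tremor severity grading).
    smECE is reported for binary tasks only.
    """
    p = pred.as_probabilities()
    if ordinal is None:
        ordinal = p.n_classes > 2
    ap_per_class = {
        p.class_names[c]: average_precision(p, c)
        for c in range(p.n_classes) if np.any(p.y_true == c)
    }
    return MetricReport(
        accuracy=accuracy(p),
        balanced_accuracy=balanced_accuracy(p),
        ap_per_class=ap_per_class,
        map=float(np.mean(list(ap_per_class.values()))),
        f1_macro=f1_macro(p),
        auroc=auroc(p),
        confusion=confusion(p).tolist(),
        mamae=mamae(p) if ordinal else None,
        smece=smece(p) if p.n_classes == 2 else None,
    )
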