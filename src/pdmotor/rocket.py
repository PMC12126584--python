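"""Random convolutional kernel transform with a ridge classification head.

Thousands of random 1-D convolution kernels are applied to every channel
of every window; each (kernel, channel) pair yields two scalar features —
the proportion of strictly positive convolution outputs (PPV) and the
maximum output — so a 3-channel input with n kernels becomes a
2 x n x 3 feature vector.  Only a linear (ridge) classifier is then fit on
these features, which keeps the trainable-parameter count tiny and makes
the method well suited to small clinical datasets.

Kernel parameter distributions follow the transform's published defaults:
length uniform on {7, 9, 11}; weights standard normal, mean-centered per
kernel; bias uniform on [-1, 1]; dilation 2**a with a uniform on
[0, log2((L_in - 1)/(l - 1))]; padding on/off equiprobably.  Windows are
z-normalized per channel before convolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import clone
from sklearn.linear_model import RidgeClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .metrics import PredictionSet, balanced_accuracy, softmax
from .selection import fold_indices, grouped_stratified_kfold
from .windows import WindowedDataset

try:  # numba accelerates the convolution loops when available
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba present in normal installs
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def deco(f):
            return f
        return deco if not (args and callable(args[0])) else args[0]


KERNEL_LENGTHS = (7, 9, 11)
RIDGE_ALPHA_GRID = np.logspace(-3, 3, 10)


@dataclass
class KernelSet:
    weights: np.ndarray   # (n_kernels, max_len), zero-padded rows
    lengths: np.ndarray   # (n_kernels,)
    biases: np.ndarray    # (n_kernels,)
    dilations: np.ndarray  # (n_kernels,)
    paddings: np.ndarray  # (n_kernels,) bool -> zero padding on/off
    seed: int

    @property
    def n_kernels(self) -> int:
        return len(self.lengths)


def generate_kernels(n_kernels: int, input_length: int, seed: int = 0) -> KernelSet:
    """Draw a reproducible random kernel set for inputs of ``input_length``."""
    if input_length < max(KERNEL_LENGTHS):
        raise ValueError(
            f"input_length must be >= {max(KERNEL_LENGTHS)} to fit every kernel length"
        )
    rng = np.random.default_rng(seed)
    lengths = rng.choice(KERNEL_LENGTHS, size=n_kernels)
    max_len = max(KERNEL_LENGTHS)
    weights = np.zeros((n_kernels, max_len))
    biases = rng.uniform(-1.0, 1.0, size=n_kernels)
    dilations = np.empty(n_kernels, dtype=np.int64)
    paddings = rng.integers(0, 2, size=n_kernels).astype(bool)
    for i, l in enumerate(lengths):
        w = rng.standard_normal(l)
        weights[i, :l] = w - w.mean()
        max_exp = np.log2((input_length - 1) / (l - 1))
        dilations[i] = int(2 ** rng.uniform(0, max_exp))
    return KernelSet(weights, lengths.astype(np.int64), biases, dilations, paddings, seed)


@njit(cache=False)
def _apply_kernels(x, weights, lengths, biases, dilations, paddings):  # pragma: no cover
    """PPV/max features for all (window, channel, kernel) triples."""
    n, n_ch, L = x.shape
    n_k = len(lengths)
    out = np.zeros((n, n_ch * n_k * 2))
    for i in range(n):
        for c in range(n_ch):
            series = x[i, c]
            for k in range(n_k):
                l = lengths[k]
                d = dilations[k]
                span = (l - 1) * d
                if paddings[k]:
                    pad = span // 2
                else:
                    pad = 0
                start = -pad
                end = L + pad - span
                if end <= start:
                    end = start + 1  # single valid (clipped) position
                ppv = 0.0
                mx = -1e18
                count = 0
                for s in range(start, end):
                    acc = biases[k]
                    for j in range(l):
                        idx = s + j * d
                        if 0 <= idx < L:
                            acc += weights[k, j] * series[idx]
                    if acc > 0:
                        ppv += 1.0
                    if acc > mx:
                        mx = acc
                    count += 1
                col = (c * n_k + k) * 2
                out[i, col] = ppv / count
                out[i, col + 1] = mx
    return out


def _znorm(x: np.ndarray) -> np.ndarray:
    mean = x.mean(axis=2, keepdims=True)
    std = x.std(axis=2, keepdims=True)
    return (x - mean) / np.where(std > 1e-12, std, 1.0)


def transform(acc: np.ndarray | WindowedDataset, kernels: KernelSet,
              znormalize: bool = True) -> np.ndarray:
    """Feature matrix of shape (N, 2 * n_kernels * n_channels).

    Column layout: channel-major, then kernel, then statistic (ppv, max).
    """
    x = acc.acc if isinstance(acc, WindowedDataset) else np.asarray(acc, float)
    if x.ndim == 2:
        x = x[None]
    if znormalize:
        x = _znorm(x)
    return _apply_kernels(
        np.ascontiguousarray(x, dtype=np.float64),
        kernels.weights, kernels.lengths, kernels.biases,
        kernels.dilations, kernels.paddings,
    )


def feature_provenance(kernels: KernelSet, n_channels: int) -> list[tuple[int, int, str]]:
    """(kernel id, channel, statistic) per feature column."""
    out = []
    for c in range(n_channels):
        for k in range(kernels.n_kernels):
            out.append((k, c, "ppv"))
            out.append((k, c, "max"))
    return out


@dataclass
class RocketModel:
    kernels: KernelSet
    scaler: StandardScaler
    classifier: RidgeClassifier
    alpha: float
    classes: np.ndarray


def _cv_splits(labels: np.ndarray, groups: np.ndarray | None, n_splits: int = 5):
    if groups is not None and len(set(groups)) >= n_splits:
        folds = grouped_stratified_kfold(groups, labels, k=n_splits, seed=0)
        return fold_indices(folds, groups)
    n_splits = min(n_splits, int(np.min(np.bincount(labels))))
    skf = StratifiedKFold(n_splits=max(2, n_splits), shuffle=True, random_state=0)
    return list(skf.split(np.zeros(len(labels)), labels))


def fit(
    features: np.ndarray,
    labels: np.ndarray,
    groups: np.ndarray | None = None,
    alpha_grid: np.ndarray = RIDGE_ALPHA_GRID,
    kernels: KernelSet | None = None,
) -> RocketModel:
    """Standardize features and fit a ridge classifier.

    The regularization strength is chosen from a log-spaced grid by
    internal cross-validation (grouped by patient when groups are given,
    else stratified), scored by balanced accuracy.
    """
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least two classes to fit a classifier")
    scaler = StandardScaler().fit(features)
    z = scaler.transform(features)
    splits = _cv_splits(labels, groups)
    best_alpha, best_score = None, -np.inf
    for alpha in alpha_grid:
        scores = []
        for train_idx, val_idx in splits:
            if len(np.unique(labels[train_idx])) < 2 or len(val_idx) == 0:
                continue
            clf = RidgeClassifier(alpha=alpha).fit(z[train_idx], labels[train_idx])
            pred = _prediction_set(clf, z[val_idx], labels[val_idx])
            scores.append(balanced_accuracy(pred))
        score = np.mean(scores) if scores else -np.inf
        if score > best_score:
            best_alpha, best_score = float(alpha), score
    classifier = RidgeClassifier(alpha=best_alpha).fit(z, labels)
    return RocketModel(kernels, scaler, classifier, best_alpha, classifier.classes_)


def _decision_matrix(clf: RidgeClassifier, z: np.ndarray) -> np.ndarray:
    d = clf.decision_function(z)
    if d.ndim == 1:  # binary: symmetric two-column likelihoods
        d = np.column_stack([-d, d])
    return d


def _prediction_set(clf, z, y_true) -> PredictionSet:
    return PredictionSet(y_true, softmax(_decision_matrix(clf, z)), is_proba=True)


def predict_proba(model: RocketModel, features: np.ndarray) -> np.ndarray:
    """Softmax-mapped class likelihoods (rows sum to 1)."""
    if features.shape[1] != model.scaler.mean_.shape[0]:
        raise ValueError(
            f"feature dimension {features.shape[1]} != model's "
            f"{model.scaler.mean_.shape[0]}"
        )
    z = model.scaler.transform(features)
    return softmax(_decision_matrix(model.classifier, z))


class RocketClassifier:
    """End-to-end convenience wrapper: windows -> kernels -> ridge."""

    def __init__(self, n_kernels: int = 10_000, seed: int = 0) -> None:
        self.n_kernels = n_kernels
        self.seed = seed
        self.kernels: KernelSet | None = None
        self.model: RocketModel | None = None

    def fit(self, dataset: WindowedDataset) -> "RocketClassifier":
        self.kernels = generate_kernels(self.n_kernels, dataset.window_length, self.seed)
        feats = transform(dataset, self.kernels)
        self.model = fit(feats, dataset.labels, groups=dataset.patient_ids,
                         kernels=self.kernels)
        return self

    def predict_proba(self, dataset: WindowedDataset) -> np.ndarray:
        feats = transform(dataset, self.kernels)
        return predict_proba(self.model, feats)

    def predict_set(self, dataset: WindowedDataset) -> PredictionSet:
        return PredictionSet(dataset.labels, self.predict_proba(dataset),
                             class_names=list(dataset.class_names))
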