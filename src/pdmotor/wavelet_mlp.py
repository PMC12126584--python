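"""Baseline classifier: 70 wavelet-derived features + a small MLP.

The feature vector encodes the domain knowledge that motor symptoms shift
wrist-motion frequency content: the acceleration magnitude series is
decomposed into nine levels of a discrete wavelet transform (Daubechies-4
by default), and seven statistics — RMS, standard deviation, maximum,
kurtosis, skew, PSD maximum, PSD minimum — are computed on the original
magnitude and on each level's detail coefficients, giving
7 x (1 + 9) = 70 named features.  A 70 -> 128 -> 128 -> K network with
sigmoid hidden units, softmax output and categorical cross-entropy loss
(Adam optimizer) closes the baseline.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal as sps
from scipy import stats
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .metrics import PredictionSet
from .windows import WindowedDataset

logger = logging.getLogger(__name__)

N_LEVELS = 9
STAT_NAMES = ("rms", "sd", "max", "kurtosis", "skew", "psd_max", "psd_min")
N_FEATURES = len(STAT_NAMES) * (N_LEVELS + 1)  # 70


def feature_names(wavelet: str = "db4") -> list[str]:
    names = [f"orig_{s}" for s in STAT_NAMES]
    for level in range(1, N_LEVELS + 1):
        names.extend(f"d{level}_{s}" for s in STAT_NAMES)
    return names


def _seven_stats(x: np.ndarray, fs: float) -> list[float]:
    x = np.asarray(x, dtype=float)
    rms = float(np.sqrt(np.mean(x**2)))
    sd = float(np.std(x))
    mx = float(np.max(x)) if len(x) else 0.0
    if sd < 1e-12:  # constant series: higher moments defined as 0
        kur, skw = 0.0, 0.0
    else:
        kur = float(stats.kurtosis(x))
        skw = float(stats.skew(x))
    nperseg = min(256, len(x))
    if len(x) >= 2:
        _, psd = sps.welch(x, fs=fs, window="hann", nperseg=nperseg,
                           noverlap=nperseg // 2)
        psd_max, psd_min = float(np.max(psd)), float(np.min(psd))
    else:
        psd_max = psd_min = 0.0
    return [rms, sd, mx, kur, skw, psd_max, psd_min]


def extract_features(window_acc: np.ndarray, fs_hz: float = 50.0,
                     wavelet: str = "db4", per_axis: bool = False) -> np.ndarray:
    """Wavelet feature vector for one window (default: 70 magnitude features).

    ``per_axis=True`` computes the 70 features per axis (210 total) instead
    of on the acceleration magnitude.
    """
    acc = np.atleast_2d(np.asarray(window_acc, dtype=float))
    if per_axis:
        return np.concatenate(
            [_features_for_series(acc[a], fs_hz, wavelet) for a in range(acc.shape[0])]
        )
    magnitude = np.sqrt((acc**2).sum(axis=0)) if acc.shape[0] > 1 else acc[0]
    return _features_for_series(magnitude, fs_hz, wavelet)


def _features_for_series(x: np.ndarray, fs: float, wavelet: str) -> np.ndarray:
    max_level = pywt.dwt_max_level(len(x), pywt.Wavelet(wavelet).dec_len)
    if max_level < N_LEVELS:
        logger.debug(
            "series length %d supports only %d wavelet levels; computing %d anyway",
            len(x), max_level, N_LEVELS,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # over-deep decomposition
        coeffs = pywt.wavedec(x, wavelet, mode="symmetric", level=N_LEVELS)
    # coeffs = [approx, d_N, ..., d_1]; detail level 1 is the finest scale
    details = coeffs[1:][::-1]  # -> [d_1, ..., d_N]
    feats = _seven_stats(x, fs)
    for level, d in enumerate(details, start=1):
        feats.extend(_seven_stats(d, fs / 2**level))
    out = np.asarray(feats, dtype=float)
    if not np.all(np.isfinite(out)):
        raise ValueError("non-finite wavelet feature encountered")
    return out


def extract_feature_matrix(dataset: WindowedDataset, wavelet: str = "db4") -> np.ndarray:
    return np.stack(
        [extract_features(dataset.acc[i], dataset.fs_hz, wavelet)
         for i in range(len(dataset))]
    )


@dataclass
class MlpConfig:
    hidden_layers: tuple[int, int] = (128, 128)
    activation: str = "logistic"  # sigmoid hidden units
    max_epochs: int = 600
    learning_rate: float = 1e-3
    seed: int = 0


@dataclass
class WaveletMlpModel:
    scaler: StandardScaler
    mlp: MLPClassifier
    config: MlpConfig
    wavelet: str = "db4"


def fit_mlp(features: np.ndarray, labels: np.ndarray,
            config: MlpConfig | None = None) -> WaveletMlpModel:
    """Train the 70 -> 128 -> 128 -> K sigmoid network with Adam.

    The softmax output layer and categorical cross-entropy objective are
    the multinomial log-loss minimized by the underlying optimizer.
    """
    config = config or MlpConfig()
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least two classes to fit the MLP")
    scaler = StandardScaler().fit(features)
    mlp = MLPClassifier(
        hidden_layer_sizes=config.hidden_layers,
        activation=config.activation,
        solver="adam",
        learning_rate_init=config.learning_rate,
        max_iter=config.max_epochs,
        random_state=config.seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warnings at reduced epochs
        mlp.fit(scaler.transform(features), labels)
    return WaveletMlpModel(scaler, mlp, config)


def predict_proba(model: WaveletMlpModel, features: np.ndarray) -> np.ndarray:
    return model.mlp.predict_proba(model.scaler.transform(features))


class WaveletMlpClassifier:
    """End-to-end convenience wrapper: windows -> 70 features -> MLP."""

    def __init__(self, config: MlpConfig | None = None, wavelet: str = "db4") -> None:
        self.config = config or MlpConfig()
        self.wavelet = wavelet
        self.model: WaveletMlpModel | None = None

    def fit(self, dataset: WindowedDataset) -> "WaveletMlpClassifier":
        feats = extract_feature_matrix(dataset, self.wavelet)
        self.model = fit_mlp(feats, dataset.labels, self.config)
        return self

    def predict_proba(self, dataset: WindowedDataset) -> np.ndarray:
        feats = extract_feature_matrix(dataset, self.wavelet)
        return predict_proba(self.model, feats)

    def predict_set(self, dataset: WindowedDataset) -> PredictionSet:
        return PredictionSet(dataset.labels, self.predict_proba(dataset),
                             class_names=list(dataset.class_names))
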