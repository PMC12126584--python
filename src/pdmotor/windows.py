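"""Fixed-length window extraction from variable-length recordings.

Time-series classifiers need equal-length inputs; clinical recordings vary
in duration with the time a task takes.  A forward-sliding window of fixed
length with a configurable overlap normalizes the length: longer recordings
contribute more windows.  Recordings shorter than one window contribute
none — a consequence that in severely imbalanced cohorts can silently drop
an entire rare class (e.g. the strongest tremor severity), which is why the
two highest tremor severities are merged into one class downstream.

Indexing is 0-based with half-open windows [start, start + L); the window
step is round(L * (1 - overlap)) with round-half-away-from-zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .simulate import AccelRecording

TREMOR_CLASS_NAMES = ["0", "1", "2", "3-4"]
BINARY_CLASS_NAMES = ["no", "yes"]


@dataclass
class Window:
    acc: np.ndarray  # (3, L)
    label: int
    patient_id: str
    task: str
    source_offset: int  # sample index into the source recording


@dataclass
class WindowedDataset:
    """Stacked windows for one symptom's classification task."""

    acc: np.ndarray  # (N, 3, L)
    labels: np.ndarray  # (N,) int class indices
    patient_ids: np.ndarray  # (N,) str
    tasks: np.ndarray  # (N,) str
    source_offsets: np.ndarray  # (N,) int
    symptom: str
    class_names: list[str]
    fs_hz: float

    def __post_init__(self) -> None:
        if len(self.labels) and self.labels.max() >= len(self.class_names):
            raise ValueError("class index out of range for class_names")

    def __len__(self) -> int:
        return self.acc.shape[0]

    @property
    def window_length(self) -> int:
        return self.acc.shape[2]

    def windows(self) -> list[Window]:
        return [
            Window(self.acc[i], int(self.labels[i]), str(self.patient_ids[i]),
                   str(self.tasks[i]), int(self.source_offsets[i]))
            for i in range(len(self))
        ]

    def subset(self, mask: np.ndarray) -> "WindowedDataset":
        return WindowedDataset(
            self.acc[mask], self.labels[mask], self.patient_ids[mask],
            self.tasks[mask], self.source_offsets[mask],
            self.symptom, list(self.class_names), self.fs_hz,
        )


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def clean_annotations(
    recordings: Sequence[AccelRecording],
) -> tuple[list[AccelRecording], list[dict]]:
    """Drop recordings with missing or implausible annotations.

    Returns the retained recordings and a removal log (one entry per
    dropped recording with the offending field).
    """
    kept: list[AccelRecording] = []
    removed: list[dict] = []

    def _log(rec: AccelRecording, reason: str) -> None:
        removed.append({"patient_id": rec.patient_id, "task": rec.task,
                        "repetition": rec.repetition, "reason": reason})

    for rec in recordings:
        if rec.tremor is None or rec.bradykinesia is None or rec.dyskinesia is None:
            _log(rec, "missing annotation")
            continue
        if not (isinstance(rec.tremor, (int, np.integer)) and 0 <= rec.tremor <= 4):
            _log(rec, f"tremor={rec.tremor!r} outside ordinal range 0-4")
            continue
        if not isinstance(rec.bradykinesia, (bool, np.bool_)):
            _log(rec, f"non-boolean bradykinesia={rec.bradykinesia!r}")
            continue
        if not isinstance(rec.dyskinesia, (bool, np.bool_)):
            _log(rec, f"non-boolean dyskinesia={rec.dyskinesia!r}")
            continue
        kept.append(rec)
    return kept, removed


def slide(
    recording: AccelRecording,
    window_length_s: float,
    overlap_frac: float = 0.5,
    symptom: str = "tremor",
) -> list[Window]:
    """Forward-sliding full windows; short recordings yield zero windows."""
    if not (0 <= overlap_frac < 1):
        raise ValueError("overlap_frac must be in [0, 1)")
    if window_length_s <= 0:
        raise ValueError("window_length_s must be positive")
    L = int(round(window_length_s * recording.fs_hz))
    step = _round_half_away(L * (1.0 - overlap_frac))
    if step == 0:
        raise ValueError(
            f"window step rounds to 0 samples (L={L}, overlap={overlap_frac})"
        )
    T = recording.acc.shape[1]
    label = recording.label(symptom)
    if label is None:
        raise ValueError("recording has no label for symptom; clean annotations first")
    out = []
    for start in range(0, T - L + 1, step):
        out.append(
            Window(
                acc=recording.acc[:, start:start + L],
                label=int(label),
                patient_id=recording.patient_id,
                task=recording.task,
                source_offset=start,
            )
        )
    return out


def n_windows(T: int, L: int, step: int) -> int:
    """Window count for a length-T series: floor((T - L)/step) + 1, 0 if T < L."""
    if T < L:
        return 0
    return (T - L) // step + 1


def build_dataset(
    recordings: Sequence[AccelRecording],
    symptom: str,
    window_length_s: float = 30.0,
    overlap_frac: float = 0.5,
) -> WindowedDataset:
    """Window every recording and stack into one labelled dataset.

    For tremor the raw ordinal severity (0-4) is kept; apply
    :func:`merge_tremor_classes` afterwards for the 4-class task.
    """
    if symptom not in ("tremor", "bradykinesia", "dyskinesia"):
        raise ValueError(f"unknown symptom {symptom!r}")
    all_windows: list[Window] = []
    fs = recordings[0].fs_hz if recordings else 50.0
    for rec in recordings:
        if rec.fs_hz != fs:
            raise ValueError("all recordings must share a sampling rate")
        all_windows.extend(slide(rec, window_length_s, overlap_frac, symptom))
    if symptom == "tremor":
        class_names = ["0", "1", "2", "3", "4"]
    else:
        class_names = list(BINARY_CLASS_NAMES)
    if not all_windows:
        L = int(round(window_length_s * fs))
        return WindowedDataset(
            np.empty((0, 3, L)), np.empty(0, int), np.empty(0, object),
            np.empty(0, object), np.empty(0, int), symptom, class_names, fs,
        )
    return WindowedDataset(
        acc=np.stack([w.acc for w in all_windows]),
        labels=np.array([w.label for w in all_windows], dtype=int),
        patient_ids=np.array([w.patient_id for w in all_windows], dtype=object),
        tasks=np.array([w.task for w in all_windows], dtype=object),
        source_offsets=np.array([w.source_offset for w in all_windows], dtype=int),
        symptom=symptom,
        class_names=class_names,
        fs_hz=fs,
    )


def merge_tremor_classes(dataset: WindowedDataset) -> WindowedDataset:
    """Merge tremor severities 3 and 4 into a single class "3-4"."""
    if dataset.symptom != "tremor":
        raise ValueError("merge_tremor_classes applies to tremor datasets only")
    labels = dataset.labels.copy()
    labels[labels == 4] = 3
    return WindowedDataset(
        acc=dataset.acc, labels=labels, patient_ids=dataset.patient_ids,
        tasks=dataset.tasks, source_offsets=dataset.source_offsets,
        symptom="tremor", class_names=list(TREMOR_CLASS_NAMES), fs_hz=dataset.fs_hz,
    )
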