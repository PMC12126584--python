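"""Grouped stratified data splitting and the random-search driver.

Patients are the grouping unit: a patient's windows must never appear on
both sides of any train/validation/test boundary, otherwise
person-specific signal characteristics leak across the split.  Splits are
additionally stratified so each side resembles the global class
distribution, using total window count per class as a duration proxy.

The assignment algorithm is greedy bin-packing: patients are processed in
decreasing order of total sample count, and each is assigned to the split
(or fold) where the resulting class counts least exceed that split's
target share of every class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np


@dataclass
class FoldSpec:
    fold_id: int
    train_patients: set
    val_patients: set


@dataclass
class TrialRecord:
    trial_id: int
    hyperparams: dict
    fold_scores: list = field(default_factory=list)
    failed: bool = False
    error: str | None = None

    @property
    def mean_score(self) -> float | None:
        valid = [s for s in self.fold_scores if s is not None]
        if self.failed or not valid:
            return None
        return float(np.mean(valid))


def _patient_class_counts(
    patients: Sequence, labels: Sequence[int], n_classes: int
) -> dict:
    counts: dict = {}
    for p, y in zip(patients, labels):
        if p not in counts:
            counts[p] = np.zeros(n_classes)
        counts[p][int(y)] += 1
    return counts


def _greedy_assign(
    counts: Mapping, targets: np.ndarray, rng: np.random.Generator
) -> dict:
    """Assign each patient to one of len(targets) bins.

    targets: fractions summing to 1.  Cost of putting a patient into a bin
    is the overshoot of the bin's class counts past ``target * global``
    summed over classes — the assignment that stays closest to globally
    proportional stratification wins; ties break by the fuller bin's
    remaining capacity, then randomly (seeded).
    """
    keys = sorted(counts.keys(), key=str)
    global_counts = np.sum([counts[k] for k in keys], axis=0)
    order = sorted(keys, key=lambda k: (-counts[k].sum(), str(k)))
    n_bins = len(targets)
    bin_counts = np.zeros((n_bins, len(global_counts)))
    assignment: dict = {}
    jitter = {k: rng.random() for k in order}  # seeded tie-break only
    for k in order:
        best, best_cost = None, None
        for b in range(n_bins):
            new = bin_counts[b] + counts[k]
            overshoot = np.maximum(new - targets[b] * global_counts, 0).sum()
            deficit = np.maximum(targets[b] * global_counts - new, 0).sum()
            cost = (overshoot, -deficit, jitter[k] * (b + 1) % 1)
            if best_cost is None or cost < best_cost:
                best, best_cost = b, cost
        assignment[k] = best
        bin_counts[best] += counts[k]
    return assignment


def grouped_stratified_holdout(
    patients: Sequence,
    labels: Sequence[int],
    fractions: tuple[float, ...] = (0.7, 0.1, 0.2),
    seed: int = 0,
) -> tuple[set, ...]:
    """Partition patients into len(fractions) disjoint sets (train/val/test).

    ``patients``/``labels`` are per-sample (e.g. per recording or per
    window); stratification targets per-class sample counts.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    unique_patients = set(patients)
    if len(unique_patients) < len(fractions):
        raise ValueError(
            f"need at least {len(fractions)} patients, got {len(unique_patients)}"
        )
    n_classes = int(np.max(labels)) + 1
    counts = _patient_class_counts(patients, labels, n_classes)
    assignment = _greedy_assign(counts, np.asarray(fractions), np.random.default_rng(seed))
    out = tuple(set() for _ in fractions)
    for patient, b in assignment.items():
        out[b].add(patient)
    return out


def grouped_stratified_kfold(
    patients: Sequence,
    labels: Sequence[int],
    k: int = 5,
    seed: int = 0,
) -> list[FoldSpec]:
    """k folds with disjoint patients and near-global class proportions.

    Each patient lands in exactly one fold's validation set; the other
    folds' union forms that fold's training set (~(k-1)/k of the data).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    unique_patients = set(patients)
    if len(unique_patients) < k:
        raise ValueError(f"need at least k={k} patients, got {len(unique_patients)}")
    n_classes = int(np.max(labels)) + 1
    counts = _patient_class_counts(patients, labels, n_classes)
    assignment = _greedy_assign(
        counts, np.full(k, 1.0 / k), np.random.default_rng(seed)
    )
    folds = []
    for fold_id in range(k):
        val = {p for p, b in assignment.items() if b == fold_id}
        train = unique_patients - val
        folds.append(FoldSpec(fold_id, train, val))
    return folds


def fold_indices(folds: list[FoldSpec], patients: Sequence) -> list[tuple[np.ndarray, np.ndarray]]:
    """Translate FoldSpecs into (train_idx, val_idx) index arrays."""
    patients = np.asarray(patients, dtype=object)
    out = []
    for fold in folds:
        val_mask = np.isin(patients, list(fold.val_patients))
        out.append((np.where(~val_mask)[0], np.where(val_mask)[0]))
    return out


# ---------------------------------------------------------------------------
# Random search over the Inception-network hyperparameter space

SEARCH_AXES = {
    "filter_length": list(range(8, 256)),
    "depth": list(range(1, 12)),
    "n_filters": [2, 4, 8, 16, 32, 64],
}
WINDOW_LENGTH_RANGE_S = (3.0, 30.0)


class _RefillingPool:
    """Uniform without-replacement sampling; pool refills when exhausted."""

    def __init__(self, values: Sequence, rng: np.random.Generator) -> None:
        self._values = list(values)
        self._rng = rng
        self._pool: list = []

    def draw(self):
        if not self._pool:
            self._pool = list(self._values)
            self._rng.shuffle(self._pool)
        return self._pool.pop()


def sample_search_space(n_trials: int, seed: int = 0) -> list[dict]:
    """Hyperparameter maps for the random search.

    Window length is real-valued in [3, 30] s, sampled uniformly with
    replacement; filter length (8-255), depth (1-11) and number of filters
    (powers of two, 2-64) are sampled uniformly without replacement, pools
    refilling once an axis is exhausted.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    pools = {name: _RefillingPool(vals, rng) for name, vals in SEARCH_AXES.items()}
    trials = []
    for _ in range(n_trials):
        trials.append(
            {
                "window_length_s": float(rng.uniform(*WINDOW_LENGTH_RANGE_S)),
                "filter_length": int(pools["filter_length"].draw()),
                "depth": int(pools["depth"].draw()),
                "n_filters": int(pools["n_filters"].draw()),
            }
        )
    return trials


@dataclass
class SearchResult:
    records: list[TrialRecord]
    jobs: list[tuple[int, int]]  # (trial_id, fold_id) in schedule order

    @property
    def n_scheduled(self) -> int:
        return len(self.jobs)


def run_search(
    trials: Sequence[dict],
    folds: Sequence[FoldSpec],
    fit_and_score: Callable[[dict, FoldSpec], float] | None = None,
    dry_run: bool = False,
) -> SearchResult:
    """Schedule |trials| x |folds| fits; average scores across folds.

    ``fit_and_score(hyperparams, fold)`` trains one model on the fold's
    training patients and returns a validation score (AP/mAP by
    convention).  A failing job marks its trial failed but the search
    continues.  ``dry_run`` enumerates the schedule without fitting.
    """
    records = [TrialRecord(i, dict(t)) for i, t in enumerate(trials)]
    jobs = [(t.trial_id, f.fold_id) for t in records for f in folds]
    if dry_run:
        return SearchResult(records, jobs)
    if fit_and_score is None:
        raise ValueError("fit_and_score required unless dry_run=True")
    for record in records:
        for fold in folds:
            try:
                score = float(fit_and_score(record.hyperparams, fold))
                record.fold_scores.append(score)
            except Exception as exc:  # noqa: BLE001 - search must continue
                record.fold_scores.append(None)
                record.failed = True
                record.error = f"fold {fold.fold_id}: {exc}"
    return SearchResult(records, jobs)
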