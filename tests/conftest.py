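"""Shared fixtures: synthetic cohorts and window datasets reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

from pdmotor.error_analysis import binarize_tremor
from pdmotor.selection import grouped_stratified_holdout
from pdmotor.simulate import CohortConfig, easy_cohort_config, generate_cohort
from pdmotor.windows import WindowedDataset, build_dataset


def _split(dataset: WindowedDataset, seed: int = 0):
    train_p, val_p, test_p = grouped_stratified_holdout(
        dataset.patient_ids, dataset.labels, (0.7, 0.1, 0.2), seed=seed
    )
    fit_mask = np.isin(dataset.patient_ids, list(train_p | val_p))
    test_mask = np.isin(dataset.patient_ids, list(test_p))
    return dataset.subset(fit_mask), dataset.subset(test_mask)


@pytest.fixture(scope="session")
def large_cohort():
    """~10 000 recordings under the default clinical-structure config."""
    config = CohortConfig(n_patients=556, repetitions_per_task=1, seed=7)
    return config, generate_cohort(config)


@pytest.fixture(scope="session")
def easy_tremor_recordings():
    return generate_cohort(easy_cohort_config(seed=0, symptom="tremor"))


@pytest.fixture(scope="session")
def easy_tremor_split(easy_tremor_recordings):
    """Binary tremor-presence task, 5 s windows, grouped 80/20 fit/test."""
    ds = build_dataset(easy_tremor_recordings, "tremor", 5.0, 0.5)
    ds = WindowedDataset(
        ds.acc, binarize_tremor(ds.labels), ds.patient_ids, ds.tasks,
        ds.source_offsets, "tremor", ["absent", "present"], ds.fs_hz,
    )
    return _split(ds)


@pytest.fixture(scope="session")
def easy_brady_split():
    """Binary bradykinesia task, 2 s windows, single-factor cohort."""
    recordings = generate_cohort(easy_cohort_config(seed=0, symptom="bradykinesia"))
    ds = build_dataset(recordings, "bradykinesia", 2.0, 0.0)
    return _split(ds)
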