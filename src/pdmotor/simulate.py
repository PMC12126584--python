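"""Synthetic cohorts of annotated tri-axial wrist accelerometer recordings.

Real studies of Parkinson's-disease (PD) motor symptoms record wrist
acceleration at 50 Hz while patients perform a battery of prescribed
activities of daily living (ADL); each task performance receives clinical
annotations (tremor severity 0-4, bradykinesia yes/no, dyskinesia yes/no).
This module generates cohorts with that statistical structure so the whole
classification and evaluation pipeline can be exercised without access to
clinical data.

The signal model is additive: symptom components are superimposed on the
voluntary motion of the task.

    acc(t) = gravity + voluntary(t) * brady_factor + tremor(t) + dyskinesia(t)

* gravity: constant 9.81 m/s^2 split over the axes by a random fixed
  sensor orientation.
* voluntary: band-limited Gaussian noise in the task's characteristic
  frequency band, scaled to the task's intensity.  Bradykinesia (slowness
  of movement) multiplies this component by an attenuation factor < 1 and
  narrows the band toward low frequencies, reproducing the empirical
  signature that bradykinetic recordings have lower magnitude S.D.
* tremor: a sinusoid with frequency drawn uniformly in the classical
  parkinsonian 4-6 Hz band, amplitude proportional to ordinal severity,
  with random phase and axis loading.
* dyskinesia: band-limited noise in 1-4 Hz (slower than tremor, faster
  than most voluntary motion), present when the flag is set.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

GRAVITY = 9.81
TREMOR_BAND = (4.0, 6.0)
DYSKINESIA_BAND = (1.0, 4.0)

SYMPTOMS = ("tremor", "bradykinesia", "dyskinesia")


@dataclass(frozen=True)
class TaskProfile:
    """Spectral/intensity profile of one prescribed motor task."""

    name: str
    base_band_hz: tuple[float, float]
    base_intensity: float  # m/s^2, std of the voluntary component per axis
    fine_motor: bool = False

    def validate(self, sampling_hz: float) -> None:
        low, high = self.base_band_hz
        if not (0 <= low < high < sampling_hz / 2):
            raise ValueError(
                f"task {self.name!r}: band {self.base_band_hz} must satisfy "
                f"0 <= low < high < Nyquist ({sampling_hz / 2} Hz)"
            )
        if self.base_intensity < 0:
            raise ValueError(f"task {self.name!r}: negative intensity")


def default_task_catalog() -> list[TaskProfile]:
    """A plausible battery of 18 ADL tasks.

    Fine-motor tasks concentrate voluntary power in bands overlapping the
    4-6 Hz tremor band; gross-motor (walking) tasks are intense but slower;
    postural tasks are nearly quiescent.
    """
    return [
        TaskProfile("drawing", (0.5, 6.0), 0.8, fine_motor=True),
        TaskProfile("writing", (0.5, 6.0), 0.7, fine_motor=True),
        TaskProfile("typing", (1.0, 8.0), 0.6, fine_motor=True),
        TaskProfile("nuts-and-bolts assembly", (0.5, 7.0), 0.9, fine_motor=True),
        TaskProfile("organizing papers", (0.5, 5.0), 0.9, fine_motor=True),
        TaskProfile("drinking", (0.3, 4.5), 0.8, fine_motor=True),
        TaskProfile("buttoning a shirt", (0.5, 6.0), 0.7, fine_motor=True),
        TaskProfile("folding laundry", (0.3, 4.0), 1.1),
        TaskProfile("pouring water", (0.3, 4.0), 0.8, fine_motor=True),
        TaskProfile("combing hair", (0.8, 5.0), 1.2),
        TaskProfile("opening a door", (0.3, 3.5), 1.0),
        TaskProfile("walking straight", (0.5, 3.5), 2.4),
        TaskProfile("walking down a passage", (0.5, 3.5), 1.7),
        TaskProfile("walking a narrow passage", (0.5, 3.0), 1.4),
        TaskProfile("walking upstairs", (0.5, 3.5), 2.0),
        TaskProfile("standing", (0.1, 1.5), 0.15),
        TaskProfile("sitting", (0.1, 1.0), 0.1),
        TaskProfile("alternating hand movements", (1.0, 4.0), 1.5),
    ]


def default_prevalence() -> dict[str, np.ndarray]:
    # Duration-weighted class shares of a strongly imbalanced clinical cohort:
    # severe tremor is very rare, dyskinesia covers ~11 % of recording time.
    return {
        "tremor": np.array([0.675, 0.227, 0.076, 0.0207, 0.0013]),
        "bradykinesia": np.array([0.68, 0.32]),
        "dyskinesia": np.array([0.89, 0.11]),
    }


@dataclass(frozen=True)
class CohortConfig:
    n_patients: int = 10
    task_catalog: Sequence[TaskProfile] = field(default_factory=default_task_catalog)
    repetitions_per_task: int = 1
    sampling_hz: float = 50.0
    duration_mean_s: float = 29.2
    duration_sd_s: float = 11.6
    duration_min_s: float = 5.0
    symptom_prevalence: dict[str, np.ndarray] = field(default_factory=default_prevalence)
    effect_scales: dict[str, float] = field(
        default_factory=lambda: {
            # tremor sinusoid amplitude per severity point, m/s^2
            "tremor": 0.6,
            # dyskinesia band-noise std, m/s^2
            "dyskinesia": 0.5,
            # multiplicative attenuation of voluntary motion under bradykinesia
            "bradykinesia": 0.55,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_hz <= 0:
            raise ValueError("sampling_hz must be positive")
        if self.duration_min_s <= 0:
            raise ValueError("duration_min_s must be positive")
        if self.n_patients < 1 or self.repetitions_per_task < 1:
            raise ValueError("n_patients and repetitions_per_task must be >= 1")
        for symptom in SYMPTOMS:
            if symptom not in self.symptom_prevalence:
                raise ValueError(f"missing prevalence table for {symptom!r}")
            p = np.asarray(self.symptom_prevalence[symptom], dtype=float)
            if p.ndim != 1 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"prevalence for {symptom!r} must be a probability vector")
        n_tremor = len(np.asarray(self.symptom_prevalence["tremor"]))
        if n_tremor != 5:
            raise ValueError("tremor prevalence must have 5 classes (severities 0-4)")
        for symptom in ("bradykinesia", "dyskinesia"):
            if len(np.asarray(self.symptom_prevalence[symptom])) != 2:
                raise ValueError(f"{symptom} prevalence must have 2 classes (no/yes)")
        for profile in self.task_catalog:
            profile.validate(self.sampling_hz)


@dataclass
class AccelRecording:
    """One task performance: 3 x T acceleration at fs_hz plus annotations."""

    patient_id: str
    task: str
    fs_hz: float
    acc: np.ndarray  # shape (3, T), m/s^2
    tremor: int | None
    bradykinesia: bool | None
    dyskinesia: bool | None
    repetition: int = 0

    @property
    def duration_s(self) -> float:
        return self.acc.shape[1] / self.fs_hz

    def label(self, symptom: str) -> int | None:
        value = getattr(self, symptom)
        return None if value is None else int(value)


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                band: tuple[float, float], target_std: float) -> np.ndarray:
    """Gaussian noise brick-wall band-limited to `band`, scaled to target_std."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not mask.any():  # degenerate: band narrower than frequency resolution
        mask[np.argmin(np.abs(freqs - 0.5 * (band[0] + band[1])))] = True
    spec[~mask] = 0.0
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    if sd > 0:
        x *= target_std / sd
    return x


def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    norm = np.linalg.norm(v)
    while norm < 1e-12:
        v = rng.standard_normal(3)
        norm = np.linalg.norm(v)
    return v / norm


def synthesize_signal(
    profile: TaskProfile,
    tremor: int,
    brady: bool,
    dysk: bool,
    duration_s: float,
    fs_hz: float = 50.0,
    seed: int | np.random.Generator = 0,
    effect_scales: dict[str, float] | None = None,
) -> np.ndarray:
    """Synthesize a 3 x T tri-axial acceleration series for one recording."""
    if duration_s < 1.0 / fs_hz:
        raise ValueError("duration_s must cover at least one sample")
    if effect_scales is None:
        effect_scales = CohortConfig().effect_scales
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration_s * fs_hz))
    t = np.arange(n) / fs_hz

    # constant gravity along a random fixed orientation
    orientation = _random_unit_vector(rng)
    acc = np.outer(orientation * GRAVITY, np.ones(n))

    # voluntary motion, attenuated + low-pass shifted when bradykinetic
    low, high = profile.base_band_hz
    intensity = profile.base_intensity
    if brady:
        intensity *= effect_scales["bradykinesia"]
        high = max(low + 0.1, low + (high - low) * 0.7)
    for axis in range(3):
        acc[axis] += _band_noise(rng, n, fs_hz, (low, high), intensity)

    # parkinsonian tremor: 4-6 Hz sinusoid, amplitude ∝ severity
    if tremor > 0:
        freq = rng.uniform(*TREMOR_BAND)
        phase = rng.uniform(0, 2 * np.pi)
        loading = _random_unit_vector(rng)
        amp = effect_scales["tremor"] * tremor
        acc += np.outer(loading, amp * np.sin(2 * np.pi * freq * t + phase))

    # dyskinesia: 1-4 Hz involuntary writhing
    if dysk:
        loading = _random_unit_vector(rng)
        noise = _band_noise(rng, n, fs_hz, DYSKINESIA_BAND, effect_scales["dyskinesia"])
        acc += np.outer(loading, noise)

    return acc


def draw_durations(config: CohortConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Truncated-normal recording durations (lower bound duration_min_s)."""
    a = (config.duration_min_s - config.duration_mean_s) / config.duration_sd_s
    return stats.truncnorm.rvs(
        a, np.inf, loc=config.duration_mean_s, scale=config.duration_sd_s,
        size=n, random_state=rng,
    )


def generate_cohort(config: CohortConfig) -> list[AccelRecording]:
    """One recording per patient x task x repetition.

    Symptom labels are drawn per (patient, task) and shared by the
    repetitions of that task, emulating the clinical setting in which a
    patient's symptom state is stable within one test-battery pass.
    Deterministic: identical (config, seed) yields a bit-identical cohort.
    """
    rng = np.random.default_rng(config.seed)
    prevalence = {s: np.asarray(p, float) for s, p in config.symptom_prevalence.items()}
    recordings: list[AccelRecording] = []
    n_total = config.n_patients * len(config.task_catalog) * config.repetitions_per_task
    durations = draw_durations(config, n_total, rng)
    i = 0
    for p in range(config.n_patients):
        patient_id = f"P{p:03d}"
        for profile in config.task_catalog:
            tremor = int(rng.choice(len(prevalence["tremor"]), p=prevalence["tremor"]))
            brady = bool(rng.choice(2, p=prevalence["bradykinesia"]))
            dysk = bool(rng.choice(2, p=prevalence["dyskinesia"]))
            for rep in range(config.repetitions_per_task):
                acc = synthesize_signal(
                    profile, tremor, brady, dysk,
                    duration_s=durations[i], fs_hz=config.sampling_hz,
                    seed=rng, effect_scales=config.effect_scales,
                )
                recordings.append(
                    AccelRecording(
                        patient_id=patient_id, task=profile.name,
                        fs_hz=config.sampling_hz, acc=acc,
                        tremor=tremor, bradykinesia=brady, dyskinesia=dysk,
                        repetition=rep,
                    )
                )
                i += 1
    return recordings


# ---------------------------------------------------------------------------
# CSV round trip (long-form samples + label table)

def write_cohort_csv(recordings: Sequence[AccelRecording], samples_path, labels_path) -> None:
    sample_frames = []
    label_rows = []
    for rec in recordings:
        t_s = np.arange(rec.acc.shape[1]) / rec.fs_hz
        sample_frames.append(
            pd.DataFrame(
                {
                    "patient_id": rec.patient_id,
                    "task": rec.task,
                    "repetition": rec.repetition,
                    "t_s": t_s,
                    "ax": rec.acc[0],
                    "ay": rec.acc[1],
                    "az": rec.acc[2],
                }
            )
        )
        label_rows.append(
            {
                "patient_id": rec.patient_id,
                "task": rec.task,
                "repetition": rec.repetition,
                "tremor": rec.tremor,
                "bradykinesia": rec.bradykinesia,
                "dyskinesia": rec.dyskinesia,
            }
        )
    pd.concat(sample_frames, ignore_index=True).to_csv(samples_path, index=False)
    pd.DataFrame(label_rows).to_csv(labels_path, index=False)


def read_cohort_csv(samples_path, labels_path, fs_hz: float = 50.0) -> list[AccelRecording]:
    samples = pd.read_csv(samples_path)
    labels = pd.read_csv(labels_path)
    labels = labels.set_index(["patient_id", "task", "repetition"])
    recordings = []
    for key, group in samples.groupby(["patient_id", "task", "repetition"], sort=False):
        group = group.sort_values("t_s")
        acc = np.vstack([group["ax"].to_numpy(), group["ay"].to_numpy(), group["az"].to_numpy()])
        row = labels.loc[key]
        tremor = None if pd.isna(row["tremor"]) else int(row["tremor"])
        recordings.append(
            AccelRecording(
                patient_id=str(key[0]), task=str(key[1]), repetition=int(key[2]),
                fs_hz=fs_hz, acc=acc,
                tremor=tremor,
                bradykinesia=None if pd.isna(row["bradykinesia"]) else bool(row["bradykinesia"]),
                dyskinesia=None if pd.isna(row["dyskinesia"]) else bool(row["dyskinesia"]),
            )
        )
    return recordings


def easy_cohort_config(n_patients: int = 12, seed: int = 0,
                       symptom: str | None = None) -> CohortConfig:
    """A small cohort with strong, well-separated symptom effects.

    Used for recovery experiments: symptom amplitudes are large relative
    to voluntary motion and the class balance is far milder than the
    clinical default, so a working classifier should approach ceiling
    performance.  Short recordings keep desk-scale runtimes low.

    ``symptom`` restricts the cohort to a single-factor experiment: the
    other symptoms' prevalences collapse to all-absent, so their signal
    components cannot confound the recovery of the one under study.
    """
    prevalence = {
        "tremor": np.array([0.45, 0.25, 0.15, 0.1, 0.05]),
        "bradykinesia": np.array([0.5, 0.5]),
        "dyskinesia": np.array([0.6, 0.4]),
    }
    if symptom is not None:
        absent = {
            "tremor": np.array([1.0, 0.0, 0.0, 0.0, 0.0]),
            "bradykinesia": np.array([1.0, 0.0]),
            "dyskinesia": np.array([1.0, 0.0]),
        }
        prevalence = {s: (prevalence[s] if s == symptom else absent[s])
                      for s in prevalence}
    return CohortConfig(
        n_patients=n_patients,
        task_catalog=[
            # comparable intensities keep the bradykinesia attenuation cue
            # separable from between-task intensity differences
            TaskProfile("drawing", (0.5, 3.0), 0.8, fine_motor=True),
            TaskProfile("walking straight", (0.5, 3.0), 1.2),
            TaskProfile("folding laundry", (0.3, 2.5), 1.0),
            TaskProfile("typing", (1.0, 3.5), 0.9, fine_motor=True),
        ],
        repetitions_per_task=2,
        duration_mean_s=12.0,
        duration_sd_s=3.0,
        duration_min_s=6.0,
        symptom_prevalence=prevalence,
        effect_scales={"tremor": 1.5, "dyskinesia": 1.2, "bradykinesia": 0.4},
        seed=seed,
    )


def config_from_dict(d: dict) -> CohortConfig:
    """Build a CohortConfig from a plain (e.g. YAML-loaded) mapping."""
    d = dict(d)
    if "task_catalog" in d:
        d["task_catalog"] = [
            TaskProfile(
                name=t["name"],
                base_band_hz=tuple(t["base_band_hz"]),
                base_intensity=float(t["base_intensity"]),
                fine_motor=bool(t.get("fine_motor", False)),
            )
            for t in d["task_catalog"]
        ]
    if "symptom_prevalence" in d:
        d["symptom_prevalence"] = {
            k: np.asarray(v, dtype=float) for k, v in d["symptom_prevalence"].items()
        }
    valid = {f.name for f in dataclasses.fields(CohortConfig)}
    unknown = set(d) - valid
    if unknown:
        raise ValueError(f"unknown cohort config keys: {sorted(unknown)}")
    return CohortConfig(**d)
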