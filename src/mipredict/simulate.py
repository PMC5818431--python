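"""Synthetic two-class motor-imagery EEG with controllable ERD effect size.

The generative model is the minimal one that exhibits the structure a CSP +
LDA decoder exploits. Two fixed, lateralized source topographies (one per
hemisphere, peaked over the sensorimotor channel region) carry band-limited
mu-rhythm oscillations. During the imagery interval of each trial the source
contralateral to the cued hand is attenuated by a factor ``1 - erd_depth``
(event-related desynchronization); the ipsilateral source is untouched.
Sources are mixed linearly into channel space on top of spatially white 1/f
background noise. There is no volume-conduction forward model, no ocular or
muscular artifact, and no non-stationarity beyond the ERD envelope itself.

Trial timing follows a cue-based protocol: each 7 s trial shows a fixation
cross for 2 s, the left/right cue for 3 s (the imagery interval), then a
cross again for 2 s; inter-trial intervals are drawn uniformly from
[0.1, 0.8] s. A session is 5–6 runs of 20 trials per class.

Cohorts add a per-subject latent skill that sets ``erd_depth`` and drives
noisy self-prediction scores on the 50–100 % scale, with pre-task
predictions drawn independently of skill (subjects have no basis to predict
before experiencing the task).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy import signal

from .table import SubjectRecord, SubjectTable

__all__ = [
    "GeneratorConfig",
    "CohortConfig",
    "Recording",
    "default_topographies",
    "generate_subject",
    "generate_cohort",
    "save_recording",
    "load_recording",
]


@dataclass
class Recording:
    """Continuous multichannel EEG with cue events.

    ``samples`` is channels x time in microvolts; ``events`` is a list of
    ``(sample_index, label, run_index)`` with ``label`` in {"left", "right"}
    and ``sample_index`` the cue onset (imagery start).
    """

    samples: np.ndarray
    sampling_rate: float
    events: list[tuple[int, str, int]]

    def __post_init__(self):
        idx = [e[0] for e in self.events]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("event sample indices must be strictly increasing")
        for s, label, _run in self.events:
            if label not in ("left", "right"):
                raise ValueError(f"event label must be left/right, got {label!r}")
            if not (0 <= s < self.samples.shape[1]):
                raise ValueError(f"event at sample {s} outside recording")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.sampling_rate


def default_topographies(n_channels: int) -> tuple[np.ndarray, np.ndarray]:
    """Two unit-norm lateralized topographies (left/right hemisphere sources).

    Gaussian bumps centred at 1/4 and 3/4 of the channel axis, standing in
    for sources under C3 and C4 in a lateral channel ordering.
    """
    x = np.arange(n_channels, dtype=float)
    width = max(n_channels / 8.0, 1.0)
    left = np.exp(-0.5 * ((x - n_channels / 4.0) / width) ** 2)
    right = np.exp(-0.5 * ((x - 3.0 * n_channels / 4.0) / width) ** 2)
    return left / np.linalg.norm(left), right / np.linalg.norm(right)


@dataclass
class GeneratorConfig:
    """Single-subject generation parameters.

    ``erd_depth`` is the fraction of contralateral mu-source amplitude
    suppressed during imagery (0 = classes identical, 1 = complete
    suppression). ``snr`` is the amplitude ratio of each source to the
    per-channel background noise (std units).
    """

    n_channels: int = 64
    sampling_rate: float = 512.0
    n_runs: int = 5
    trials_per_class_per_run: int = 20
    trial_duration: float = 7.0
    cue_onset: float = 2.0        # s into the trial
    imagery_duration: float = 3.0  # s after cue onset
    erd_depth: float = 0.5
    mu_band: tuple[float, float] = (8.0, 12.0)
    noise_exponent: float = 1.0
    snr: float = 0.4
    iti_range: tuple[float, float] = (0.1, 0.8)
    source_topographies: tuple[np.ndarray, np.ndarray] | None = None
    seed: int | Sequence[int] = 0

    def validate(self) -> None:
        if not (0.0 <= self.erd_depth <= 1.0):
            raise ValueError(f"erd_depth must be in [0, 1], got {self.erd_depth}")
        if self.trials_per_class_per_run <= 0:
            raise ValueError("trials_per_class_per_run must be positive")
        if self.n_runs <= 0:
            raise ValueError("n_runs must be positive")
        lo, hi = self.mu_band
        if not (0 < lo < hi < self.sampling_rate / 2):
            raise ValueError(f"mu_band {self.mu_band} violates Nyquist at "
                             f"{self.sampling_rate} Hz")
        if self.cue_onset + self.imagery_duration > self.trial_duration:
            raise ValueError("imagery interval exceeds trial duration")
        if self.source_topographies is not None:
            for t in self.source_topographies:
                if len(t) != self.n_channels:
                    raise ValueError("topography length != n_channels")
                if not np.isclose(np.linalg.norm(t), 1.0, atol=1e-6):
                    raise ValueError("topographies must have unit norm")


def _one_over_f_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                      exponent: float, sampling_rate: float) -> np.ndarray:
    """Spatially white noise with a 1/f**exponent power spectrum, unit std."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sampling_rate)
    # amplitude shaping: power ~ f^-exponent; flat below 1 Hz to avoid blow-up
    shape = np.ones_like(freqs)
    nz = freqs >= 1.0
    shape[nz] = freqs[nz] ** (-exponent / 2.0)
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1) * shape
    noise = np.fft.irfft(spec, n=n_samples, axis=1)
    noise /= noise.std(axis=1, keepdims=True)
    return noise


def _mu_source(rng: np.random.Generator, n_samples: int, band, fs) -> np.ndarray:
    """Band-limited oscillation: white noise band-passed to the mu band, unit std."""
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n_samples))
    return x / x.std()


def generate_subject(config: GeneratorConfig) -> Recording:
    """Generate one subject's continuous recording. Deterministic given seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    n_trial = int(round(config.trial_duration * fs))
    pad = int(round(1.0 * fs))  # head/tail padding, keeps filtering edges away

    # trial layout: per run, shuffled 20+20 labels, random ITIs
    starts, labels, runs = [], [], []
    cursor = pad
    for run in range(config.n_runs):
        run_labels = ["left"] * config.trials_per_class_per_run + \
                     ["right"] * config.trials_per_class_per_run
        rng.shuffle(run_labels)
        for lab in run_labels:
            starts.append(cursor)
            labels.append(lab)
            runs.append(run)
            iti = rng.uniform(*config.iti_range)
            cursor += n_trial + int(round(iti * fs))
    n_samples = cursor + pad

    src_rng = np.random.default_rng(rng.integers(2**31))
    s_left = _mu_source(src_rng, n_samples, config.mu_band, fs)
    s_right = _mu_source(src_rng, n_samples, config.mu_band, fs)

    # ERD envelopes: contralateral source attenuated during imagery
    env_left = np.ones(n_samples)   # envelope of the left-hemisphere source
    env_right = np.ones(n_samples)
    cue = int(round(config.cue_onset * fs))
    img = int(round(config.imagery_duration * fs))
    gain = 1.0 - config.erd_depth
    for start, lab in zip(starts, labels):
        a, b = start + cue, start + cue + img
        if lab == "left":        # left-hand imagery -> right hemisphere ERD
            env_right[a:b] = gain
        else:
            env_left[a:b] = gain

    topo = config.source_topographies
    if topo is None:
        topo = default_topographies(config.n_channels)
    topo_l, topo_r = (np.asarray(t, dtype=float) for t in topo)

    noise_rng = np.random.default_rng(rng.integers(2**31))
    x = _one_over_f_noise(noise_rng, config.n_channels, n_samples,
                          config.noise_exponent, fs)
    x += config.snr * (np.outer(topo_l, s_left * env_left) +
                       np.outer(topo_r, s_right * env_right))
    x *= 10.0  # nominal microvolt scale

    events = [(s + cue, lab, run) for s, lab, run in zip(starts, labels, runs)]
    return Recording(samples=x, sampling_rate=fs, events=events)


@dataclass
class CohortConfig:
    """Cohort-level parameters: latent skill spread and self-prediction noise.

    ``skill_distribution`` maps an rng and a count to erd_depth draws; the
    default is uniform on [0.1, 0.9], spanning near-illiterate to proficient
    subjects. ``prediction_noise_sd`` may be a scalar (same noise at every
    run) or a per-run sequence (e.g. decreasing, to emulate subjects whose
    self-assessment sharpens with task experience). ``prediction_link`` maps
    skill in [0, 1] to the 50–100 % prediction scale.
    """

    n_subjects: int = 20
    skill_distribution: Callable[[np.random.Generator, int], np.ndarray] = \
        lambda rng, n: rng.uniform(0.1, 0.9, size=n)
    prediction_noise_sd: float | Sequence[float] = 5.0
    prediction_link: Callable[[np.ndarray], np.ndarray] = \
        lambda skill: 50.0 + 50.0 * np.asarray(skill)
    pre_task_range: tuple[float, float] = (50.0, 90.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 3:
            raise ValueError(
                f"cohort needs at least 3 subjects, got {self.n_subjects}")


def generate_cohort(
    cohort: CohortConfig, base: GeneratorConfig,
) -> tuple[list[Recording], SubjectTable]:
    """Generate a cohort of recordings plus a subject table with simulated scores.

    Per subject: ``erd_depth`` is drawn from the skill distribution; each
    run's accuracy prediction is ``clamp(link(skill) + noise, 50, 100)`` and
    AP is their mean; preAP is drawn independently of skill. The table's ACC
    column is left unset — decoding fills it.
    """
    cohort.validate()
    base.validate()
    rng = np.random.default_rng(cohort.seed)
    skills = np.clip(cohort.skill_distribution(rng, cohort.n_subjects), 0.0, 1.0)
    noise_sd = np.atleast_1d(np.asarray(cohort.prediction_noise_sd, dtype=float))
    if noise_sd.size == 1:
        noise_sd = np.full(base.n_runs, noise_sd[0])
    if noise_sd.size != base.n_runs:
        raise ValueError(
            f"prediction_noise_sd has {noise_sd.size} entries for "
            f"{base.n_runs} runs")

    subject_seeds = rng.integers(2**31, size=cohort.n_subjects)
    recordings, records = [], []
    for i, (skill, sseed) in enumerate(zip(skills, subject_seeds)):
        rec = generate_subject(replace(base, erd_depth=float(skill),
                                       seed=int(sseed)))
        recordings.append(rec)
        target = float(np.clip(cohort.prediction_link(skill), 50.0, 100.0))
        run_preds = np.clip(target + rng.normal(0.0, noise_sd), 50.0, 100.0)
        records.append(SubjectRecord(
            subject_id=f"sim{i + 1}",
            pre_task_prediction=float(rng.uniform(*cohort.pre_task_range)),
            easiness=float(np.clip(1.0 + 4.0 * skill, 1.0, 5.0)),
            mean_run_prediction=float(run_preds.mean()),
            run_predictions=[float(v) for v in run_preds],
        ))
    table = SubjectTable(records, provenance=f"synthetic:seed={cohort.seed}")
    return recordings, table


def save_recording(rec: Recording, prefix: str | Path) -> None:
    """Write ``<prefix>.npy`` (channels x time) + ``<prefix>.json`` sidecar."""
    prefix = Path(prefix)
    np.save(prefix.with_suffix(".npy"), rec.samples)
    sidecar = {
        "sampling_rate": rec.sampling_rate,
        "events": [[int(s), lab, int(run)] for s, lab, run in rec.events],
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar))


def load_recording(prefix: str | Path) -> Recording:
    prefix = Path(prefix)
    samples = np.load(prefix.with_suffix(".npy"))
    meta = json.loads(prefix.with_suffix(".json").read_text())
    events = [(int(s), lab, int(run)) for s, lab, run in meta["events"]]
    return Recording(samples=samples, sampling_rate=float(meta["sampling_rate"]),
                     events=events)
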