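"""Band-pass filtering and cue-locked epoching.

The decoding band is 8–30 Hz (mu + beta), applied zero-phase to the
continuous recording before epoching so filter edge transients never touch
trial windows. Epochs are cut from the half-open window [0.4, 2.4) s after
cue onset, with sample index = floor(t * rate).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .simulate import Recording

__all__ = ["EpochSet", "bandpass", "epoch"]

CLASSES = ("left", "right")


@dataclass
class EpochSet:
    """Epoched trials: ``epochs`` is trials x channels x time."""

    epochs: np.ndarray
    labels: np.ndarray      # per-trial, "left"/"right"
    run_index: np.ndarray   # per-trial int
    sampling_rate: float
    window: tuple[float, float] = (0.4, 2.4)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        self.run_index = np.asarray(self.run_index)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be trials x channels x time")
        n = self.epochs.shape[0]
        if len(self.labels) != n or len(self.run_index) != n:
            raise ValueError("labels/run_index length must match trial count")

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    def class_counts(self) -> dict[str, int]:
        return {c: int(np.sum(self.labels == c)) for c in CLASSES}

    def select(self, mask) -> "EpochSet":
        return EpochSet(self.epochs[mask], self.labels[mask],
                        self.run_index[mask], self.sampling_rate, self.window)

    def runs(self) -> list[int]:
        return sorted(int(r) for r in np.unique(self.run_index))


def bandpass(recording: Recording, low: float = 8.0, high: float = 30.0,
             order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass of every channel; events untouched."""
    nyq = recording.sampling_rate / 2.0
    if not (0.0 < low < high < nyq):
        raise ValueError(
            f"band edges ({low}, {high}) must satisfy 0 < low < high < "
            f"Nyquist ({nyq} Hz)")
    sos = signal.butter(order, (low, high), btype="bandpass",
                        fs=recording.sampling_rate, output="sos")
    filtered = signal.sosfiltfilt(sos, recording.samples, axis=1)
    return Recording(samples=filtered, sampling_rate=recording.sampling_rate,
                     events=list(recording.events))


def epoch(recording: Recording,
          window: tuple[float, float] = (0.4, 2.4)) -> EpochSet:
    """Cut one epoch per cue event from the half-open window [t0, t1) s.

    Raises if any event's window falls outside the recording, listing the
    offending events.
    """
    t0, t1 = window
    if t1 <= t0:
        raise ValueError(f"empty window {window}")
    fs = recording.sampling_rate
    off0 = int(np.floor(t0 * fs))
    off1 = int(np.floor(t1 * fs))
    n_samples = recording.samples.shape[1]

    bad = [(s, lab, run) for s, lab, run in recording.events
           if s + off0 < 0 or s + off1 > n_samples]
    if bad:
        raise ValueError(
            f"{len(bad)} event(s) whose window [{t0}, {t1}) s falls outside "
            f"the recording: {bad[:5]}{'...' if len(bad) > 5 else ''}")

    epochs = np.stack([recording.samples[:, s + off0:s + off1]
                       for s, _lab, _run in recording.events])
    labels = np.array([lab for _s, lab, _run in recording.events])
    runs = np.array([run for _s, _lab, run in recording.events])
    return EpochSet(epochs=epochs, labels=labels, run_index=runs,
                    sampling_rate=fs, window=(t0, t1))
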