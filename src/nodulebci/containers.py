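"""Core in-memory containers shared across the pipeline.

An :class:`EEGRecording` is the continuous multichannel signal with stimulus
event markers; an :class:`Epoch` is one fixed-length per-stimulus window with
its binary target label, the unit that gets classified.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Event", "EEGRecording", "Epoch"]


@dataclass(frozen=True)
class Event:
    """Stimulus marker: sample index of onset, image identity, target flag."""

    sample: int
    identity: int
    is_target: bool


@dataclass
class EEGRecording:
    """Continuous multichannel EEG in microvolts.

    data has shape (n_channels, n_samples); events are sorted by onset sample
    and must lie inside the recording.  At least two channels are required so
    that a common average reference is meaningful.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)
    events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (n_channels, n_samples)")
        if self.data.shape[0] < 2:
            raise ValueError("need at least 2 channels")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not self.channel_labels:
            self.channel_labels = [f"EEG{i:02d}" for i in range(self.n_channels)]
        if len(self.channel_labels) != self.n_channels:
            raise ValueError("channel_labels length mismatch")
        samples = [e.sample for e in self.events]
        if samples != sorted(samples):
            self.events = sorted(self.events, key=lambda e: e.sample)
            samples = [e.sample for e in self.events]
        if samples and (samples[0] < 0 or samples[-1] >= self.n_samples):
            raise ValueError("event sample index outside the recording")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class Epoch:
    """One stimulus-locked window: (n_channels, n_window_samples) in µV."""

    data: np.ndarray
    fs: float
    is_target: bool
    identity: int
    t0_offset_ms: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("epoch data must be 2-D (n_channels, n_samples)")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]
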