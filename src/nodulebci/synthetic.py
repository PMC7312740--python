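"""Synthetic oddball RSVP EEG sessions and CT image fixtures with known truth.

The generator emulates the study conditions of the interpreter experiment:
rapid serial presentation at a fixed 200 ms onset interval, rare target
images embedded among background images at a 1:5 ratio, each image identity
repeated a fixed number of times, and a frontal-dominant positive deflection
(P300-like, peaking near 300 ms with an ~40 ms full width at half maximum)
added to the EEG whenever a target image is on screen.  Background activity
is per-channel 1/f noise plus an optional 10 Hz rhythm; there is no head
model, volume conduction, or artifact simulation.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .containers import EEGRecording, Event
from .errors import ValidationError

__all__ = [
    "SimConfig",
    "default_frontal_weights",
    "default_channel_labels",
    "generate_event_schedule",
    "generate_oddball_session",
    "generate_synthetic_ct",
]

# A small frontal-to-occipital label sequence; prefixes beyond 16 channels
# fall back to numbered labels.
_CANONICAL_LABELS = [
    "Fp1", "Fp2", "Fz", "F3", "F4", "Cz", "C3", "C4",
    "Pz", "P3", "P4", "Oz", "O1", "O2", "T7", "T8",
]


def default_channel_labels(n_channels: int) -> list[str]:
    labels = _CANONICAL_LABELS[:n_channels]
    labels += [f"EEG{i:02d}" for i in range(len(labels), n_channels)]
    return labels


def default_frontal_weights(n_channels: int) -> np.ndarray:
    """Per-channel scaling of the target response.

    The target response is prefrontal-dominant: the frontal quarter of the
    montage (at least two channels) gets weight 1 and the remaining channels
    decay linearly to 0.2.  Exact numbers are a modelling choice; only the
    frontal dominance is prescribed by the underlying physiology.
    """
    n_front = max(2, n_channels // 4)
    n_front = min(n_front, n_channels)
    w = np.ones(n_channels)
    rest = n_channels - n_front
    if rest > 0:
        w[n_front:] = np.linspace(1.0, 0.2, rest + 1)[1:]
    return w


@dataclass
class SimConfig:
    """Study-condition knobs for one simulated oddball session.

    Defaults mirror the experimental protocol: 1000 Hz acquisition, 200 ms
    inter-stimulus onset interval, 1 target per 5 background images, 13
    repetitions per image identity, P300 peak at 300 ms spanning roughly
    280-320 ms.
    """

    n_channels: int = 8
    fs: float = 1000.0
    n_events: int = 312
    target_ratio: float = 1.0 / 6.0
    isi_ms: float = 200.0
    n_repetitions: int = 13
    p300_amplitude: float = 5.0      # µV at the peak on full-weight channels
    p300_latency_ms: float = 300.0
    p300_width_ms: float = 40.0      # full width at half maximum
    noise_sd: float = 10.0           # µV per channel
    noise_alpha: float = 1.0         # 1/f^alpha background exponent
    alpha_amplitude: float = 2.0     # µV, 10 Hz rhythm; 0 disables
    alpha_freq_hz: float = 10.0
    frontal_weights: np.ndarray | None = None
    seed: int = 0
    max_duration_s: float = 1800.0

    def __post_init__(self) -> None:
        if not (0.0 < self.target_ratio < 1.0):
            raise ValidationError("target_ratio must lie in (0, 1)")
        if self.fs <= 0:
            raise ValidationError("fs must be positive")
        if self.n_events < 1:
            raise ValidationError("n_events must be >= 1")
        if self.n_channels < 2:
            raise ValidationError("need at least 2 channels")
        if self.noise_sd < 0 or self.p300_amplitude < 0:
            raise ValidationError("noise_sd and p300_amplitude must be >= 0")
        if self.n_repetitions < 1 or self.isi_ms <= 0:
            raise ValidationError("n_repetitions >= 1 and isi_ms > 0 required")
        if self.frontal_weights is None:
            self.frontal_weights = default_frontal_weights(self.n_channels)
        self.frontal_weights = np.asarray(self.frontal_weights, dtype=float)
        if self.frontal_weights.shape != (self.n_channels,):
            raise ValidationError("frontal_weights must have length n_channels")
        if np.any(self.frontal_weights < 0) or not np.isclose(
            self.frontal_weights.max(), 1.0
        ):
            raise ValidationError("frontal_weights must be >= 0 with max 1")


def generate_event_schedule(
    n_identities: int,
    target_ratio: float,
    n_repetitions: int,
    seed: int = 0,
) -> list[tuple[int, bool]]:
    """Exact-count oddball schedule: (identity, is_target) pairs in order.

    Every identity appears exactly ``n_repetitions`` times and the number of
    target identities is ``round(n_identities * target_ratio)`` (exact when
    divisible).  The full event list is a seeded permutation, so counts are
    deterministic while order is randomised — matching how oddball blocks fix
    proportions in practice rather than drawing i.i.d. stimuli.
    """
    if n_identities < 1 or n_repetitions < 1:
        raise ValidationError("counts must be >= 1")
    if not (0.0 < target_ratio < 1.0):
        raise ValidationError("target_ratio must lie in (0, 1)")
    n_targets = int(round(n_identities * target_ratio))
    if not (1 <= n_targets <= n_identities - 1):
        raise ValidationError(
            "target_ratio incompatible with n_identities: no valid target count"
        )
    events = [
        (ident, ident < n_targets)
        for ident in range(n_identities)
        for _ in range(n_repetitions)
    ]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(events))
    return [events[i] for i in order]


def _powerlaw_noise(
    n_channels: int, n_samples: int, alpha: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-channel 1/f^alpha noise, unit variance, generated spectrally."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n_samples)
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** (-alpha / 2.0)
    x = np.fft.irfft(spec * scale[None, :], n=n_samples, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _p300_template(config: SimConfig) -> np.ndarray:
    """Gaussian positive half-wave peaking at the configured latency.

    sigma is chosen so the full width at half maximum equals p300_width_ms,
    i.e. the deflection spans roughly the 280-320 ms window at defaults.
    """
    fs = config.fs
    sigma_s = (config.p300_width_ms / 1000.0) / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    half_span = int(round(4 * sigma_s * fs))
    center = int(round(config.p300_latency_ms / 1000.0 * fs))
    t = np.arange(center - half_span, center + half_span + 1)
    g = np.exp(-0.5 * ((t / fs - config.p300_latency_ms / 1000.0) / sigma_s) ** 2)
    return t, config.p300_amplitude * g


def generate_oddball_session(config: SimConfig) -> EEGRecording:
    """Simulate one oddball RSVP session as a continuous recording.

    Event onsets are spaced ``isi_ms`` apart with one second of padding on
    either side.  Target events additively carry the frontal-weighted P300
    template; the schedule, noise, and rhythm phases are all derived from
    ``config.seed`` so the recording is bit-identical across calls.

    n_events is rounded to a whole number of repetition blocks
    (n_identities = round(n_events / n_repetitions), each shown
    n_repetitions times).
    """
    n_identities = max(2, int(round(config.n_events / config.n_repetitions)))
    ss = np.random.SeedSequence(config.seed)
    seed_sched, seed_noise, seed_phase = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)
    ]
    schedule = generate_event_schedule(
        n_identities, config.target_ratio, config.n_repetitions, seed=seed_sched
    )
    n_events = len(schedule)

    isi_samples = int(round(config.isi_ms / 1000.0 * config.fs))
    pad = int(round(1.0 * config.fs))
    n_samples = pad + n_events * isi_samples + pad
    if n_samples / config.fs > config.max_duration_s:
        raise ValidationError(
            f"session of {n_samples / config.fs:.1f} s exceeds "
            f"max_duration_s={config.max_duration_s}"
        )

    noise_rng = np.random.default_rng(seed_noise)
    data = config.noise_sd * _powerlaw_noise(
        config.n_channels, n_samples, config.noise_alpha, noise_rng
    )
    if config.alpha_amplitude > 0:
        phase_rng = np.random.default_rng(seed_phase)
        phases = phase_rng.uniform(0, 2 * np.pi, size=config.n_channels)
        t = np.arange(n_samples) / config.fs
        data += config.alpha_amplitude * np.sin(
            2 * np.pi * config.alpha_freq_hz * t[None, :] + phases[:, None]
        )

    events: list[Event] = []
    tmpl_idx, tmpl = _p300_template(config)
    for i, (ident, is_target) in enumerate(schedule):
        onset = pad + i * isi_samples
        events.append(Event(sample=onset, identity=ident, is_target=is_target))
        if is_target and config.p300_amplitude > 0:
            idx = tmpl_idx + onset
            ok = (idx >= 0) & (idx < n_samples)
            data[:, idx[ok]] += config.frontal_weights[:, None] * tmpl[None, ok]

    return EEGRecording(
        data=data,
        fs=config.fs,
        channel_labels=default_channel_labels(config.n_channels),
        events=events,
    )


# ---------------------------------------------------------------------------
# Synthetic CT fixtures for the presentation module
# ---------------------------------------------------------------------------

def generate_synthetic_ct(
    shape: tuple[int, ...],
    n_nodules: int,
    nodule_intensity_range: tuple[float, float] = (800.0, 1000.0),
    seed: int = 0,
    nodule_radius_range: tuple[int, int] = (3, 6),
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic 16-bit CT-like stack plus a boolean nodule mask.

    The background mimics a bimodal chest histogram: bright soft tissue
    (~1200 raw units) with two dark elliptical lung fields (~300 units).
    Nodules are bright disks strictly inside the lung fields, mutually
    separated so each forms its own connected component.  This is a display
    fixture, not an anatomical model.
    """
    if n_nodules < 0:
        raise ValidationError("n_nodules must be >= 0")
    if len(shape) == 2:
        stack_shape = (1,) + tuple(shape)
        squeeze = True
    elif len(shape) == 3:
        stack_shape = tuple(shape)
        squeeze = False
    else:
        raise ValidationError("shape must be 2-D or 3-D")
    if min(stack_shape) < 1:
        raise ValidationError("shape entries must be positive")
    n_slices, h, w = stack_shape
    rng = np.random.default_rng(seed)

    stack = rng.normal(1200.0, 30.0, size=stack_shape)
    yy, xx = np.mgrid[0:h, 0:w]
    lungs = np.zeros((h, w), dtype=bool)
    for cx_frac in (0.3, 0.7):
        cy, cx = 0.5 * h, cx_frac * w
        ry, rx = 0.32 * h, 0.16 * w
        lungs |= ((yy - cy) / max(ry, 1)) ** 2 + ((xx - cx) / max(rx, 1)) ** 2 <= 1.0
    for s in range(n_slices):
        stack[s][lungs] = rng.normal(300.0, 40.0, size=int(lungs.sum()))

    mask = np.zeros(stack_shape, dtype=bool)
    centers: list[tuple[int, int, int, int]] = []  # (slice, y, x, r)
    lo, hi = nodule_intensity_range
    attempts = 0
    placed = 0
    while placed < n_nodules:
        attempts += 1
        if attempts > 200 * max(1, n_nodules):
            raise ValidationError(
                "could not place all nodules inside the lung region"
            )
        r = int(rng.integers(nodule_radius_range[0], nodule_radius_range[1] + 1))
        s = int(rng.integers(0, n_slices))
        y = int(rng.integers(r + 1, h - r - 1)) if h > 2 * r + 2 else -1
        x = int(rng.integers(r + 1, w - r - 1)) if w > 2 * r + 2 else -1
        if y < 0 or x < 0:
            raise ValidationError("nodules cannot fit in the image")
        disk = (yy - y) ** 2 + (xx - x) ** 2 <= r**2
        if not lungs[disk].all():
            continue
        # keep components disjoint regardless of slice adjacency
        if any((y - cy) ** 2 + (x - cx) ** 2 <= (r + cr + 3) ** 2
               for _, cy, cx, cr in centers):
            continue
        stack[s][disk] = rng.uniform(lo, hi, size=int(disk.sum()))
        mask[s][disk] = True
        centers.append((s, y, x, r))
        placed += 1

    stack = np.clip(stack, 0, 65535).astype(np.uint16)
    if squeeze:
        return stack[0], mask[0]
    return stack, mask
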