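"""Respiratory motion model and surrogate trace.

The platform motion follows the idealized breathing waveform

    A(phi) = A0 * (1 - cos(2*pi*phi))**2,   phi in [0, 1],

with relative phase phi advancing linearly in time over a fixed period T.
Phase 0 is end-exhale (the displacement minimum, A(0) = 0) and phase 0.5 is
peak inhale; the peak-to-peak excursion is 4*A0. The defaults (T = 5 s,
A0 = 0.75 cm, i.e. 3.0 cm excursion) describe regular breathing of a
superior-inferior moving target.

An infrared-marker style surrogate trace is generated from the same
waveform (the marker platform moves in phase with the imaged platform) and
is what the retrospective sorting stage consumes; the sorter never sees the
ground-truth phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_A0 = 0.75      # cm; gives the 3.0 cm peak-to-peak excursion
DEFAULT_PERIOD = 5.0   # s
DEFAULT_SURROGATE_RATE = 30.0  # Hz


@dataclass
class MotionWaveform:
    """Breathing waveform parameters: amplitude constant, period, start phase."""

    A0: float = DEFAULT_A0
    period: float = DEFAULT_PERIOD
    phase0: float = 0.0

    def __post_init__(self):
        if self.A0 < 0:
            raise ValueError("A0 must be non-negative")
        if self.period <= 0:
            raise ValueError("period must be positive")
        if not 0 <= self.phase0 < 1:
            raise ValueError("phase0 must lie in [0, 1)")


@dataclass
class SurrogateTrace:
    """Timestamped surrogate displacement samples (both in native units)."""

    timestamps: np.ndarray  # s
    amplitudes: np.ndarray  # cm
    sample_rate: float      # Hz

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.timestamps.shape != self.amplitudes.shape:
            raise ValueError("timestamps and amplitudes must have equal length")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def to_csv(self, path) -> None:
        np.savetxt(path, np.column_stack([self.timestamps, self.amplitudes]),
                   delimiter=",", header="time_s,amplitude_cm", comments="")

    @classmethod
    def from_csv(cls, path) -> "SurrogateTrace":
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
        ts = arr[:, 0]
        rate = 1.0 / float(np.median(np.diff(ts))) if len(ts) > 1 else 0.0
        return cls(timestamps=ts, amplitudes=arr[:, 1], sample_rate=rate)


def amplitude_at_phase(waveform: MotionWaveform, phi):
    """Displacement (cm) at relative phase ``phi`` in [0, 1]."""
    phi = np.asarray(phi, dtype=float)
    if np.any((phi < 0) | (phi > 1)):
        raise ValueError("phase must lie in [0, 1]")
    return waveform.A0 * (1.0 - np.cos(2.0 * np.pi * phi)) ** 2


def phase_at_time(waveform: MotionWaveform, t):
    """Relative phase in [0, 1) at time ``t`` (s)."""
    t = np.asarray(t, dtype=float)
    return np.mod(t / waveform.period + waveform.phase0, 1.0)


def displacement_at_time(waveform: MotionWaveform, t):
    """Displacement (cm) at time ``t`` (s)."""
    return amplitude_at_phase(waveform, phase_at_time(waveform, t))


def excursion_for_waveform(waveform: MotionWaveform) -> float:
    """Peak-to-peak displacement over one cycle: max A(phi) - min A(phi) = 4*A0."""
    return 4.0 * waveform.A0


def generate_surrogate_trace(waveform: MotionWaveform, duration: float,
                             sample_rate: float = DEFAULT_SURROGATE_RATE,
                             noise_sd: float = 0.0,
                             seed: int | None = None) -> SurrogateTrace:
    """Sample the waveform at a uniform rate, optionally with Gaussian noise.

    ``noise_sd`` is the standard deviation (cm) of additive position noise,
    emulating marker-tracking jitter; 0 gives the ideal trace. Deterministic
    for a given seed.
    """
    if duration <= 0 or sample_rate <= 0:
        raise ValueError("duration and sample_rate must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    n = int(np.floor(duration * sample_rate)) + 1
    ts = np.arange(n) / sample_rate
    amp = displacement_at_time(waveform, ts)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        amp = amp + rng.normal(0.0, noise_sd, size=amp.shape)
    return SurrogateTrace(timestamps=ts, amplitudes=amp,
                         sample_rate=sample_rate)


def mean_interframe_motion(waveform: MotionWaveform, frame_rate: float,
                           n_samples: int = 200_000) -> float:
    """Mean absolute displacement change (cm) between consecutive frames.

    Averages |A(t + 1/F) - A(t)| over one breathing period by dense numerical
    sampling. In the fast-frame limit this tends to the closed form
    mean|dA/dt| / F = 8*A0 / (T*F): the waveform's total variation per period
    is twice the excursion, 8*A0.
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    t = np.linspace(0.0, waveform.period, n_samples, endpoint=False)
    d0 = displacement_at_time(waveform, t)
    d1 = displacement_at_time(waveform, t + 1.0 / frame_rate)
    return float(np.mean(np.abs(d1 - d0)))
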