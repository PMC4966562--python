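"""Retrospective respiratory phase sorting.

Phase is estimated from the surrogate trace alone (never from the
ground-truth waveform): breathing-cycle anchors are the detected local
maxima of the surrogate displacement, which for the idealized waveform sit
at relative phase 0.5 (peak inhale), and phase advances linearly in time
between consecutive anchors. End-exhale (the displacement minimum) is
therefore phase 0 by construction. Projections are then assigned to
``n_bins`` half-open phase bins [k/n, (k+1)/n) by their timestamp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .acquisition import ProjectionSet
from .errors import InsufficientCyclesError
from .motion import SurrogateTrace

#: Peak detection: minimum separation as a fraction of the cycle length and
#: prominence as a fraction of the trace range.
MIN_SEPARATION_FRAC = 0.5
PROMINENCE_FRAC = 0.1


@dataclass
class PhaseFunction:
    """Piecewise-linear cumulative phase anchored at surrogate peaks.

    Calling it returns the relative phase in [0, 1) at arbitrary times;
    times beyond the first/last anchor are extrapolated with the nearest
    cycle length (flagged via :meth:`is_extrapolated`).
    """

    anchor_times: np.ndarray  # s, detected peak times (phase 0.5 each)
    span: tuple               # (t_min, t_max) of the underlying trace

    def cumulative(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        at = self.anchor_times
        vals = 0.5 + np.arange(len(at))
        cum = np.interp(t, at, vals)
        # linear extrapolation with the first/last cycle length
        lo = t < at[0]
        hi = t > at[-1]
        if np.any(lo):
            cum = np.where(lo, 0.5 + (t - at[0]) / (at[1] - at[0]), cum)
        if np.any(hi):
            cum = np.where(
                hi, vals[-1] + (t - at[-1]) / (at[-1] - at[-2]), cum)
        return cum

    def __call__(self, t) -> np.ndarray:
        return np.mod(self.cumulative(t), 1.0)

    def is_extrapolated(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return (t < self.anchor_times[0]) | (t > self.anchor_times[-1])

    @property
    def cycle_lengths(self) -> np.ndarray:
        return np.diff(self.anchor_times)


@dataclass
class PhaseAssignment:
    """Per-projection phase and bin label."""

    projection_phases: np.ndarray  # in [0, 1)
    bin_labels: np.ndarray         # int in [0, n_bins)
    n_bins: int
    extrapolated: np.ndarray | None = None

    def bin_indices(self, label: int) -> np.ndarray:
        return np.nonzero(self.bin_labels == label)[0]

    def bin_sizes(self) -> np.ndarray:
        return np.bincount(self.bin_labels, minlength=self.n_bins)

    def to_csv(self, path, timestamps=None) -> None:
        n = len(self.projection_phases)
        ts = (np.asarray(timestamps, dtype=float) if timestamps is not None
              else np.full(n, np.nan))
        arr = np.column_stack(
            [np.arange(n), ts, self.projection_phases, self.bin_labels])
        np.savetxt(path, arr, delimiter=",",
                   header="projection_index,timestamp_s,phase,bin",
                   comments="", fmt=["%d", "%.6f", "%.6f", "%d"])


def phase_function(trace: SurrogateTrace,
                   min_period: float | None = None,
                   prominence_frac: float = PROMINENCE_FRAC) -> PhaseFunction:
    """Detect breathing-cycle anchors in the trace and build the phase map.

    Peak detection requires a prominence of ``prominence_frac`` of the trace
    range and a separation of at least half the cycle length; when
    ``min_period`` is not given the cycle length is taken from a first
    prominence-only pass.
    """
    amp = trace.amplitudes
    rng = float(np.ptp(amp))
    if rng <= 0 or not np.isfinite(rng):
        raise InsufficientCyclesError("surrogate trace has no modulation")
    prominence = prominence_frac * rng
    if min_period is None:
        first, _ = find_peaks(amp, prominence=prominence)
        if len(first) >= 2:
            min_period = float(np.median(np.diff(trace.timestamps[first])))
    kwargs = {"prominence": prominence}
    if min_period is not None:
        dt = float(np.median(np.diff(trace.timestamps)))
        kwargs["distance"] = max(1, int(MIN_SEPARATION_FRAC * min_period / dt))
    peaks, _ = find_peaks(amp, **kwargs)
    if len(peaks) < 2:
        raise InsufficientCyclesError(
            f"found {len(peaks)} breathing peak(s); need at least 2 cycles")
    return PhaseFunction(
        anchor_times=trace.timestamps[peaks],
        span=(float(trace.timestamps[0]), float(trace.timestamps[-1])))


def estimate_phase(trace: SurrogateTrace, **kwargs) -> np.ndarray:
    """Relative phase in [0, 1) at every trace sample."""
    return phase_function(trace, **kwargs)(trace.timestamps)


def assign_bins(projection_timestamps, phase_fn, n_bins: int,
                check_span: bool = True,
                centered: bool = False) -> PhaseAssignment:
    """Assign each projection to a phase bin via its timestamp.

    ``phase_fn`` maps times to phase in [0, 1) (a :class:`PhaseFunction` or
    any callable). By default bins are half-open intervals anchored at the
    lower edge, [k/n, (k+1)/n), so a phase of exactly k/n goes to bin k.
    With ``centered=True`` bin k instead spans [k/n - 1/(2n), k/n + 1/(2n))
    (wrapping at 1), i.e. each bin is centered on its nominal phase k/n --
    the convention of clinical retrospective 4D sorting, where the
    peak-inhale bin straddles phase 0.5. Centered bins track the extreme of
    an amplitude waveform symmetrically and are what the 4D excursion
    pipeline uses.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be at least 1")
    ts = np.asarray(projection_timestamps, dtype=float)
    extrapolated = None
    if isinstance(phase_fn, PhaseFunction):
        if check_span:
            lo, hi = phase_fn.span
            if np.any(ts < lo) or np.any(ts > hi):
                raise ValueError(
                    "projection timestamps fall outside the surrogate trace")
        extrapolated = phase_fn.is_extrapolated(ts)
    phases = np.asarray(phase_fn(ts), dtype=float)
    if centered:
        labels = np.floor(phases * n_bins + 0.5).astype(int) % n_bins
    else:
        labels = np.minimum(np.floor(phases * n_bins).astype(int), n_bins - 1)
    return PhaseAssignment(projection_phases=phases, bin_labels=labels,
                           n_bins=n_bins, extrapolated=extrapolated)


def partition_projections(projections: ProjectionSet,
                          assignment: PhaseAssignment) -> list:
    """Split a projection set into one subset per phase bin.

    Subsets are disjoint, keep their timestamps and angles, and their sizes
    sum to the input projection count (possibly with empty bins).
    """
    if len(assignment.bin_labels) != projections.n_projections:
        raise ValueError("assignment length does not match projection count")
    return [projections.subset(assignment.bin_indices(k))
            for k in range(assignment.n_bins)]
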