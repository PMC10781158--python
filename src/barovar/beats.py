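"""Beat detection and segmentation for continuous arterial-pressure recordings.

The continuous signal is a directly recorded arterial-pressure waveform
(mmHg, uniform sampling).  Beat extraction reduces it to a *systogram*
(per-beat systolic pressure) and *tachogram* (per-beat pulse interval, the
time between consecutive systolic peaks), the two series on which all
variability and baroreflex endpoints are computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

log = logging.getLogger(__name__)

__all__ = [
    "PressureWaveform",
    "BeatSeries",
    "SegmentSet",
    "NoBeatsError",
    "detect_systolic_peaks",
    "split_segments",
]


class NoBeatsError(ValueError):
    """Raised when a waveform contains no detectable systolic peaks."""


@dataclass(frozen=True)
class PressureWaveform:
    """Uniformly sampled arterial-pressure trace.

    Parameters
    ----------
    samples : array of float
        Pressure in mmHg.
    fs : float
        Sampling rate in Hz.
    start_time : float
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    fs: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError("waveform needs at least 2 samples")
        if not np.all(np.isfinite(samples)):
            raise ValueError("waveform contains non-finite samples")

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.fs

    @property
    def duration(self) -> float:
        return (self.samples.size - 1) / self.fs


@dataclass(frozen=True)
class BeatSeries:
    """Per-beat systolic times, systolic pressures and pulse intervals.

    ``t`` (s), ``sbp`` (mmHg) and ``pi`` (ms) have equal length and are
    aligned per beat.  A pulse interval is the time elapsed since the
    previous systolic peak; series built from a detected waveform therefore
    start at the second detected beat.
    """

    t: np.ndarray
    sbp: np.ndarray
    pi: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        sbp = np.asarray(self.sbp, dtype=float)
        pi = np.asarray(self.pi, dtype=float)
        for name, arr in (("t", t), ("sbp", sbp), ("pi", pi)):
            object.__setattr__(self, name, arr)
        if not (t.size == sbp.size == pi.size):
            raise ValueError("t, sbp and pi must have equal length")
        if t.size < 1:
            raise ValueError("empty beat series")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("beat times must be strictly increasing")
        if not np.all(pi > 0):
            raise ValueError("pulse intervals must be positive")
        if not (np.all(np.isfinite(sbp)) and np.all(np.isfinite(t))):
            raise ValueError("beat series contains non-finite values")

    @property
    def n_beats(self) -> int:
        return int(self.t.size)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def window(self, start: float, stop: float, closed_right: bool = False) -> "BeatSeries":
        """Beats with ``start <= t < stop`` (``<= stop`` if closed_right)."""
        if closed_right:
            mask = (self.t >= start) & (self.t <= stop)
        else:
            mask = (self.t >= start) & (self.t < stop)
        if mask.sum() < 2:
            raise ValueError(
                f"window [{start:.1f}, {stop:.1f}) s retains fewer than 2 beats"
            )
        return BeatSeries(self.t[mask], self.sbp[mask], self.pi[mask])


@dataclass(frozen=True)
class SegmentSet:
    """Non-overlapping analysis windows cut from one recording."""

    segments: list[BeatSeries] = field(default_factory=list)
    window_s: float = 300.0
    count: int = 3

    def __post_init__(self) -> None:
        if len(self.segments) != self.count:
            raise ValueError("segment count does not match declared count")

    def __iter__(self):
        return iter(self.segments)

    def __len__(self) -> int:
        return len(self.segments)


def detect_systolic_peaks(
    w: PressureWaveform,
    min_pi_ms: float = 120.0,
    min_prominence_mmhg: float = 10.0,
) -> BeatSeries:
    """Detect systolic peaks in a pressure waveform.

    A sample is a systolic peak if it is a local maximum with prominence of
    at least ``min_prominence_mmhg`` and lies at least ``min_pi_ms`` after
    the previous accepted peak (refractory rule; the taller of two
    conflicting candidates wins).  The 120 ms default refractory period
    corresponds to a 500 bpm ceiling, above any rat heart rate.

    Returns a :class:`BeatSeries` starting at the second detected peak,
    since the first peak has no defined pulse interval.
    """
    if not min_pi_ms > 0:
        raise ValueError("min_pi_ms must be positive")
    distance = max(1, int(round(min_pi_ms / 1000.0 * w.fs)))
    idx, _ = find_peaks(w.samples, distance=distance, prominence=min_prominence_mmhg)
    if idx.size < 2:
        raise NoBeatsError("no beats detected")
    t = w.start_time + idx / w.fs
    pi = np.diff(t) * 1000.0
    median_hr_hz = 1000.0 / np.median(pi)
    if w.fs < 4 * median_hr_hz:
        log.warning(
            "sampling rate %.1f Hz is below 4x the detected heart rate (%.2f Hz); "
            "peak amplitudes may be under-sampled",
            w.fs,
            median_hr_hz,
        )
    return BeatSeries(t=t[1:], sbp=w.samples[idx][1:], pi=pi)


def split_segments(
    b: BeatSeries,
    window_s: float = 300.0,
    count: int = 3,
    placement: str = "even",
    starts: list[float] | None = None,
) -> SegmentSet:
    """Cut ``count`` non-overlapping windows of ``window_s`` seconds.

    ``placement`` controls where the windows sit in the record:

    - ``"even"`` (default): evenly spaced so the first window starts at the
      beginning and the last ends at the end of the record;
    - ``"first"``: contiguous windows from the start;
    - ``"explicit"``: user-supplied ``starts`` (seconds).
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    total = b.duration
    needed = count * window_s
    if total < needed:
        raise ValueError(
            f"recording spans {total:.1f} s but {count} windows of "
            f"{window_s:.0f} s require {needed:.0f} s"
        )
    t0 = float(b.t[0])
    if placement == "even":
        if count == 1:
            offsets = [t0]
        else:
            step = (total - window_s) / (count - 1)
            offsets = [t0 + i * step for i in range(count)]
    elif placement == "first":
        offsets = [t0 + i * window_s for i in range(count)]
    elif placement == "explicit":
        if starts is None or len(starts) != count:
            raise ValueError("explicit placement requires `starts` of length `count`")
        offsets = sorted(float(s) for s in starts)
        for a, bb in zip(offsets, offsets[1:]):
            if bb - a < window_s:
                raise ValueError("explicit windows overlap")
    else:
        raise ValueError(f"unknown placement {placement!r}")
    segments = []
    for i, start in enumerate(offsets):
        closed = i == count - 1 and placement == "even"
        segments.append(b.window(start, start + window_s, closed_right=closed))
    return SegmentSet(segments=segments, window_s=window_s, count=count)
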