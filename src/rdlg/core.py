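"""Core domain types: sampled signals, spike trains, labeled time intervals.

All times are seconds on one shared session clock.  Intervals are half-open
``[start, end)`` and sample indexing is 0-based: sample ``i`` of a signal
occurs at ``t0_s + i / rate_hz``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

import numpy as np

INTERVAL_KINDS = {
    "ripple", "sharp_wave", "swr", "delta", "spindle", "off_period",
    "nrem", "rem", "wake", "other", "immobility",
}

REGIONS = {"CA1", "RSC"}
CELL_CLASSES = {"excitatory", "inhibitory", "unclassified"}


class ValidationError(ValueError):
    """Raised when a domain invariant is violated."""


class FormatError(ValueError):
    """Raised when an on-disk file does not match the expected layout."""


@dataclass
class SampledSignal:
    """Uniformly sampled signal (LFP or EMG), in microvolts or a.u."""

    samples: np.ndarray
    rate_hz: float
    t0_s: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.rate_hz <= 0:
            raise ValidationError(f"rate_hz must be positive, got {self.rate_hz}")
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValidationError("samples must be a non-empty 1-D array")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n / self.rate_hz

    @property
    def end_s(self) -> float:
        return self.t0_s + self.duration_s

    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n) / self.rate_hz

    def index_of(self, t_s: float) -> int:
        """Index of the sample bin containing time ``t_s`` (clipped to range)."""
        i = int(np.floor((t_s - self.t0_s) * self.rate_hz))
        return min(max(i, 0), self.n - 1)

    def slice(self, start_s: float, end_s: float) -> "SampledSignal":
        i0 = max(0, int(np.ceil((start_s - self.t0_s) * self.rate_hz)))
        i1 = min(self.n, int(np.ceil((end_s - self.t0_s) * self.rate_hz)))
        if i1 <= i0:
            raise ValidationError("empty signal slice")
        return SampledSignal(self.samples[i0:i1], self.rate_hz,
                             self.t0_s + i0 / self.rate_hz, self.label)


@dataclass
class SpikeTrain:
    """Sorted spike times of one unit."""

    unit_id: str
    region: str
    times_s: np.ndarray
    cell_class: str = "unclassified"

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=np.float64)
        if self.region not in REGIONS:
            raise ValidationError(
                f"unit {self.unit_id}: unknown region {self.region!r}")
        if self.times_s.size and np.any(np.diff(self.times_s) < 0):
            raise ValidationError(
                f"unit {self.unit_id}: spike times not sorted")
        if self.cell_class not in CELL_CLASSES:
            raise ValidationError(
                f"unit {self.unit_id}: unknown cell class {self.cell_class!r}")

    @property
    def n_spikes(self) -> int:
        return self.times_s.size

    def rate_hz(self, duration_s: float) -> float:
        return self.n_spikes / duration_s if duration_s > 0 else np.nan


@dataclass(frozen=True)
class Interval:
    """Half-open labeled time interval with optional peak annotation."""

    start_s: float
    end_s: float
    kind: str = "other"
    peak_s: Optional[float] = None
    peak_score: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ValidationError(
                f"interval start {self.start_s} must precede end {self.end_s}")
        if self.peak_s is not None and not (self.start_s <= self.peak_s <= self.end_s):
            raise ValidationError("peak_s outside interval")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def contains(self, t: float) -> bool:
        return self.start_s <= t < self.end_s

    def overlaps(self, other: "Interval") -> bool:
        return self.start_s < other.end_s and other.start_s < self.end_s


class IntervalSet:
    """Ordered collection of intervals of one kind.

    Intervals are kept sorted by start time.  ``merged()`` produces the
    non-overlapping union required by the within-kind invariant.
    """

    def __init__(self, intervals: Iterable[Interval] = (), kind: str = "other"):
        self.kind = kind
        self.intervals = sorted(intervals, key=lambda iv: (iv.start_s, iv.end_s))

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    @classmethod
    def from_arrays(cls, starts, ends, kind="other", peaks=None, scores=None):
        peaks = [None] * len(starts) if peaks is None else peaks
        scores = [None] * len(starts) if scores is None else scores
        ivs = [Interval(float(s), float(e), kind,
                        None if p is None or (isinstance(p, float) and np.isnan(p)) else float(p),
                        None if q is None or (isinstance(q, float) and np.isnan(q)) else float(q))
               for s, e, p, q in zip(starts, ends, peaks, scores)]
        return cls(ivs, kind)

    @property
    def starts(self) -> np.ndarray:
        return np.array([iv.start_s for iv in self.intervals])

    @property
    def ends(self) -> np.ndarray:
        return np.array([iv.end_s for iv in self.intervals])

    @property
    def peaks(self) -> np.ndarray:
        return np.array([np.nan if iv.peak_s is None else iv.peak_s
                         for iv in self.intervals])

    @property
    def peak_scores(self) -> np.ndarray:
        return np.array([np.nan if iv.peak_score is None else iv.peak_score
                         for iv in self.intervals])

    def total_duration_s(self) -> float:
        return float(sum(iv.duration_s for iv in self.merged()))

    def merged(self, gap_s: float = 0.0) -> "IntervalSet":
        """Union of intervals, merging overlaps and gaps ``< gap_s``."""
        if not self.intervals:
            return IntervalSet([], self.kind)
        out = []
        cur_s, cur_e = self.intervals[0].start_s, self.intervals[0].end_s
        best_peak, best_score = self.intervals[0].peak_s, self.intervals[0].peak_score
        for iv in self.intervals[1:]:
            if iv.start_s - cur_e < gap_s or iv.start_s <= cur_e:
                cur_e = max(cur_e, iv.end_s)
                if (iv.peak_score is not None
                        and (best_score is None or iv.peak_score > best_score)):
                    best_peak, best_score = iv.peak_s, iv.peak_score
            else:
                out.append(Interval(cur_s, cur_e, self.kind, best_peak, best_score))
                cur_s, cur_e = iv.start_s, iv.end_s
                best_peak, best_score = iv.peak_s, iv.peak_score
        out.append(Interval(cur_s, cur_e, self.kind, best_peak, best_score))
        return IntervalSet(out, self.kind)

    def select(self, predicate) -> "IntervalSet":
        return IntervalSet([iv for iv in self.intervals if predicate(iv)], self.kind)

    def membership(self, times: np.ndarray) -> np.ndarray:
        """Boolean mask: which of ``times`` fall in the union of intervals."""
        times = np.asarray(times, dtype=np.float64)
        if not self.intervals:
            return np.zeros(times.shape, dtype=bool)
        m = self.merged()
        starts, ends = m.starts, m.ends
        idx = np.searchsorted(starts, times, side="right") - 1
        ok = idx >= 0
        out = np.zeros(times.shape, dtype=bool)
        out[ok] = times[ok] < ends[idx[ok]]
        return out

    def intersect_span(self, start_s: float, end_s: float) -> "IntervalSet":
        """Clip the set to ``[start_s, end_s)``."""
        out = []
        for iv in self.merged():
            s, e = max(iv.start_s, start_s), min(iv.end_s, end_s)
            if s < e:
                out.append(Interval(s, e, self.kind, None, None))
        return IntervalSet(out, self.kind)


@dataclass
class UnitWaveform:
    """Mean spike waveform of one unit, window -0.2 to +0.8 ms around trough."""

    unit_id: str
    mean_waveform: np.ndarray
    dt_ms: float
    trough_index: int
    channel: int = 0

    def __post_init__(self) -> None:
        self.mean_waveform = np.asarray(self.mean_waveform, dtype=np.float64)
        if self.dt_ms <= 0:
            raise ValidationError("dt_ms must be positive")
        if not 0 <= self.trough_index < self.mean_waveform.size:
            raise ValidationError("trough_index outside waveform")

    def times_ms(self) -> np.ndarray:
        return (np.arange(self.mean_waveform.size) - self.trough_index) * self.dt_ms


@dataclass
class Session:
    """One recording phase: signals, spikes, events, states, behavior."""

    phase: str  # pre_sleep | task | post_sleep
    signals: dict = field(default_factory=dict)
    trains: list = field(default_factory=list)
    events: dict = field(default_factory=dict)
    hypnogram: Optional[IntervalSet] = None
    trajectory = None  # pandas DataFrame (time_s, x_cm, y_cm) or None
    trials = None      # pandas DataFrame or None
    waveforms: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.phase not in {"pre_sleep", "task", "post_sleep"}:
            raise ValidationError(f"unknown phase {self.phase!r}")

    def span(self) -> Interval:
        """Smallest interval covering all signals and spikes."""
        t0, t1 = np.inf, -np.inf
        for sig in self.signals.values():
            t0, t1 = min(t0, sig.t0_s), max(t1, sig.end_s)
        for tr in self.trains:
            if tr.n_spikes:
                t0 = min(t0, tr.times_s[0])
                t1 = max(t1, tr.times_s[-1] + 1e-9)
        if not np.isfinite(t0):
            raise ValidationError("session has no signals or spikes")
        return Interval(t0, t1, "other")

    def trains_in(self, region: str) -> list:
        return [tr for tr in self.trains if tr.region == region]


# ---------------------------------------------------------------------------
# Operations

def restrict(train: SpikeTrain, ivs: IntervalSet) -> SpikeTrain:
    """Spikes falling in the union of half-open ``[start, end)`` intervals."""
    mask = ivs.membership(train.times_s)
    return replace(train, times_s=train.times_s[mask])


def bin_counts(trains: list, bin_s: float, span: Interval) -> tuple:
    """Spike-count matrix (bins x units) tiling ``span`` with half-open bins.

    Returns ``(counts, edges)`` where ``edges`` has ``n_bins + 1`` entries.
    The last partial bin is dropped so every bin has full width.
    """
    if bin_s <= 0:
        raise ValidationError("bin_s must be positive")
    n_bins = int(np.floor((span.end_s - span.start_s) / bin_s + 1e-9))
    if n_bins < 1:
        raise ValidationError("span shorter than one bin")
    edges = span.start_s + bin_s * np.arange(n_bins + 1)
    counts = np.zeros((n_bins, len(trains)), dtype=np.int64)
    for u, tr in enumerate(trains):
        idx = np.floor((tr.times_s - span.start_s) / bin_s).astype(np.int64)
        ok = (idx >= 0) & (idx < n_bins)
        counts[:, u] = np.bincount(idx[ok], minlength=n_bins)
    return counts, edges


def zscore(x: np.ndarray, axis=0, ddof: int = 0) -> np.ndarray:
    """Z-score with a degenerate-SD guard (zero variance -> zeros)."""
    x = np.asarray(x, dtype=np.float64)
    mu = np.mean(x, axis=axis, keepdims=True)
    sd = np.std(x, axis=axis, ddof=ddof, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    return (x - mu) / sd
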