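"""Peri-SWR spiking statistics.

PSTHs are 1-ms firing-rate histograms in a +-1 s window around SWR onsets,
z-scored to the 0.5-1 s pre-onset baseline and smoothed with a 20-ms
Gaussian.  SWR modulation is tested against per-event circular shift
shuffles of the spike train: the score is the summed squared deviation of
the PSTH from the mean shuffled PSTH inside a region-specific window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats

from .core import Interval, IntervalSet, SpikeTrain, ValidationError

log = logging.getLogger("rdlg.psth")

# modulation-score windows relative to SWR onset, per region
MOD_WINDOW_RSC = (-0.200, 0.200)
MOD_WINDOW_CA1 = (0.0, 0.100)


@dataclass
class PsthMatrix:
    unit_ids: list
    lags_s: np.ndarray
    z: np.ndarray            # units x lags
    n_events: int
    baseline_s: tuple = (-1.0, -0.5)
    smooth_sd_s: float = 0.020


@dataclass
class ModulationResult:
    unit_id: str
    score: float
    null_scores: np.ndarray
    p: float
    modulated: bool
    window_s: tuple
    flagged: str = ""


def eligible_anchors(anchor_times, min_sep_s: float = 0.300) -> np.ndarray:
    """Greedy earliest-first selection of anchors separated by >= min_sep_s."""
    out = []
    last = -np.inf
    for t in np.sort(np.asarray(anchor_times, dtype=float)):
        if t - last >= min_sep_s:
            out.append(t)
            last = t
    return np.array(out)


def _lag_histogram(times: np.ndarray, anchors: np.ndarray, edges: np.ndarray
                   ) -> np.ndarray:
    """Counts of spike lags relative to each anchor, pooled over anchors."""
    lo, hi = edges[0], edges[-1]
    bin_s = edges[1] - edges[0]
    n_bins = edges.size - 1
    counts = np.zeros(n_bins, dtype=np.int64)
    i0 = np.searchsorted(times, anchors + lo)
    i1 = np.searchsorted(times, anchors + hi)
    for a, j0, j1 in zip(anchors, i0, i1):
        idx = np.floor((times[j0:j1] - a - lo) / bin_s).astype(np.int64)
        idx = idx[(idx >= 0) & (idx < n_bins)]
        counts += np.bincount(idx, minlength=n_bins)
    return counts


def _smooth_rows(x: np.ndarray, sd_bins: float) -> np.ndarray:
    if sd_bins <= 0:
        return x
    half = int(np.ceil(4 * sd_bins))
    k = np.exp(-0.5 * (np.arange(-half, half + 1) / sd_bins) ** 2)
    k /= k.sum()
    pad = np.pad(x, [(0, 0), (half, half)], mode="edge")
    return sps.fftconvolve(pad, k[None, :], mode="valid")


def _zscore_baseline(rates: np.ndarray, lags: np.ndarray, baseline) -> np.ndarray:
    bl = (lags >= baseline[0]) & (lags < baseline[1])
    mu = rates[:, bl].mean(axis=1, keepdims=True)
    sd = rates[:, bl].std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (rates - mu) / sd


def compute_psth(trains, anchors, bin_s: float = 0.001, span=(-1.0, 1.0),
                 baseline=(-1.0, -0.5), smooth_sd_s: float = 0.020,
                 min_anchors: int = 50, min_sep_s: float = 0.300) -> PsthMatrix:
    """Anchor-averaged z-scored PSTH matrix for a list of spike trains.

    Requires at least ``min_anchors`` anchors separated by ``min_sep_s``
    (sessions below that are skipped upstream with a logged reason).
    """
    anchors = eligible_anchors(anchors, min_sep_s)
    if anchors.size < min_anchors:
        raise ValidationError(
            f"only {anchors.size} eligible anchors < {min_anchors} required")
    n_bins = int(round((span[1] - span[0]) / bin_s))
    edges = span[0] + bin_s * np.arange(n_bins + 1)
    lags = edges[:-1] + bin_s / 2
    rates = np.empty((len(trains), n_bins))
    for u, tr in enumerate(trains):
        counts = _lag_histogram(tr.times_s, anchors, edges)
        rates[u] = counts / (anchors.size * bin_s)
    z = _smooth_rows(_zscore_baseline(rates, lags, baseline),
                     smooth_sd_s / bin_s)
    return PsthMatrix([tr.unit_id for tr in trains], lags, z,
                      int(anchors.size), tuple(baseline), smooth_sd_s)


def test_modulation(train: SpikeTrain, anchors, window=MOD_WINDOW_RSC,
                    n_shuffle: int = 1000, max_shift_s: float = None,
                    seed: int = 0,
                    bin_s: float = 0.001, span=(-1.0, 1.0),
                    baseline=(-1.0, -0.5), smooth_sd_s: float = 0.020,
                    min_anchors: int = 50, alpha: float = 0.05,
                    use_smoothed: bool = True) -> ModulationResult:
    """Shift-shuffle test for peri-SWR modulation of one unit.

    Each shuffle rotates the spikes of every peri-event window by an
    independent uniform amount, circular within the window, which destroys
    spike-event alignment while preserving each window's spike count and
    interval structure.  (A single whole-train shift would move a genuine
    peri-event response to a different lag but keep it aligned across
    events, leaving the test blind to exactly the modulation it is meant to
    detect.)  ``max_shift_s`` defaults to the full window half-width: a
    full-circle rotation makes real and shuffled PSTHs exactly exchangeable
    under a homogeneous spike train, which restricted shifts are not.  The unit's PSTH score (summed
    squared deviation from the mean shuffled PSTH inside ``window``) is
    compared with the same score of each shuffle; p is the +1-corrected
    fraction of null scores at or above the real score.
    """
    rng = np.random.default_rng(seed)
    anchors = eligible_anchors(anchors)
    if anchors.size < min_anchors:
        raise ValidationError(
            f"only {anchors.size} eligible anchors < {min_anchors} required")
    if train.n_spikes == 0:
        return ModulationResult(train.unit_id, 0.0, np.zeros(n_shuffle), 1.0,
                                False, tuple(window), flagged="zero-spike unit")
    times = train.times_s

    n_bins = int(round((span[1] - span[0]) / bin_s))
    edges = span[0] + bin_s * np.arange(n_bins + 1)
    lags = edges[:-1] + bin_s / 2
    width = span[1] - span[0]
    if max_shift_s is None:
        max_shift_s = width / 2.0

    # per-anchor relative lags, concatenated, with anchor membership
    i0 = np.searchsorted(times, anchors + span[0])
    i1 = np.searchsorted(times, anchors + span[1])
    rel = np.concatenate([times[a:b] - t0 for a, b, t0 in zip(i0, i1, anchors)]) \
        if anchors.size else np.empty(0)
    member = np.repeat(np.arange(anchors.size), i1 - i0)

    def _hist(lag_vals):
        idx = np.floor((lag_vals - span[0]) / bin_s).astype(np.int64)
        idx = np.clip(idx, 0, n_bins - 1)
        return np.bincount(idx, minlength=n_bins)

    hists = np.empty((n_shuffle + 1, n_bins))
    hists[0] = _hist(rel)
    for k in range(n_shuffle):
        d = rng.uniform(-max_shift_s, max_shift_s, size=anchors.size)
        shifted = np.mod(rel - span[0] + d[member], width) + span[0]
        hists[k + 1] = _hist(shifted)

    rates = hists / (anchors.size * bin_s)
    z = _zscore_baseline(rates, lags, baseline)
    if use_smoothed:
        z = _smooth_rows(z, smooth_sd_s / bin_s)
    w = (lags >= window[0]) & (lags < window[1])
    ref = z[1:, w].mean(axis=0)
    dev = ((z[:, w] - ref) ** 2).sum(axis=1)
    score, null = float(dev[0]), dev[1:]
    p = (1.0 + np.sum(null >= score)) / (1.0 + n_shuffle)
    return ModulationResult(train.unit_id, score, null, float(p),
                            bool(p < alpha), tuple(window))


def cross_correlogram(times_a, times_b, bin_s: float = 0.010,
                      span=(-0.5, 0.5), n_null: int = 0, seed: int = 0) -> dict:
    """Histogram of lags (b - a) between two event/spike time series.

    With ``n_null > 0`` adds a null band from circular shifts of series b
    (2.5th/97.5th percentile per bin).
    """
    times_a = np.sort(np.asarray(times_a, dtype=float))
    times_b = np.sort(np.asarray(times_b, dtype=float))
    n_bins = int(round((span[1] - span[0]) / bin_s))
    edges = span[0] + bin_s * np.arange(n_bins + 1)
    counts = (_lag_histogram(times_b, times_a, edges) if times_a.size
              else np.zeros(n_bins, dtype=np.int64))
    out = {"lags_s": edges[:-1] + bin_s / 2, "counts": counts, "edges": edges}
    if n_null > 0 and times_a.size and times_b.size:
        rng = np.random.default_rng(seed)
        lo = min(times_a[0], times_b[0]) + span[0]
        hi = max(times_a[-1], times_b[-1]) + span[1]
        null = np.empty((n_null, n_bins))
        for k in range(n_null):
            shifted = np.sort(lo + np.mod(times_b - lo + rng.uniform(0, hi - lo),
                                          hi - lo))
            null[k] = _lag_histogram(shifted, times_a, edges)
        out["null_lo"], out["null_hi"] = np.percentile(null, [2.5, 97.5], axis=0)
    return out


def psth_by_size(trains, swrs: IntervalSet, size_labels,
                 windows=((-0.100, 0.0), (0.0, 0.050), (0.200, 0.300)),
                 min_events: int = 5, **psth_kw) -> dict:
    """Class-wise PSTHs plus one-way ANOVA of window activity across classes.

    Per SWR the population mean spike count in each window (rate, Hz per
    unit) is the ANOVA sample; groups are the SWR size classes.  Classes
    with fewer than ``min_events`` SWRs are omitted with a warning; fewer
    than two usable classes is an error.
    """
    size_labels = list(size_labels)
    onsets = np.array([iv.start_s for iv in swrs])
    classes = {}
    for lab in sorted(set(size_labels)):
        sel = onsets[[i for i, s in enumerate(size_labels) if s == lab]]
        if sel.size < min_events:
            log.warning("size class %r has %d < %d events; omitted",
                        lab, sel.size, min_events)
            continue
        classes[lab] = sel
    if len(classes) < 2:
        raise ValidationError("need at least two size classes with events")

    psths = {lab: compute_psth(trains, sel, min_anchors=min_events,
                               **psth_kw)
             for lab, sel in classes.items()}

    anova = {}
    for w in windows:
        groups = []
        for lab, sel in classes.items():
            vals = []
            for a in sel:
                c = sum(np.searchsorted(tr.times_s, a + w[1])
                        - np.searchsorted(tr.times_s, a + w[0])
                        for tr in trains)
                vals.append(c / (len(trains) * (w[1] - w[0])))
            groups.append(vals)
        F, p = stats.f_oneway(*groups)
        anova[w] = {"F": float(F), "p": float(p),
                    "class_means": {lab: float(np.mean(g)) for lab, g
                                    in zip(classes, groups)}}
    return {"psths": psths, "anova": anova}


def off_peri_swr(off: IntervalSet, swrs: IntervalSet, span=(-1.0, 1.0),
                 bin_s: float = 0.050, post_window_s: float = 0.400) -> dict:
    """OFF-period onset/offset probability around SWR onsets + duration CDFs.

    Lag histograms are normalized per SWR (probability of an OFF onset or
    offset in each lag bin).  Durations of OFF periods starting within
    ``post_window_s`` after a SWR onset are compared with the remaining OFF
    durations by a two-sided rank-sum test.
    """
    if len(off) == 0 or len(swrs) == 0:
        raise ValidationError("need both OFF periods and SWRs")
    swr_on = swrs.starts
    n_bins = int(round((span[1] - span[0]) / bin_s))
    edges = span[0] + bin_s * np.arange(n_bins + 1)
    on_h = _lag_histogram(off.starts, swr_on, edges) / swr_on.size
    off_h = _lag_histogram(off.ends, swr_on, edges) / swr_on.size

    durs = off.ends - off.starts
    j = np.searchsorted(swr_on, off.starts)
    prev_lag = off.starts - np.where(j > 0, swr_on[np.maximum(j - 1, 0)], -np.inf)
    post_mask = (j > 0) & (prev_lag > 0) & (prev_lag <= post_window_s)
    post_durs, other_durs = durs[post_mask], durs[~post_mask]
    if post_durs.size and other_durs.size:
        stat, p = stats.mannwhitneyu(post_durs, other_durs,
                                     alternative="two-sided")
    else:
        stat, p = np.nan, np.nan
    return {"lags_s": edges[:-1] + bin_s / 2,
            "onset_prob": on_h, "offset_prob": off_h,
            "post_durations_s": post_durs, "other_durations_s": other_durs,
            "ranksum_stat": float(stat), "p": float(p)}
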