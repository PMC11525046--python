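"""Offline detection of ripples, sharp waves, SWRs, delta waves, spindles,
SWR-coupled cortical events, SWR size classes, and population OFF periods.

All detectors operate on z-scored transforms of the LFP so thresholds are in
SD units of the session background.  Intervals are half-open seconds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Interval, IntervalSet, SampledSignal, ValidationError
from .filters import band_envelope_z, bandpass, gaussian_smooth

log = logging.getLogger("rdlg.detect")


@dataclass
class DetectorConfig:
    """Every numeric detection threshold, with published defaults."""

    ripple_band: tuple = (140.0, 250.0)
    ripple_thr_env: float = 1.0      # SD; envelope must stay above this
    ripple_thr_peak: float = 4.0     # SD; envelope peak must exceed this
    ripple_dur_s: tuple = (0.015, 0.200)
    ripple_merge_gap_s: float = 0.020
    envelope_smooth_sd_s: float = 0.010
    spindle_smooth_sd_s: float = 0.025

    sharpwave_band: tuple = (5.0, 40.0)
    sharpwave_thr: float = 2.5       # SD of |z|
    sharpwave_dur_s: tuple = (0.020, 0.400)

    delta_hi_hz: float = 4.0
    delta_dur_s: tuple = (0.150, 0.450)
    delta_peak_hi: float = 2.0       # D(peak) > 2 with D(end) <= 0, or
    delta_peak_lo: float = 1.0       # D(peak) > 1 with D(end) < -1.5
    delta_end_hi: float = 0.0
    delta_end_lo: float = -1.5

    spindle_band: tuple = (10.0, 20.0)
    spindle_thr_env: float = 2.5
    spindle_thr_peak: float = 5.0
    spindle_min_dur_s: float = 0.5
    spindle_merge_gap_s: float = 0.4
    spindle_max_merged_s: float = 3.0

    pair_window_s: tuple = (0.0, 0.250)
    size_thresholds: tuple = (4.0, 6.0, 10.0)  # small / medium / large

    off_min_units: int = 5
    off_min_gap_s: float = 0.100
    off_merge_gap_s: float = 0.005

    def __post_init__(self) -> None:
        lo, mid, hi = self.size_thresholds
        if not lo < mid < hi:
            raise ValidationError("size thresholds must be ordered")
        for d in (self.ripple_dur_s, self.sharpwave_dur_s, self.delta_dur_s):
            if d[0] <= 0 or d[1] <= d[0]:
                raise ValidationError("duration window must be positive and ordered")


def _runs(mask: np.ndarray) -> list:
    """Maximal runs of True as (i0, i1) half-open index pairs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        ends = np.r_[ends, mask.size]
    return list(zip(starts, ends))


def _merge_index_runs(runs: list, gap_samples: float) -> list:
    """Merge runs whose separation is strictly below ``gap_samples``."""
    if not runs:
        return []
    out = [list(runs[0])]
    for s, e in runs[1:]:
        if s - out[-1][1] < gap_samples:
            out[-1][1] = e
        else:
            out.append([s, e])
    return [tuple(r) for r in out]


def detect_ripples(lfp: SampledSignal, band=(140.0, 250.0), thr_env: float = 1.0,
                   thr_peak: float = 4.0, dur=(0.015, 0.200),
                   merge_gap: float = 0.020, smooth_sd_s: float = 0.010,
                   kind: str = "ripple") -> IntervalSet:
    """High-frequency burst detection on the normalized squared envelope.

    The band signal is squared, Gaussian-smoothed and z-scored, giving R(t).
    Candidate events are maximal excursions of R(t) above ``thr_env``; events
    separated by less than ``merge_gap`` are merged first, then events must
    last between ``dur[0]`` and ``dur[1]`` and peak above ``thr_peak``.
    """
    env = band_envelope_z(lfp, band, smooth_sd_s)
    fs = lfp.rate_hz
    runs = _merge_index_runs(_runs(env > thr_env), merge_gap * fs)
    out = []
    for i0, i1 in runs:
        dur_s = (i1 - i0) / fs
        if not dur[0] <= dur_s <= dur[1]:
            continue
        ipk = i0 + int(np.argmax(env[i0:i1]))
        if env[ipk] <= thr_peak:
            continue
        out.append(Interval(lfp.t0_s + i0 / fs, lfp.t0_s + i1 / fs, kind,
                            lfp.t0_s + ipk / fs, float(env[ipk])))
    return IntervalSet(out, kind)


def detect_sharp_waves(lfp_channels, band=(5.0, 40.0), thr: float = 2.5,
                       dur=(0.020, 0.400)) -> IntervalSet:
    """Sharp-wave deflections on the averaged CA1 LFP.

    The channel-average is band-passed and z-scored; candidate events are
    absolute excursions above ``thr`` SD lasting ``dur[0]``-``dur[1]`` s
    (deflection polarity depends on the referencing, so |z| is used).
    """
    if isinstance(lfp_channels, SampledSignal):
        lfp_channels = [lfp_channels]
    if not lfp_channels:
        raise ValidationError("need at least one CA1 channel")
    ref = lfp_channels[0]
    stack = np.mean([c.samples for c in lfp_channels], axis=0)
    avg = SampledSignal(stack, ref.rate_hz, ref.t0_s, "CA1-avg")
    filt = bandpass(avg, band[0], band[1])
    sd = np.std(filt)
    z = np.abs(filt - np.mean(filt)) / (sd if sd > 0 else 1.0)
    fs = avg.rate_hz
    out = []
    for i0, i1 in _runs(z > thr):
        dur_s = (i1 - i0) / fs
        if not dur[0] <= dur_s <= dur[1]:
            continue
        ipk = i0 + int(np.argmax(z[i0:i1]))
        out.append(Interval(avg.t0_s + i0 / fs, avg.t0_s + i1 / fs,
                            "sharp_wave", avg.t0_s + ipk / fs, float(z[ipk])))
    return IntervalSet(out, "sharp_wave")


def pair_swr(ripples: IntervalSet, sharp_waves: IntervalSet,
             valid_states: IntervalSet = None) -> IntervalSet:
    """SWRs: ripples co-occurring with a sharp wave, inside valid states.

    A ripple is retained only if it temporally overlaps at least one sharp
    wave and (when ``valid_states`` is given) its peak lies inside the valid
    union (NREM during sleep, immobility during the task).
    """
    sw_starts, sw_ends = sharp_waves.starts, sharp_waves.ends
    out = []
    for rip in ripples:
        if sw_starts.size == 0:
            break
        j = np.searchsorted(sw_starts, rip.end_s)
        overl = np.any(sw_ends[:j] > rip.start_s)
        if not overl:
            continue
        anchor = rip.peak_s if rip.peak_s is not None else rip.start_s
        if valid_states is not None and not valid_states.membership(
                np.array([anchor]))[0]:
            continue
        out.append(Interval(rip.start_s, rip.end_s, "swr", rip.peak_s,
                            rip.peak_score))
    return IntervalSet(out, "swr")


def detect_delta(lfp_rsc: SampledSignal, hi_hz: float = 4.0,
                 dur=(0.150, 0.450), peak_hi: float = 2.0,
                 peak_lo: float = 1.0, end_hi: float = 0.0,
                 end_lo: float = -1.5) -> IntervalSet:
    """Cortical delta waves from the low-passed z-scored LFP D(t).

    Candidates are positive local maxima of D(t); the onset is the preceding
    upward zero crossing and the end is the following trough (local minimum).
    Events must last ``dur[0]``-``dur[1]`` s from onset to end and satisfy
    either amplitude clause: D(peak) > ``peak_hi`` with D(end) <= ``end_hi``,
    or D(peak) > ``peak_lo`` with D(end) < ``end_lo``.
    """
    filt = bandpass(lfp_rsc, 0.0, hi_hz)
    sd = np.std(filt)
    D = (filt - np.mean(filt)) / (sd if sd > 0 else 1.0)
    fs = lfp_rsc.rate_hz

    rising = np.flatnonzero((D[:-1] <= 0) & (D[1:] > 0)) + 1
    dD = np.diff(D)
    maxima = np.flatnonzero((dD[:-1] > 0) & (dD[1:] <= 0)) + 1
    minima = np.flatnonzero((dD[:-1] < 0) & (dD[1:] >= 0)) + 1

    out = []
    for ipk in maxima:
        if D[ipk] <= peak_lo:
            continue
        k = np.searchsorted(rising, ipk)
        if k == 0:
            continue
        i_on = rising[k - 1]
        m = np.searchsorted(minima, ipk)
        if m == len(minima):
            continue
        i_end = minima[m]
        dur_s = (i_end - i_on) / fs
        if not dur[0] <= dur_s <= dur[1]:
            continue
        d_pk, d_end = D[ipk], D[i_end]
        if (d_pk > peak_hi and d_end <= end_hi) or \
           (d_pk > peak_lo and d_end < end_lo):
            out.append(Interval(lfp_rsc.t0_s + i_on / fs,
                                lfp_rsc.t0_s + i_end / fs, "delta",
                                lfp_rsc.t0_s + ipk / fs, float(d_pk)))
    return IntervalSet(out, "delta").merged()


def detect_spindles(lfp_rsc: SampledSignal, band=(10.0, 20.0),
                    thr_env: float = 2.5, thr_peak: float = 5.0,
                    min_dur: float = 0.5, merge_gap: float = 0.4,
                    max_merged: float = 3.0,
                    smooth_sd_s: float = 0.025) -> IntervalSet:
    """Sleep spindles on the normalized squared 10-20 Hz envelope S(t).

    Excursions above ``thr_env`` are merged when separated by less than
    ``merge_gap``; merged events must last more than ``min_dur`` but no more
    than ``max_merged`` seconds and peak above ``thr_peak``.
    """
    env = band_envelope_z(lfp_rsc, band, smooth_sd_s)
    fs = lfp_rsc.rate_hz
    runs = _merge_index_runs(_runs(env > thr_env), merge_gap * fs)
    out = []
    for i0, i1 in runs:
        dur_s = (i1 - i0) / fs
        if dur_s <= min_dur or dur_s > max_merged:
            continue
        ipk = i0 + int(np.argmax(env[i0:i1]))
        if env[ipk] <= thr_peak:
            continue
        out.append(Interval(lfp_rsc.t0_s + i0 / fs, lfp_rsc.t0_s + i1 / fs,
                            "spindle", lfp_rsc.t0_s + ipk / fs,
                            float(env[ipk])))
    return IntervalSet(out, "spindle")


def pair_sequences(swrs: IntervalSet, cortical: IntervalSet,
                   window=(0.0, 0.250)) -> list:
    """SWR->cortical event pairs: cortical peak 0-250 ms after a SWR peak.

    Each cortical event is paired with its nearest preceding qualifying SWR
    only, so no cortical event is double counted.
    """
    swr_peaks = swrs.peaks
    pairs = []
    if swr_peaks.size == 0:
        return pairs
    order = np.argsort(swr_peaks)
    sorted_peaks = swr_peaks[order]
    for cev in cortical:
        if cev.peak_s is None:
            continue
        j = np.searchsorted(sorted_peaks, cev.peak_s) - 1
        if j < 0:
            continue
        lag = cev.peak_s - sorted_peaks[j]
        if window[0] < lag <= window[1]:
            pairs.append((swrs[int(order[j])], cev))
    return pairs


def classify_swr_size(swrs: IntervalSet,
                      thresholds=(4.0, 6.0, 10.0)) -> list:
    """Label each SWR by envelope peak amplitude: small >4, medium >6, large >10 SD."""
    lo, mid, hi = thresholds
    labels = []
    for iv in swrs:
        if iv.peak_score is None:
            raise ValidationError("SWR missing peak_score; rerun detection")
        if iv.peak_score > hi:
            labels.append("large")
        elif iv.peak_score > mid:
            labels.append("medium")
        elif iv.peak_score > lo:
            labels.append("small")
        else:
            labels.append("sub")
    return labels


def detect_off_periods(rsc_trains: list, span: Interval,
                       min_units: int = 5, min_gap: float = 0.100,
                       merge_gap: float = 0.005,
                       valid: IntervalSet = None) -> IntervalSet:
    """Population OFF periods: >``min_gap`` s with zero pooled RSC spikes.

    Requires at least ``min_units`` RSC trains (otherwise the session is
    skipped and an empty set returned with a logged reason).  OFF periods
    separated by less than ``merge_gap`` are merged.  When ``valid`` is given
    the search runs independently inside each valid interval.
    """
    if len(rsc_trains) < min_units:
        log.warning("OFF detection skipped: %d RSC units < %d required",
                    len(rsc_trains), min_units)
        return IntervalSet([], "off_period")
    pooled = np.sort(np.concatenate([tr.times_s for tr in rsc_trains])
                     if rsc_trains else np.empty(0))
    segments = ([(iv.start_s, iv.end_s) for iv in valid.merged()]
                if valid is not None else [(span.start_s, span.end_s)])
    out = []
    for seg_s, seg_e in segments:
        inside = pooled[(pooled >= seg_s) & (pooled < seg_e)]
        bounds = np.r_[seg_s, inside, seg_e]
        gaps = np.diff(bounds)
        for k in np.flatnonzero(gaps > min_gap):
            out.append(Interval(float(bounds[k]), float(bounds[k + 1]),
                                "off_period"))
    return IntervalSet(out, "off_period").merged(gap_s=merge_gap)


def ripple_features(ripples: IntervalSet, analyzed_duration_s: float) -> pd.DataFrame:
    """Per-event feature table plus incidence over the analyzed time.

    Columns: start_s, duration_s, peak_norm_power; the frame carries
    ``rate_per_min`` in ``.attrs``.
    """
    rows = [{"start_s": iv.start_s, "duration_s": iv.duration_s,
             "peak_norm_power": np.nan if iv.peak_score is None else iv.peak_score}
            for iv in ripples]
    df = pd.DataFrame(rows, columns=["start_s", "duration_s", "peak_norm_power"])
    minutes = analyzed_duration_s / 60.0
    df.attrs["rate_per_min"] = len(ripples) / minutes if minutes > 0 else 0.0
    return df
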