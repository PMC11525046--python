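"""Sleep scoring from hippocampal LFP and EMG.

Wake is flagged by the z-scored EMG envelope; among immobility epochs the
theta/delta ratio (6-10 Hz vs 1-4 Hz band power in 256-sample windows)
separates REM (ratio >= 2) from NREM (ratio < 2).  Boundaries between
differing stages are padded with 5-s "other" intervals and stages shorter
than 30 s are relabeled "other" (transition stages).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import Interval, IntervalSet, SampledSignal, SpikeTrain, ValidationError, restrict
from .filters import bandpass, gaussian_smooth


@dataclass
class StateScoreTrace:
    """Aligned scoring series on one time grid."""

    t: np.ndarray
    theta_delta_ratio: np.ndarray
    emg_z: np.ndarray
    wake_threshold: float


def compute_emg_z(emg: SampledSignal, band=(20.0, 150.0),
                  smooth_sd_s: float = 0.050) -> np.ndarray:
    """Z-scored EMG envelope: 20-150 Hz band-pass, rectified, smoothed.

    Returns one value per input sample.  A constant signal yields zeros
    (degenerate-SD guard).
    """
    filt = bandpass(emg, band[0], band[1])
    env = gaussian_smooth(np.abs(filt), smooth_sd_s * emg.rate_hz)
    sd = np.std(env)
    # degenerate-SD guard: a (near-)constant signal has no EMG content
    if sd <= 1e-9 * max(1.0, float(np.abs(emg.samples).max())):
        return np.zeros_like(env)
    return (env - np.mean(env)) / sd


def theta_delta_ratio(lfp: SampledSignal, window_samples: int = 256,
                      hop_samples: int = None, score_rate_hz: float = 125.0,
                      theta_band=(6.0, 10.0), delta_band=(1.0, 4.0),
                      smooth_sd_s: float = 0.050) -> tuple:
    """Theta/delta band-power ratio per 256-sample scoring window.

    The LFP is first decimated to ``score_rate_hz`` (both bands live below
    10 Hz; at the raw 1250 Hz a 256-sample window spans only 0.2 s, which
    cannot resolve 1-4 Hz from 6-10 Hz).  Band power then comes from a
    Welch periodogram over each ``window_samples`` block, non-overlapping by
    default.  Returns ``(t_centers, ratio)``; the ratio series is
    Gaussian-smoothed with ``smooth_sd_s``.
    """
    q = max(1, int(round(lfp.rate_hz / score_rate_hz)))
    x = sps.decimate(lfp.samples, q, ftype="fir", zero_phase=True) if q > 1 \
        else lfp.samples
    fs = lfp.rate_hz / q
    if window_samples > x.size:
        raise ValidationError("ratio window longer than signal")
    hop = hop_samples or window_samples
    n_win = 1 + (x.size - window_samples) // hop
    starts = np.arange(n_win) * hop
    freqs, psds = sps.welch(x[starts[:, None] + np.arange(window_samples)],
                            fs=fs, nperseg=window_samples, axis=1)
    th = (freqs >= theta_band[0]) & (freqs <= theta_band[1])
    de = (freqs >= delta_band[0]) & (freqs <= delta_band[1])
    eps = np.finfo(float).tiny
    ratio = (psds[:, th].sum(axis=1) + eps) / (psds[:, de].sum(axis=1) + eps)
    t = lfp.t0_s + (starts + window_samples / 2) / fs
    dt = hop / fs
    ratio = gaussian_smooth(ratio, smooth_sd_s / dt)
    return t, ratio


def score_states(trace: StateScoreTrace, ratio_threshold: float = 2.0,
                 min_dur_s: float = 30.0, gap_s: float = 5.0,
                 span=None) -> IntervalSet:
    """Build a hypnogram tiling the session from aligned scoring series.

    Per-sample states: wake where ``emg_z >= wake_threshold``; otherwise NREM
    where the theta/delta ratio is below ``ratio_threshold``, REM where at or
    above it.  ``gap_s`` of "other" is inserted at each boundary between
    differing stages and stages shorter than ``min_dur_s`` become "other".
    """
    t, ratio, emg_z = trace.t, trace.theta_delta_ratio, trace.emg_z
    if np.all(np.isnan(ratio)) or np.all(np.isnan(emg_z)):
        raise ValidationError("all-NaN scoring series")
    state = np.where(emg_z >= trace.wake_threshold, "wake",
                     np.where(ratio >= ratio_threshold, "rem", "nrem"))

    t0 = span[0] if span is not None else float(t[0])
    t1 = span[1] if span is not None else float(t[-1])
    # segment runs of equal state
    segs = []
    start = t0
    cur = state[0]
    for i in range(1, len(state)):
        if state[i] != cur:
            edge = 0.5 * (t[i - 1] + t[i])
            segs.append([start, edge, cur])
            start, cur = edge, state[i]
    segs.append([start, t1, cur])

    # absorb brief flickers (< gap_s) into the longer neighbouring stage
    # before the transition-stage rule, otherwise a 2-s blip can fragment a
    # long stage into sub-minimum pieces
    changed = True
    while changed and len(segs) > 1:
        changed = False
        for k, (s, e, st) in enumerate(segs):
            if e - s >= gap_s:
                continue
            left = segs[k - 1] if k > 0 else None
            right = segs[k + 1] if k < len(segs) - 1 else None
            target = max((x for x in (left, right) if x is not None),
                         key=lambda x: x[1] - x[0])
            segs[k][2] = target[2]
            changed = True
        merged0 = []
        for s, e, st in segs:
            if merged0 and merged0[-1][2] == st:
                merged0[-1][1] = e
            else:
                merged0.append([s, e, st])
        segs = merged0

    # short stages become "other" (transition stages)
    segs = [[s, e, (st if e - s >= min_dur_s else "other")] for s, e, st in segs]
    # re-merge neighbours that now share a label
    merged = []
    for s, e, st in segs:
        if merged and merged[-1][2] == st:
            merged[-1][1] = e
        else:
            merged.append([s, e, st])
    # pad boundaries between differing (non-other) stages with gap_s of other
    out = []
    half = gap_s / 2.0
    for k, (s, e, st) in enumerate(merged):
        lo = s + (half if k > 0 and st != "other" and merged[k - 1][2] != "other"
                  else 0.0)
        hi = e - (half if k < len(merged) - 1 and st != "other"
                  and merged[k + 1][2] != "other" else 0.0)
        if lo > s:
            out.append(Interval(s, lo, "other"))
        if hi > lo:
            out.append(Interval(lo, hi, st))
        if e > hi:
            out.append(Interval(hi, e, "other"))
    # merge adjacent intervals that share a label (e.g. paired boundary pads)
    merged_out = []
    for iv in sorted(out, key=lambda v: v.start_s):
        if merged_out and merged_out[-1].kind == iv.kind \
                and np.isclose(merged_out[-1].end_s, iv.start_s):
            merged_out[-1] = Interval(merged_out[-1].start_s, iv.end_s,
                                      iv.kind)
        else:
            merged_out.append(iv)
    return IntervalSet(merged_out, "other")


def score_sleep_session(lfp: SampledSignal, emg: SampledSignal,
                        wake_threshold: float = 0.5,
                        ratio_threshold: float = 2.0,
                        grid_s: float = 1.0) -> IntervalSet:
    """End-to-end scoring: EMG_z + theta/delta ratio -> hypnogram."""
    emg_z = compute_emg_z(emg)
    t_r, ratio = theta_delta_ratio(lfp)
    # resample both onto a common grid
    t_grid = np.arange(lfp.t0_s + grid_s / 2, lfp.end_s, grid_s)
    ratio_g = np.interp(t_grid, t_r, ratio)
    emg_t = emg.times()
    emg_g = np.interp(t_grid, emg_t, emg_z)
    trace = StateScoreTrace(t_grid, ratio_g, emg_g, wake_threshold)
    return score_states(trace, ratio_threshold,
                        span=(lfp.t0_s, lfp.end_s))


def state_rate_ratio(train: SpikeTrain, hypnogram: IntervalSet,
                     state_a: str = "nrem", state_b: str = "wake") -> float:
    """Normalized firing-rate contrast (FR_a - FR_b) / (FR_a + FR_b).

    Positive values mean the unit fires faster in ``state_a``.  Returns NaN
    when both rates are zero (undefined).
    """
    rates = {}
    for st in (state_a, state_b):
        ivs = IntervalSet([iv for iv in hypnogram if iv.kind == st], st)
        dur = ivs.total_duration_s()
        if dur == 0:
            raise ValidationError(f"state {st} absent from hypnogram")
        rates[st] = restrict(train, ivs).n_spikes / dur
    fa, fb = rates[state_a], rates[state_b]
    if fa + fb == 0:
        return float("nan")
    return (fa - fb) / (fa + fb)
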