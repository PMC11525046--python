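"""Synthetic recording generator with known ground truth.

Produces sessions in the same containers the readers build from disk:
state-switching LFP (1/f background plus state-dependent oscillations),
EMG with wake bursts, inserted ripple/sharp-wave, delta and spindle events
with known times and amplitudes, and inhomogeneous-Poisson spike trains
carrying peri-SWR modulation kernels, cross-region lagged coupling,
co-firing templates, spatial/trial-type/speed tuning, and two waveform
families for cell typing and cross-session tracking.

Event amplitudes are specified in detection-SD units: the generator
calibrates inserted component amplitudes against the same normalized
transforms the detectors use, iterating a short fixed point so the requested
peak z-scores hold on the fully assembled signal.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .core import Interval, IntervalSet, SampledSignal, Session, SpikeTrain, UnitWaveform
from .filters import band_envelope_z, bandpass, gaussian_smooth


# ---------------------------------------------------------------------------
# configuration

@dataclass
class KernelSpec:
    """Peri-SWR rate-multiplier kernel: Gaussian bump in lag."""

    center_s: float = 0.0
    sd_s: float = 0.025
    gain: float = 1.0  # multiplier at the bump peak; 1 = unmodulated


@dataclass
class CouplingSpec:
    """Lagged rate modulation of target units by the source ensemble."""

    direction: Optional[str] = None  # "rsc2ca1" | "ca12rsc" | None
    lag_s: float = 0.050             # source leads target by this much
    strength: float = 0.0


@dataclass
class SleepConfig:
    duration_s: float = 600.0
    fs_hz: float = 1250.0
    # state schedule (dwell ranges, seconds); all >= the 30 s scoring minimum
    wake_dwell_s: tuple = (45.0, 70.0)
    nrem_dwell_s: tuple = (100.0, 160.0)
    rem_dwell_s: tuple = (35.0, 55.0)
    # oscillation amplitudes relative to broadband background SD
    theta_amp: float = 1.2
    nrem_delta_amp: float = 0.25
    emg_wake_factor: float = 4.0
    # flatten the envelope of the detection bands' background (constant-
    # envelope phase noise): emulates the dense multiunit noise floor of real
    # LFP so detection-SD units stay stable between sparse inserted events
    flatten_detection_bands: bool = True
    # inserted events (peak amplitudes in detection-SD units)
    n_ripples: int = 60
    ripple_freq_hz: float = 180.0
    ripple_dur_s: tuple = (0.055, 0.100)
    ripple_peak_sd: tuple = (6.0, 12.0)
    ripple_min_sep_s: float = 0.35
    sharpwave_peak_sd: tuple = (6.0, 9.0)
    sharpwave_dur_s: float = 0.080
    n_delta: int = 80
    delta_peak_sd: tuple = (5.0, 6.5)
    n_spindles: int = 30
    spindle_freq_hz: float = 13.0
    spindle_dur_s: tuple = (0.78, 1.05)
    spindle_peak_sd: tuple = (5.8, 6.8)
    # spiking
    n_ca1: int = 10
    n_rsc: int = 8
    ca1_rate_hz: tuple = (2.0, 5.0)
    rsc_rate_hz: tuple = (2.0, 5.0)
    ca1_kernel: KernelSpec = field(default_factory=lambda: KernelSpec(0.030, 0.020, 3.0))
    rsc_kernel: KernelSpec = field(default_factory=lambda: KernelSpec(-0.060, 0.025, 2.5))
    kernel_gain_jitter_sd: float = 0.5   # lognormal sigma of per-event gain
    size_coupled_gain: bool = False      # scale kernel gain with ripple amplitude
    coupling: CouplingSpec = field(default_factory=CouplingSpec)
    # template reactivation at SWRs
    template_weights: Optional[dict] = None  # {"ca1": [...], "rsc": [...]}
    react_strength: float = 0.0
    react_prob: float = 0.9
    react_sd_s: float = 0.040
    # OFF periods (inserted RSC silence)
    off_after_swr_prob: float = 0.0
    off_lag_s: float = 0.100
    off_dur_s: tuple = (0.120, 0.250)
    n_off_random: int = 0


@dataclass
class SpatialUnitSpec:
    """Tuning of one task-phase unit."""

    base_rate_hz: float = 4.0
    field_center: Optional[tuple] = None  # (x_cm, y_cm)
    field_width_cm: float = 6.0
    field_gain: float = 5.0
    gain_left: float = 1.0     # trial-type multipliers inside the field
    gain_right: float = 1.0
    speed_slope: float = 0.0   # rate = base + slope * speed when set
    region: str = "RSC"


@dataclass
class TaskConfig:
    n_trials: int = 40
    frame_hz: float = 25.0
    stem_len_cm: float = 30.0
    stem_width_cm: float = 6.0
    arm_x_cm: float = 24.0
    run_speed_cm_s: tuple = (16.0, 24.0)
    delay_pause_s: float = 3.0
    reward_pause_s: float = 2.0
    p_error: float = 0.05
    units: tuple = ()              # SpatialUnitSpec per unit
    n_ca1: int = 0                 # extra CA1 units for template work
    ca1_rate_hz: tuple = (2.0, 5.0)
    template_weights: Optional[dict] = None
    template_strength: float = 0.0
    template_burst_prob: float = 0.3


# ---------------------------------------------------------------------------
# ground truth

@dataclass
class GroundTruth:
    states: list = field(default_factory=list)        # (state, start, end)
    event_times: dict = field(default_factory=dict)   # kind -> list of peaks
    event_amps: dict = field(default_factory=dict)    # kind -> requested SD
    unit_specs: dict = field(default_factory=dict)
    coupling: dict = field(default_factory=dict)
    template_weights: dict = field(default_factory=dict)
    event_gains: list = field(default_factory=list)   # per-SWR kernel jitter
    react_amounts: list = field(default_factory=list)
    off_periods: list = field(default_factory=list)
    identity_map: dict = field(default_factory=dict)
    trials: list = field(default_factory=list)

    def state_set(self, state: str) -> IntervalSet:
        return IntervalSet([Interval(s, e, state)
                            for st, s, e in self.states if st == state], state)

    def save(self, path) -> None:
        def _clean(obj):
            if isinstance(obj, dict):
                return {k: _clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_clean(v) for v in obj]
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj
        with open(path, "w") as fh:
            json.dump(_clean(asdict(self)), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# helpers

def one_over_f_noise(n: int, rng: np.random.Generator, alpha: float = 1.0,
                     fs: float = 1250.0, f_floor: float = 0.5) -> np.ndarray:
    """Unit-SD 1/f^alpha noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    scale = np.maximum(f, f_floor) ** (-alpha / 2.0)
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n)
    sd = np.std(x)
    return x / (sd if sd > 0 else 1.0)


def _draw_state_sequence(cfg: SleepConfig, rng) -> list:
    """Wake / NREM / REM blocks covering the session, dwell >= 30 s."""
    out, t = [], 0.0
    dur = cfg.duration_s

    def dwell(rg):
        return float(rng.uniform(*rg))

    order = ["wake", "nrem", "rem", "nrem", "wake", "nrem", "rem", "nrem"]
    i = 0
    while t < dur - 40.0:
        st = order[i % len(order)]
        d = dwell({"wake": cfg.wake_dwell_s, "nrem": cfg.nrem_dwell_s,
                   "rem": cfg.rem_dwell_s}[st])
        d = min(d, dur - t)
        if dur - (t + d) < 40.0:  # avoid a sub-minimum final block
            d = dur - t
        out.append((st, t, t + d))
        t += d
        i += 1
    if t < dur:
        out.append(("nrem", t, dur))
    return out


def _place_event_times(segments: list, n: int, min_sep: float, margin: float,
                       rng) -> np.ndarray:
    """Sample ``n`` times inside segments (shrunk by margin), min separation."""
    segs = [(s + margin, e - margin) for s, e in segments if e - s > 2 * margin]
    if not segs:
        return np.empty(0)
    lens = np.array([e - s for s, e in segs])
    times: list = []
    for _ in range(200 * n):
        if len(times) >= n:
            break
        k = rng.choice(len(segs), p=lens / lens.sum())
        t = float(rng.uniform(*segs[k]))
        if all(abs(t - u) >= min_sep for u in times):
            times.append(t)
    return np.sort(np.array(times))


def _add_bump(arr: np.ndarray, fs: float, t0: float, shape_fn, half_span_s: float):
    i0 = max(0, int((t0 - half_span_s) * fs))
    i1 = min(arr.size, int((t0 + half_span_s) * fs) + 1)
    if i1 <= i0:
        return
    t = np.arange(i0, i1) / fs - t0
    arr[i0:i1] += shape_fn(t)


def _flatten_band(x: np.ndarray, fs: float, lo: float, hi: float) -> np.ndarray:
    """Replace a band's content by constant-envelope phase noise of equal power."""
    from scipy.signal import hilbert
    band = bandpass(SampledSignal(x, fs), lo, hi)
    env = np.abs(hilbert(band))
    env = np.maximum(env, 1e-9 * max(env.max(), 1e-30))
    rms = np.sqrt(np.mean(band ** 2))
    return x - band + (band / env) * rms * np.sqrt(2.0)


def _spikes_from_rate(rate_hz: np.ndarray, dt_s: float, t0: float, rng) -> np.ndarray:
    """Inhomogeneous Poisson spikes from a rate sampled on a regular grid."""
    lam = np.clip(rate_hz, 0.0, None) * dt_s
    counts = rng.poisson(lam)
    idx = np.repeat(np.flatnonzero(counts), counts[counts > 0])
    times = t0 + (idx + rng.uniform(size=idx.size)) * dt_s
    return np.sort(times)


# ---------------------------------------------------------------------------
# sleep sessions

def simulate_sleep_session(cfg: SleepConfig = None, seed: int = 0,
                           phase: str = "post_sleep"):
    """Generate one sleep session and its ground truth.

    LFP per region is 1/f background plus state-dependent oscillations plus
    inserted events; EMG has high variance in wake; spikes are inhomogeneous
    Poisson with rate = baseline x state factor x peri-SWR kernel x coupling
    x template-reactivation factor.  Identical seeds give identical output.
    """
    cfg = cfg or SleepConfig()
    rng = np.random.default_rng(seed)
    fs = cfg.fs_hz
    n = int(round(cfg.duration_s * fs))
    gt = GroundTruth()

    states = _draw_state_sequence(cfg, rng)
    gt.states = [(st, float(s), float(e)) for st, s, e in states]
    nrem_segs = [(s, e) for st, s, e in states if st == "nrem"]
    t_grid = np.arange(n) / fs

    state_arr = np.zeros(n, dtype=np.int8)  # 0 wake, 1 nrem, 2 rem
    code = {"wake": 0, "nrem": 1, "rem": 2}
    for st, s, e in states:
        state_arr[int(s * fs):int(e * fs)] = code[st]

    # --- backgrounds
    bg_sd = 50.0  # microvolt scale for the broadband background
    lfp_ca1 = bg_sd * one_over_f_noise(n, rng, fs=fs)
    lfp_rsc = bg_sd * one_over_f_noise(n, rng, fs=fs)

    theta = np.sin(2 * np.pi * 8.0 * t_grid + rng.uniform(0, 2 * np.pi))
    slow = np.sin(2 * np.pi * 2.0 * t_grid + rng.uniform(0, 2 * np.pi))
    rem_mask = (state_arr == 2).astype(np.float64)
    wake_mask = (state_arr == 0).astype(np.float64)
    nrem_mask = (state_arr == 1).astype(np.float64)
    soft = gaussian_smooth(rem_mask + 0.6 * wake_mask, 0.5 * fs)
    lfp_ca1 += cfg.theta_amp * bg_sd * soft * theta
    lfp_rsc += 0.5 * cfg.theta_amp * bg_sd * soft * theta
    soft_n = gaussian_smooth(nrem_mask, 0.5 * fs)
    lfp_ca1 += cfg.nrem_delta_amp * bg_sd * soft_n * slow
    lfp_rsc += cfg.nrem_delta_amp * bg_sd * soft_n * slow

    if cfg.flatten_detection_bands:
        lfp_ca1 = _flatten_band(lfp_ca1, fs, 140.0, 250.0)
        lfp_rsc = _flatten_band(lfp_rsc, fs, 140.0, 250.0)
        # cortical spindle band is quiet outside spindles: attenuate the
        # background there so inserted spindles dominate their own band
        lfp_rsc = lfp_rsc - 0.85 * bandpass(
            SampledSignal(lfp_rsc, fs), 10.0, 20.0)

    # --- event times
    rip_times = _place_event_times(nrem_segs, cfg.n_ripples,
                                   cfg.ripple_min_sep_s, 1.5, rng)
    delta_times = _place_event_times(nrem_segs, cfg.n_delta, 0.6, 1.0, rng)
    spin_times = _place_event_times(nrem_segs, cfg.n_spindles, 2.2, 1.6, rng)

    rip_amp = rng.uniform(*cfg.ripple_peak_sd, size=rip_times.size)
    sw_amp = rng.uniform(*cfg.sharpwave_peak_sd, size=rip_times.size)
    delta_amp = rng.uniform(*cfg.delta_peak_sd, size=delta_times.size)
    spin_amp = rng.uniform(*cfg.spindle_peak_sd, size=spin_times.size)
    rip_dur = rng.uniform(*cfg.ripple_dur_s, size=rip_times.size)
    spin_dur = rng.uniform(*cfg.spindle_dur_s, size=spin_times.size)

    gt.event_times = {"ripple": rip_times.tolist(),
                      "sharp_wave": rip_times.tolist(),
                      "delta": delta_times.tolist(),
                      "spindle": spin_times.tolist(),
                      "swr": rip_times.tolist()}
    gt.event_amps = {"ripple": rip_amp.tolist(), "sharp_wave": sw_amp.tolist(),
                     "delta": delta_amp.tolist(), "spindle": spin_amp.tolist()}

    # --- event component builders (per-event amplitude vectors in raw units)
    rip_sd = rip_dur / 4.0
    rip_ph = rng.uniform(0, 2 * np.pi, size=rip_times.size)
    spin_ph = rng.uniform(0, 2 * np.pi, size=spin_times.size)

    def _build_rip(amps):
        comp = np.zeros(n)
        for t0, a, sd, ph in zip(rip_times, amps, rip_sd, rip_ph):
            _add_bump(comp, fs, t0,
                      lambda t, a=a, sd=sd, ph=ph:
                      a * np.exp(-t * t / (2 * sd * sd)) *
                      np.sin(2 * np.pi * cfg.ripple_freq_hz * t + ph), 4 * sd)
        return comp

    def _build_sw(amps):
        comp = np.zeros(n)
        d = cfg.sharpwave_dur_s
        for t0, a in zip(rip_times, amps):
            _add_bump(comp, fs, t0,
                      lambda t, a=a, d=d:
                      -a * np.cos(np.pi * t / d) * ((t >= -d / 2) & (t < d / 2)),
                      d)
        return comp

    def _build_delta(amps):
        # triphasic: leading dip pins the onset zero crossing, main positive
        # peak, then the after-trough that the amplitude clauses test
        comp = np.zeros(n)
        for t0, a in zip(delta_times, amps):
            _add_bump(comp, fs, t0,
                      lambda t, a=a:
                      a * (-0.30 * np.exp(-(t + 0.16) ** 2 / (2 * 0.055 ** 2))
                           + np.exp(-t * t / (2 * 0.055 ** 2))
                           - 0.55 * np.exp(-(t - 0.18) ** 2 / (2 * 0.075 ** 2))),
                      0.60)
        return comp

    def _build_spin(amps):
        # waxing-waning: sustained plateau (~50 ms soft edges) carrying a
        # brief central crest, so the envelope clears the peak threshold
        # while the plateau alone sustains the entry threshold
        comp = np.zeros(n)
        for t0, a, d, ph in zip(spin_times, amps, spin_dur, spin_ph):
            _add_bump(comp, fs, t0,
                      lambda t, a=a, d=d, ph=ph:
                      a * 0.5 *
                      (np.tanh((t + d / 2) / 0.05) - np.tanh((t - d / 2) / 0.05)) *
                      (0.85 + 0.15 * np.exp(-t * t / (2 * 0.08 ** 2))) *
                      np.sin(2 * np.pi * cfg.spindle_freq_hz * t + ph),
                      d / 2 + 0.25)
        return comp

    def _peak_near(trace, times, w_s=0.015):
        idx = np.clip((np.asarray(times) * fs).astype(int), 0, n - 1)
        w = int(w_s * fs)
        return np.array([trace[max(0, i - w):i + w + 1].max() for i in idx])

    # --- per-event amplitude calibration against the detectors' own
    #     normalized transforms (2 fixed-point passes)
    uv = 0.1 * bg_sd  # initial raw amplitude unit
    a_rip = uv * np.sqrt(rip_amp)
    a_sw = uv * sw_amp
    a_delta = uv * delta_amp
    a_spin = uv * np.sqrt(spin_amp)
    for _ in range(4):
        ca1 = lfp_ca1 + _build_rip(a_rip) + _build_sw(a_sw)
        rsc = lfp_rsc + _build_delta(a_delta) + _build_spin(a_spin)
        sig_ca1 = SampledSignal(ca1, fs, 0.0, "CA1-lfp")
        sig_rsc = SampledSignal(rsc, fs, 0.0, "RSC-lfp")
        if rip_times.size:
            env = band_envelope_z(sig_ca1, (140.0, 250.0))
            ach = np.maximum(_peak_near(env, rip_times), 0.05)
            a_rip *= np.sqrt(np.clip(rip_amp / ach, 0.25, 4.0))
            f_sw = bandpass(sig_ca1, 5.0, 40.0)
            zsw = np.abs(f_sw - f_sw.mean()) / f_sw.std()
            ach = np.maximum(_peak_near(zsw, rip_times), 0.05)
            a_sw *= np.clip(sw_amp / ach, 0.25, 4.0)
        if delta_times.size:
            f_d = bandpass(sig_rsc, 0.0, 4.0)
            zd = (f_d - f_d.mean()) / f_d.std()
            ach = np.maximum(_peak_near(zd, delta_times), 0.05)
            a_delta *= np.clip(delta_amp / ach, 0.25, 4.0)
        if spin_times.size:
            envs = band_envelope_z(sig_rsc, (10.0, 20.0), 0.025)
            # calibrate on the plateau (median over the event core): the
            # plateau carries 0.85^2 of the crest power by construction
            ach = []
            for t0, d in zip(spin_times, spin_dur):
                i0 = max(0, int((t0 - d / 2 + 0.12) * fs))
                i1 = min(n, int((t0 + d / 2 - 0.12) * fs))
                ach.append(np.median(envs[i0:i1]) if i1 > i0 else 0.05)
            ach = np.maximum(np.asarray(ach), 0.05)
            a_spin *= np.sqrt(np.clip(0.72 * spin_amp / ach, 0.25, 4.0))

    lfp_ca1 += _build_rip(a_rip) + _build_sw(a_sw)
    lfp_rsc += _build_delta(a_delta) + _build_spin(a_spin)

    # --- EMG: 20-150 Hz noise, amplitude raised in wake
    emg_carrier = bandpass(SampledSignal(rng.standard_normal(n), fs), 20.0, 150.0)
    emg_carrier /= np.std(emg_carrier)
    emg_amp = 1.0 + (cfg.emg_wake_factor - 1.0) * gaussian_smooth(wake_mask, 0.25 * fs)
    emg = 20.0 * emg_amp * emg_carrier

    # --- spikes
    dt = 0.001
    n_ms = int(round(cfg.duration_s / dt))
    tg = (np.arange(n_ms) + 0.5) * dt
    state_ms = state_arr[np.clip((tg * fs).astype(int), 0, n - 1)]
    nrem_ms = state_ms == 1

    gains = np.exp(rng.normal(0.0, cfg.kernel_gain_jitter_sd, size=rip_times.size))
    if cfg.size_coupled_gain and rip_times.size:
        gains = gains * (rip_amp / np.mean(rip_amp))
    gt.event_gains = gains.tolist()

    tw = cfg.template_weights or {}
    u_ca1 = np.asarray(tw.get("ca1", np.zeros(cfg.n_ca1)), dtype=float)
    v_rsc = np.asarray(tw.get("rsc", np.zeros(cfg.n_rsc)), dtype=float)
    gt.template_weights = {"ca1": u_ca1.tolist(), "rsc": v_rsc.tolist()}
    react = np.where(rng.uniform(size=rip_times.size) < cfg.react_prob,
                     cfg.react_strength, 0.0)
    gt.react_amounts = react.tolist()

    def _kernel_factor(kern: KernelSpec, per_event_gain: np.ndarray) -> np.ndarray:
        fac = np.ones(n_ms)
        if kern.gain == 1.0 and not per_event_gain.size:
            return fac
        for t0, g in zip(rip_times, per_event_gain):
            amp = (kern.gain - 1.0) * g
            if amp == 0.0:
                continue
            c, sdk = kern.center_s, kern.sd_s
            i0 = max(0, int((t0 + c - 4 * sdk) / dt))
            i1 = min(n_ms, int((t0 + c + 4 * sdk) / dt) + 1)
            tt = tg[i0:i1] - t0 - c
            fac[i0:i1] += amp * np.exp(-tt * tt / (2 * sdk * sdk))
        return fac

    def _react_factor(w: float) -> np.ndarray:
        fac = np.ones(n_ms)
        if w == 0.0 or not rip_times.size:
            return fac
        sdk = cfg.react_sd_s
        for t0, a in zip(rip_times, react):
            if a == 0.0:
                continue
            i0 = max(0, int((t0 - 4 * sdk) / dt))
            i1 = min(n_ms, int((t0 + 4 * sdk) / dt) + 1)
            tt = tg[i0:i1] - t0
            fac[i0:i1] += w * a * np.exp(-tt * tt / (2 * sdk * sdk))
        return np.clip(fac, 0.05, None)

    # OFF periods: silence all RSC units
    off_ivs = []
    for t0 in rip_times:
        if rng.uniform() < cfg.off_after_swr_prob:
            d = rng.uniform(*cfg.off_dur_s)
            off_ivs.append((t0 + cfg.off_lag_s, t0 + cfg.off_lag_s + d))
    if cfg.n_off_random:
        rand_t = _place_event_times(nrem_segs, cfg.n_off_random, 1.0, 0.5, rng)
        for t0 in rand_t:
            off_ivs.append((t0, t0 + rng.uniform(*cfg.off_dur_s)))
    gt.off_periods = [(float(a), float(b)) for a, b in sorted(off_ivs)]
    off_mask = np.ones(n_ms)
    for a, b in off_ivs:
        off_mask[int(a / dt):int(b / dt)] = 0.0

    ca1_base = rng.uniform(*cfg.ca1_rate_hz, size=cfg.n_ca1)
    rsc_base = rng.uniform(*cfg.rsc_rate_hz, size=cfg.n_rsc)

    ca1_fac = _kernel_factor(cfg.ca1_kernel, gains)
    rsc_fac = _kernel_factor(cfg.rsc_kernel, gains)

    trains: list = []
    rsc_rates = []
    for j in range(cfg.n_rsc):
        r = rsc_base[j] * rsc_fac * _react_factor(v_rsc[j]) * off_mask
        rsc_rates.append(r)

    # coupling: smoothed, mean-normalized lagged source ensemble rate
    coup = cfg.coupling
    gt.coupling = asdict(coup)
    ca1_coup = np.ones(n_ms)
    if coup.direction == "rsc2ca1" and coup.strength > 0:
        # source = realized RSC spikes so the coupling is causal in the data
        src_spikes = [_spikes_from_rate(r, dt, 0.0, rng) for r in rsc_rates]
        pooled = np.concatenate(src_spikes) if src_spikes else np.empty(0)
        hist = np.bincount(np.clip((pooled / dt).astype(int), 0, n_ms - 1),
                           minlength=n_ms).astype(float)
        sm = gaussian_smooth(hist, 0.020 / dt)
        base = sm[nrem_ms].mean() if nrem_ms.any() else sm.mean()
        norm = sm / (base if base > 0 else 1.0)
        shift = int(round(coup.lag_s / dt))
        lagged = np.ones(n_ms)
        if shift < n_ms:
            lagged[shift:] = norm[:n_ms - shift]
        ca1_coup = np.clip(1.0 + coup.strength * (lagged - 1.0), 0.0, None)
        # keep the realized source spikes as the RSC trains
        for j, sp in enumerate(src_spikes):
            trains.append(SpikeTrain(f"rsc{j:02d}", "RSC", sp))
    else:
        for j, r in enumerate(rsc_rates):
            trains.append(SpikeTrain(f"rsc{j:02d}", "RSC",
                                     _spikes_from_rate(r, dt, 0.0, rng)))

    for i in range(cfg.n_ca1):
        r = ca1_base[i] * ca1_fac * _react_factor(u_ca1[i]) * ca1_coup
        trains.append(SpikeTrain(f"ca1{i:02d}", "CA1",
                                 _spikes_from_rate(r, dt, 0.0, rng)))
    trains.sort(key=lambda tr: tr.unit_id)

    for tr in trains:
        region = tr.region
        i = int(tr.unit_id[3:])
        kern = cfg.ca1_kernel if region == "CA1" else cfg.rsc_kernel
        base = ca1_base[i] if region == "CA1" else rsc_base[i]
        w = u_ca1[i] if region == "CA1" and i < u_ca1.size else (
            v_rsc[i] if region == "RSC" and i < v_rsc.size else 0.0)
        gt.unit_specs[tr.unit_id] = {
            "region": region, "base_rate_hz": float(base),
            "kernel": asdict(kern), "template_w": float(w)}

    session = Session(phase=phase)
    session.signals = {
        "CA1-lfp": SampledSignal(lfp_ca1, fs, 0.0, "CA1-lfp"),
        "RSC-lfp": SampledSignal(lfp_rsc, fs, 0.0, "RSC-lfp"),
        "EMG": SampledSignal(emg, fs, 0.0, "EMG"),
    }
    session.trains = trains
    session.hypnogram = IntervalSet(
        [Interval(s, e, st) for st, s, e in states], "other")
    session.events["swr_true"] = IntervalSet(
        [Interval(t - 0.04, t + 0.04, "swr", t, float(a))
         for t, a in zip(rip_times, rip_amp)], "swr")
    return session, gt


# ---------------------------------------------------------------------------
# task sessions

def _figure8_path(cfg: TaskConfig, side: str) -> np.ndarray:
    """Waypoints (cm) of one lap: delay -> stem -> side arm -> back to delay."""
    ax = cfg.arm_x_cm if side == "R" else -cfg.arm_x_cm
    s = cfg.stem_len_cm
    return np.array([
        (0.0, -10.0),   # delay area
        (0.0, 0.0),     # stem entry
        (0.0, s),       # stem exit / choice point
        (ax, s),        # turn onto side arm
        (ax, s - 8.0),  # reward site
        (ax, -10.0),    # down the outer arm
        (0.0, -10.0),   # back to delay
    ])


def simulate_task_session(cfg: TaskConfig = None, seed: int = 0):
    """Figure-8 alternation task: trajectory, trials, and tuned spiking.

    The stem (30 cm x 6 cm) is divided into three 10-cm subareas by the
    downstream analysis; units fire per spatial / trial-type / speed tuning,
    and an optional cross-region co-firing template is expressed during run
    segments (stem entry to reward).
    """
    cfg = cfg or TaskConfig()
    if cfg.n_trials < 1:
        raise ValueError("zero trials requested")
    if cfg.stem_len_cm % 3 != 0 and abs(cfg.stem_len_cm / 3 - round(cfg.stem_len_cm / 3)) > 1e-9:
        raise ValueError("stem length must divide into 3 equal subareas")
    rng = np.random.default_rng(seed)
    frame_dt = 1.0 / cfg.frame_hz

    rows = []
    trial_rows = []
    t = 0.0
    pos_list = []
    for k in range(cfg.n_trials):
        sched = "L" if k % 2 == 0 else "R"
        err = rng.uniform() < cfg.p_error
        turn = ("R" if sched == "L" else "L") if err else sched
        path = _figure8_path(cfg, turn)
        seglen = np.linalg.norm(np.diff(path, axis=0), axis=1)
        cum = np.r_[0.0, np.cumsum(seglen)]
        total = cum[-1]

        t_start = t
        # delay pause
        n_pause = int(round(cfg.delay_pause_s / frame_dt))
        for _ in range(n_pause):
            pos_list.append((t, path[0][0] + rng.normal(0, 0.15),
                             path[0][1] + rng.normal(0, 0.15)))
            t += frame_dt
        # run the lap with a smoothly varying speed
        v0 = rng.uniform(*cfg.run_speed_cm_s)
        dist = 0.0
        stem_entry = stem_exit = reward_t = None
        ph = rng.uniform(0, 2 * np.pi)
        while dist < total:
            v = max(4.0, v0 * (1.0 + 0.25 * np.sin(2 * np.pi * 0.2 * t + ph)
                               + rng.normal(0, 0.05)))
            dist = min(total, dist + v * frame_dt)
            j = np.searchsorted(cum, dist, side="right") - 1
            j = min(j, len(seglen) - 1)
            frac = (dist - cum[j]) / seglen[j] if seglen[j] > 0 else 0.0
            xy = path[j] + frac * (path[j + 1] - path[j])
            pos_list.append((t, float(xy[0]), float(xy[1])))
            if stem_entry is None and dist >= cum[1]:
                stem_entry = t
            if stem_exit is None and dist >= cum[2]:
                stem_exit = t
            if reward_t is None and dist >= cum[4]:
                reward_t = t
                for _ in range(int(round(cfg.reward_pause_s / frame_dt))):
                    t += frame_dt
                    pos_list.append((t, float(xy[0]) + rng.normal(0, 0.15),
                                     float(xy[1]) + rng.normal(0, 0.15)))
            t += frame_dt
        trial_rows.append({"trial_id": k, "trial_type": sched,
                           "correct": not err, "start_s": t_start,
                           "stem_entry_s": stem_entry, "stem_exit_s": stem_exit,
                           "reward_s": reward_t, "end_s": t})

    traj = pd.DataFrame(pos_list, columns=["time_s", "x_cm", "y_cm"])
    trials = pd.DataFrame(trial_rows)
    gt = GroundTruth()
    gt.trials = trial_rows

    # instantaneous speed (cm per frame interval)
    dx = np.r_[0.0, np.hypot(np.diff(traj.x_cm), np.diff(traj.y_cm))]
    speed = dx / frame_dt
    times = traj.time_s.to_numpy()

    # trial type per frame
    ttype = np.full(times.size, "", dtype=object)
    correct = np.zeros(times.size, dtype=bool)
    for r in trial_rows:
        m = (times >= r["start_s"]) & (times < r["end_s"])
        ttype[m] = r["trial_type"]
        correct[m] = r["correct"]

    # run-epoch template latent (100-ms blocks)
    run_mask = np.zeros(times.size, dtype=bool)
    for r in trial_rows:
        if r["stem_entry_s"] is not None and r["reward_s"] is not None:
            run_mask |= (times >= r["stem_entry_s"]) & (times < r["reward_s"])
    latent = np.zeros(times.size)
    if cfg.template_strength > 0:
        block = np.floor(times / 0.1).astype(int)
        uniq = np.unique(block[run_mask])
        on = rng.uniform(size=uniq.size) < cfg.template_burst_prob
        lut = dict(zip(uniq[on], np.ones(on.sum())))
        latent = np.where(run_mask,
                          np.array([lut.get(b, 0.0) for b in block]), 0.0)
        latent *= cfg.template_strength

    tw = cfg.template_weights or {}
    u_ca1 = np.asarray(tw.get("ca1", np.zeros(cfg.n_ca1)), dtype=float)
    v_rsc = np.asarray(tw.get("rsc", np.zeros(len(cfg.units))), dtype=float)
    gt.template_weights = {"ca1": u_ca1.tolist(), "rsc": v_rsc.tolist()}

    trains = []
    x, y = traj.x_cm.to_numpy(), traj.y_cm.to_numpy()
    for j, spec in enumerate(cfg.units):
        if spec.speed_slope != 0.0:
            rate = spec.base_rate_hz + spec.speed_slope * speed
        else:
            rate = np.full(times.size, spec.base_rate_hz)
            if spec.field_center is not None:
                cx, cy = spec.field_center
                d2 = (x - cx) ** 2 + (y - cy) ** 2
                bump = np.exp(-d2 / (2 * spec.field_width_cm ** 2))
                tgain = np.where(ttype == "L", spec.gain_left,
                                 np.where(ttype == "R", spec.gain_right, 1.0))
                rate = rate * (1.0 + (spec.field_gain * tgain - 1.0) * bump)
        w = v_rsc[j] if j < v_rsc.size else 0.0
        rate = np.clip(rate * (1.0 + w * latent), 0.0, None)
        sp = _spikes_from_rate(rate, frame_dt, float(times[0]), rng)
        trains.append(SpikeTrain(f"rsc{j:02d}", spec.region, sp))
        gt.unit_specs[f"rsc{j:02d}"] = asdict(spec)

    for i in range(cfg.n_ca1):
        base = rng.uniform(*cfg.ca1_rate_hz)
        w = u_ca1[i] if i < u_ca1.size else 0.0
        rate = np.clip(base * (1.0 + w * latent), 0.0, None)
        sp = _spikes_from_rate(rate, frame_dt, float(times[0]), rng)
        trains.append(SpikeTrain(f"ca1{i:02d}", "CA1", sp))
        gt.unit_specs[f"ca1{i:02d}"] = {"base_rate_hz": float(base),
                                        "template_w": float(w)}
    trains.sort(key=lambda tr: tr.unit_id)

    session = Session(phase="task")
    session.trains = trains
    session.trajectory = traj
    session.trials = trials
    return session, gt


# ---------------------------------------------------------------------------
# waveforms

def waveform_template(trough_to_peak_ms: float, dt_ms: float = 1.0 / 30.0,
                      amp_uv: float = 100.0, trough_w_ms: float = 0.07,
                      peak_amp: float = 0.45, pre_amp: float = 0.18,
                      pre_w_ms: float = 0.045) -> np.ndarray:
    """Parametric mean waveform on the -0.2..+0.8 ms window around the trough.

    The shape parameters beyond trough-to-peak duration give individual
    units idiosyncratic waveforms, as real units have.
    """
    t = np.arange(-0.2, 0.8 + 1e-9, dt_ms)
    ttp = trough_to_peak_ms
    w = (-np.exp(-t * t / (2 * trough_w_ms ** 2))
         + peak_amp * np.exp(-(t - ttp) ** 2 / (2 * (0.22 * ttp + 0.04) ** 2))
         + pre_amp * np.exp(-(t + 0.14) ** 2 / (2 * pre_w_ms ** 2)))
    return amp_uv * w / np.abs(w.min())


def simulate_waveforms(n_wide: int, n_narrow: int, noise_sd: float = 0.05,
                       seed: int = 0, phases=("pre_sleep", "task", "post_sleep"),
                       n_channels: int = 8, drift_sd: float = 0.03,
                       wide_ttp_ms: tuple = (0.6, 0.8),
                       narrow_ttp_ms: tuple = (0.2, 0.4)):
    """Two waveform families replicated across phases with noise and drift.

    Returns ``(waveforms, identity, families)``: per-phase waveform lists
    (unit order shuffled per phase, ids anonymized), the true cross-phase
    identity maps keyed ``"<phase_a>:<phase_b>"``, and the family of each
    true unit.  ``noise_sd`` and ``drift_sd`` are fractions of the
    peak-to-trough amplitude.
    """
    rng = np.random.default_rng(seed)
    dt_ms = 1.0 / 30.0
    n_units = n_wide + n_narrow
    ttp = np.r_[rng.uniform(*wide_ttp_ms, size=n_wide),
                rng.uniform(*narrow_ttp_ms, size=n_narrow)]
    fam = ["wide"] * n_wide + ["narrow"] * n_narrow
    amp = rng.uniform(80.0, 160.0, size=n_units)
    chan = rng.integers(0, n_channels, size=n_units)
    trough_w = rng.uniform(0.055, 0.095, size=n_units)
    peak_a = rng.uniform(0.30, 0.60, size=n_units)
    pre_a = rng.uniform(0.08, 0.28, size=n_units)
    pre_w = rng.uniform(0.035, 0.060, size=n_units)
    base = [waveform_template(ttp[i], dt_ms, amp[i], trough_w[i], peak_a[i],
                              pre_a[i], pre_w[i]) for i in range(n_units)]

    waveforms = {}
    phase_ids = {}
    for ph in phases:
        order = rng.permutation(n_units)
        lst = []
        ids = {}
        for pos, i in enumerate(order):
            w = base[i].copy()
            p2t = w.max() - w.min()
            w = w * (1.0 + rng.normal(0.0, drift_sd))
            w = w + rng.normal(0.0, noise_sd * p2t, size=w.size)
            uid = f"{ph}_{pos:03d}"
            lst.append(UnitWaveform(uid, w, dt_ms, int(np.argmin(base[i])),
                                    int(chan[i])))
            ids[i] = uid
        waveforms[ph] = lst
        phase_ids[ph] = ids

    identity = {}
    for a in phases:
        for b in phases:
            if a != b:
                identity[f"{a}:{b}"] = {phase_ids[a][i]: phase_ids[b][i]
                                        for i in range(n_units)}
    families = {phase_ids[ph][i]: fam[i] for ph in phases for i in range(n_units)}
    return waveforms, identity, families
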