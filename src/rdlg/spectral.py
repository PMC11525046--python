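"""Spectrograms, peri-event spectrograms, PSD band ratios, wavelet coherence."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import SampledSignal, ValidationError

BANDS = {"delta": (1.0, 4.0), "theta": (6.0, 10.0),
         "spindle": (10.0, 20.0), "ripple": (140.0, 250.0)}


@dataclass
class TimeFrequencyMap:
    times_s: np.ndarray
    freqs_hz: np.ndarray
    power: np.ndarray  # freqs x times
    normalization: str = "log"  # log | zscore_baseline | linear
    baseline_s: tuple = None

    def __post_init__(self):
        if self.power.shape != (self.freqs_hz.size, self.times_s.size):
            raise ValidationError("power dims inconsistent with axes")


def _morlet_tfr(x: np.ndarray, fs: float, freqs: np.ndarray,
                n_cycles: float = 7.0) -> np.ndarray:
    """Morlet wavelet power via FFT convolution, one row per frequency."""
    n = x.size
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    X = np.fft.fft(x, nfft)
    out = np.empty((freqs.size, n))
    fft_f = np.fft.fftfreq(nfft, 1.0 / fs)
    for i, f0 in enumerate(freqs):
        sigma_f = f0 / n_cycles
        # Gaussian in frequency domain centered on f0 (analytic wavelet)
        H = np.exp(-0.5 * ((fft_f - f0) / sigma_f) ** 2)
        H[fft_f < 0] = 0.0
        conv = np.fft.ifft(X * H)[:n]
        out[i] = np.abs(conv) ** 2
    return out


def spectrogram(signal: SampledSignal, method: str = "stft",
                freqs=None, nperseg: int = 256, noverlap: int = None,
                n_cycles: float = 7.0) -> TimeFrequencyMap:
    """Time-frequency power map via short-time Fourier or Morlet transform.

    STFT power is scaled so total power matches time-domain variance
    (Parseval, density scaling); requested frequencies above Nyquist raise.
    """
    nyq = signal.rate_hz / 2
    if freqs is not None and np.max(freqs) >= nyq:
        raise ValidationError("requested frequency at or above Nyquist")
    if method == "stft":
        f, t, S = sps.spectrogram(signal.samples, fs=signal.rate_hz,
                                  nperseg=nperseg, noverlap=noverlap,
                                  scaling="density", mode="psd")
        if freqs is not None:
            keep = (f >= np.min(freqs)) & (f <= np.max(freqs))
            f, S = f[keep], S[keep]
        return TimeFrequencyMap(signal.t0_s + t, f, S, "linear")
    elif method == "morlet":
        if freqs is None:
            freqs = np.geomspace(1.0, nyq * 0.8, 60)
        freqs = np.asarray(freqs, dtype=float)
        P = _morlet_tfr(signal.samples, signal.rate_hz, freqs, n_cycles)
        return TimeFrequencyMap(signal.times(), freqs, P, "linear")
    raise ValidationError(f"unknown method {method!r}")


def peri_event_spectrogram(signal: SampledSignal, anchors,
                           window_s=(-1.0, 1.0), baseline_s=(-1.0, -0.5),
                           freqs=None, n_cycles: float = 7.0) -> TimeFrequencyMap:
    """Anchor-averaged Morlet map, z-scored per frequency to the baseline.

    Each anchor contributes the power in ``window_s`` around it; rows are
    z-scored using mean and SD over the baseline lags of the average map,
    so baseline rows have mean approximately 0.
    """
    fs = signal.rate_hz
    if freqs is None:
        freqs = np.geomspace(2.0, min(250.0, fs / 2 * 0.9), 50)
    freqs = np.asarray(freqs, dtype=float)
    i_lo = int(np.round(window_s[0] * fs))
    i_hi = int(np.round(window_s[1] * fs))
    anchors = [a for a in np.atleast_1d(anchors)
               if (a - signal.t0_s) * fs + i_lo >= 0
               and (a - signal.t0_s) * fs + i_hi < signal.n]
    if not anchors:
        raise ValidationError("no anchor has a full window inside the signal")
    P = _morlet_tfr(signal.samples, fs, freqs, n_cycles)
    lags = np.arange(i_lo, i_hi) / fs
    acc = np.zeros((freqs.size, lags.size))
    for a in anchors:
        i0 = int(np.round((a - signal.t0_s) * fs))
        acc += P[:, i0 + i_lo:i0 + i_hi]
    acc /= len(anchors)
    bl = (lags >= baseline_s[0]) & (lags < baseline_s[1])
    mu = acc[:, bl].mean(axis=1, keepdims=True)
    sd = acc[:, bl].std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return TimeFrequencyMap(lags, freqs, (acc - mu) / sd,
                            "zscore_baseline", baseline_s)


def psd(signal: SampledSignal, nperseg: int = 4096) -> tuple:
    """Welch power spectral density; returns (freqs, psd)."""
    return sps.welch(signal.samples, fs=signal.rate_hz,
                     nperseg=min(nperseg, signal.n))


def band_power_ratio(psd_a: tuple, psd_b: tuple, bands: dict = None) -> dict:
    """Per-band integrated power ratio a/b on a shared frequency grid."""
    bands = bands or BANDS
    fa, Pa = psd_a
    fb, Pb = psd_b
    if fa.shape != fb.shape or not np.allclose(fa, fb):
        raise ValidationError("PSDs must share one frequency grid")
    out = {}
    for name, (lo, hi) in bands.items():
        m = (fa >= lo) & (fa <= hi)
        if not m.any():
            raise ValidationError(f"band {name} outside frequency grid")
        out[name] = float(np.trapezoid(Pa[m], fa[m])
                          / np.trapezoid(Pb[m], fb[m]))
    return out


def wavelet_coherence(sig_a: SampledSignal, sig_b: SampledSignal,
                      freqs, n_cycles: float = 7.0,
                      smooth_s: float = 0.25) -> TimeFrequencyMap:
    """Magnitude-squared wavelet coherence, bounded [0, 1].

    Cross- and auto-spectra are smoothed over time (Gaussian, ``smooth_s``
    scaled down at high frequency); a signal's coherence with itself is 1.
    """
    if sig_a.rate_hz != sig_b.rate_hz:
        raise ValidationError("signals must share one sampling rate")
    if sig_a.n != sig_b.n:
        raise ValidationError("signals must share one length")
    from scipy.ndimage import gaussian_filter1d
    fs = sig_a.rate_hz
    freqs = np.asarray(freqs, dtype=float)
    n = sig_a.n
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    A = np.fft.fft(sig_a.samples, nfft)
    B = np.fft.fft(sig_b.samples, nfft)
    fft_f = np.fft.fftfreq(nfft, 1.0 / fs)
    coh = np.empty((freqs.size, n))
    for i, f0 in enumerate(freqs):
        sigma_f = f0 / n_cycles
        H = np.exp(-0.5 * ((fft_f - f0) / sigma_f) ** 2)
        H[fft_f < 0] = 0.0
        wa = np.fft.ifft(A * H)[:n]
        wb = np.fft.ifft(B * H)[:n]
        # smooth over ~n_cycles periods, at least smooth_s
        sd = max(smooth_s, 2 * n_cycles / f0) * fs / 4
        sxy = (gaussian_filter1d(np.real(wa * np.conj(wb)), sd) ** 2
               + gaussian_filter1d(np.imag(wa * np.conj(wb)), sd) ** 2)
        sxx = gaussian_filter1d(np.abs(wa) ** 2, sd)
        syy = gaussian_filter1d(np.abs(wb) ** 2, sd)
        denom = sxx * syy
        denom[denom == 0] = np.finfo(float).tiny
        coh[i] = np.clip(sxy / denom, 0.0, 1.0)
    return TimeFrequencyMap(sig_a.times(), freqs, coh, "linear")


def pre_post_band_ratio(tfmap: TimeFrequencyMap, pre_s=(-0.100, 0.0),
                        post_s=(0.0, 0.100), bands: dict = None) -> dict:
    """Post/pre mean-power ratio per band over peri-event lag windows."""
    bands = bands or BANDS
    t = tfmap.times_s
    pre = (t >= pre_s[0]) & (t < pre_s[1])
    post = (t >= post_s[0]) & (t < post_s[1])
    out = {}
    for name, (lo, hi) in bands.items():
        m = (tfmap.freqs_hz >= lo) & (tfmap.freqs_hz <= hi)
        if not m.any():
            continue
        a = tfmap.power[np.ix_(m, post)].mean()
        b = tfmap.power[np.ix_(m, pre)].mean()
        out[name] = float(a / b) if b != 0 else np.inf
    return out
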