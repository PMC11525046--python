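"""Shared filtering primitives (Butterworth band-pass, Gaussian smoothing)."""

from __future__ import annotations

import numpy as np
from scipy import signal as sps
from scipy.ndimage import gaussian_filter1d

from .core import SampledSignal, ValidationError


def bandpass(sig: SampledSignal, lo_hz: float, hi_hz: float,
             order: int = 3) -> np.ndarray:
    """Zero-phase Butterworth filter; ``lo_hz <= 0`` means low-pass."""
    nyq = sig.rate_hz / 2.0
    if hi_hz >= nyq:
        raise ValidationError(
            f"band edge {hi_hz} Hz at or above Nyquist ({nyq} Hz)")
    if lo_hz <= 0:
        sos = sps.butter(order, hi_hz / nyq, btype="low", output="sos")
    else:
        sos = sps.butter(order, [lo_hz / nyq, hi_hz / nyq], btype="band",
                         output="sos")
    pad = 3 * (2 * order + 1)
    if sig.n <= pad:
        raise ValidationError("signal shorter than filter warm-up")
    return sps.sosfiltfilt(sos, sig.samples)


def gaussian_smooth(x: np.ndarray, sd_samples: float) -> np.ndarray:
    if sd_samples <= 0:
        return np.asarray(x, dtype=np.float64)
    return gaussian_filter1d(np.asarray(x, dtype=np.float64), sd_samples,
                             mode="nearest")


def band_envelope_z(sig: SampledSignal, band: tuple, smooth_sd_s: float = 0.01,
                    return_stats: bool = False):
    """Band-pass -> square -> Gaussian-smooth -> z-score.

    This is the normalized detection signal used for ripples and spindles.
    """
    filt = bandpass(sig, band[0], band[1])
    power = gaussian_smooth(filt ** 2, smooth_sd_s * sig.rate_hz)
    mu, sd = float(np.mean(power)), float(np.std(power))
    if sd == 0:
        z = np.zeros_like(power)
    else:
        z = (power - mu) / sd
    if return_stats:
        return z, mu, sd
    return z
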