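"""Putative cell-type classification from mean waveforms and ACGs.

RSC units: waveforms normalized by peak-to-trough amplitude on the
-0.2..+0.8 ms window, PCA to 3 components, Euclidean-linkage hierarchical
clustering cut at 3 clusters, clusters mapped to wide (putative excitatory)
vs narrow (putative inhibitory) by mean trough-to-peak duration (the middle
cluster joins the nearer class centroid and is flagged).

CA1 units follow the fixed rule set: narrow interneuron when trough-to-peak
<= 0.425 ms; pyramidal when trough-to-peak > 0.425 ms and the ACG rise
constant tau_rise <= 6 ms; anything else is unclassified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import curve_fit

from .core import SpikeTrain, UnitWaveform, ValidationError

log = logging.getLogger("rdlg.celltypes")

CA1_TTP_THRESHOLD_MS = 0.425
CA1_TAU_RISE_MAX_MS = 6.0


@dataclass
class WaveformFeatures:
    unit_id: str
    trough_to_peak_ms: float
    trough_to_peak_amp_uv: float
    peak_to_trough_amp_uv: float   # trough vs first peak before the trough
    acg_tau_rise_ms: float = np.nan


def waveform_features(wf: UnitWaveform) -> WaveformFeatures:
    """Local waveform features around the trough."""
    w = wf.mean_waveform
    it = wf.trough_index
    after = w[it:]
    ipk = it + int(np.argmax(after))
    ttp_ms = (ipk - it) * wf.dt_ms
    ttp_amp = float(w[ipk] - w[it])
    before = w[:it + 1]
    # first peak before the trough: last local maximum, else the max value
    pre_peak = float(before.max()) if before.size else 0.0
    p2t_amp = float(pre_peak - w[it])
    return WaveformFeatures(wf.unit_id, float(ttp_ms), ttp_amp, p2t_amp)


def normalized_waveform(wf: UnitWaveform) -> np.ndarray:
    w = wf.mean_waveform
    amp = w.max() - w.min()
    if amp == 0:
        raise ValidationError(f"unit {wf.unit_id}: flat waveform")
    return w / amp


def classify_rsc(waveforms, n_clusters: int = 3, n_pcs: int = 3) -> dict:
    """Wide/narrow classification of RSC units by hierarchical clustering.

    Returns ``{"labels": {unit_id: "wide"|"narrow"}, "cluster": {...},
    "flags": [...]}``.  Fewer than ``n_clusters`` units is a degenerate
    input and is flagged; identical waveforms raise (zero-variance PCA).
    """
    flags = []
    if len(waveforms) < max(n_clusters, 3):
        return {"labels": {wf.unit_id: "unclassified" for wf in waveforms},
                "cluster": {}, "flags": ["degenerate: too few units"]}
    X = np.array([normalized_waveform(wf) for wf in waveforms])
    Xc = X - X.mean(axis=0)
    if np.allclose(Xc, 0):
        raise ValidationError("zero-variance waveforms: PCA undefined "
                              "(all waveforms identical)")
    # PCA via SVD, first n_pcs components
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    pcs = U[:, :n_pcs] * S[:n_pcs]
    Z = linkage(pcs, method="ward", metric="euclidean")
    clusters = fcluster(Z, n_clusters, criterion="maxclust")
    if len(set(clusters)) < n_clusters:
        flags.append("degenerate: fewer clusters than requested")

    ttp = np.array([waveform_features(wf).trough_to_peak_ms
                    for wf in waveforms])
    means = {c: ttp[clusters == c].mean() for c in set(clusters)}
    order = sorted(means, key=means.get)  # narrowest first
    mapping = {order[0]: "narrow", order[-1]: "wide"}
    for c in order[1:-1]:
        lo, hi = means[order[0]], means[order[-1]]
        mapping[c] = "narrow" if abs(means[c] - lo) <= abs(means[c] - hi) \
            else "wide"
        flags.append(f"middle cluster {c} mapped to {mapping[c]} by centroid")
    labels = {wf.unit_id: mapping[c] for wf, c in zip(waveforms, clusters)}
    return {"labels": labels,
            "cluster": {wf.unit_id: int(c) for wf, c in zip(waveforms, clusters)},
            "flags": flags}


def classify_ca1(features) -> dict:
    """Rule-based CA1 typing from trough-to-peak and acg_tau_rise."""
    labels = {}
    for f in features:
        if f.trough_to_peak_ms <= CA1_TTP_THRESHOLD_MS:
            labels[f.unit_id] = "inhibitory"
        elif np.isnan(f.acg_tau_rise_ms):
            labels[f.unit_id] = "unclassified"
            log.info("unit %s: missing acg_tau_rise with wide waveform",
                     f.unit_id)
        elif f.acg_tau_rise_ms <= CA1_TAU_RISE_MAX_MS:
            labels[f.unit_id] = "excitatory"
        else:
            labels[f.unit_id] = "unclassified"
    return labels


def autocorrelogram(train: SpikeTrain, bin_ms: float = 0.5,
                    span_ms: float = 50.0) -> tuple:
    """One-sided spike-train autocorrelogram (counts per positive lag bin)."""
    t = train.times_s
    n_bins = int(round(span_ms / bin_ms))
    edges_s = np.arange(n_bins + 1) * bin_ms / 1000.0
    counts = np.zeros(n_bins, dtype=np.int64)
    hi = span_ms / 1000.0
    j1 = np.searchsorted(t, t + hi)
    for i, stop in enumerate(j1):
        lags = t[i + 1:stop] - t[i]
        idx = np.floor(lags * 1000.0 / bin_ms).astype(int)
        counts += np.bincount(idx[idx < n_bins], minlength=n_bins)
    centers = (edges_s[:-1] + edges_s[1:]) / 2 * 1000.0  # ms
    return centers, counts


def acg_tau_rise(train: SpikeTrain, bin_ms: float = 0.5, span_ms: float = 50.0,
                 min_spikes: int = 300) -> float:
    """Rise time constant (ms) of the ACG refractory recovery.

    Fits the ACG with the sum-of-exponentials form
    ``a*exp(-x/tau_decay) - b*exp(-x/tau_rise) + c*exp(-x/tau_burst) + d``
    and returns tau_rise; NaN on too few spikes or fit failure (flat
    Poisson-like ACGs typically fail or hit the bound and return NaN).
    """
    if train.n_spikes < min_spikes:
        return np.nan
    x, y = autocorrelogram(train, bin_ms, span_ms)
    y = y.astype(float)
    scale = y[x > 20].mean() if np.any(x > 20) else y.mean()
    if scale <= 0:
        return np.nan
    y = y / scale

    def model(x, a, tau_d, b, tau_r, c, tau_b, d):
        return (a * np.exp(-x / tau_d) - b * np.exp(-x / tau_r)
                + c * np.exp(-x / tau_b) + d)

    p0 = (0.5, 20.0, 1.0, 3.0, 0.5, 1.5, 1.0)
    bounds = ([0, 1.0, 0.1, 0.1, 0, 0.1, 0], [10, 500, 10, 25.0, 10, 5.0, 5])
    try:
        popt, _ = curve_fit(model, x, y, p0=p0, bounds=bounds, maxfev=5000)
    except Exception:
        return np.nan
    tau_rise = float(popt[3])
    # flat ACG: rise amplitude negligible or at the bound -> undefined
    if popt[2] < 0.15 or tau_rise >= bounds[1][3] - 1e-6:
        return np.nan
    return tau_rise
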