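"""Cross-regional pairwise correlations and template reactivation strength.

The run-epoch co-firing template is the cell-pair correlation matrix
C = Z_CA1(run)^T Z_RSC(run) / n_bins on 100-ms z-scored counts; the
reactivation strength at sleep bin t is R(t) = z_CA1(t) C z_RSC(t)^T,
z-scored over the sleep epoch.  Peri-SWR reactivation is the SWR-triggered
average of R compared at lag 0 with random-onset surrogates by a one-sided
Wilcoxon signed-rank test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import Interval, IntervalSet, ValidationError, bin_counts, restrict, zscore

log = logging.getLogger("rdlg.react")

MIN_ENSEMBLE = 4  # cells per region


@dataclass
class ReactivationTrace:
    template: np.ndarray      # n_CA1 x n_RSC
    t: np.ndarray             # bin centers (s)
    R: np.ndarray             # z-scored reactivation strength per bin
    R_raw: np.ndarray
    bin_s: float
    n_ca1: int
    n_rsc: int


def _epoch_counts(trains, epochs: IntervalSet, bin_s: float):
    """Concatenated per-epoch count matrices and bin centers."""
    mats, centers = [], []
    for iv in epochs.merged():
        if iv.duration_s < bin_s:
            continue
        c, edges = bin_counts(trains, bin_s, iv)
        mats.append(c)
        centers.append(edges[:-1] + bin_s / 2)
    if not mats:
        raise ValidationError("epochs too short for one bin")
    return np.vstack(mats), np.concatenate(centers)


def pair_correlations(ca1_trains, rsc_trains, epochs_by_phase: dict,
                      bin_s: float = 0.050, n_surrogate: int = 100,
                      alpha: float = 0.05, sig_phase: str = "task_run",
                      seed: int = 0) -> pd.DataFrame:
    """Pearson correlations of 50-ms binned counts for all CA1-RSC pairs.

    One row per pair with an ``r_<phase>`` column per phase and a
    significance class from circular-shift surrogates of the RSC counts in
    ``sig_phase``: positive / negative / unreliable (two-sided alpha, or
    zero-variance counts).
    """
    rng = np.random.default_rng(seed)
    rows = [{"ca1_unit": a.unit_id, "rsc_unit": b.unit_id}
            for a in ca1_trains for b in rsc_trains]
    sig_r = None
    for phase, epochs in epochs_by_phase.items():
        ca1_m, _ = _epoch_counts(ca1_trains, epochs, bin_s)
        rsc_m, _ = _epoch_counts(rsc_trains, epochs, bin_s)
        k = 0
        thr = {}
        for i in range(ca1_m.shape[1]):
            x = ca1_m[:, i].astype(float)
            for j in range(rsc_m.shape[1]):
                y = rsc_m[:, j].astype(float)
                if x.std() == 0 or y.std() == 0:
                    rows[k][f"r_{phase}"] = np.nan
                else:
                    rows[k][f"r_{phase}"] = float(np.corrcoef(x, y)[0, 1])
                k += 1
        if phase == sig_phase:
            n = ca1_m.shape[0]
            shifts = rng.integers(1, n, size=n_surrogate)
            k = 0
            for i in range(ca1_m.shape[1]):
                x = ca1_m[:, i].astype(float)
                xs = x.std()
                for j in range(rsc_m.shape[1]):
                    y = rsc_m[:, j].astype(float)
                    if xs == 0 or y.std() == 0:
                        rows[k]["class"] = "unreliable"
                        k += 1
                        continue
                    null = np.array([np.corrcoef(np.roll(x, s), y)[0, 1]
                                     for s in shifts])
                    lo, hi = np.quantile(null, [alpha / 2, 1 - alpha / 2])
                    r = rows[k][f"r_{phase}"]
                    rows[k]["class"] = ("positive" if r > hi else
                                        "negative" if r < lo else "unreliable")
                    k += 1
    return pd.DataFrame(rows)


def build_template(ca1_counts_run: np.ndarray, rsc_counts_run: np.ndarray,
                   min_cells: int = MIN_ENSEMBLE) -> np.ndarray:
    """Run-epoch cell-pair correlation template C (n_CA1 x n_RSC).

    Counts are z-scored per cell over the run bins; silent cells (zero
    variance) are excluded with a warning before the ensemble-size check.
    Returns C = Z_ca1^T Z_rsc / n_bins.
    """
    ca1 = np.asarray(ca1_counts_run, dtype=float)
    rsc = np.asarray(rsc_counts_run, dtype=float)
    if ca1.shape[0] != rsc.shape[0]:
        raise ValidationError("count matrices must share the bin axis")
    keep_a = ca1.std(axis=0) > 0
    keep_b = rsc.std(axis=0) > 0
    if not keep_a.all() or not keep_b.all():
        log.warning("excluding %d CA1 and %d RSC silent cells",
                    (~keep_a).sum(), (~keep_b).sum())
    ca1, rsc = ca1[:, keep_a], rsc[:, keep_b]
    if ca1.shape[1] < min_cells or rsc.shape[1] < min_cells:
        raise ValidationError(
            f"ensemble needs at least {min_cells} cells per region "
            f"(got {ca1.shape[1]} CA1, {rsc.shape[1]} RSC)")
    n_bins = ca1.shape[0]
    return zscore(ca1).T @ zscore(rsc) / n_bins


def reactivation_strength(C: np.ndarray, ca1_counts: np.ndarray,
                          rsc_counts: np.ndarray, t_centers: np.ndarray,
                          bin_s: float = 0.100) -> ReactivationTrace:
    """Time-resolved reactivation strength R(t) = z_CA1(t) C z_RSC(t)^T.

    Sleep counts are z-scored with the match-epoch statistics; R is then
    z-scored over the epoch before any cross-phase combination.
    """
    ca1 = np.asarray(ca1_counts, dtype=float)
    rsc = np.asarray(rsc_counts, dtype=float)
    if ca1.shape[1] != C.shape[0] or rsc.shape[1] != C.shape[1]:
        raise ValidationError("count matrices do not match template dims")
    za, zb = zscore(ca1), zscore(rsc)
    raw = np.einsum("ti,ij,tj->t", za, C, zb)
    sd = raw.std()
    Rz = (raw - raw.mean()) / (sd if sd > 0 else 1.0)
    return ReactivationTrace(C, np.asarray(t_centers), Rz, raw, bin_s,
                             C.shape[0], C.shape[1])


def peri_swr_reactivation(trace: ReactivationTrace, swr_onsets,
                          window=(-1.0, 1.0), n_shuffle: int = 100,
                          seed: int = 0) -> dict:
    """SWR-triggered average of R(t) with a random-onset null.

    The null redraws as many onsets as real SWRs uniformly within the trace
    span, ``n_shuffle`` times; significance at lag 0 is a one-sided Wilcoxon
    signed-rank test of the per-event R at onset against the shuffle-mean
    lag-0 value.
    """
    swr_onsets = np.asarray(swr_onsets, dtype=float)
    if swr_onsets.size == 0:
        raise ValidationError("no SWR onsets")
    rng = np.random.default_rng(seed)
    t, R, bin_s = trace.t, trace.R, trace.bin_s
    lo = int(np.floor(window[0] / bin_s))
    hi = int(np.ceil(window[1] / bin_s))
    lags = np.arange(lo, hi + 1) * bin_s

    def triggered(onsets):
        rows = []
        for o in onsets:
            i = int(np.argmin(np.abs(t - o)))
            if i + lo < 0 or i + hi >= R.size:
                continue
            rows.append(R[i + lo:i + hi + 1])
        return np.array(rows)

    real = triggered(swr_onsets)
    if real.size == 0:
        raise ValidationError("no SWR with a full window inside the trace")
    null_means = np.empty((n_shuffle, lags.size))
    for k in range(n_shuffle):
        fake = rng.uniform(t[0] - window[0], t[-1] - window[1],
                           size=swr_onsets.size)
        m = triggered(np.sort(fake))
        null_means[k] = m.mean(axis=0) if m.size else np.nan
    i0 = int(np.flatnonzero(np.isclose(lags, 0.0))[0])
    null_lag0 = float(np.nanmean(null_means[:, i0]))
    diffs = real[:, i0] - null_lag0
    if np.allclose(diffs, 0):
        p = 0.5
    else:
        _, p = stats.wilcoxon(diffs, alternative="greater")
    return {"lags_s": lags, "mean": real.mean(axis=0),
            "null_mean": np.nanmean(null_means, axis=0),
            "null_lo": np.nanpercentile(null_means, 2.5, axis=0),
            "null_hi": np.nanpercentile(null_means, 97.5, axis=0),
            "p_lag0": float(p), "n_events": int(real.shape[0])}


def run_epochs_from_trials(trials: pd.DataFrame) -> IntervalSet:
    """Run epochs (stem entry to reward approach) from the trial table,
    correct trials only."""
    ivs = []
    for r in trials.itertuples():
        if not bool(r.correct):
            continue
        if pd.notna(r.stem_entry_s) and pd.notna(r.reward_s) \
                and r.reward_s > r.stem_entry_s:
            ivs.append(Interval(float(r.stem_entry_s), float(r.reward_s),
                                "other"))
    return IntervalSet(ivs, "other")
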