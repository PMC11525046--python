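"""Spatial coding on the figure-8 maze: rate maps, place fields, stem-trial
analysis (splitter vs location-related cells), and speed-cell screening.

Rate maps use 0.36 cm square bins with 5x5-bin Gaussian smoothing of spike
and occupancy maps before division; spikes are used only while running
faster than 3 cm/s, and units with at most 200 spikes in the session are
excluded.  Stem firing is summarized per trial and subarea (3 x 10 cm
segments of the 30 cm stem) and classified by a two-way ANOVA with subarea
and trial type as factors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter, label

from .core import SpikeTrain, ValidationError

log = logging.getLogger("rdlg.spatial")

BIN_CM = 0.36
SPEED_MIN_CM_S = 3.0
MIN_SPIKES = 200
FIELD_RATE_FACTOR = 2.0
FIELD_MIN_BINS = 40
FIELD_MAX_EXTENT = 7  # bounding box in bins


@dataclass
class RateMap:
    x_edges: np.ndarray
    y_edges: np.ndarray
    occupancy_s: np.ndarray
    spike_counts: np.ndarray
    rate_hz: np.ndarray
    mean_rate_hz: float


def trajectory_speed(traj: pd.DataFrame) -> np.ndarray:
    """Instantaneous speed (cm/s) from frame-to-frame displacements."""
    t = traj["time_s"].to_numpy()
    dx = np.hypot(np.diff(traj["x_cm"].to_numpy()),
                  np.diff(traj["y_cm"].to_numpy()))
    dt = np.diff(t)
    dt[dt <= 0] = np.nan
    v = dx / dt
    return np.r_[v[:1], v]


def rate_map(train: SpikeTrain, traj: pd.DataFrame,
             bin_cm: float = BIN_CM, speed_min: float = SPEED_MIN_CM_S,
             min_spikes: int = MIN_SPIKES, smooth_bins: float = 1.0,
             min_occ_s: float = 0.050) -> RateMap:
    """Speed-filtered occupancy-normalized firing-rate map.

    The Gaussian kernel (SD ``smooth_bins``, truncated to the neighbouring
    5x5 bins) smooths spike and time maps separately before division.
    Raises when the unit has fewer than ``min_spikes`` speed-filtered
    spikes (excluded with a reason).
    """
    t = traj["time_s"].to_numpy()
    x = traj["x_cm"].to_numpy()
    y = traj["y_cm"].to_numpy()
    v = trajectory_speed(traj)
    moving = v > speed_min
    if not moving.any():
        raise ValidationError("no samples above the speed threshold")
    frame_dt = float(np.median(np.diff(t)))

    # spike positions by interpolation; speed filter per spike
    sx = np.interp(train.times_s, t, x)
    sy = np.interp(train.times_s, t, y)
    sv = np.interp(train.times_s, t, v)
    keep = sv > speed_min
    if keep.sum() <= min_spikes:
        raise ValidationError(
            f"unit {train.unit_id}: {keep.sum()} speed-filtered spikes "
            f"<= {min_spikes} required")

    x_edges = np.arange(x.min() - bin_cm, x.max() + 2 * bin_cm, bin_cm)
    y_edges = np.arange(y.min() - bin_cm, y.max() + 2 * bin_cm, bin_cm)
    occ, _, _ = np.histogram2d(x[moving], y[moving],
                               bins=(x_edges, y_edges))
    occ = occ * frame_dt
    spk, _, _ = np.histogram2d(sx[keep], sy[keep], bins=(x_edges, y_edges))
    # 5x5 neighbourhood Gaussian (SD 1 bin, radius 2)
    occ_s = gaussian_filter(occ, smooth_bins, truncate=2.0, mode="constant")
    spk_s = gaussian_filter(spk, smooth_bins, truncate=2.0, mode="constant")
    rate = np.zeros_like(occ_s)
    # occupancy floor: rates in barely-visited bins are unstable
    nz = occ_s > min_occ_s
    rate[nz] = spk_s[nz] / occ_s[nz]
    mean_rate = float(keep.sum() / (moving.sum() * frame_dt))
    return RateMap(x_edges, y_edges, occ, spk, rate, mean_rate)


def find_place_fields(rmap: RateMap, rate_factor: float = FIELD_RATE_FACTOR,
                      min_bins: int = FIELD_MIN_BINS,
                      max_extent: int = FIELD_MAX_EXTENT) -> list:
    """Connected supra-threshold components qualifying as place fields.

    A field is a connected component of bins with rate >= ``rate_factor`` x
    the unit's mean rate, containing at least ``min_bins`` bins, whose
    bounding box fits in ``max_extent`` x ``max_extent`` bins.
    """
    thr = rate_factor * rmap.mean_rate_hz
    mask = (rmap.rate_hz >= thr) & (rmap.occupancy_s > 0)
    labeled, n = label(mask)
    fields = []
    for k in range(1, n + 1):
        ii, jj = np.nonzero(labeled == k)
        if ii.size < min_bins:
            continue
        if np.ptp(ii) + 1 > max_extent or np.ptp(jj) + 1 > max_extent:
            continue
        fields.append({"n_bins": int(ii.size),
                       "peak_rate_hz": float(rmap.rate_hz[ii, jj].max()),
                       "centroid_bin": (float(ii.mean()), float(jj.mean()))})
    return fields


def stem_trial_rates(train: SpikeTrain, traj: pd.DataFrame,
                     trials: pd.DataFrame, stem_x=(-3.0, 3.0),
                     stem_y=(0.0, 30.0), n_subareas: int = 3) -> pd.DataFrame:
    """Firing rate per correct trial and stem subarea.

    The stem is split into ``n_subareas`` equal segments along its axis;
    the rate is spikes / time-in-subarea within each trial's stem pass.
    Incorrect trials are excluded.
    """
    t = traj["time_s"].to_numpy()
    x = traj["x_cm"].to_numpy()
    y = traj["y_cm"].to_numpy()
    frame_dt = float(np.median(np.diff(t)))
    edges = np.linspace(stem_y[0], stem_y[1], n_subareas + 1)
    sx = np.interp(train.times_s, t, x)
    sy = np.interp(train.times_s, t, y)
    rows = []
    for r in trials.itertuples():
        if not bool(r.correct):
            continue
        if pd.isna(r.stem_entry_s) or pd.isna(r.stem_exit_s):
            continue
        in_tr = (t >= r.stem_entry_s) & (t < r.stem_exit_s)
        s_in = (train.times_s >= r.stem_entry_s) & (train.times_s < r.stem_exit_s)
        for a in range(n_subareas):
            sel = in_tr & (x >= stem_x[0]) & (x <= stem_x[1]) \
                & (y >= edges[a]) & (y < edges[a + 1])
            dur = sel.sum() * frame_dt
            cnt = int(np.sum(s_in & (sx >= stem_x[0]) & (sx <= stem_x[1])
                             & (sy >= edges[a]) & (sy < edges[a + 1])))
            if dur > 0:
                rows.append({"trial_id": r.trial_id, "trial_type": r.trial_type,
                             "subarea": a + 1, "rate_hz": cnt / dur})
    return pd.DataFrame(rows)


def classify_stem_cell(stem_rates: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Two-way ANOVA (subarea x trial type) classification of a stem cell.

    splitter: significant main effect of trial type or subarea x type
    interaction; location_related: significant subarea main effect only;
    neither: otherwise.
    """
    if stem_rates.empty or stem_rates["trial_type"].nunique() < 2:
        raise ValidationError("need both trial types with stem passes")
    import statsmodels.api as sm
    from statsmodels.formula.api import ols
    df = stem_rates.copy()
    model = ols("rate_hz ~ C(subarea) * C(trial_type)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    p_sub = float(table.loc["C(subarea)", "PR(>F)"])
    p_type = float(table.loc["C(trial_type)", "PR(>F)"])
    p_int = float(table.loc["C(subarea):C(trial_type)", "PR(>F)"])
    if p_type < alpha or p_int < alpha:
        lab = "splitter"
    elif p_sub < alpha:
        lab = "location_related"
    else:
        lab = "neither"
    return {"label": lab, "p_subarea": p_sub, "p_trial_type": p_type,
            "p_interaction": p_int, "anova": table}


def speed_score(train: SpikeTrain, traj: pd.DataFrame,
                speed_range=(5.0, 35.0), bin_cm_s: float = 1.0,
                n_shuffle: int = 100, min_shift_s: float = 10.0,
                smooth_s: float = 0.250, alpha: float = 0.01,
                seed: int = 0) -> dict:
    """Speed tuning score and speed-cell flag.

    The score is the absolute Pearson correlation between the smoothed
    instantaneous firing rate (spike counts per frame, 250-ms Gaussian) and
    running speed, over frames inside ``speed_range``.  A unit is a speed
    cell when the score exceeds the 99th percentile of ``n_shuffle``
    circular shifts of the rate along the trajectory (random amount between
    ``min_shift_s`` and session length minus ``min_shift_s``, end wrapped
    to the beginning) and the correlation p-value is below ``alpha``.
    Shifts confined to a narrow range would give strongly correlated null
    draws (the score decorrelates only over ~1 s of shift), collapsing the
    effective null sample and inflating the false-positive rate far above
    the percentile rule's nominal level.  The binned tuning curve is
    returned descriptively.
    """
    rng = np.random.default_rng(seed)
    t = traj["time_s"].to_numpy()
    v = trajectory_speed(traj)
    frame_dt = float(np.median(np.diff(t)))
    if np.nanstd(v) <= 1e-9 * max(1.0, float(np.nanmean(v))):
        raise ValidationError("constant speed: correlation undefined")
    sel = (v >= speed_range[0]) & (v <= speed_range[1])
    if sel.sum() < 10:
        raise ValidationError("too few samples inside the speed range")

    edges = np.r_[t - frame_dt / 2, t[-1] + frame_dt / 2]
    counts = np.histogram(train.times_s, bins=edges)[0].astype(float)
    from .filters import gaussian_smooth
    rate = gaussian_smooth(counts, smooth_s / frame_dt) / frame_dt

    r_obs = float(stats.pearsonr(rate[sel], v[sel])[0])
    score = abs(r_obs)
    # correlation p-value with autocorrelation-corrected sample size: the
    # 250-ms-smoothed rate and the speed are both serially dependent, so the
    # naive n would make the t-test vacuous
    def _lag1(x):
        x = x - x.mean()
        return float(np.dot(x[:-1], x[1:]) / max(np.dot(x, x), 1e-12))
    rho = max(0.0, _lag1(rate[sel])) * max(0.0, _lag1(v[sel]))
    n_eff = max(5.0, sel.sum() * (1 - rho) / (1 + rho))
    tstat = score * np.sqrt((n_eff - 2) / max(1e-12, 1 - score ** 2))
    p_obs = 2 * stats.t.sf(tstat, n_eff - 2)
    span = t[-1] - t[0]
    hi_shift = max(span - min_shift_s, min_shift_s + 1.0)
    null = np.empty(n_shuffle)
    for k in range(n_shuffle):
        shift = rng.uniform(min_shift_s, hi_shift)
        shifted = np.roll(rate, int(round(shift / frame_dt)))
        null[k] = abs(float(stats.pearsonr(shifted[sel], v[sel])[0]))
    thr = float(np.percentile(null, 99))
    flag = bool(score > thr and p_obs < alpha)

    v_bins = np.arange(speed_range[0], speed_range[1] + bin_cm_s, bin_cm_s)
    which = np.digitize(v, v_bins) - 1
    tuning = np.full(v_bins.size - 1, np.nan)
    for b in range(v_bins.size - 1):
        m = sel & (which == b)
        if m.sum() * frame_dt > 0.5:
            tuning[b] = counts[m].sum() / (m.sum() * frame_dt)
    return {"score": score, "p": float(p_obs), "null_99": thr,
            "speed_cell": flag, "tuning_speed": v_bins[:-1] + bin_cm_s / 2,
            "tuning_rate_hz": tuning}


def exclude_speed_cells(labels: dict, speed_flags: dict) -> dict:
    """Drop stem-cell labels for units flagged as speed cells."""
    out = {}
    for uid, lab in labels.items():
        if speed_flags.get(uid, False):
            log.info("unit %s: %s label removed (speed cell)", uid, lab)
            continue
        out[uid] = lab
    if labels and not out:
        log.warning("all labeled cells were speed cells")
    return out
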