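"""End-to-end validation scenarios on synthetic ground truth.

Each function generates its own data with the package's simulators, runs
the corresponding analysis stage, and measures recovery / calibration /
power.  Problem sizes are fixed study conditions (documented in the methods
note); every scenario is seeded and deterministic.
"""

from __future__ import annotations

import numpy as np

from . import detect
from .core import Interval, IntervalSet, SpikeTrain, ValidationError
from .glm import _cv_gain, compare_gains, predict_cell_counts
from .psth import test_modulation
from .react import (_epoch_counts, build_template, peri_swr_reactivation,
                    reactivation_strength, run_epochs_from_trials)
from .sleep import score_sleep_session
from .spatial import classify_stem_cell, speed_score, stem_trial_rates
from .synth import (CouplingSpec, KernelSpec, SleepConfig, SpatialUnitSpec,
                    TaskConfig, simulate_sleep_session, simulate_task_session,
                    simulate_waveforms)
from .tracking import match_units
from .celltypes import classify_rsc


def _precision_recall(peaks, truth, tol):
    truth = np.asarray(truth)
    peaks = np.asarray(peaks)
    if peaks.size == 0:
        return 0.0, 0.0
    tp = sum(bool(np.any(np.abs(truth - p) < tol)) for p in peaks)
    rec = float(np.mean([np.any(np.abs(peaks - t) < tol) for t in truth]))
    return tp / peaks.size, rec


def detector_fidelity(seed: int = 0) -> dict:
    """Recall/precision of all four detectors on one 10-minute session."""
    sess, gt = simulate_sleep_session(SleepConfig(), seed=seed)
    nrem = gt.state_set("nrem")
    out = {}
    for kind, ivs, tol in (
            ("ripple", detect.detect_ripples(sess.signals["CA1-lfp"]), 0.05),
            ("sharp_wave", detect.detect_sharp_waves(sess.signals["CA1-lfp"]),
             0.08),
            ("delta", detect.detect_delta(sess.signals["RSC-lfp"]), 0.15),
            ("spindle", detect.detect_spindles(sess.signals["RSC-lfp"]), 0.4)):
        peaks = ivs.peaks[nrem.membership(ivs.peaks)]
        p, r = _precision_recall(peaks, gt.event_times[kind], tol)
        out[f"{kind}_precision"] = p
        out[f"{kind}_recall"] = r
    return out


def off_oracle_discrepancies(n_rasters: int = 1000, seed: int = 0) -> int:
    """Exact agreement of OFF detection with a literal merge-sort oracle."""
    rng = np.random.default_rng(seed)
    bad = 0
    for _ in range(n_rasters):
        n_units = int(rng.integers(5, 9))
        trains = [SpikeTrain(f"u{i}", "RSC",
                             np.sort(rng.uniform(0, 5, rng.integers(3, 60))))
                  for i in range(n_units)]
        got = detect.detect_off_periods(trains, Interval(0, 5))
        pooled = np.sort(np.concatenate([tr.times_s for tr in trains]))
        bounds = np.r_[0.0, pooled, 5.0]
        want = [(a, b) for a, b in zip(bounds[:-1], bounds[1:]) if b - a > 0.1]
        merged = []
        for a, b in want:
            if merged and a - merged[-1][1] < 0.005:
                merged[-1] = (merged[-1][0], b)
            else:
                merged.append((a, b))
        if [(iv.start_s, iv.end_s) for iv in got] != merged:
            bad += 1
    return bad


def sleep_scoring_agreement(n_seeds: int = 20, seed0: int = 0,
                            duration_s: float = 400.0) -> list:
    """Per-bin state agreement away from +-5 s transition zones, per seed."""
    out = []
    for k in range(n_seeds):
        sess, gt = simulate_sleep_session(
            SleepConfig(duration_s=duration_s, n_delta=40, n_spindles=15),
            seed=seed0 + k)
        hyp = score_sleep_session(sess.signals["CA1-lfp"],
                                  sess.signals["EMG"])
        edges = sorted({s for _, s, e in gt.states}
                       | {e for _, s, e in gt.states})[1:-1]
        tgrid = np.arange(0.5, duration_s, 1.0)
        truth = np.array(["other"] * tgrid.size, dtype=object)
        for st, s, e in gt.states:
            truth[(tgrid >= s) & (tgrid < e)] = st
        pred = np.array(["other"] * tgrid.size, dtype=object)
        for iv in hyp:
            pred[(tgrid >= iv.start_s) & (tgrid < iv.end_s)] = iv.kind
        keep = np.array([all(abs(t - ed) > 5 for ed in edges) for t in tgrid])
        out.append(float(np.mean(truth[keep] == pred[keep])))
    return out


def _poisson_unit(rate, duration, rng):
    n = rng.poisson(rate * duration)
    return SpikeTrain("u", "RSC", np.sort(rng.uniform(0, duration, n)))


def _bump_unit(anchors, rate, duration, rng, gain, center, sd):
    base = rng.uniform(0, duration, rng.poisson(rate * duration))
    extra = rate * (gain - 1.0) * sd * np.sqrt(2 * np.pi)
    parts = [base]
    for a in anchors:
        k = rng.poisson(extra)
        parts.append(a + center + sd * rng.standard_normal(k))
    t = np.concatenate(parts)
    return SpikeTrain("u", "RSC", np.sort(t[(t >= 0) & (t < duration)]))


def modulation_type1(n_units: int = 400, n_shuffle: int = 200,
                     seed: int = 0, duration_s: float = 400.0) -> float:
    """Rejection rate of the modulation test on homogeneous Poisson units."""
    rng = np.random.default_rng(seed)
    anchors = np.sort(rng.uniform(5, duration_s - 5, 60))
    rej = 0
    for i in range(n_units):
        tr = _poisson_unit(rng.uniform(2.0, 6.0), duration_s, rng)
        r = test_modulation(tr, anchors, n_shuffle=n_shuffle, seed=seed + i)
        rej += r.modulated
    return rej / n_units


def modulation_power(n_units: int = 60, n_shuffle: int = 200, seed: int = 0,
                     duration_s: float = 400.0, gain: float = 2.0) -> float:
    """Power against broad pre-SWR rate bumps (6 Hz units, sigma 60 ms)."""
    rng = np.random.default_rng(seed)
    anchors = np.sort(rng.uniform(5, duration_s - 5, 55))
    rej = 0
    for i in range(n_units):
        tr = _bump_unit(anchors, 6.0, duration_s, rng, gain, -0.06, 0.06)
        r = test_modulation(tr, anchors, n_shuffle=n_shuffle,
                            seed=seed + 1000 + i)
        rej += r.modulated
    return rej / n_units


def _react_once(seed: int, react_strength: float) -> dict:
    n_ca1 = n_rsc = 8
    u = np.r_[np.ones(4), -np.ones(4)]
    tw = {"ca1": u.tolist(), "rsc": u.tolist()}
    task, _ = simulate_task_session(
        TaskConfig(n_trials=24,
                   units=tuple(SpatialUnitSpec(base_rate_hz=5.0)
                               for _ in range(n_rsc)),
                   n_ca1=n_ca1, ca1_rate_hz=(3.0, 6.0), template_weights=tw,
                   template_strength=0.8), seed=seed)
    run = run_epochs_from_trials(task.trials)
    ca1_t = sorted(task.trains_in("CA1"), key=lambda t: t.unit_id)
    rsc_t = sorted(task.trains_in("RSC"), key=lambda t: t.unit_id)
    C = build_template(_epoch_counts(ca1_t, run, 0.1)[0],
                       _epoch_counts(rsc_t, run, 0.1)[0])
    sleep, gt = simulate_sleep_session(
        SleepConfig(duration_s=300.0, n_ca1=n_ca1, n_rsc=n_rsc, n_delta=0,
                    n_spindles=0, ca1_rate_hz=(3.0, 6.0),
                    rsc_rate_hz=(4.0, 6.0), template_weights=tw,
                    react_strength=react_strength), seed=seed + 5000)
    nrem = gt.state_set("nrem")
    cm, tc = _epoch_counts(sorted(sleep.trains_in("CA1"),
                                  key=lambda t: t.unit_id), nrem, 0.1)
    rm, _ = _epoch_counts(sorted(sleep.trains_in("RSC"),
                                 key=lambda t: t.unit_id), nrem, 0.1)
    trace = reactivation_strength(C, cm, rm, tc)
    return peri_swr_reactivation(trace, np.array(gt.event_times["swr"]),
                                 seed=seed)


def reactivation_rejection_rate(n_seeds: int = 50, seed0: int = 0,
                                react_strength: float = 1.5) -> dict:
    rej = 0
    peak_at_zero = 0
    for k in range(n_seeds):
        res = _react_once(seed0 + k, react_strength)
        rej += res["p_lag0"] < 0.05
        peak_at_zero += abs(res["lags_s"][int(np.argmax(res["mean"]))]) <= 0.1
    return {"rejection_rate": rej / n_seeds,
            "peak_at_lag0_rate": peak_at_zero / n_seeds}


def _glm_session(seed: int, strength: float):
    # pre-SWR RSC burst (peak -50 ms, sigma 20 ms, 3x gain, event-to-event
    # gain jitter) driving CA1 through a 50-ms lagged rate coupling
    cfg = SleepConfig(duration_s=450.0, n_ca1=7, n_rsc=8, n_delta=0,
                      n_spindles=0, ca1_rate_hz=(3.0, 6.0),
                      rsc_rate_hz=(4.0, 7.0),
                      ca1_kernel=KernelSpec(0.030, 0.030, 2.0),
                      rsc_kernel=KernelSpec(-0.050, 0.020, 3.0),
                      kernel_gain_jitter_sd=0.6,
                      coupling=CouplingSpec("rsc2ca1", 0.050, strength))
    return simulate_sleep_session(cfg, seed=seed)


def glm_direction_rates(n_seeds: int = 30, seed0: int = 0,
                        strength: float = 1.3, n_shuffle: int = 25,
                        n_baseline: int = 25) -> dict:
    """Fraction of seeds with significant RSC->CA1 prediction per window."""
    sig = {(-100, 0): 0, (-200, -100): 0}
    gains = []
    for k in range(n_seeds):
        sess, gt = _glm_session(seed0 + k, strength)
        onsets = np.array(gt.event_times["swr"])
        rsc = sorted(sess.trains_in("RSC"), key=lambda t: t.unit_id)
        ca1 = sorted(sess.trains_in("CA1"), key=lambda t: t.unit_id)
        for w in sig:
            results = []
            for i, tgt in enumerate(ca1):
                try:
                    results.append(predict_cell_counts(
                        rsc, tgt, onsets, w, (0, 100), n_shuffle=n_shuffle,
                        n_baseline=n_baseline, seed=seed0 + 97 * k + i,
                        min_active_swrs=25))
                except ValidationError:
                    continue
            if results:
                cmp = compare_gains(results)
                if cmp["p"] < 0.05 and cmp["mean_real"] > cmp["mean_shuffled"]:
                    sig[w] += 1
                if w == (-100, 0):
                    gains.append(cmp["mean_real"])
    return {"sig_rate_minus100_0": sig[(-100, 0)] / n_seeds,
            "sig_rate_minus200_minus100": sig[(-200, -100)] / n_seeds,
            "mean_gain_minus100_0": float(np.mean(gains)) if gains else np.nan}


def glm_null_gain_median(n_units: int = 100, seed: int = 0) -> float:
    """Median cross-validated gain for pure-noise predictor/target pairs."""
    rng = np.random.default_rng(seed)
    gains = [_cv_gain(rng.poisson(0.5, (60, 6)).astype(float),
                      rng.poisson(0.5, 60).astype(float), 5, 25,
                      np.random.default_rng(seed + i))
             for i in range(n_units)]
    return float(np.median(gains))


def tracking_metrics(n_seeds: int = 50, noise_sd: float = 0.05,
                     seed0: int = 0) -> dict:
    tot = corr = cross = 0
    zero_ok = True
    for k in range(n_seeds):
        wfs, ident, fam = simulate_waveforms(10, 8, noise_sd=noise_sd,
                                             seed=seed0 + k)
        idm = ident["pre_sleep:post_sleep"]
        for m in match_units(wfs["pre_sleep"], wfs["post_sleep"]):
            if m.accepted:
                tot += 1
                if idm[m.pre_unit] == m.post_unit:
                    corr += 1
                elif fam[m.pre_unit] != fam[m.post_unit]:
                    cross += 1
    for k in range(5):
        wfs, ident, _ = simulate_waveforms(10, 8, noise_sd=0.0, drift_sd=0.0,
                                           seed=seed0 + 900 + k)
        idm = ident["pre_sleep:post_sleep"]
        ms = [m for m in match_units(wfs["pre_sleep"], wfs["post_sleep"])
              if m.accepted]
        if len(ms) != 18 or any(idm[m.pre_unit] != m.post_unit for m in ms):
            zero_ok = False
    return {"accuracy": corr / max(1, tot),
            "cross_family_accepts": cross,
            "zero_noise_exact": zero_ok,
            "n_accepted": tot}


def celltype_accuracy(n_seeds: int = 50, seed0: int = 0,
                      noise_sd: float = 0.05) -> float:
    ok = n = 0
    for k in range(n_seeds):
        wfs, _, fam = simulate_waveforms(20, 20, noise_sd=noise_sd,
                                         seed=seed0 + k)
        res = classify_rsc(wfs["post_sleep"])
        for uid, lab in res["labels"].items():
            n += 1
            ok += (lab == "wide") == (fam[uid] == "wide")
    return ok / n


def spatial_rates(n_seeds: int = 100, seed0: int = 0) -> dict:
    """Detection and false-positive rates of the stem/speed classifiers."""
    units = (
        SpatialUnitSpec(3.0, (0.0, 25.0), 5.0, 5.0, gain_left=1.0,
                        gain_right=0.2),              # splitter
        SpatialUnitSpec(3.0, (0.0, 15.0), 5.0, 4.0),  # location-related
        SpatialUnitSpec(4.0),                         # null
        SpatialUnitSpec(1.0, speed_slope=0.2),        # speed cell
    )
    hits = {"splitter": 0, "location": 0, "null_splitter": 0,
            "speed_tp": 0, "speed_fp": 0}
    for k in range(n_seeds):
        sess, _ = simulate_task_session(
            TaskConfig(n_trials=30, units=units), seed=seed0 + k)
        trains = sorted(sess.trains_in("RSC"), key=lambda t: t.unit_id)
        labs = []
        for tr in trains[:3]:
            sr = stem_trial_rates(tr, sess.trajectory, sess.trials)
            labs.append(classify_stem_cell(sr)["label"])
        hits["splitter"] += labs[0] == "splitter"
        hits["location"] += labs[1] == "location_related"
        hits["null_splitter"] += labs[2] == "splitter"
        hits["speed_tp"] += speed_score(trains[3], sess.trajectory,
                                        seed=seed0 + k)["speed_cell"]
        hits["speed_fp"] += speed_score(trains[2], sess.trajectory,
                                        seed=seed0 + k)["speed_cell"]
    return {k: v / n_seeds for k, v in hits.items()}
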