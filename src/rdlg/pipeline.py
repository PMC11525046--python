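"""End-to-end orchestration over a pre-sleep / task / post-sleep recording.

``run_pipeline`` executes sleep scoring, event detection, cell typing and
tracking, peri-SWR statistics, reactivation, GLM prediction and spatial
coding in dependency order, writing TSV/JSON outputs stamped with the
config hash and seed.  The pipeline is a pure function of (inputs, config,
seed): repeated runs are byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import detect as det
from . import io as rio
from .celltypes import classify_rsc, waveform_features
from .config import config_hash, default_config
from .core import Interval, IntervalSet, Session, ValidationError
from .glm import compare_gains, predict_cell_counts
from .psth import MOD_WINDOW_CA1, MOD_WINDOW_RSC, compute_psth, off_peri_swr, test_modulation
from .react import (_epoch_counts, build_template, pair_correlations,
                    peri_swr_reactivation, reactivation_strength,
                    run_epochs_from_trials)
from .sleep import score_sleep_session
from .spatial import classify_stem_cell, exclude_speed_cells, speed_score, stem_trial_rates
from .synth import (CouplingSpec, SleepConfig, SpatialUnitSpec, TaskConfig,
                    simulate_sleep_session, simulate_task_session,
                    simulate_waveforms)
from .tracking import match_units, track_three_phases

log = logging.getLogger("rdlg.pipeline")


def simulate_recording_set(cfg: dict, seed: int) -> dict:
    """Pre-sleep, task and post-sleep synthetic sessions with one unit set."""
    sim = cfg["simulate"]
    rng = np.random.default_rng(seed)
    n_ca1, n_rsc = sim["n_ca1"], sim["n_rsc"]
    u = rng.choice([1.0, -1.0], size=n_ca1)
    v = rng.choice([1.0, -1.0], size=n_rsc)
    tw = {"ca1": u.tolist(), "rsc": v.tolist()}

    pre, gt_pre = simulate_sleep_session(
        SleepConfig(duration_s=sim["sleep_duration_s"], n_ca1=n_ca1,
                    n_rsc=n_rsc, template_weights=tw,
                    off_after_swr_prob=sim["off_after_swr_prob"],
                    n_off_random=sim["n_off_random"]),
        seed=seed + 1, phase="pre_sleep")
    # task units: two splitters, two location-related, one speed cell, rest
    # untuned, so every downstream classifier has work to do
    specs = []
    for j in range(n_rsc):
        if j == 0:
            specs.append(SpatialUnitSpec(3.0, (0.0, 25.0), 5.0, 5.0,
                                         gain_left=1.0, gain_right=0.2))
        elif j == 1:
            specs.append(SpatialUnitSpec(3.0, (0.0, 5.0), 5.0, 5.0,
                                         gain_left=0.2, gain_right=1.0))
        elif j in (2, 3):
            specs.append(SpatialUnitSpec(3.0, (0.0, 15.0), 5.0, 4.0))
        elif j == 4:
            specs.append(SpatialUnitSpec(1.0, speed_slope=0.2))
        else:
            specs.append(SpatialUnitSpec(base_rate_hz=4.0))
    task, gt_task = simulate_task_session(
        TaskConfig(n_trials=sim["n_trials"], units=tuple(specs),
                   n_ca1=n_ca1, template_weights=tw,
                   template_strength=sim["template_strength"]),
        seed=seed + 2)
    post, gt_post = simulate_sleep_session(
        SleepConfig(duration_s=sim["sleep_duration_s"], n_ca1=n_ca1,
                    n_rsc=n_rsc, template_weights=tw,
                    react_strength=sim["react_strength"],
                    coupling=CouplingSpec(sim["coupling_direction"],
                                          sim["coupling_lag_s"],
                                          sim["coupling_strength"]),
                    off_after_swr_prob=sim["off_after_swr_prob"],
                    n_off_random=sim["n_off_random"]),
        seed=seed + 3, phase="post_sleep")
    waveforms, identity, families = simulate_waveforms(
        sim["n_wide"], sim["n_narrow"], sim["waveform_noise_sd"],
        seed=seed + 4)
    for sess, ph in ((pre, "pre_sleep"), (task, "task"), (post, "post_sleep")):
        sess.waveforms = waveforms[ph]
    return {"pre_sleep": (pre, gt_pre), "task": (task, gt_task),
            "post_sleep": (post, gt_post), "identity": identity,
            "families": families}


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _detect_sleep_events(sess: Session, hyp: IntervalSet, cfg: dict) -> dict:
    d = cfg["detect"]
    ca1 = sess.signals["CA1-lfp"]
    rsc = sess.signals["RSC-lfp"]
    nrem = IntervalSet([iv for iv in hyp if iv.kind == "nrem"], "nrem")
    rip = det.detect_ripples(ca1, tuple(d["ripple"]["band_hz"]),
                             d["ripple"]["thr_env"], d["ripple"]["thr_peak"],
                             tuple(d["ripple"]["dur_s"]),
                             d["ripple"]["merge_gap_s"],
                             d["ripple"]["smooth_sd_s"])
    sw = det.detect_sharp_waves(ca1, tuple(d["sharp_wave"]["band_hz"]),
                                d["sharp_wave"]["thr"],
                                tuple(d["sharp_wave"]["dur_s"]))
    swr = det.pair_swr(rip, sw, nrem)
    delta = det.detect_delta(rsc, d["delta"]["hi_hz"],
                             tuple(d["delta"]["dur_s"]), d["delta"]["peak_hi"],
                             d["delta"]["peak_lo"], d["delta"]["end_hi"],
                             d["delta"]["end_lo"])
    spin = det.detect_spindles(rsc, tuple(d["spindle"]["band_hz"]),
                               d["spindle"]["thr_env"],
                               d["spindle"]["thr_peak"],
                               d["spindle"]["min_dur_s"],
                               d["spindle"]["merge_gap_s"],
                               d["spindle"]["max_merged_s"],
                               d["spindle"]["smooth_sd_s"])
    off = det.detect_off_periods(sess.trains_in("RSC"), sess.span(),
                                 d["off"]["min_units"], d["off"]["min_gap_s"],
                                 d["off"]["merge_gap_s"], valid=nrem)
    return {"ripple": rip, "sharp_wave": sw, "swr": swr, "delta": delta,
            "spindle": spin, "off_period": off, "nrem": nrem}


def run_pipeline(cfg: dict = None, seed: int = None, out_dir="rdlg_out",
                 session_dirs: dict = None) -> dict:
    """Execute all stages; returns a report dict (also written as JSON)."""
    cfg = cfg or default_config()
    seed = cfg["seed"] if seed is None else seed
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = {"seed": seed, "config_hash": config_hash(cfg), "stages": {}}

    if session_dirs:
        sessions = {ph: (rio.read_session(p), None)
                    for ph, p in session_dirs.items()}
    else:
        sessions = simulate_recording_set(cfg, seed)

    # --- sleep scoring + event detection per sleep phase
    events = {}
    for ph in ("pre_sleep", "post_sleep"):
        sess, _gt = sessions[ph]
        sc = cfg["sleep_scoring"]
        hyp = score_sleep_session(sess.signals["CA1-lfp"],
                                  sess.signals["EMG"],
                                  sc["wake_threshold"], sc["ratio_threshold"])
        sess.hypnogram = hyp
        rio.write_hypnogram(hyp, out / f"{ph}_hypnogram.tsv")
        ev = _detect_sleep_events(sess, hyp, cfg)
        events[ph] = ev
        for kind, ivs in ev.items():
            rio.write_events(ivs, out / f"{ph}_{kind}.tsv")
        report["stages"][f"{ph}_detect"] = {k: len(v) for k, v in ev.items()}

    # --- cell typing and tracking
    post_sess = sessions["post_sleep"][0]
    rsc_types = classify_rsc(post_sess.waveforms)
    feats = [waveform_features(w) for w in post_sess.waveforms]
    _write_tsv(pd.DataFrame(
        [{"unit_id": f.unit_id, "trough_to_peak_ms": f.trough_to_peak_ms,
          "label": rsc_types["labels"].get(f.unit_id, "unclassified")}
         for f in feats]), out / "cell_types.tsv")
    pre_sess, task_sess = sessions["pre_sleep"][0], sessions["task"][0]
    matches = match_units(pre_sess.waveforms, post_sess.waveforms)
    _write_tsv(pd.DataFrame(
        [{"pre_unit": m.pre_unit, "post_unit": m.post_unit,
          "score": m.score, "corr": m.waveform_correlation,
          "wf_similarity": m.waveform_similarity,
          "dtw_scale": m.dtw_scale_factor,
          "dur_sim": m.local_sims[0], "ttp_amp_sim": m.local_sims[1],
          "p2t_amp_sim": m.local_sims[2],
          "accepted": m.accepted, "review": m.review_flag}
         for m in matches]), out / "matches.tsv")
    tracked = track_three_phases(pre_sess.waveforms, task_sess.waveforms,
                                 post_sess.waveforms)
    report["stages"]["tracking"] = {"n_matches": len(matches),
                                    "n_accepted": sum(m.accepted
                                                      for m in matches),
                                    "n_tracked_3": len(tracked)}

    # --- peri-SWR statistics (post sleep)
    pcfg = cfg["psth"]
    swr = events["post_sleep"]["swr"]
    onsets = swr.starts
    mod_rows = []
    psth_err = None
    try:
        trains = post_sess.trains
        pm = compute_psth(trains, onsets, pcfg["bin_s"],
                          tuple(pcfg["span_s"]), tuple(pcfg["baseline_s"]),
                          pcfg["smooth_sd_s"], pcfg["min_anchors"],
                          pcfg["min_sep_s"])
        np.save(out / "psth_z.npy", pm.z.astype(np.float64))
        for i, tr in enumerate(trains):
            win = MOD_WINDOW_CA1 if tr.region == "CA1" else MOD_WINDOW_RSC
            r = test_modulation(
                tr, onsets, win, cfg["pipeline"]["psth_n_shuffle"],
                pcfg["max_shift_s"], seed=seed + 31 * i)
            mod_rows.append({"unit_id": tr.unit_id, "region": tr.region,
                             "score": r.score, "p": r.p,
                             "modulated": r.modulated})
    except ValidationError as e:
        psth_err = str(e)
        log.warning("PSTH stage skipped: %s", e)
    _write_tsv(pd.DataFrame(mod_rows,
                            columns=["unit_id", "region", "score", "p",
                                     "modulated"]), out / "modulation.tsv")
    report["stages"]["psth"] = {"n_units": len(mod_rows),
                                "n_modulated": int(sum(r["modulated"]
                                                       for r in mod_rows)),
                                "skipped": psth_err}

    # --- OFF periods around SWRs
    try:
        off_res = off_peri_swr(events["post_sleep"]["off_period"], swr)
        report["stages"]["off_peri_swr"] = {
            "p": off_res["p"],
            "peak_lag_s": float(off_res["lags_s"][
                int(np.argmax(off_res["onset_prob"]))])}
    except ValidationError as e:
        report["stages"]["off_peri_swr"] = {"skipped": str(e)}

    # --- reactivation
    rcfg = cfg["react"]
    try:
        run = run_epochs_from_trials(task_sess.trials)
        ca1_t = sorted(task_sess.trains_in("CA1"), key=lambda t: t.unit_id)
        rsc_t = sorted(task_sess.trains_in("RSC"), key=lambda t: t.unit_id)
        C = build_template(_epoch_counts(ca1_t, run, rcfg["bin_s"])[0],
                           _epoch_counts(rsc_t, run, rcfg["bin_s"])[0],
                           rcfg["min_cells"])
        nrem_post = events["post_sleep"]["nrem"]
        ca1_s = sorted(post_sess.trains_in("CA1"), key=lambda t: t.unit_id)
        rsc_s = sorted(post_sess.trains_in("RSC"), key=lambda t: t.unit_id)
        cm, tc = _epoch_counts(ca1_s, nrem_post, rcfg["bin_s"])
        rm, _ = _epoch_counts(rsc_s, nrem_post, rcfg["bin_s"])
        trace = reactivation_strength(C, cm, rm, tc, rcfg["bin_s"])
        _write_tsv(pd.DataFrame({"t_s": trace.t, "R_z": trace.R}),
                   out / "reactivation.tsv")
        pairs = pair_correlations(
            ca1_t, rsc_t,
            {"task_run": run, "post_nrem": nrem_post},
            rcfg["pair_bin_s"], rcfg["n_surrogate"], rcfg["alpha"],
            sig_phase="task_run", seed=seed + 23)
        _write_tsv(pairs, out / "pair_correlations.tsv")
        pr = peri_swr_reactivation(trace, onsets, tuple(rcfg["window_s"]),
                                   rcfg["n_shuffle"], seed=seed + 7)
        _write_tsv(pd.DataFrame({"lag_s": pr["lags_s"], "mean_R": pr["mean"],
                                 "null_mean": pr["null_mean"]}),
                   out / "peri_swr_react.tsv")
        report["stages"]["react"] = {"p_lag0": pr["p_lag0"],
                                     "peak_lag_s": float(pr["lags_s"][
                                         int(np.argmax(pr["mean"]))])}
    except ValidationError as e:
        report["stages"]["react"] = {"skipped": str(e)}

    # --- GLM directional prediction
    gcfg = cfg["glm"]
    glm_rows = []
    for direction in ("rsc2ca1", "ca12rsc"):
        src = "RSC" if direction == "rsc2ca1" else "CA1"
        dst = "CA1" if direction == "rsc2ca1" else "RSC"
        preds = sorted(post_sess.trains_in(src), key=lambda t: t.unit_id)
        tgts = sorted(post_sess.trains_in(dst), key=lambda t: t.unit_id)
        for w in [tuple(x) for x in cfg["pipeline"]["glm_windows_ms"]]:
            results = []
            for i, tgt in enumerate(tgts):
                try:
                    results.append(predict_cell_counts(
                        preds, tgt, onsets, w,
                        tuple(gcfg["target_window_ms"]), gcfg["k_folds"],
                        cfg["pipeline"]["glm_n_shuffle"],
                        cfg["pipeline"]["glm_n_baseline"],
                        seed=seed + 13 * i, min_swrs=gcfg["min_swrs"],
                        min_cells=gcfg["min_cells"],
                        min_active_swrs=min(gcfg["min_active_swrs"],
                                            len(onsets) // 2)))
                except ValidationError:
                    continue
            row = {"direction": direction, "window_ms": str(w),
                   "n_cells": len(results)}
            if results:
                row.update({k: v for k, v in compare_gains(results).items()
                            if k != "n_cells"})
            glm_rows.append(row)
    _write_tsv(pd.DataFrame(glm_rows), out / "glm_results.tsv")
    report["stages"]["glm"] = {"n_rows": len(glm_rows)}

    # --- spatial coding
    scfg = cfg["spatial"]
    labels, fl = {}, {}
    for tr in sorted(task_sess.trains_in("RSC"), key=lambda t: t.unit_id):
        try:
            sr = stem_trial_rates(tr, task_sess.trajectory, task_sess.trials)
            labels[tr.unit_id] = classify_stem_cell(
                sr, scfg["anova_alpha"])["label"]
        except ValidationError:
            continue
        try:
            fl[tr.unit_id] = speed_score(
                tr, task_sess.trajectory,
                tuple(scfg["speed_range_cm_s"]), scfg["speed_bin_cm_s"],
                scfg["speed_n_shuffle"], scfg["speed_min_shift_s"],
                alpha=scfg["speed_alpha"], seed=seed + 17)["speed_cell"]
        except ValidationError:
            fl[tr.unit_id] = False
    final = exclude_speed_cells(labels, fl)
    _write_tsv(pd.DataFrame(
        [{"unit_id": u, "label": lab, "speed_cell": fl.get(u, False)}
         for u, lab in sorted(labels.items())]), out / "stem_labels.tsv")
    report["stages"]["spatial"] = {
        "n_splitter": sum(1 for v in final.values() if v == "splitter"),
        "n_location": sum(1 for v in final.values()
                          if v == "location_related")}

    # --- pre/post contrasts
    contrasts = pre_post_contrasts(sessions, events)
    _write_tsv(contrasts, out / "contrasts.tsv")

    (out / "report.json").write_text(
        json.dumps(report, sort_keys=True, indent=1, default=str))
    return report


def pre_post_contrasts(sessions: dict, events: dict) -> pd.DataFrame:
    """Pre- vs post-NREM incidence and event-property contrasts.

    Incidences (per NREM minute) of SWR, SWR-delta and SWR-spindle pairs,
    plus mean OFF duration, with post/pre ratios.  With several sessions
    these rows feed a paired signed-rank test; a single session yields the
    ratios with the test marked underpowered.
    """
    rows = []
    for metric in ("swr", "swr_delta", "swr_spindle", "off_duration"):
        vals = {}
        for ph in ("pre_sleep", "post_sleep"):
            ev = events[ph]
            nrem_min = ev["nrem"].total_duration_s() / 60.0
            if metric == "swr":
                v = len(ev["swr"]) / nrem_min if nrem_min else np.nan
            elif metric == "swr_delta":
                v = len(det.pair_sequences(ev["swr"], ev["delta"])) / nrem_min \
                    if nrem_min else np.nan
            elif metric == "swr_spindle":
                v = len(det.pair_sequences(ev["swr"], ev["spindle"])) \
                    / nrem_min if nrem_min else np.nan
            else:
                d = [iv.duration_s for iv in ev["off_period"]]
                v = float(np.mean(d)) if d else np.nan
            vals[ph] = v
        ratio = (vals["post_sleep"] / vals["pre_sleep"]
                 if vals["pre_sleep"] else np.nan)
        rows.append({"metric": metric, "pre": vals["pre_sleep"],
                     "post": vals["post_sleep"], "post_pre_ratio": ratio,
                     "note": "single session: paired test underpowered"})
    return pd.DataFrame(rows)
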