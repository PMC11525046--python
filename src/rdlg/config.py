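"""Pipeline configuration: every numeric constant, as one YAML document."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml

DEFAULTS = {
    "seed": 0,
    "sleep_scoring": {
        "wake_threshold": 0.5,       # SD of EMG_z
        "ratio_threshold": 2.0,      # theta/delta REM cutoff
        "min_dur_s": 30.0,           # shorter stages become "other"
        "gap_s": 5.0,                # boundary padding
        "window_samples": 256,
        "score_rate_hz": 125.0,
        "emg_band_hz": [20.0, 150.0],
        "smooth_sd_s": 0.050,
    },
    "detect": {
        "ripple": {"band_hz": [140.0, 250.0], "thr_env": 1.0, "thr_peak": 4.0,
                   "dur_s": [0.015, 0.200], "merge_gap_s": 0.020,
                   "smooth_sd_s": 0.010},
        "sharp_wave": {"band_hz": [5.0, 40.0], "thr": 2.5,
                       "dur_s": [0.020, 0.400]},
        "delta": {"hi_hz": 4.0, "dur_s": [0.150, 0.450], "peak_hi": 2.0,
                  "peak_lo": 1.0, "end_hi": 0.0, "end_lo": -1.5},
        "spindle": {"band_hz": [10.0, 20.0], "thr_env": 2.5, "thr_peak": 5.0,
                    "min_dur_s": 0.5, "merge_gap_s": 0.4, "max_merged_s": 3.0,
                    "smooth_sd_s": 0.025},
        "pair_window_s": [0.0, 0.250],
        "size_thresholds": [4.0, 6.0, 10.0],
        "off": {"min_units": 5, "min_gap_s": 0.100, "merge_gap_s": 0.005},
    },
    "psth": {
        "bin_s": 0.001, "span_s": [-1.0, 1.0], "baseline_s": [-1.0, -0.5],
        "smooth_sd_s": 0.020, "min_anchors": 50, "min_sep_s": 0.300,
        "n_shuffle": 1000, "max_shift_s": None, "alpha": 0.05,
        "window_rsc_s": [-0.200, 0.200], "window_ca1_s": [0.0, 0.100],
        "anova_windows_s": [[-0.100, 0.0], [0.0, 0.050], [0.200, 0.300]],
    },
    "react": {
        "pair_bin_s": 0.050, "bin_s": 0.100, "min_cells": 4,
        "n_shuffle": 100, "window_s": [-1.0, 1.0], "n_surrogate": 100,
        "alpha": 0.05,
    },
    "glm": {
        "windows_ms": [[-200, -100], [-100, 0], [0, 100], [100, 200],
                       [200, 300]],
        "target_window_ms": [0, 100], "k_folds": 5, "n_shuffle": 100,
        "n_baseline": 100, "min_swrs": 50, "min_cells": 5,
        "min_active_swrs": 50, "bin_s": 0.100,
    },
    "celltypes": {
        "ca1_ttp_ms": 0.425, "ca1_tau_rise_max_ms": 6.0,
        "n_clusters": 3, "n_pcs": 3,
        "acg_bin_ms": 0.5, "acg_span_ms": 50.0,
    },
    "tracking": {
        "w_local": 0.2, "w_global": 0.8, "corr_min": 0.95,
        "dur_sim_min": 0.7, "dtw_band_frac": 0.2, "ambiguity_margin": 0.02,
    },
    "simulate": {
        # three-phase synthetic recording used by `rdlg run` when no
        # session directories are given
        "sleep_duration_s": 400.0, "n_trials": 30,
        "n_ca1": 8, "n_rsc": 8,
        "template_strength": 0.8, "react_strength": 1.5,
        "coupling_direction": "rsc2ca1", "coupling_lag_s": 0.050,
        "coupling_strength": 1.0,
        "off_after_swr_prob": 0.5, "n_off_random": 10,
        "n_wide": 10, "n_narrow": 6, "waveform_noise_sd": 0.03,
    },
    "pipeline": {
        # reduced shuffle counts keep the default end-to-end run short;
        # stage-level functions default to the published counts
        "glm_n_shuffle": 20, "glm_n_baseline": 25, "psth_n_shuffle": 200,
        "glm_windows_ms": [[-100, 0], [0, 100]],
    },
    "spatial": {
        "bin_cm": 0.36, "speed_min_cm_s": 3.0, "min_spikes": 200,
        "field_rate_factor": 2.0, "field_min_bins": 40, "field_max_extent": 7,
        "speed_range_cm_s": [5.0, 35.0], "speed_bin_cm_s": 1.0,
        "speed_n_shuffle": 100, "speed_min_shift_s": 10.0,
        "speed_alpha": 0.01, "anova_alpha": 0.05,
        "stem_len_cm": 30.0, "n_subareas": 3,
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def default_config() -> dict:
    return json.loads(json.dumps(DEFAULTS))  # deep copy


def load_config(path=None, overrides: dict = None) -> dict:
    cfg = default_config()
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def save_config(cfg: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]
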