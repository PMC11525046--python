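"""Cross-validated GLM prediction of peri-SWR spiking and SWR occurrence.

Per predicted cell: ensemble spike counts of the other region in a predictor
window around each SWR onset predict the cell's count in a target window,
with a Poisson GLM (log link) under 5-fold cross-validation.  Prediction
error is the mean absolute difference between predicted and actual counts;
the baseline error permutes the actual test-fold counts; prediction gain is
mean baseline error / mean real error.  Control gains re-run the identical
pipeline after whole-set shuffles that pair each SWR's predictors with
another SWR's target.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression, PoissonRegressor

from .core import ValidationError
from .psth import eligible_anchors

log = logging.getLogger("rdlg.glm")

WINDOWS_MS = ((-200, -100), (-100, 0), (0, 100), (100, 200), (200, 300))


@dataclass
class PredictionResult:
    predicted_unit: str
    predictor_region: str
    predictor_window_ms: tuple
    target_window_ms: tuple
    gain_real: float
    gains_shuffled: np.ndarray
    p: float = np.nan
    n_events: int = 0
    flags: list = field(default_factory=list)


def window_counts(trains, anchors, window_ms) -> np.ndarray:
    """Events x units spike-count matrix in a window around each anchor."""
    lo, hi = window_ms[0] / 1000.0, window_ms[1] / 1000.0
    out = np.empty((len(anchors), len(trains)), dtype=np.int64)
    for u, tr in enumerate(trains):
        out[:, u] = (np.searchsorted(tr.times_s, np.asarray(anchors) + hi)
                     - np.searchsorted(tr.times_s, np.asarray(anchors) + lo))
    return out


def _stratified_folds(n: int, k: int, rng) -> list:
    """Random equal-size folds (remainder spread round-robin)."""
    idx = rng.permutation(n)
    return [np.sort(idx[i::k]) for i in range(k)]


def _fit_predict_poisson(Xtr, ytr, Xte, alpha: float = 1e-4,
                         flags=None) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        try:
            model = PoissonRegressor(alpha=alpha, max_iter=300)
            model.fit(Xtr, ytr)
        except Exception:
            # ridge-stabilized refit for degenerate folds
            if flags is not None:
                flags.append("ridge-stabilized")
            model = PoissonRegressor(alpha=1.0, max_iter=500)
            model.fit(Xtr, ytr)
    return model.predict(Xte)


def _cv_gain(X: np.ndarray, y: np.ndarray, k: int, n_baseline: int, rng,
             flags=None) -> float:
    """5-fold CV prediction gain = mean permuted-count error / mean real error."""
    folds = _stratified_folds(y.size, k, rng)
    real_err, base_err = [], []
    for te in folds:
        tr = np.setdiff1d(np.arange(y.size), te)
        pred = _fit_predict_poisson(X[tr], y[tr], X[te], flags=flags)
        real_err.append(np.mean(np.abs(pred - y[te])))
        be = [np.mean(np.abs(pred - rng.permutation(y[te])))
              for _ in range(n_baseline)]
        base_err.append(np.mean(be))
    mr, mb = float(np.mean(real_err)), float(np.mean(base_err))
    if mr == 0:
        return 1.0 if mb == 0 else np.inf
    return mb / mr


def predict_cell_counts(predictor_trains, target_train, swr_onsets,
                        predictor_window_ms, target_window_ms=(0, 100),
                        k: int = 5, n_shuffle: int = 100,
                        n_baseline: int = 100, seed: int = 0,
                        min_swrs: int = 50, min_cells: int = 5,
                        min_active_swrs: int = 50) -> PredictionResult:
    """Prediction gain for one target cell from the other region's ensemble.

    Eligibility follows the published rules: at least ``min_swrs`` SWRs
    separated by 300 ms, at least ``min_cells`` predictor cells, and a
    target that spiked in more than ``min_active_swrs`` SWRs.  Control gains
    come from ``n_shuffle`` whole-set event permutations run through the
    identical cross-validation pipeline.
    """
    rng = np.random.default_rng(seed)
    anchors = eligible_anchors(swr_onsets)
    if anchors.size < min_swrs:
        raise ValidationError(f"{anchors.size} eligible SWRs < {min_swrs}")
    if len(predictor_trains) < min_cells:
        raise ValidationError(
            f"{len(predictor_trains)} predictor cells < {min_cells}")
    X = window_counts(predictor_trains, anchors, predictor_window_ms).astype(float)
    y = window_counts([target_train], anchors, target_window_ms)[:, 0].astype(float)
    if np.count_nonzero(y) <= min_active_swrs:
        raise ValidationError(
            f"target spiked in {np.count_nonzero(y)} SWRs "
            f"<= {min_active_swrs} required")
    flags: list = []
    gain = _cv_gain(X, y, k, n_baseline, np.random.default_rng(seed + 1),
                    flags=flags)
    shuffled = np.empty(n_shuffle)
    for s in range(n_shuffle):
        perm = rng.permutation(y.size)
        shuffled[s] = _cv_gain(X, y[perm], k, n_baseline,
                               np.random.default_rng(seed + 2 + s))
    region = predictor_trains[0].region
    return PredictionResult(target_train.unit_id, region,
                            tuple(predictor_window_ms),
                            tuple(target_window_ms), float(gain), shuffled,
                            n_events=int(anchors.size), flags=flags)


def predict_swr_occurrence(rsc_trains, swr_onsets, span, bin_s: float = 0.100,
                           k: int = 5, n_shuffle: int = 100,
                           n_baseline: int = 100, seed: int = 0) -> PredictionResult:
    """Binomial GLM predicting SWR occurrence per 100-ms bin from RSC counts.

    Folds are stratified so every fold keeps both classes; the error is the
    mean absolute difference between predicted probability and the 0/1
    occurrence; shuffled gains permute the occurrence vector (same count of
    SWR bins) through the identical pipeline.
    """
    rng = np.random.default_rng(seed)
    from .core import bin_counts
    counts, edges = bin_counts(rsc_trains, bin_s, span)
    centers = edges[:-1] + bin_s / 2
    occ = np.zeros(centers.size, dtype=int)
    idx = np.floor((np.asarray(swr_onsets) - span.start_s) / bin_s).astype(int)
    occ[idx[(idx >= 0) & (idx < occ.size)]] = 1
    if occ.sum() == 0:
        raise ValidationError("no SWR falls inside the span")
    if occ.sum() == occ.size:
        raise ValidationError("occurrence vector has a single class")
    X = counts.astype(float)

    def cv_gain_binom(y, rng_fold):
        pos, neg = np.flatnonzero(y == 1), np.flatnonzero(y == 0)
        fpos = _stratified_folds(pos.size, k, rng_fold)
        fneg = _stratified_folds(neg.size, k, rng_fold)
        real_err, base_err = [], []
        for fp, fn in zip(fpos, fneg):
            te = np.sort(np.r_[pos[fp], neg[fn]])
            tr = np.setdiff1d(np.arange(y.size), te)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                model = LogisticRegression(C=100.0, max_iter=500)
                model.fit(X[tr], y[tr])
            p = model.predict_proba(X[te])[:, 1]
            real_err.append(np.mean(np.abs(p - y[te])))
            be = [np.mean(np.abs(p - rng_fold.permutation(y[te])))
                  for _ in range(n_baseline)]
            base_err.append(np.mean(be))
        mr, mb = float(np.mean(real_err)), float(np.mean(base_err))
        return (1.0 if mb == 0 else np.inf) if mr == 0 else mb / mr

    gain = cv_gain_binom(occ, np.random.default_rng(seed + 1))
    shuffled = np.empty(n_shuffle)
    for s in range(n_shuffle):
        y_s = rng.permutation(occ)
        shuffled[s] = cv_gain_binom(y_s, np.random.default_rng(seed + 2 + s))
    return PredictionResult("swr_occurrence", "RSC", (0, 0),
                            (int(bin_s * 1000), 0), float(gain), shuffled,
                            n_events=int(occ.sum()))


def compare_gains(results: list) -> dict:
    """Two-sided rank-sum of real vs shuffled gains across predicted cells."""
    real = np.array([r.gain_real for r in results])
    shuf = np.concatenate([r.gains_shuffled for r in results])
    stat, p = stats.ranksums(real, shuf)
    return {"stat": float(stat), "p": float(p),
            "mean_real": float(real.mean()), "mean_shuffled": float(shuf.mean()),
            "n_cells": len(results)}


def directional_summary(trains_by_region: dict, swr_onsets,
                        windows_ms=WINDOWS_MS, target_window_ms=(0, 100),
                        n_shuffle: int = 100, n_baseline: int = 100,
                        seed: int = 0, cell_classes: dict = None,
                        min_active_swrs: int = 50) -> dict:
    """Window x direction grid of ensemble prediction significance.

    For each direction (RSC ensemble predicting CA1 cells and vice versa)
    and each predictor window, prediction gains for every eligible target
    cell are compared with their whole-set-shuffle controls by a two-sided
    rank-sum test.  ``cell_classes`` optionally maps unit_id -> class to
    split target cells.
    """
    out = {}
    for direction in ("rsc2ca1", "ca12rsc"):
        src = "RSC" if direction == "rsc2ca1" else "CA1"
        dst = "CA1" if direction == "rsc2ca1" else "RSC"
        predictors = trains_by_region[src]
        targets = trains_by_region[dst]
        for w in windows_ms:
            results = []
            for i, tgt in enumerate(targets):
                try:
                    r = predict_cell_counts(predictors, tgt, swr_onsets, w,
                                            target_window_ms,
                                            n_shuffle=n_shuffle,
                                            n_baseline=n_baseline,
                                            seed=seed + 97 * i,
                                            min_active_swrs=min_active_swrs)
                except ValidationError as e:
                    log.info("skip %s @%s: %s", tgt.unit_id, w, e)
                    continue
                results.append(r)
            cell = {"results": results}
            if results:
                cell.update(compare_gains(results))
            if cell_classes:
                for cls in sorted(set(cell_classes.values())):
                    sub = [r for r in results
                           if cell_classes.get(r.predicted_unit) == cls]
                    if sub:
                        cell[f"by_class/{cls}"] = compare_gains(sub)
            out[(direction, w)] = cell
    return out
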