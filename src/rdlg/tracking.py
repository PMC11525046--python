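"""Cross-session single-unit matching from mean waveforms.

Candidate matches are restricted to units on the same channel.  Each
pre/post candidate pair gets a similarity score combining:

* local features — trough-to-peak duration, trough-to-peak amplitude and
  peak-to-trough amplitude, each compared as
  ``max(0, 1 - |pre - post| / pre)``;
* global features after dynamic-time-warping alignment of the normalized
  waveforms — waveform similarity (1 minus the maximum pointwise distance of
  the warped waveforms, normalized by peak-to-trough amplitude), Pearson
  correlation of the warped waveforms, and the DTW scale factor
  (len(original) / len(warped)) penalizing excessive warping.

``score = (1/5) * ||local||_2 + (4/5) * ||global||_2``.  A pre unit's best
candidate is accepted when the waveform correlation is >= 0.95 and the
duration similarity >= 0.7; a post unit claimed by several pre units keeps
only the largest score.  Ambiguities carry a review flag replacing manual
curation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .celltypes import normalized_waveform, waveform_features

log = logging.getLogger("rdlg.tracking")

W_LOCAL = 1.0 / 5.0
W_GLOBAL = 4.0 / 5.0
CORR_MIN = 0.95
DUR_SIM_MIN = 0.7
AMBIGUITY_MARGIN = 0.02


@dataclass
class MatchScore:
    pre_unit: str
    post_unit: str
    local_sims: tuple
    waveform_similarity: float
    waveform_correlation: float
    dtw_scale_factor: float
    score: float
    accepted: bool = False
    review_flag: str = ""


def _dtw_path(a: np.ndarray, b: np.ndarray, band_frac: float = 0.2) -> tuple:
    """Classic DTW alignment path with a Sakoe-Chiba band.

    Returns (ia, ib): index arrays of equal length tracing the optimal
    monotone alignment of ``a`` and ``b`` under squared distance.
    """
    n, m = a.size, b.size
    band = max(1, int(band_frac * max(n, m)))
    D = np.full((n + 1, m + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        j_lo = max(1, i - band)
        j_hi = min(m, i + band)
        ai = a[i - 1]
        for j in range(j_lo, j_hi + 1):
            cost = (ai - b[j - 1]) ** 2
            D[i, j] = cost + min(D[i - 1, j], D[i, j - 1], D[i - 1, j - 1])
    # backtrack
    ia, ib = [n - 1], [m - 1]
    i, j = n, m
    while i > 1 or j > 1:
        steps = ((D[i - 1, j - 1], i - 1, j - 1),
                 (D[i - 1, j], i - 1, j),
                 (D[i, j - 1], i, j - 1))
        _, i, j = min(steps, key=lambda s: s[0])
        ia.append(i - 1)
        ib.append(j - 1)
    return np.array(ia[::-1]), np.array(ib[::-1])


def _local_sim(pre: float, post: float) -> float:
    if pre == 0:
        return 1.0 if post == 0 else 0.0
    return max(0.0, 1.0 - abs(pre - post) / abs(pre))


def score_pair(pre, post, band_frac: float = 0.2) -> MatchScore:
    """Similarity score for one pre/post waveform pair."""
    f_pre, f_post = waveform_features(pre), waveform_features(post)
    local = (
        _local_sim(f_pre.trough_to_peak_ms, f_post.trough_to_peak_ms),
        _local_sim(f_pre.trough_to_peak_amp_uv, f_post.trough_to_peak_amp_uv),
        _local_sim(f_pre.peak_to_trough_amp_uv, f_post.peak_to_trough_amp_uv),
    )
    a, b = normalized_waveform(pre), normalized_waveform(post)
    # light smoothing: mean waveforms are smooth at the sample scale, so a
    # 3-point average strips residual estimation noise without moving the
    # trough/peak landmarks
    k = np.array([0.25, 0.5, 0.25])
    a = np.convolve(np.pad(a, 1, mode="edge"), k, mode="valid")
    b = np.convolve(np.pad(b, 1, mode="edge"), k, mode="valid")
    ia, ib = _dtw_path(a, b, band_frac)
    wa, wb = a[ia], b[ib]
    wf_sim = float(max(0.0, 1.0 - np.max(np.abs(wa - wb))))
    if np.std(wa) == 0 or np.std(wb) == 0:
        corr = 0.0
    else:
        corr = float(np.corrcoef(wa, wb)[0, 1])
    scale = a.size / wa.size
    glob = (wf_sim, max(corr, 0.0), scale)
    score = (W_LOCAL * float(np.linalg.norm(local))
             + W_GLOBAL * float(np.linalg.norm(glob)))
    return MatchScore(pre.unit_id, post.unit_id, local, wf_sim, corr,
                      float(scale), score)


def match_units(pre_waveforms, post_waveforms, band_frac: float = 0.2) -> list:
    """Greedy one-to-one matching of pre to post units on shared channels."""
    by_channel = {}
    for wf in post_waveforms:
        by_channel.setdefault(wf.channel, []).append(wf)

    candidates: list = []
    for pre in pre_waveforms:
        cands = by_channel.get(pre.channel, [])
        if not cands:
            log.info("pre unit %s: no candidates on channel %d",
                     pre.unit_id, pre.channel)
            continue
        scored = [score_pair(pre, post, band_frac) for post in cands]
        best = max(scored, key=lambda s: s.score)
        runner = sorted((s.score for s in scored), reverse=True)
        if len(runner) > 1 and runner[0] - runner[1] < AMBIGUITY_MARGIN:
            # the runner-up is within score noise: this is the case the
            # original workflow resolved by manual inspection, so the match
            # is exported for review instead of auto-accepted
            best.review_flag = (f"ambiguous: runner-up within "
                                f"{AMBIGUITY_MARGIN}")
        elif best.waveform_correlation >= CORR_MIN \
                and best.local_sims[0] >= DUR_SIM_MIN:
            best.accepted = True
        candidates.append(best)

    # a post unit claimed by several pre units keeps the largest score
    by_post = {}
    for m in candidates:
        if not m.accepted:
            continue
        cur = by_post.get(m.post_unit)
        if cur is None or m.score > cur.score:
            if cur is not None:
                cur.accepted = False
                cur.review_flag = (cur.review_flag + "; " if cur.review_flag
                                   else "") + "lost post unit to higher score"
                m.review_flag = (m.review_flag + "; " if m.review_flag
                                 else "") + "contested post unit"
            by_post[m.post_unit] = m
    return candidates


@dataclass
class TrackedUnit:
    post_unit: str
    pre_unit: str
    task_unit: str
    flags: list = field(default_factory=list)


def track_three_phases(pre_waveforms, task_waveforms, post_waveforms,
                       band_frac: float = 0.2,
                       check_consistency: bool = True) -> list:
    """Units tracked through pre-sleep, task and post-sleep.

    Pre/post and task/post matchings are intersected on the post unit; only
    units present in all three phases survive.  With ``check_consistency``
    the pre/task matching closes the triangle: a post unit whose pre and
    task partners do not match each other is excluded as a conflicting
    chain.  Review flags of the contributing matches carry forward.
    """
    pre_post = {m.post_unit: m for m in
                match_units(pre_waveforms, post_waveforms, band_frac)
                if m.accepted}
    task_post = {m.post_unit: m for m in
                 match_units(task_waveforms, post_waveforms, band_frac)
                 if m.accepted}
    pre_task = {}
    if check_consistency:
        pre_task = {m.pre_unit: m.post_unit for m in
                    match_units(pre_waveforms, task_waveforms, band_frac)
                    if m.accepted}
    out = []
    for post_id in sorted(set(pre_post) & set(task_post)):
        a, b = pre_post[post_id], task_post[post_id]
        flags = [f for f in (a.review_flag, b.review_flag) if f]
        if check_consistency and a.pre_unit in pre_task \
                and pre_task[a.pre_unit] != b.pre_unit:
            log.info("post unit %s excluded: pre %s and task %s chains "
                     "disagree", post_id, a.pre_unit, b.pre_unit)
            continue
        out.append(TrackedUnit(post_id, a.pre_unit, b.pre_unit, flags))
    return out
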