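import numpy as np
import pytest
from scipy import signal as sps

from rdlg.core import Interval, IntervalSet, SampledSignal, SpikeTrain, ValidationError
from rdlg.sleep import (StateScoreTrace, compute_emg_z, score_sleep_session,
                        score_states, state_rate_ratio, theta_delta_ratio)

FS = 1250.0


def _sig(x, t0=0.0):
    return SampledSignal(np.asarray(x, dtype=float), FS, t0)


class TestEmgZ:
    def test_constant_signal_gives_zeros(self):
        z = compute_emg_z(_sig(np.full(5000, 3.7)))
        assert np.allclose(z, 0.0)

    def test_higher_variance_half_scores_higher(self):
        rng = np.random.default_rng(0)
        x = np.r_[rng.standard_normal(12500),
                  np.sqrt(10) * rng.standard_normal(12500)]
        z = compute_emg_z(_sig(x))
        assert z[:12500].mean() < z[12500:].mean()

    def test_too_short_signal(self):
        with pytest.raises(ValidationError):
            compute_emg_z(_sig(np.zeros(5)))


class TestThetaDeltaRatio:
    def _tone(self, f, n=int(60 * FS), amp=1.0, floor=0.05, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(n) / FS
        return amp * np.sin(2 * np.pi * f * t) + floor * rng.standard_normal(n)

    def test_theta_tone_high_ratio(self):
        _, r = theta_delta_ratio(_sig(self._tone(8.0)))
        assert np.median(r) > 2

    def test_delta_tone_low_ratio(self):
        _, r = theta_delta_ratio(_sig(self._tone(2.0)))
        assert np.median(r) < 2

    def test_equal_tones_ratio_near_one(self):
        # oracle: a long Welch periodogram over the whole signal
        x = self._tone(2.0) + self._tone(8.0, seed=1)
        _, r = theta_delta_ratio(_sig(x))
        f, p = sps.welch(sps.decimate(x, 10, ftype="fir"), fs=125.0,
                         nperseg=4096)
        th = np.trapezoid(p[(f >= 6) & (f <= 10)], f[(f >= 6) & (f <= 10)])
        de = np.trapezoid(p[(f >= 1) & (f <= 4)], f[(f >= 1) & (f <= 4)])
        assert np.isclose(np.median(r), th / de, rtol=0.25)
        assert 0.7 < np.median(r) < 1.4

    def test_window_longer_than_signal(self):
        with pytest.raises(ValidationError):
            theta_delta_ratio(_sig(np.zeros(600)), window_samples=256)


class TestScoreStates:
    def _trace(self, emg, ratio, thr=0.5):
        t = np.arange(len(emg)) + 0.5
        return StateScoreTrace(t, np.asarray(ratio, float),
                               np.asarray(emg, float), thr)

    def test_all_wake(self):
        hyp = score_states(self._trace([2.0] * 120, [1.0] * 120))
        assert len(hyp) == 1 and hyp[0].kind == "wake"

    def test_immobile_high_ratio_is_rem(self):
        hyp = score_states(self._trace([0.0] * 60, [3.0] * 60))
        assert [iv.kind for iv in hyp] == ["rem"]

    def test_short_stage_becomes_other(self):
        emg = [2.0] * 60 + [0.0] * 20 + [2.0] * 60
        ratio = [1.0] * 140
        hyp = score_states(self._trace(emg, ratio))
        kinds = [iv.kind for iv in hyp]
        assert "nrem" not in kinds and "other" in kinds

    def test_boundary_padding(self):
        emg = [2.0] * 60 + [0.0] * 120
        ratio = [1.0] * 180
        hyp = score_states(self._trace(emg, ratio))
        kinds = [iv.kind for iv in hyp]
        assert kinds == ["wake", "other", "nrem"]
        other = hyp[1]
        assert np.isclose(other.duration_s, 5.0)

    def test_tiles_session_no_gaps(self):
        rng = np.random.default_rng(2)
        emg = rng.choice([0.0, 2.0], size=300, p=[0.7, 0.3])
        ratio = rng.uniform(0.5, 3.5, size=300)
        hyp = score_states(self._trace(emg, ratio), span=(0.0, 300.0))
        assert hyp[0].start_s == 0.0 and hyp[-1].end_s == 300.0
        for a, b in zip(hyp, hyp.intervals[1:]):
            assert np.isclose(a.end_s, b.start_s)

    def test_all_nan_errors(self):
        with pytest.raises(ValidationError):
            score_states(self._trace([np.nan] * 40, [np.nan] * 40))


class TestStateRateRatio:
    HYP = IntervalSet([Interval(0, 100, "nrem"), Interval(100, 200, "wake")])

    def _train(self, nrem_rate, wake_rate):
        rng = np.random.default_rng(1)
        a = np.sort(rng.uniform(0, 100, int(nrem_rate * 100)))
        b = np.sort(rng.uniform(100, 200, int(wake_rate * 100)))
        return SpikeTrain("u", "RSC", np.r_[a, b])

    def test_symmetry_zero(self):
        assert abs(state_rate_ratio(self._train(2, 2), self.HYP)) < 1e-12

    def test_printed_formula(self):
        # (3 - 1) / (3 + 1) = 0.5
        assert np.isclose(state_rate_ratio(self._train(3, 1), self.HYP), 0.5)

    def test_wake_only_unit_is_minus_one(self):
        assert state_rate_ratio(self._train(0, 4), self.HYP) == -1.0

    def test_silent_unit_undefined(self):
        tr = SpikeTrain("u", "RSC", np.empty(0))
        assert np.isnan(state_rate_ratio(tr, self.HYP))

    def test_bounded(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            v = state_rate_ratio(
                self._train(rng.uniform(0, 5), rng.uniform(0, 5)), self.HYP)
            assert np.isnan(v) or -1.0 <= v <= 1.0


def test_end_to_end_scoring_matches_ground_truth(sleep_session):
    sess, gt = sleep_session
    hyp = score_sleep_session(sess.signals["CA1-lfp"], sess.signals["EMG"])
    edges = sorted({s for _, s, e in gt.states} | {e for _, s, e in gt.states})
    edges = edges[1:-1]
    tgrid = np.arange(0.5, 600, 1.0)
    truth = np.array(["other"] * tgrid.size, dtype=object)
    for st, s, e in gt.states:
        truth[(tgrid >= s) & (tgrid < e)] = st
    pred = np.array(["other"] * tgrid.size, dtype=object)
    for iv in hyp:
        pred[(tgrid >= iv.start_s) & (tgrid < iv.end_s)] = iv.kind
    keep = np.array([all(abs(t - ed) > 5 for ed in edges) for t in tgrid])
    assert np.mean(truth[keep] == pred[keep]) >= 0.95
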