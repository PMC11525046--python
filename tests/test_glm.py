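import numpy as np
import pytest

from rdlg.core import Interval, SpikeTrain, ValidationError
from rdlg.glm import (_cv_gain, compare_gains, predict_cell_counts,
                      predict_swr_occurrence, window_counts)
from rdlg.synth import CouplingSpec, KernelSpec, SleepConfig, simulate_sleep_session


def coupled_session(seed, strength):
    cfg = SleepConfig(duration_s=500, n_ca1=7, n_rsc=8, n_delta=0,
                      n_spindles=0, ca1_rate_hz=(3.0, 6.0),
                      rsc_rate_hz=(4.0, 7.0),
                      ca1_kernel=KernelSpec(0.030, 0.030, 2.0),
                      rsc_kernel=KernelSpec(-0.060, 0.025, 2.5),
                      coupling=CouplingSpec("rsc2ca1", 0.050, strength))
    return simulate_sleep_session(cfg, seed=seed)


class TestWindowCounts:
    def test_counts_match_searchsorted_oracle(self):
        rng = np.random.default_rng(0)
        tr = SpikeTrain("u", "RSC", np.sort(rng.uniform(0, 100, 500)))
        anchors = np.sort(rng.uniform(5, 95, 30))
        X = window_counts([tr], anchors, (-100, 0))
        for i, a in enumerate(anchors):
            want = np.sum((tr.times_s >= a - 0.1) & (tr.times_s < a))
            assert X[i, 0] == want


class TestCvGain:
    def test_null_gain_near_one(self):
        rng = np.random.default_rng(1)
        gains = [_cv_gain(rng.poisson(0.5, (60, 6)).astype(float),
                          rng.poisson(0.5, 60).astype(float), 5, 25,
                          np.random.default_rng(i)) for i in range(30)]
        assert 0.95 <= np.median(gains) <= 1.05

    def test_informative_predictor_gain_above_one(self):
        rng = np.random.default_rng(2)
        X = rng.poisson(2.0, (100, 5)).astype(float)
        lam = np.exp(0.3 * (X.sum(axis=1) - X.sum(axis=1).mean()))
        y = rng.poisson(lam).astype(float)
        gain = _cv_gain(X, y, 5, 50, np.random.default_rng(3))
        assert gain > 1.05

    def test_degenerate_all_zero_target(self):
        rng = np.random.default_rng(4)
        X = rng.poisson(1.0, (50, 5)).astype(float)
        y = np.zeros(50)
        gain = _cv_gain(X, y, 5, 10, np.random.default_rng(5))
        assert gain == 1.0


class TestPredictCellCounts:
    def test_eligibility_rules(self):
        sess, gt = coupled_session(0, 0.0)
        onsets = np.array(gt.event_times["swr"])
        rsc = sess.trains_in("RSC")
        ca1 = sess.trains_in("CA1")
        with pytest.raises(ValidationError, match="predictor cells"):
            predict_cell_counts(rsc[:3], ca1[0], onsets, (-100, 0))
        with pytest.raises(ValidationError, match="eligible SWRs"):
            predict_cell_counts(rsc, ca1[0], onsets[:20], (-100, 0))
        mute = SpikeTrain("mute", "CA1", np.array([1.0]))
        with pytest.raises(ValidationError, match="spiked in"):
            predict_cell_counts(rsc, mute, onsets, (-100, 0))

    def test_reproducible_under_seed(self):
        sess, gt = coupled_session(1, 1.0)
        onsets = np.array(gt.event_times["swr"])
        rsc = sorted(sess.trains_in("RSC"), key=lambda t: t.unit_id)
        tgt = sorted(sess.trains_in("CA1"), key=lambda t: t.unit_id)[0]
        a = predict_cell_counts(rsc, tgt, onsets, (-100, 0), n_shuffle=5,
                                n_baseline=10, seed=9, min_active_swrs=20)
        b = predict_cell_counts(rsc, tgt, onsets, (-100, 0), n_shuffle=5,
                                n_baseline=10, seed=9, min_active_swrs=20)
        assert a.gain_real == b.gain_real
        np.testing.assert_array_equal(a.gains_shuffled, b.gains_shuffled)

    def test_coupling_detected_in_leading_window(self):
        sess, gt = coupled_session(2, 1.0)
        onsets = np.array(gt.event_times["swr"])
        rsc = sorted(sess.trains_in("RSC"), key=lambda t: t.unit_id)
        results = []
        for i, tgt in enumerate(sorted(sess.trains_in("CA1"),
                                       key=lambda t: t.unit_id)):
            try:
                results.append(predict_cell_counts(
                    rsc, tgt, onsets, (-100, 0), n_shuffle=25,
                    n_baseline=25, seed=11 + i, min_active_swrs=25))
            except ValidationError:
                continue
        cmp = compare_gains(results)
        assert cmp["mean_real"] > cmp["mean_shuffled"]
        assert cmp["p"] < 0.05


class TestPredictOccurrence:
    def test_all_zero_occurrence_errors(self):
        rng = np.random.default_rng(6)
        trains = [SpikeTrain(f"r{i}", "RSC",
                             np.sort(rng.uniform(0, 50, 200)))
                  for i in range(6)]
        with pytest.raises(ValidationError):
            predict_swr_occurrence(trains, [], Interval(0, 50))

    def test_rate_coupled_occurrence_gain(self):
        rng = np.random.default_rng(7)
        # SWR probability raised in bins where ensemble count is high
        n_bins, n_units = 1200, 6
        counts = rng.poisson(1.0, (n_bins, n_units))
        drive = counts.sum(axis=1)
        p = 0.01 + 0.10 * (drive > np.percentile(drive, 85))
        occ = rng.uniform(size=n_bins) < p
        trains = []
        for u in range(n_units):
            ts = []
            for b in range(n_bins):
                ts.extend(b * 0.1 + rng.uniform(0, 0.1, counts[b, u]))
            trains.append(SpikeTrain(f"r{u}", "RSC", np.sort(ts)))
        onsets = (np.flatnonzero(occ) + 0.5) * 0.1
        res = predict_swr_occurrence(trains, onsets, Interval(0, 120),
                                     n_shuffle=10, n_baseline=10, seed=8)
        assert res.gain_real > np.percentile(res.gains_shuffled, 95)


class TestDirectionalSummary:
    def test_single_window_grid(self):
        from rdlg.glm import directional_summary
        sess, gt = coupled_session(3, 1.0)
        onsets = np.array(gt.event_times["swr"])
        trains = {"RSC": sorted(sess.trains_in("RSC"),
                                key=lambda t: t.unit_id),
                  "CA1": sorted(sess.trains_in("CA1"),
                                key=lambda t: t.unit_id)}
        grid = directional_summary(trains, onsets, windows_ms=((-100, 0),),
                                   n_shuffle=3, n_baseline=5, seed=1,
                                   min_active_swrs=25)
        assert set(grid) == {("rsc2ca1", (-100, 0)), ("ca12rsc", (-100, 0))}
        cell = grid[("rsc2ca1", (-100, 0))]
        assert cell["results"] and "p" in cell
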