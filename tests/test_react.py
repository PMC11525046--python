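import numpy as np
import pytest

from conftest import poisson_train
from rdlg.core import Interval, IntervalSet, SpikeTrain, ValidationError
from rdlg.react import (ReactivationTrace, _epoch_counts, build_template,
                        pair_correlations, peri_swr_reactivation,
                        reactivation_strength, run_epochs_from_trials)


class TestPairCorrelations:
    def _epochs(self, dur=100.0):
        return {"task_run": IntervalSet([Interval(0, dur)])}

    def test_identical_counts_r_one(self):
        rng = np.random.default_rng(0)
        times = np.sort(rng.uniform(0, 100, 400))
        a = SpikeTrain("c", "CA1", times)
        b = SpikeTrain("r", "RSC", times.copy())
        df = pair_correlations([a], [b], self._epochs())
        assert np.isclose(df["r_task_run"].iloc[0], 1.0)
        assert df["class"].iloc[0] == "positive"

    def test_silent_unit_unreliable(self):
        a = SpikeTrain("c", "CA1", np.sort(
            np.random.default_rng(1).uniform(0, 100, 200)))
        b = SpikeTrain("r", "RSC", np.empty(0))
        df = pair_correlations([a], [b], self._epochs())
        assert df["class"].iloc[0] == "unreliable"
        assert np.isnan(df["r_task_run"].iloc[0])

    def test_independent_pairs_rarely_significant(self):
        rng = np.random.default_rng(2)
        ca1 = [poisson_train(4.0, 200.0, rng, f"c{i}", "CA1")
               for i in range(4)]
        rsc = [poisson_train(4.0, 200.0, rng, f"r{j}", "RSC")
               for j in range(4)]
        df = pair_correlations(ca1, rsc,
                               {"task_run": IntervalSet([Interval(0, 200)])},
                               seed=5)
        frac_sig = np.mean(df["class"] != "unreliable")
        assert frac_sig <= 0.25  # 16 pairs at alpha 0.05


class TestBuildTemplate:
    def test_covarying_pair_entry_near_one(self):
        rng = np.random.default_rng(3)
        shared = rng.poisson(3.0, size=2000)
        ca1 = np.c_[shared, rng.poisson(3.0, size=(2000, 3))]
        rsc = np.c_[shared, rng.poisson(3.0, size=(2000, 3))]
        C = build_template(ca1, rsc)
        assert C[0, 0] > 0.95
        off = np.abs(C).sum() - np.abs(C[0, 0])
        assert off / (C.size - 1) < 0.05

    def test_independent_noise_small_entries(self):
        rng = np.random.default_rng(4)
        C = build_template(rng.poisson(2.0, size=(10000, 5)),
                           rng.poisson(2.0, size=(10000, 5)))
        assert np.abs(C).max() < 0.05

    def test_fewer_than_four_cells_rejected(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValidationError, match="at least 4"):
            build_template(rng.poisson(2.0, size=(100, 3)),
                           rng.poisson(2.0, size=(100, 6)))

    def test_silent_cell_excluded_then_checked(self):
        rng = np.random.default_rng(6)
        ca1 = rng.poisson(2.0, size=(100, 4)).astype(float)
        ca1[:, 0] = 0.0
        with pytest.raises(ValidationError):
            build_template(ca1, rng.poisson(2.0, size=(100, 4)))

    def test_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(7)
        ca1 = rng.poisson(3.0, size=(500, 4)).astype(float)
        rsc = rng.poisson(3.0, size=(500, 4)).astype(float)
        C1 = build_template(ca1, rsc)
        C2 = build_template(ca1 * 7.0 + 2.0, rsc)
        np.testing.assert_allclose(C1, C2, atol=1e-12)


class TestReactivationStrength:
    def test_printed_arithmetic(self):
        # z_CA1=(1,2), z_RSC=(3,4), C=I -> raw R = 1*3 + 2*4 = 11
        za = np.array([1.0, 2.0])
        zb = np.array([3.0, 4.0])
        raw = za @ np.eye(2) @ zb
        assert raw == 11.0

    def test_zero_template_zero_raw(self):
        rng = np.random.default_rng(8)
        C = np.zeros((4, 4))
        tr = reactivation_strength(C, rng.poisson(2, (50, 4)),
                                   rng.poisson(2, (50, 4)), np.arange(50) * 0.1)
        assert np.allclose(tr.R_raw, 0.0)

    def test_dimension_mismatch_errors(self):
        with pytest.raises(ValidationError):
            reactivation_strength(np.zeros((4, 4)), np.zeros((10, 5)),
                                  np.zeros((10, 4)), np.arange(10) * 0.1)

    def test_zscored_over_epoch(self):
        rng = np.random.default_rng(9)
        C = rng.standard_normal((4, 4)) * 0.1
        tr = reactivation_strength(C, rng.poisson(3, (500, 4)),
                                   rng.poisson(3, (500, 4)),
                                   np.arange(500) * 0.1)
        assert abs(tr.R.mean()) < 1e-9 and np.isclose(tr.R.std(), 1.0)


class TestPeriSwr:
    def _trace(self, n=3000, seed=0):
        rng = np.random.default_rng(seed)
        R = rng.standard_normal(n)
        return ReactivationTrace(np.zeros((4, 4)), np.arange(n) * 0.1, R, R,
                                 0.1, 4, 4), rng

    def test_no_swr_errors(self):
        tr, _ = self._trace()
        with pytest.raises(ValidationError):
            peri_swr_reactivation(tr, [])

    def test_injected_elevation_detected_at_lag0(self):
        tr, rng = self._trace(seed=1)
        onsets = np.sort(rng.uniform(10, 280, 60))
        idx = np.round(onsets / 0.1).astype(int)
        tr.R[idx] += 1.5
        res = peri_swr_reactivation(tr, onsets, seed=2)
        assert res["p_lag0"] < 0.05
        assert abs(res["lags_s"][np.argmax(res["mean"])]) <= 0.1

    def test_null_not_rejected_mostly(self):
        rej = 0
        for s in range(10):
            tr, rng = self._trace(seed=100 + s)
            onsets = np.sort(rng.uniform(10, 280, 60))
            res = peri_swr_reactivation(tr, onsets, seed=s)
            rej += res["p_lag0"] < 0.05
        assert rej <= 2

    def test_expected_R_zero_under_independence(self):
        rng = np.random.default_rng(11)
        C = build_template(rng.poisson(3, (600, 5)), rng.poisson(3, (600, 5)))
        tr = reactivation_strength(C, rng.poisson(3, (2000, 5)),
                                   rng.poisson(3, (2000, 5)),
                                   np.arange(2000) * 0.1)
        se = tr.R_raw.std() / np.sqrt(tr.R_raw.size)
        assert abs(tr.R_raw.mean()) < 3 * se + 1e-9


def test_run_epochs_skip_incorrect_trials(task_session):
    sess, _ = task_session
    run = run_epochs_from_trials(sess.trials)
    n_correct = int(sess.trials["correct"].sum())
    assert 0 < len(run) <= n_correct
    counts, _ = _epoch_counts(sess.trains[:2], run, 0.1)
    assert counts.shape[1] == 2
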