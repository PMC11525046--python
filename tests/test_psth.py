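import numpy as np
import pytest

from conftest import bump_train, poisson_train
from rdlg.core import Interval, IntervalSet, SpikeTrain, ValidationError
from rdlg.psth import (compute_psth, cross_correlogram, eligible_anchors,
                       off_peri_swr, psth_by_size)
from rdlg.psth import test_modulation as modulation_test

DUR = 400.0
RNG = np.random.default_rng(123)
ANCHORS = np.sort(RNG.uniform(5, DUR - 5, 60))


class TestEligibleAnchors:
    def test_greedy_separation(self):
        got = eligible_anchors([0.0, 0.1, 0.35, 0.5, 1.0], 0.3)
        assert got.tolist() == [0.0, 0.35, 1.0]


class TestComputePsth:
    def test_homogeneous_unit_flat(self):
        tr = poisson_train(4.0, DUR, np.random.default_rng(1))
        pm = compute_psth([tr], ANCHORS)
        assert np.abs(pm.z).max() < 4.0

    def test_bump_recovered_at_its_lag(self):
        tr = bump_train(ANCHORS, 6.0, DUR, np.random.default_rng(2),
                        gain=4.0, center=-0.06, sd=0.03)
        pm = compute_psth([tr], ANCHORS)
        peak_lag = pm.lags_s[np.argmax(pm.z[0])]
        assert abs(peak_lag - (-0.06)) <= 0.015

    def test_too_few_anchors_rejected(self):
        tr = poisson_train(4.0, DUR, np.random.default_rng(3))
        with pytest.raises(ValidationError, match="eligible anchors"):
            compute_psth([tr], ANCHORS[:49])

    def test_baseline_window_mean_near_zero(self):
        trs = [poisson_train(5.0, DUR, np.random.default_rng(4 + i), f"u{i}")
               for i in range(3)]
        anchors = np.sort(np.random.default_rng(9).uniform(5, DUR - 5, 500))
        pm = compute_psth(trs, anchors, min_sep_s=0.0, min_anchors=50)
        bl = (pm.lags_s >= -1.0) & (pm.lags_s < -0.5)
        assert np.abs(pm.z[:, bl].mean(axis=1)).max() < 0.05


class TestModulation:
    def test_deterministic_under_seed(self):
        tr = poisson_train(4.0, DUR, np.random.default_rng(5))
        a = modulation_test(tr, ANCHORS, n_shuffle=100, seed=7)
        b = modulation_test(tr, ANCHORS, n_shuffle=100, seed=7)
        assert a.p == b.p and a.score == b.score
        np.testing.assert_array_equal(a.null_scores, b.null_scores)

    def test_zero_spike_unit_flagged(self):
        tr = SpikeTrain("mute", "RSC", np.empty(0))
        r = modulation_test(tr, ANCHORS)
        assert not r.modulated and r.flagged

    def test_modulated_unit_detected(self):
        tr = bump_train(ANCHORS, 6.0, DUR, np.random.default_rng(6),
                        gain=3.0, center=-0.06, sd=0.06)
        r = modulation_test(tr, ANCHORS, n_shuffle=200, seed=1)
        assert r.modulated and r.p < 0.05

    def test_type_one_error_near_alpha(self):
        rej = 0
        n = 80
        for i in range(n):
            tr = poisson_train(4.0, DUR, np.random.default_rng(100 + i))
            r = modulation_test(tr, ANCHORS, n_shuffle=100, seed=i)
            rej += r.modulated
        # binomial(80, 0.05) 99% band
        assert rej <= 11


class TestCrossCorrelogram:
    def test_fixed_shift_dominant_bin(self):
        a = np.sort(np.random.default_rng(0).uniform(0, 100, 200))
        res = cross_correlogram(a, a + 0.06, bin_s=0.01, span=(-0.5, 0.5))
        assert abs(res["lags_s"][np.argmax(res["counts"])] - 0.06) < 0.011

    def test_empty_series_zero_histogram(self):
        res = cross_correlogram([], [1.0, 2.0], bin_s=0.01)
        assert res["counts"].sum() == 0

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        a = np.sort(rng.uniform(0, 50, 100))
        b = np.sort(rng.uniform(0, 50, 120))
        ab = cross_correlogram(a, b, bin_s=0.02, span=(-0.4, 0.4))
        ba = cross_correlogram(b, a, bin_s=0.02, span=(-0.4, 0.4))
        np.testing.assert_array_equal(ab["counts"], ba["counts"][::-1])

    def test_independent_series_inside_null_band(self):
        rng = np.random.default_rng(2)
        a = np.sort(rng.uniform(0, 200, 300))
        b = np.sort(rng.uniform(0, 200, 300))
        res = cross_correlogram(a, b, bin_s=0.05, span=(-0.5, 0.5),
                                n_null=200, seed=3)
        frac_out = np.mean((res["counts"] > res["null_hi"])
                           | (res["counts"] < res["null_lo"]))
        assert frac_out < 0.25


class TestPsthBySize:
    def _trains_gain_by_amp(self, amps, rng):
        # firing gain proportional to event amplitude
        trains = []
        for u in range(4):
            extras = []
            for a, amp in zip(ANCHORS, amps):
                k = rng.poisson(0.4 * amp)
                extras.append(a + 0.03 + 0.02 * rng.standard_normal(k))
            base = rng.uniform(0, DUR, rng.poisson(3.0 * DUR))
            trains.append(SpikeTrain(f"u{u}", "RSC",
                                     np.sort(np.r_[base,
                                                   np.concatenate(extras)])))
        return trains

    def test_amplitude_coupled_firing_significant(self):
        rng = np.random.default_rng(3)
        amps = rng.uniform(4.5, 14, ANCHORS.size)
        labels = ["large" if a > 10 else "medium" if a > 6 else "small"
                  for a in amps]
        swrs = IntervalSet([Interval(a - 0.03, a + 0.05, "swr", a, s)
                            for a, s in zip(ANCHORS, amps)], "swr")
        res = psth_by_size(self._trains_gain_by_amp(amps, rng), swrs, labels)
        w = (0.0, 0.050)
        assert res["anova"][w]["p"] < 0.05
        means = res["anova"][w]["class_means"]
        assert means["large"] > means["small"]

    def test_single_class_errors(self):
        swrs = IntervalSet([Interval(a - 0.03, a + 0.05, "swr", a, 5.0)
                            for a in ANCHORS], "swr")
        trains = [poisson_train(3.0, DUR, np.random.default_rng(8))]
        with pytest.raises(ValidationError):
            psth_by_size(trains, swrs, ["small"] * len(ANCHORS))


class TestOffPeriSwr:
    def test_inserted_off_after_swr_peaks_at_lag(self):
        rng = np.random.default_rng(4)
        swrs = IntervalSet([Interval(a, a + 0.05, "swr", a) for a in ANCHORS],
                           "swr")
        offs = IntervalSet([Interval(a + 0.1, a + 0.1 + rng.uniform(0.11, 0.2),
                                     "off_period") for a in ANCHORS],
                           "off_period")
        res = off_peri_swr(offs, swrs)
        assert abs(res["lags_s"][np.argmax(res["onset_prob"])] - 0.125) < 0.08

    def test_independent_off_flat(self):
        rng = np.random.default_rng(5)
        swrs = IntervalSet([Interval(a, a + 0.05, "swr", a) for a in ANCHORS],
                           "swr")
        offs = IntervalSet([Interval(t, t + 0.15, "off_period")
                            for t in np.sort(rng.uniform(0, DUR, 80))],
                           "off_period").merged()
        res = off_peri_swr(offs, swrs)
        prof = res["onset_prob"]
        assert prof.max() - prof.min() < 0.15

    def test_empty_inputs_error(self):
        swrs = IntervalSet([Interval(1, 2, "swr", 1.5)], "swr")
        with pytest.raises(ValidationError):
            off_peri_swr(IntervalSet([], "off_period"), swrs)
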