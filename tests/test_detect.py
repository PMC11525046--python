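import numpy as np
import pytest

from rdlg.core import Interval, IntervalSet, SampledSignal, SpikeTrain, ValidationError
from rdlg.detect import (DetectorConfig, classify_swr_size, detect_delta,
                         detect_off_periods, detect_ripples,
                         detect_sharp_waves, detect_spindles, pair_sequences,
                         pair_swr, ripple_features)
from rdlg.filters import band_envelope_z
from rdlg.synth import _flatten_band

FS = 1250.0


def burst_signal(bursts, duration_s=10.0, freq=180.0, seed=0, amp=12.0):
    """Flat-band background with inserted high-frequency bursts.

    ``bursts``: list of (center_s, duration_s).  Amplitudes are large
    multiples of the band floor so every burst clears the peak threshold.
    """
    rng = np.random.default_rng(seed)
    n = int(duration_s * FS)
    x = _flatten_band(rng.standard_normal(n), FS, 140.0, 250.0)
    t = np.arange(n) / FS
    for c, d in bursts:
        env = np.exp(-((t - c) ** 2) / (2 * (d / 4) ** 2))
        x = x + amp * env * np.sin(2 * np.pi * freq * (t - c))
    return SampledSignal(x, FS, 0.0, "CA1-lfp")


def literal_ripple_oracle(lfp, thr_env=1.0, thr_peak=4.0, dur=(0.015, 0.2),
                          merge_gap=0.020, smooth_sd_s=0.010):
    """Direct O(n) scan implementing the detection rules verbatim."""
    env = band_envelope_z(lfp, (140.0, 250.0), smooth_sd_s)
    above = env > thr_env
    segments = []
    i = 0
    while i < env.size:
        if above[i]:
            j = i
            while j < env.size and above[j]:
                j += 1
            segments.append([i, j])
            i = j
        else:
            i += 1
    merged = []
    for s in segments:
        if merged and (s[0] - merged[-1][1]) / FS < merge_gap:
            merged[-1][1] = s[1]
        else:
            merged.append(s)
    out = []
    for i0, i1 in merged:
        d = (i1 - i0) / FS
        if dur[0] <= d <= dur[1] and env[i0:i1].max() > thr_peak:
            ipk = i0 + int(np.argmax(env[i0:i1]))
            out.append((i0 / FS, i1 / FS, ipk / FS, env[ipk]))
    return out


class TestRipples:
    def test_matches_literal_oracle_on_fixture(self):
        lfp = burst_signal([(2.0, 0.05), (4.0, 0.08), (7.0, 0.06)], seed=1)
        got = detect_ripples(lfp)
        want = literal_ripple_oracle(lfp)
        assert len(got) == len(want)
        for iv, (s, e, p, score) in zip(got, want):
            assert np.isclose(iv.start_s, s) and np.isclose(iv.end_s, e)
            assert np.isclose(iv.peak_s, p)
            assert np.isclose(iv.peak_score, score)

    def test_short_burst_rejected_long_burst_kept(self):
        # same amplitude: a 10 ms burst carries too little band energy to
        # clear the detection rules, a 50 ms burst is kept
        lfp = burst_signal([(3.0, 0.010), (7.0, 0.050)], seed=2, amp=8.0)
        got = detect_ripples(lfp)
        assert any(abs(iv.peak_s - 7.0) < 0.05 for iv in got)
        assert all(not (2.9 < iv.peak_s < 3.1) for iv in got)

    def test_nearby_bursts_merged(self):
        # two bursts whose supra-threshold segments sit ~15 ms apart
        lfp = burst_signal([(5.0, 0.03), (5.065, 0.03)], seed=3, amp=15.0)
        got = detect_ripples(lfp)
        near = [iv for iv in got if 4.9 < iv.peak_s < 5.2]
        assert len(near) == 1

    def test_band_above_nyquist_errors(self):
        sig = SampledSignal(np.zeros(1000), 400.0)
        with pytest.raises(ValidationError):
            detect_ripples(sig, band=(140.0, 250.0))

    def test_time_reversal_symmetry(self):
        lfp = burst_signal([(2.0, 0.05), (6.5, 0.07)], seed=4)
        fwd = detect_ripples(lfp)
        rev = detect_ripples(SampledSignal(lfp.samples[::-1].copy(), FS))
        assert len(fwd) == len(rev)


class TestSharpWaves:
    def test_flat_signal_empty(self):
        rng = np.random.default_rng(0)
        sig = SampledSignal(0.01 * rng.standard_normal(12500) + 5.0, FS)
        # uniform noise: no 2.5 SD excursion lasting 20 ms in the 5-40 band
        got = detect_sharp_waves(sig)
        assert all(iv.peak_score < 4 for iv in got)

    def test_inserted_deflection_detected(self):
        rng = np.random.default_rng(1)
        n = int(10 * FS)
        t = np.arange(n) / FS
        x = rng.standard_normal(n)
        d = 0.08
        m = (t >= 5 - d / 2) & (t < 5 + d / 2)
        x[m] -= 30 * np.sin(np.pi * (t[m] - (5 - d / 2)) / d)
        got = detect_sharp_waves(SampledSignal(x, FS))
        assert any(abs(iv.peak_s - 5.0) < 0.05 for iv in got)

    def test_long_deflection_rejected(self):
        # a 600 ms deflection exceeds the 400 ms maximum duration
        rng = np.random.default_rng(2)
        n = int(10 * FS)
        t = np.arange(n) / FS
        x = rng.standard_normal(n)
        d = 0.6
        m = (t >= 5 - d / 2) & (t < 5 + d / 2)
        x[m] -= 40 * np.sin(np.pi * (t[m] - (5 - d / 2)) / d)
        got = detect_sharp_waves(SampledSignal(x, FS))
        assert all(not (4.8 < (iv.peak_s or 0) < 5.2) for iv in got)


class TestPairing:
    RIP = IntervalSet([Interval(1.0, 1.05, "ripple", 1.02, 6.0),
                       Interval(2.0, 2.06, "ripple", 2.03, 8.0),
                       Interval(3.0, 3.05, "ripple", 3.02, 5.0)], "ripple")
    SW = IntervalSet([Interval(0.98, 1.10, "sharp_wave"),
                      Interval(2.97, 3.10, "sharp_wave")], "sharp_wave")
    NREM = IntervalSet([Interval(0.0, 2.5, "nrem")], "nrem")

    def test_conjunction_and_state_gate(self):
        got = pair_swr(self.RIP, self.SW, self.NREM)
        # ripple 1: overlaps SW, in NREM -> kept; ripple 2: no SW -> dropped;
        # ripple 3: SW but outside NREM -> dropped
        assert [iv.peak_s for iv in got] == [1.02]
        assert got[0].kind == "swr"

    def test_no_state_filter_keeps_overlapping(self):
        got = pair_swr(self.RIP, self.SW, None)
        assert [iv.peak_s for iv in got] == [1.02, 3.02]

    def test_sequence_pairing_window(self):
        swrs = IntervalSet([Interval(1.0, 1.05, "swr", 1.0)], "swr")
        cort = IntervalSet([Interval(1.0, 1.4, "delta", 1.06),   # +60 ms
                            Interval(0.5, 0.9, "delta", 0.88),   # before
                            Interval(1.3, 1.7, "delta", 1.40)],  # +400 ms
                           "delta")
        pairs = pair_sequences(swrs, cort)
        assert len(pairs) == 1
        assert pairs[0][1].peak_s == 1.06

    def test_each_cortical_pairs_nearest_preceding_swr(self):
        swrs = IntervalSet([Interval(1.0, 1.05, "swr", 1.0),
                            Interval(1.1, 1.15, "swr", 1.1)], "swr")
        cort = IntervalSet([Interval(1.1, 1.5, "delta", 1.2)], "delta")
        pairs = pair_sequences(swrs, cort)
        assert len(pairs) == 1 and pairs[0][0].peak_s == 1.1


class TestSizeClasses:
    def test_partition(self):
        swrs = IntervalSet([Interval(0, 1, "swr", 0.5, s)
                            for s in (12.0, 7.0, 4.5)], "swr")
        assert classify_swr_size(swrs) == ["large", "medium", "small"]

    def test_missing_score_errors(self):
        swrs = IntervalSet([Interval(0, 1, "swr", 0.5, None)], "swr")
        with pytest.raises(ValidationError):
            classify_swr_size(swrs)

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValidationError):
            DetectorConfig(size_thresholds=(6.0, 4.0, 10.0))


class TestOffPeriods:
    def _trains(self, times_lists):
        return [SpikeTrain(f"u{i}", "RSC", np.sort(np.asarray(t)))
                for i, t in enumerate(times_lists)]

    def test_gap_definition(self):
        trains = self._trains([[9.9, 10.16], [9.95], [9.8], [9.85], [9.92]])
        got = detect_off_periods(trains, Interval(9.5, 10.5))
        assert any(np.isclose(iv.start_s, 10.0, atol=0.11)
                   and iv.duration_s > 0.1 for iv in got)

    def test_80ms_gap_not_off(self):
        base = [9.0, 9.95, 10.03, 11.0]
        trains = self._trains([base] * 5)
        got = detect_off_periods(trains, Interval(9.4, 9.9))
        assert all(not (9.9 < iv.start_s < 10.05) for iv in got)

    def test_merge_within_5ms(self):
        # two >100 ms gaps separated by one spike cluster of 3 ms
        base = [1.0, 1.150, 1.153, 1.300]
        trains = self._trains([base] * 5)
        got = detect_off_periods(trains, Interval(0.9, 1.4))
        offs = [(round(iv.start_s, 3), round(iv.end_s, 3)) for iv in got]
        assert (1.0, 1.3) in offs

    def test_fewer_than_min_units_skips(self, caplog):
        trains = self._trains([[1.0], [2.0]])
        with caplog.at_level("WARNING", logger="rdlg.detect"):
            got = detect_off_periods(trains, Interval(0, 3))
        assert len(got) == 0
        assert any("skipped" in r.message for r in caplog.records)

    def test_matches_exact_oracle_on_random_rasters(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            trains = self._trains(
                [rng.uniform(0, 5, rng.integers(3, 50)) for _ in range(5)])
            got = detect_off_periods(trains, Interval(0, 5))
            pooled = np.sort(np.concatenate([tr.times_s for tr in trains]))
            bounds = np.r_[0.0, pooled, 5.0]
            want = [(a, b) for a, b in zip(bounds[:-1], bounds[1:])
                    if b - a > 0.1]
            # merge <5 ms
            merged = []
            for a, b in want:
                if merged and a - merged[-1][1] < 0.005:
                    merged[-1] = (merged[-1][0], b)
                else:
                    merged.append((a, b))
            assert [(iv.start_s, iv.end_s) for iv in got] == merged


class TestRippleFeatures:
    def test_arithmetic(self):
        rip = IntervalSet([Interval(10.0, 10.06, "ripple", 10.02, 6.5)],
                          "ripple")
        df = ripple_features(rip, analyzed_duration_s=120.0)
        assert np.isclose(df["duration_s"].iloc[0], 0.06)
        assert np.isclose(df.attrs["rate_per_min"], 0.5)

    def test_empty(self):
        df = ripple_features(IntervalSet([], "ripple"), 60.0)
        assert df.empty and df.attrs["rate_per_min"] == 0.0


def test_detectors_recover_inserted_events(sleep_session):
    """Recall/precision against ground truth on a full synthetic session."""
    sess, gt = sleep_session
    nrem = gt.state_set("nrem")
    checks = [
        ("ripple", detect_ripples(sess.signals["CA1-lfp"]), 0.05),
        ("sharp_wave", detect_sharp_waves(sess.signals["CA1-lfp"]), 0.08),
        ("delta", detect_delta(sess.signals["RSC-lfp"]), 0.15),
        ("spindle", detect_spindles(sess.signals["RSC-lfp"]), 0.4),
    ]
    for kind, ivs, tol in checks:
        truth = np.asarray(gt.event_times[kind])
        peaks = ivs.peaks[nrem.membership(ivs.peaks)]
        tp = sum(bool(np.any(np.abs(truth - p) < tol)) for p in peaks)
        precision = tp / max(1, len(peaks))
        recall = np.mean([np.any(np.abs(peaks - t) < tol) for t in truth])
        assert precision >= 0.9, f"{kind} precision {precision:.2f}"
        assert recall >= 0.9, f"{kind} recall {recall:.2f}"
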