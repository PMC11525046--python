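import numpy as np
import pandas as pd
import pytest

from rdlg.core import SpikeTrain, ValidationError
from rdlg.spatial import (RateMap, classify_stem_cell, exclude_speed_cells,
                          find_place_fields, rate_map, speed_score,
                          stem_trial_rates, trajectory_speed)


def synthetic_map(shape=(60, 60), mean=2.0):
    rate = np.full(shape, mean)
    occ = np.ones(shape)
    return RateMap(np.arange(shape[0] + 1) * 0.36,
                   np.arange(shape[1] + 1) * 0.36, occ, rate * occ, rate,
                   float(mean))


class TestFindPlaceFields:
    def test_flat_map_no_fields(self):
        assert find_place_fields(synthetic_map()) == []

    def test_compact_component_of_45_bins_is_field(self):
        m = synthetic_map()
        patch = np.zeros((7, 7), dtype=bool)
        patch.ravel()[:45] = True
        m.rate_hz[10:17, 20:27][patch] = 5.0
        fields = find_place_fields(m)
        assert len(fields) == 1 and fields[0]["n_bins"] == 45

    def test_20_bins_not_a_field(self):
        m = synthetic_map()
        m.rate_hz[10:14, 20:25] = 5.0  # 20 bins
        assert find_place_fields(m) == []

    def test_oversized_component_rejected(self):
        m = synthetic_map()
        m.rate_hz[5:25, 30:34] = 5.0  # 80 bins but 20-bin bounding box
        assert find_place_fields(m) == []

    def test_translation_invariance(self):
        a = synthetic_map()
        patch = np.ones((7, 7), dtype=bool)
        a.rate_hz[5:12, 5:12][patch] = 6.0
        b = synthetic_map()
        b.rate_hz[40:47, 30:37][patch] = 6.0
        fa, fb = find_place_fields(a), find_place_fields(b)
        assert len(fa) == len(fb) == 1
        assert fa[0]["n_bins"] == fb[0]["n_bins"]


class TestRateMap:
    def test_place_field_peak_near_center(self, task_session):
        sess, _ = task_session
        tr = sorted(sess.trains_in("RSC"), key=lambda t: t.unit_id)[0]
        rm = rate_map(tr, sess.trajectory)
        i, j = np.unravel_index(np.argmax(rm.rate_hz), rm.rate_hz.shape)
        px = rm.x_edges[i] + 0.18
        py = rm.y_edges[j] + 0.18
        # peak lies inside the field, and the field-center bin is hot
        assert abs(px - 0.0) < 6.0 and abs(py - 25.0) < 6.0
        ic = np.searchsorted(rm.x_edges, 0.0) - 1
        jc = np.searchsorted(rm.y_edges, 25.0) - 1
        assert rm.rate_hz[ic, jc] > 2.0 * rm.mean_rate_hz

    def test_rate_integral_conserves_spikes(self, task_session):
        sess, _ = task_session
        tr = sorted(sess.trains_in("RSC"), key=lambda t: t.unit_id)[2]
        rm = rate_map(tr, sess.trajectory)
        integral = np.nansum(rm.rate_hz * rm.occupancy_s)
        assert np.isclose(integral, rm.spike_counts.sum(), rtol=0.05)

    def test_low_spike_unit_excluded(self, task_session):
        sess, _ = task_session
        sparse = SpikeTrain("sparse", "RSC", np.array([10.0, 20.0, 30.0]))
        with pytest.raises(ValidationError, match="200"):
            rate_map(sparse, sess.trajectory)


class TestClassifyStemCell:
    def _rates(self, table):
        rows = []
        for trial in range(16):
            ttype = "L" if trial % 2 == 0 else "R"
            rng = np.random.default_rng(trial)
            for sub in (1, 2, 3):
                rows.append({"trial_id": trial, "trial_type": ttype,
                             "subarea": sub,
                             "rate_hz": table[ttype][sub - 1]
                             + rng.normal(0, 0.4)})
        return pd.DataFrame(rows)

    def test_trial_type_effect_is_splitter(self):
        df = self._rates({"L": (2, 2, 10), "R": (2, 2, 2)})
        assert classify_stem_cell(df)["label"] == "splitter"

    def test_subarea_only_is_location_related(self):
        df = self._rates({"L": (2, 6, 10), "R": (2, 6, 10)})
        assert classify_stem_cell(df)["label"] == "location_related"

    def test_homogeneous_is_neither(self):
        df = self._rates({"L": (4, 4, 4), "R": (4, 4, 4)})
        assert classify_stem_cell(df)["label"] == "neither"

    def test_missing_trial_type_errors(self):
        df = self._rates({"L": (2, 2, 10), "R": (2, 2, 2)})
        with pytest.raises(ValidationError):
            classify_stem_cell(df[df.trial_type == "L"])


class TestStemTrialRates:
    def test_incorrect_trials_excluded(self, task_session):
        sess, _ = task_session
        tr = sorted(sess.trains_in("RSC"), key=lambda t: t.unit_id)[0]
        sr = stem_trial_rates(tr, sess.trajectory, sess.trials)
        bad = set(sess.trials.loc[~sess.trials.correct, "trial_id"])
        assert not (set(sr.trial_id) & bad)
        assert set(sr.subarea) == {1, 2, 3}

    def test_splitter_unit_classified(self, task_session):
        sess, _ = task_session
        trains = sorted(sess.trains_in("RSC"), key=lambda t: t.unit_id)
        sr = stem_trial_rates(trains[0], sess.trajectory, sess.trials)
        assert classify_stem_cell(sr)["label"] == "splitter"


class TestSpeedScore:
    def test_speed_tuned_unit_flagged(self, task_session):
        sess, _ = task_session
        tr = sorted(sess.trains_in("RSC"), key=lambda t: t.unit_id)[3]
        res = speed_score(tr, sess.trajectory, seed=1)
        assert res["speed_cell"] and res["score"] > res["null_99"]

    def test_untuned_unit_not_flagged(self, task_session):
        sess, _ = task_session
        tr = sorted(sess.trains_in("RSC"), key=lambda t: t.unit_id)[2]
        res = speed_score(tr, sess.trajectory, seed=2)
        assert not res["speed_cell"]

    def test_constant_speed_errors(self):
        t = np.arange(0, 60, 0.04)
        traj = pd.DataFrame({"time_s": t, "x_cm": 10 * t, "y_cm": 0.0})
        tr = SpikeTrain("u", "RSC", np.sort(
            np.random.default_rng(0).uniform(0, 60, 300)))
        with pytest.raises(ValidationError):
            speed_score(tr, traj)


class TestExcludeSpeedCells:
    def test_flagged_removed_rest_kept(self):
        labels = {"a": "splitter", "b": "location_related"}
        out = exclude_speed_cells(labels, {"a": True, "b": False})
        assert out == {"b": "location_related"}

    def test_all_flagged_warns(self, caplog):
        with caplog.at_level("WARNING", logger="rdlg.spatial"):
            out = exclude_speed_cells({"a": "splitter"}, {"a": True})
        assert out == {} and caplog.records


def test_trajectory_speed_matches_displacement(task_session):
    sess, _ = task_session
    v = trajectory_speed(sess.trajectory)
    assert v.min() >= 0
    assert 10 < np.percentile(v, 90) < 40
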