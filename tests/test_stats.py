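"""Spatial and circular statistics of the dance floor."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from waggledance.drift import MotionModelParams, simulate_dances
from waggledance.stats import (
    binned_orientation_field,
    choice_situation_analysis,
    dance_floor_area_fraction,
    dance_floor_center,
    filter_days_by_median_count,
    follower_target_map,
    group_distance_timeseries,
    median_location_by_direction,
    moods_median_test,
    offset_alignment_scores,
    sign_test_one_sided,
)


def phases(xy, angles):
    xy = np.asarray(xy, float)
    return pd.DataFrame({"x_mm": xy[:, 0], "y_mm": xy[:, 1],
                         "alpha_rad": angles})


class TestCenter:
    def test_odd_count(self):
        assert dance_floor_center([(0, 0), (10, 0), (20, 0)]) == (10.0, 0.0)

    def test_single_phase(self):
        assert dance_floor_center([(3.5, 7.0)]) == (3.5, 7.0)

    def test_even_count_matches_order_statistic_oracle(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 100, (10, 2))
        cx, cy = dance_floor_center(pts)
        xs, ys = np.sort(pts[:, 0]), np.sort(pts[:, 1])
        assert cx == pytest.approx((xs[4] + xs[5]) / 2)
        assert cy == pytest.approx((ys[4] + ys[5]) / 2)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            dance_floor_center(np.empty((0, 2)))


class TestAlignmentScores:
    center = (50.0, 50.0)

    @pytest.mark.parametrize("pos, alpha, expected", [
        ((51.0, 50.0), 0.0, 1.0),
        ((51.0, 50.0), np.pi, -1.0),
        ((50.0, 51.0), 0.0, 0.0),
    ])
    def test_geometry(self, pos, alpha, expected):
        out = offset_alignment_scores(phases([pos], [alpha]), self.center)
        assert out.scores[0] == pytest.approx(expected, abs=1e-12)

    def test_center_phase_excluded_and_counted(self):
        out = offset_alignment_scores(
            phases([(50.0, 50.0), (60.0, 50.0)], [0.0, 0.0]), self.center)
        assert len(out.scores) == 1 and out.n_at_center == 1

    def test_rotation_invariance_about_center(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 100, (50, 2))
        ang = rng.uniform(-np.pi, np.pi, 50)
        s0 = offset_alignment_scores(phases(pts, ang), self.center).scores
        th = 0.9
        c, s = np.cos(th), np.sin(th)
        rel = pts - self.center
        rot = np.column_stack([c * rel[:, 0] - s * rel[:, 1],
                               s * rel[:, 0] + c * rel[:, 1]]) + self.center
        s1 = offset_alignment_scores(phases(rot, ang + th), self.center).scores
        np.testing.assert_allclose(s1, s0, atol=1e-9)


class TestSignTest:
    def test_five_of_five(self):
        n_pos, n, p = sign_test_one_sided(np.ones(5))
        assert (n_pos, n) == (5, 5)
        assert p == pytest.approx(0.03125)

    def test_nine_of_ten(self):
        scores = np.array([1.0] * 9 + [-1.0])
        _, _, p = sign_test_one_sided(scores)
        assert p == pytest.approx(11 / 1024)

    def test_zeros_excluded(self):
        n_pos, n, _ = sign_test_one_sided(np.array([0.0, 0.0, 1.0, -1.0]))
        assert (n_pos, n) == (1, 2)

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            sign_test_one_sided(np.zeros(3))


class TestOrientationField:
    def test_identical_angles_full_length(self):
        f = binned_orientation_field(phases([(5, 5), (6, 6)], [0.3, 0.3]))
        occ = f.counts > 0
        assert occ.sum() == 1
        assert f.mean_length[occ][0] == pytest.approx(1.0)
        assert f.mean_direction[occ][0] == pytest.approx(0.3)

    def test_opposite_angles_cancel(self):
        f = binned_orientation_field(phases([(5, 5), (6, 6)], [0.0, np.pi]))
        occ = f.counts > 0
        assert f.mean_length[occ][0] == pytest.approx(0.0, abs=1e-12)

    def test_counts_sum_to_total(self):
        rng = np.random.default_rng(2)
        p = phases(rng.uniform(0, 390, (200, 2)), rng.uniform(0, 6.28, 200))
        f = binned_orientation_field(p)
        assert f.counts.sum() == 200

    def test_simulated_drift_points_outward(self):
        sim = simulate_dances(MotionModelParams(), seed=1)
        f = binned_orientation_field(sim, direction_col="alpha_rad")
        cx, cy = dance_floor_center(sim)
        occ = f.counts > 0
        bx = (f.x_edges[:-1] + f.x_edges[1:]) / 2
        by = (f.y_edges[:-1] + f.y_edges[1:]) / 2
        gx, gy = np.meshgrid(bx, by, indexing="ij")
        off = np.stack([gx - cx, gy - cy], axis=-1)
        norm = np.linalg.norm(off, axis=-1)
        ok = occ & (norm > 1e-9)
        outward = (f.mean_vector[..., 0] * off[..., 0]
                   + f.mean_vector[..., 1] * off[..., 1]) / np.where(norm > 0, norm, 1)
        assert outward[ok].mean() > 0.1


class TestMedianLocationByDirection:
    def test_half_open_bin_convention(self):
        p = phases([(1, 1), (2, 2)], [np.radians(4.9), np.radians(5.0)])
        out = median_location_by_direction(p)
        assert set(out["bin"]) == {0, 1}

    def test_rightward_phases_sit_right_of_leftward(self):
        sim = simulate_dances(MotionModelParams(), seed=2)
        out = median_location_by_direction(sim, direction_col="alpha_rad")
        right = out[out["bin"] == 0]["x_mm"].iloc[0]
        left = out[out["bin"] == 36]["x_mm"].iloc[0]  # alpha ~ pi
        assert right > left


class TestAreaFraction:
    def test_single_occupied_cell(self):
        p = np.tile([(5.0, 5.0)], (100, 1))
        assert dance_floor_area_fraction(p) == pytest.approx(1 / 960)

    def test_equal_cells_greedy(self):
        # 100 cells with equal counts on the 40x24 grid: 95 cells cover 95%
        xs = (np.arange(100) % 20) * 10.0 + 5.0
        ys = (np.arange(100) // 20) * 10.0 + 5.0
        pts = np.repeat(np.column_stack([xs, ys]), 4, axis=0)
        assert dance_floor_area_fraction(pts) == pytest.approx(95 / 960)

    def test_monotone_in_coverage(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 390, (500, 2)) * [1, 0.6]
        fracs = [dance_floor_area_fraction(pts, coverage=c)
                 for c in (0.5, 0.8, 0.95, 1.0)]
        assert fracs == sorted(fracs)


class TestFilterDays:
    def test_strictly_above_median(self):
        assert filter_days_by_median_count({"a": 1, "b": 2, "c": 3}) == ["c"]

    def test_all_equal_keeps_none(self):
        assert filter_days_by_median_count({"a": 2, "b": 2}) == []

    def test_even_count_median(self):
        kept = filter_days_by_median_count({"a": 1, "b": 2, "c": 3, "d": 4})
        assert sorted(kept) == ["c", "d"]


class TestMoodsMedianTest:
    def test_hand_computed_table(self):
        chi2, p, n = moods_median_test([1, 2, 3], [4, 5, 6])
        assert chi2 == pytest.approx(6.0)
        assert n == 6

    def test_identical_groups(self):
        chi2, p, _ = moods_median_test([1, 2, 3], [1, 2, 3])
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_contingency_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            a = rng.normal(0, 1, rng.integers(5, 40))
            b = rng.normal(rng.uniform(-1, 1), 1, rng.integers(5, 40))
            chi2, p, _ = moods_median_test(a, b)
            med = np.median(np.concatenate([a, b]))
            table = [[(a > med).sum(), (a <= med).sum()],
                     [(b > med).sum(), (b <= med).sum()]]
            if min(np.sum(table, 0).min(), np.sum(table, 1).min()) == 0:
                continue
            ref = sps.chi2_contingency(table, correction=False)
            assert abs(chi2 - ref.statistic) < 1e-9
            assert abs(p - ref.pvalue) < 1e-9


class TestGroupDistances:
    def _samples(self, pos_by_event, label_by_event, n_times=10):
        rows = []
        for ev, (x, y) in pos_by_event.items():
            for t in range(n_times):
                rows.append({"event_id": ev, "group": label_by_event[ev],
                             "rel_time": float(t), "x_mm": x, "y_mm": y})
        return pd.DataFrame(rows)

    def test_planted_separation(self):
        pos = {0: (0.0, 0.0), 1: (0.0, 0.0), 2: (20.0, 0.0), 3: (20.0, 0.0)}
        lab = {0: "f1", 1: "f1", 2: "f2", 3: "f2"}
        out = group_distance_timeseries(self._samples(pos, lab), bin_width_s=5.0)
        assert np.allclose(out["intra_mean"], 0.0)
        assert np.allclose(out["inter_mean"], 20.0)

    def test_shuffled_labels_remove_separation(self):
        rng = np.random.default_rng(5)
        pos = {i: (float(rng.normal(0, 5)), float(rng.normal(0, 5)))
               for i in range(40)}
        lab = {i: "f1" if i < 20 else "f2" for i in range(40)}
        out = group_distance_timeseries(self._samples(pos, lab, n_times=5))
        diff = (out["inter_mean"] - out["intra_mean"]).abs().max()
        ci = (out["inter_ci95"] + out["intra_ci95"]).max()
        assert diff < ci

    def test_sparse_bins_omitted(self):
        df = pd.DataFrame([{"event_id": 0, "group": "f1", "rel_time": 0.0,
                            "x_mm": 0.0, "y_mm": 0.0}])
        assert len(group_distance_timeseries(df)) == 0


class TestFollowerTargetMap:
    def test_unanimous_feeder(self):
        rng = np.random.default_rng(6)
        ev = pd.DataFrame({"x_mm": rng.uniform(0, 100, 50),
                           "y_mm": rng.uniform(0, 100, 50),
                           "feeder_id": 1})
        out = follower_target_map(ev)
        assert (out["feeder_id"] == 1).all()

    def test_majority_vote_per_bin(self):
        ev = pd.DataFrame({"x_mm": [5.0] * 4, "y_mm": [5.0] * 4,
                           "feeder_id": [1, 1, 1, 2]})
        out = follower_target_map(ev)
        assert len(out) == 1 and out["feeder_id"].iloc[0] == 1

    def test_mask_is_minimal_ninety_percent_cover(self):
        rng = np.random.default_rng(7)
        ev = pd.DataFrame({"x_mm": rng.uniform(0, 390, 300),
                           "y_mm": rng.uniform(0, 230, 300),
                           "feeder_id": rng.integers(1, 3, 300)})
        out = follower_target_map(ev)
        total = out["count"].sum()
        masked = out[out["in_mask"]].sort_values("count")
        assert masked["count"].sum() >= 0.9 * total
        assert masked["count"].sum() - masked["count"].iloc[0] < 0.9 * total


class TestChoiceSituations:
    def _inputs(self):
        # follower 10 follows dance 0, then chooses among dances 1 (10 mm
        # away, feeder 1) and 2 (50 mm away, feeder 2) and takes dance 1
        dances = pd.DataFrame({
            "dance_id": [0, 1, 2],
            "bee_id": [1, 2, 3],
            "start": [0.0, 15.0, 15.0],
            "end": [12.0, 60.0, 60.0],
            "feeder_id": [1, 1, 2],
        })
        follows = pd.DataFrame({
            "follower_id": [10, 10],
            "dancer_id": [1, 2],
            "dance_id": [0, 1],
            "start": [2.0, 30.0],
            "end": [10.0, 40.0],
        })
        det = pd.DataFrame({
            "bee_id": [10, 2, 3],
            "time": [30.0, 30.0, 30.0],
            "x_mm": [100.0, 110.0, 150.0],
            "y_mm": [100.0, 100.0, 100.0],
        })
        return follows, dances, det

    def test_distances_and_choice_flags(self):
        rec, summary = choice_situation_analysis(*self._inputs())
        assert len(rec) == 2
        followed = rec[rec["followed"]]
        ignored = rec[~rec["followed"]]
        assert followed["distance_mm"].iloc[0] == pytest.approx(10.0)
        assert ignored["distance_mm"].iloc[0] == pytest.approx(50.0)
        assert summary["followed"]["mean_mm"] == pytest.approx(10.0)
        assert summary["not_followed"]["mean_mm"] == pytest.approx(50.0)

    def test_single_feeder_candidates_excluded(self):
        follows, dances, det = self._inputs()
        dances["feeder_id"] = 1  # both candidates advertise the same feeder
        rec, _ = choice_situation_analysis(follows, dances, det)
        assert len(rec) == 0

    def test_initial_dancer_not_a_candidate(self):
        follows, dances, det = self._inputs()
        # make the initial dancer also dance at choice time for feeder 2
        dances.loc[2, "bee_id"] = 1
        rec, _ = choice_situation_analysis(follows, dances, det)
        assert len(rec) == 0

    def test_followed_dances_are_closer_in_simulated_scenes(self):
        # in scenes with concurrent dances to separated feeder regions, the
        # dance a follower picks next is the nearer one, and same-feeder
        # dances sit closer than other-feeder dances
        from waggledance.scene import SceneConfig, generate_scene

        recs = []
        for seed in range(6):
            cfg = SceneConfig(n_dancers=8, n_followers=14, n_idle=0,
                              duration=600.0, overlapping_dances=True,
                              follows_per_follower=3, dances_per_dancer=2,
                              seed=seed)
            sc = generate_scene(cfg)
            gt = sc.ground_truth
            rec, _ = choice_situation_analysis(
                gt.follow_events, gt.dance_events, sc.detections)
            if len(rec):
                recs.append(rec)
        rec = pd.concat(recs, ignore_index=True)
        assert rec["situation"].nunique() >= 2
        assert rec[rec["followed"]]["distance_mm"].mean() < \
            rec[~rec["followed"]]["distance_mm"].mean()
        same = rec[rec["same_feeder_as_initial"] == True]["distance_mm"]  # noqa: E712
        other = rec[rec["same_feeder_as_initial"] == False]["distance_mm"]  # noqa: E712
        assert same.mean() < other.mean()
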