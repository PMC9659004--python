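"""Linking, displacement filtering, motion-state segmentation and
active-transport summaries."""

import numpy as np
import pandas as pd
import pytest

from virocount import (SegmentSpec, TrajectoryPlan, ValidationError,
                       make_trajectory_set)
from virocount.tracking import (active_transport_stats, classify_segments,
                                classify_tracks, count_motile,
                                filter_by_displacement, link_spots)


def _detections(tracks: dict[int, np.ndarray]) -> pd.DataFrame:
    rows = []
    for tid, xy in tracks.items():
        for f, (x, y) in enumerate(xy):
            rows.append(dict(frame=f, x_um=x, y_um=y, true_id=tid))
    return pd.DataFrame(rows)


class TestLinking:
    def test_static_spot_yields_one_full_track(self):
        det = _detections({0: np.tile([5.0, 5.0], (50, 1))})
        tracks = link_spots(det)
        assert tracks["track_id"].nunique() == 1
        assert len(tracks) == 50

    def test_parallel_spots_never_switch(self):
        a = np.column_stack([np.arange(30) * 0.3, np.zeros(30)])
        b = a + [0.0, 2.0]  # always 2 um apart
        det = _detections({0: a, 1: b})
        tracks = link_spots(det)
        assert tracks["track_id"].nunique() == 2
        merged = tracks.merge(det, on=["frame", "x_um", "y_um"])
        for _, g in merged.groupby("track_id"):
            assert g["true_id"].nunique() == 1

    def test_gap_longer_than_max_gap_splits_track(self):
        xy = np.tile([5.0, 5.0], (20, 1))
        det = _detections({0: xy})
        det = det[(det.frame < 7) | (det.frame >= 13)]  # 6 missing frames
        assert link_spots(det, max_gap=5)["track_id"].nunique() == 2

    def test_gap_within_max_gap_is_closed_and_interpolated(self):
        xy = np.column_stack([np.arange(20) * 0.1, np.zeros(20)])
        det = _detections({0: xy})
        det = det[(det.frame < 7) | (det.frame >= 12)]  # 5 missing frames
        tracks = link_spots(det, max_gap=5)
        assert tracks["track_id"].nunique() == 1
        assert tracks["interpolated"].sum() == 5
        gap = tracks[tracks.interpolated].sort_values("frame")
        assert np.allclose(gap["x_um"], np.arange(7, 12) * 0.1)

    def test_every_detection_lands_in_exactly_one_track(self, rng):
        det = _detections({i: rng.uniform(0, 50, (15, 2)).cumsum(axis=0) / 10
                           for i in range(6)})
        tracks = link_spots(det)
        real = tracks[~tracks.interpolated]
        assert len(real) == len(det)

    def test_missing_columns_raise(self):
        with pytest.raises(ValidationError):
            link_spots(pd.DataFrame(dict(x_um=[1.0], y_um=[1.0])))


class TestDisplacementFilter:
    def test_static_removed_straight_kept_zero_keeps_all(self):
        static = np.tile([1.0, 1.0], (10, 1))
        straight = np.column_stack([np.linspace(0, 2, 10), np.zeros(10)])
        tracks = pd.concat([
            pd.DataFrame(dict(track_id=0, frame=range(10),
                              x_um=static[:, 0], y_um=static[:, 1])),
            pd.DataFrame(dict(track_id=1, frame=range(10),
                              x_um=straight[:, 0], y_um=straight[:, 1]))])
        kept = filter_by_displacement(tracks, 1.0)
        assert set(kept["track_id"]) == {1}
        assert set(filter_by_displacement(tracks, 0.0)["track_id"]) == {0, 1}


class TestClassification:
    def test_noise_free_ballistic_track_is_one_active_segment(self):
        plan = TrajectoryPlan(0.1, [SegmentSpec("active", 6.0,
                                                dict(v=0.61))], 0.0)
        obs, _ = make_trajectory_set(plan, 1, seed=1)
        labels, segs = classify_segments(obs, dt=0.1)
        assert len(segs) == 1
        assert segs[0].state == "active"
        # velocity estimator is exactly unbiased on noise-free input
        assert segs[0].velocity == pytest.approx(0.61, abs=1e-12)

    def test_confined_track_mostly_confined(self):
        plan = TrajectoryPlan(0.1, [SegmentSpec("confined", 20.0,
                                                dict(L=0.2, D=0.05))],
                              0.02)
        obs, _ = make_trajectory_set(plan, 3, seed=2)
        lab, _ = classify_tracks(obs, 0.1, localization_sd=0.02)
        assert (lab["state"] == "confined").mean() >= 0.9

    def test_composite_track_recovers_two_active_runs(self):
        plan = TrajectoryPlan(0.1, [
            SegmentSpec("active", 5.0, dict(v=0.61)),
            SegmentSpec("normal_diffusion", 5.0, dict(D=0.01)),
            SegmentSpec("active", 5.0, dict(v=0.61))], 0.02)
        obs, truth = make_trajectory_set(plan, 10, seed=3)
        lab, segs = classify_tracks(obs, 0.1, localization_sd=0.02)
        m = lab.merge(truth.points[["track_id", "frame", "state"]],
                      on=["track_id", "frame"], suffixes=("_pred", "_true"))
        assert (m["state_pred"] == m["state_true"]).mean() >= 0.85
        for tid in m["track_id"].unique():
            active = [s for s in segs
                      if s.track_id == tid and s.state == "active"]
            assert len(active) == 2

    def test_segments_tile_track_exactly(self):
        plan = TrajectoryPlan(0.1, [
            SegmentSpec("active", 4.0, dict(v=0.6)),
            SegmentSpec("normal_diffusion", 4.0, dict(D=0.02))], 0.02)
        obs, _ = make_trajectory_set(plan, 5, seed=4)
        for _, g in obs.groupby("track_id"):
            labels, segs = classify_segments(g, dt=0.1,
                                             localization_sd=0.02)
            frames = g.sort_values("frame")["frame"].to_numpy()
            covered = []
            for s in segs:
                covered.extend(range(s.start_frame, s.end_frame + 1))
            assert covered == list(frames)

    def test_short_track_gets_single_global_label(self):
        xy = np.column_stack([np.arange(8) * 0.06, np.zeros(8)])
        track = pd.DataFrame(dict(track_id=0, frame=range(8),
                                  x_um=xy[:, 0], y_um=xy[:, 1]))
        labels, segs = classify_segments(track, dt=0.1, window=15)
        assert len(segs) == 1
        assert len(set(labels)) == 1

    def test_dt_validation(self):
        track = pd.DataFrame(dict(track_id=0, frame=[0, 1],
                                  x_um=[0.0, 0.1], y_um=[0.0, 0.0]))
        with pytest.raises(ValidationError):
            classify_segments(track, dt=0.0)


class TestSummaries:
    def test_velocity_arithmetic(self):
        plan = TrajectoryPlan(0.1, [SegmentSpec("active", 60.0,
                                                dict(v=0.61))], 0.0)
        obs, _ = make_trajectory_set(plan, 1, seed=5)
        _, segs = classify_segments(obs, dt=0.1)
        stats = active_transport_stats(segs)
        assert stats["mean_velocity"] == pytest.approx(0.61, abs=1e-9)
        assert stats["mean_run_length"] == pytest.approx(36.6, abs=1e-6)

    def test_empty_active_set_reports_status(self):
        stats = active_transport_stats([])
        assert stats["status"] == "no active runs"
        assert stats["n"] == 0

    def test_count_motile(self):
        rows = []
        for tid in range(10):
            v = 5.0 / 60.0 if tid < 4 else 0.0  # 4 tracks travel 5 um
            for f in range(61):
                rows.append(dict(track_id=tid, frame=f, x_um=v * f,
                                 y_um=0.0))
        tracks = pd.DataFrame(rows)
        assert count_motile(tracks, dt=1.0) == 4
        static = tracks[tracks.track_id >= 4]
        assert count_motile(static, dt=1.0) == 0
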