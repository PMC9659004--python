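"""Generator ground-truth guarantees: flux conservation, determinism,
kinematics, diffusion laws and region bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from virocount import (Microtubule, OpticsModel, PlacementError, RunSpec,
                       SegmentSpec, TrajectoryPlan, ValidationError,
                       make_cell_scene, make_invitro_movie, make_spot_scene,
                       make_trajectory_set)


class TestSpotScene:
    def test_noise_free_flux_conservation(self, quiet_optics):
        images, truth = make_spot_scene([(60, 1, 0)], quiet_optics,
                                        (64, 64), seed=1)
        assert images[0].sum() == pytest.approx(60 * 100.0, rel=1e-6)

    def test_flux_sums_over_all_spots(self, quiet_optics):
        images, truth = make_spot_scene([(24, 3, 0), (120, 2, 0)],
                                        quiet_optics, (128, 128), seed=2)
        expected = (3 * 24 + 2 * 120) * 100.0
        assert images[0].sum() == pytest.approx(expected, rel=1e-6)

    def test_seed_determinism_bit_identical(self, default_optics):
        a, ta = make_spot_scene([(60, 20, 0)], default_optics, seed=7)
        b, tb = make_spot_scene([(60, 20, 0)], default_optics, seed=7)
        assert np.array_equal(a[0], b[0])
        pd.testing.assert_frame_equal(ta.spots, tb.spots)

    def test_truth_completeness_unique_ids(self, default_optics):
        _, truth = make_spot_scene([(24, 10, 0), (180, 5, 0)],
                                   default_optics, seed=3)
        assert len(truth.spots) == 15
        assert truth.spots["id"].is_unique

    def test_min_separation_respected(self, default_optics):
        _, truth = make_spot_scene([(60, 30, 0)], default_optics,
                                   (256, 256), min_separation=15.0, seed=4)
        xy = truth.spots[["x_px", "y_px"]].to_numpy()
        d = np.linalg.norm(xy[:, None] - xy[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 15.0

    def test_overcrowded_field_raises_placement_error(self, default_optics):
        with pytest.raises(PlacementError, match="min_separation"):
            make_spot_scene([(60, 500, 0)], default_optics, (64, 64),
                            min_separation=10.0, seed=5)

    def test_optics_validation(self):
        with pytest.raises(ValidationError):
            OpticsModel(pixel_size=0.0)
        with pytest.raises(ValidationError):
            OpticsModel(psf_sigma=-1.0)


class TestInvitroMovie:
    def _mt(self, length=15.0):
        return Microtubule(id=0, start=(2.0, 5.0), end=(2.0 + length, 5.0))

    def test_constant_speed_kinematics(self, quiet_optics):
        mt = self._mt()
        run = RunSpec(id=0, mt_id=0, speed=0.5, start_time=0.0,
                      duration=10.0, start_s=1.0)
        movie, truth = make_invitro_movie([mt], [run], quiet_optics,
                                          frame_interval=1.0, n_frames=11,
                                          field_size=(128, 256), seed=0)
        pos = truth.positions.sort_values("frame")
        disp = pos["s_um"].iloc[-1] - pos["s_um"].iloc[0]
        assert disp == pytest.approx(5.0, abs=1e-9)
        # collinear with the (horizontal) microtubule
        assert pos["y_um"].nunique() == 1

    def test_run_exceeding_mt_without_end_behaviour_raises(self,
                                                           quiet_optics):
        mt = self._mt(length=3.0)
        run = RunSpec(id=0, mt_id=0, speed=1.0, start_time=0.0,
                      duration=10.0, start_s=0.0)
        with pytest.raises(ValidationError, match="end_behaviour"):
            make_invitro_movie([mt], [run], quiet_optics, 1.0, 12,
                               (128, 256), seed=0)

    def test_reach_end_stop_parks_at_tip(self, quiet_optics):
        mt = self._mt(length=5.0)
        run = RunSpec(id=0, mt_id=0, speed=1.0, start_time=0.0,
                      duration=20.0, start_s=0.0,
                      end_behaviour="reach_end_stop")
        movie, truth = make_invitro_movie([mt], [run], quiet_optics, 1.0,
                                          15, (128, 256), seed=0)
        tail = truth.positions.query("frame >= 6")
        assert np.allclose(tail["s_um"], 5.0)

    def test_planted_speed_distribution(self, default_optics):
        rng = np.random.default_rng(0)
        speeds = rng.normal(0.66, 0.14, 20).clip(0.05)
        mts = [Microtubule(id=i, start=(2.0, 2.0 + i), end=(22.0, 2.0 + i))
               for i in range(20)]
        runs = [RunSpec(id=i, mt_id=i, speed=float(speeds[i]),
                        start_time=0.0, duration=12.0, start_s=1.0,
                        end_behaviour="reach_end_stop")
                for i in range(20)]
        _, truth = make_invitro_movie(mts, runs, default_optics, 1.0, 16,
                                      (256, 256), seed=1)
        se = 0.14 / np.sqrt(20)
        assert abs(truth.runs["speed"].mean() - 0.66) < 3 * se + \
            abs(speeds.mean() - truth.runs["speed"].mean()) + 1e-12
        assert truth.runs["speed"].mean() == pytest.approx(speeds.mean())


class TestTrajectories:
    def test_active_net_displacement(self):
        plan = TrajectoryPlan(dt=0.1, segments=[
            SegmentSpec("active", 60.0, dict(v=0.61))],
            localization_noise_sd=0.0)
        obs, truth = make_trajectory_set(plan, 1, seed=0)
        xy = obs[["x_um", "y_um"]].to_numpy()
        net = np.hypot(*(xy[-1] - xy[0]))
        assert net == pytest.approx(36.6, rel=1e-9)

    def test_diffusion_msd_law(self):
        plan = TrajectoryPlan(dt=0.1, segments=[
            SegmentSpec("normal_diffusion", 100.0, dict(D=0.05))])
        obs, _ = make_trajectory_set(plan, 1, seed=5)
        xy = obs[["x_um", "y_um"]].to_numpy()
        lags = np.arange(1, 11)
        msd = [np.mean(np.sum((xy[l:] - xy[:-l]) ** 2, axis=1))
               for l in lags]
        slope = np.polyfit(lags * 0.1, msd, 1)[0]
        assert slope == pytest.approx(4 * 0.05, rel=0.15)

    def test_subdiffusion_exponent_below_09(self):
        plan = TrajectoryPlan(dt=0.1, segments=[
            SegmentSpec("subdiffusion", 60.0, dict(D=0.05, H=0.3))])
        obs, _ = make_trajectory_set(plan, 3, seed=6)
        lags = np.arange(1, 11)
        for _, g in obs.groupby("track_id"):
            xy = g[["x_um", "y_um"]].to_numpy()
            msd = [np.mean(np.sum((xy[l:] - xy[:-l]) ** 2, axis=1))
                   for l in lags]
            expo = np.polyfit(np.log(lags), np.log(msd), 1)[0]
            assert expo < 0.9

    def test_confined_never_leaves_disc(self):
        plan = TrajectoryPlan(dt=0.1, segments=[
            SegmentSpec("confined", 50.0, dict(L=0.2, D=0.05))])
        _, truth = make_trajectory_set(plan, 2, seed=7)
        for _, g in truth.points.groupby("track_id"):
            p = g[["x_um", "y_um"]].to_numpy()
            r = np.hypot(p[:, 0] - p[0, 0], p[:, 1] - p[0, 1])
            assert r.max() <= 0.2 + 1e-9

    def test_per_point_truth_labels_cover_every_frame(self):
        plan = TrajectoryPlan(dt=0.1, segments=[
            SegmentSpec("active", 2.0, dict(v=0.5)),
            SegmentSpec("normal_diffusion", 2.0, dict(D=0.02))])
        obs, truth = make_trajectory_set(plan, 4, seed=8)
        assert len(obs) == len(truth.points)
        assert set(truth.points["state"]) == {"active", "normal_diffusion"}

    @pytest.mark.parametrize("state,params", [
        ("active", dict(v=-0.1)),
        ("normal_diffusion", dict(D=0.0)),
        ("confined", dict(L=-1.0, D=0.05)),
        ("subdiffusion", dict(D=0.05, H=0.7)),
    ])
    def test_invalid_segment_params_raise(self, state, params):
        with pytest.raises(ValidationError):
            SegmentSpec(state, 1.0, params)

    def test_invalid_dt_raises(self):
        with pytest.raises(ValidationError):
            TrajectoryPlan(dt=0.0, segments=[
                SegmentSpec("active", 1.0, dict(v=0.5))])

    def test_determinism(self):
        plan = TrajectoryPlan(dt=0.1, segments=[
            SegmentSpec("normal_diffusion", 5.0, dict(D=0.02))])
        a, _ = make_trajectory_set(plan, 3, seed=9, origin_span_um=50.0)
        b, _ = make_trajectory_set(plan, 3, seed=9, origin_span_um=50.0)
        pd.testing.assert_frame_equal(a, b)


class TestCellScene:
    square = [(0.0, 0.0), (20.0, 0.0), (20.0, 20.0), (0.0, 20.0)]

    def test_uniform_square_peripheral_fraction(self):
        _, spots, _ = make_cell_scene(self.square, {"uniform": 10000},
                                      0.1, seed=9)
        frac = (spots["region"] == "peripheral").mean()
        assert frac == pytest.approx(0.75, abs=0.02)

    def test_all_spots_at_centroid_are_interior(self):
        _, spots, _ = make_cell_scene(self.square,
                                      {"at": [(10.0, 10.0)] * 5}, 0.1,
                                      seed=0)
        assert (spots["region"] == "interior").all()

    def test_zero_spots_is_not_an_error(self):
        _, spots, _ = make_cell_scene(self.square, {"uniform": 0}, 0.1,
                                      seed=0)
        assert spots.empty

    def test_self_intersecting_polygon_raises(self):
        bowtie = [(0, 0), (10, 10), (10, 0), (0, 10)]
        with pytest.raises(ValidationError, match="simple"):
            make_cell_scene(bowtie, {"uniform": 1}, 0.1, seed=0)

    def test_planted_interior_peripheral_counts(self):
        _, spots, _ = make_cell_scene(self.square,
                                      {"interior": 70, "peripheral": 30},
                                      0.1, seed=11)
        assert (spots["region"] == "peripheral").sum() == 30
        assert (spots["region"] == "interior").sum() == 70
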