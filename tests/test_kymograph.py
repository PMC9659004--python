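"""Kymograph reconstruction, run extraction, motility rates, summaries."""

import numpy as np
import pandas as pd
import pytest

from virocount import (AnalysisConfig, Microtubule, OpticsModel, RunSpec,
                       ValidationError, build_kymograph, extract_runs,
                       make_invitro_movie, motility_rate, summarize_runs)
from virocount.kymograph import Run, traces_from_detections
from virocount.pipeline import analyse_invitro_movie, default_invitro_scene


def _trace(t, s):
    return pd.DataFrame(dict(frame=np.arange(len(t)), t=t, s_um=s))


class TestBuildKymograph:
    def _movie(self, speeds, n_frames=16, seed=0,
               optics=OpticsModel(read_noise_sd=0.0, shot_noise=False,
                                  background_level=10.0)):
        mt = Microtubule(id=0, start=(2.0, 5.0), end=(22.0, 5.0))
        runs = [RunSpec(id=i, mt_id=0, speed=v, start_time=0.0,
                        duration=12.0, start_s=1.0 + 6.0 * i,
                        end_behaviour="reach_end_stop")
                for i, v in enumerate(speeds)]
        movie, truth = make_invitro_movie([mt], runs, optics, 1.0,
                                          n_frames, (128, 256), seed=seed)
        return movie, mt

    def test_static_spot_is_a_vertical_stripe(self):
        movie, mt = self._movie([0.0])
        k = build_kymograph(movie, [mt.start, mt.end], 3, 0.1, 1.0)
        cols = np.argmax(k.data, axis=1)
        assert np.all(cols == cols[0])

    def test_moving_spot_slope_matches_speed(self):
        movie, mt = self._movie([0.5])
        k = build_kymograph(movie, [mt.start, mt.end], 3, 0.1, 1.0)
        pos = np.argmax(k.data, axis=1)[:13] * k.pixel_size
        slope = np.polyfit(np.arange(13) * 1.0, pos, 1)[0]
        assert slope == pytest.approx(0.5, rel=0.03)

    def test_empty_movie_is_pure_background(self):
        optics = OpticsModel(read_noise_sd=0.0, shot_noise=False,
                             background_level=10.0, camera_offset=100.0)
        movie, _ = make_invitro_movie(
            [Microtubule(id=0, start=(2.0, 5.0), end=(22.0, 5.0))], [],
            optics, 1.0, 5, (128, 256), seed=0)
        k = build_kymograph(movie, [(2.0, 5.0), (22.0, 5.0)], 3, 0.1, 1.0)
        assert np.allclose(k.data, 110.0)

    def test_path_outside_image_names_sample(self):
        movie = np.zeros((3, 64, 64))
        with pytest.raises(ValidationError, match="sample"):
            build_kymograph(movie, [(1.0, 1.0), (20.0, 1.0)], 3, 0.1, 1.0)


class TestExtractRuns:
    def test_constant_speed_trace_yields_one_accurate_run(self):
        t = np.arange(16.0)
        s = np.minimum(t, 12.0) * 0.66 + 1.0
        runs = extract_runs(_trace(t, s), 1.0)
        assert len(runs) == 1
        assert runs[0].velocity == pytest.approx(0.66, abs=0.01)
        assert runs[0].run_length == pytest.approx(0.66 * 12, rel=0.1)

    def test_zero_speed_trace_yields_no_runs(self):
        t = np.arange(20.0)
        runs = extract_runs(_trace(t, np.full(20, 3.0)), 1.0)
        assert runs == []

    def test_run_parking_at_tip_is_reached_end(self):
        mt = Microtubule(id=0, start=(0.0, 0.0), end=(10.0, 0.0))
        t = np.arange(20.0)
        s = np.minimum(1.0 + 0.66 * t, 10.0)  # parks at the plus end
        runs = extract_runs(_trace(t, s), 1.0, mt=mt)
        assert len(runs) == 1
        assert runs[0].end_fate == "reached_end"
        assert runs[0].direction == "plus"
        # the stationary tail is not part of the run length
        assert runs[0].run_length <= 9.0 + 1e-9

    def test_short_trace_gives_no_runs(self):
        t = np.arange(2.0)
        assert extract_runs(_trace(t, t * 1.0), 1.0) == []

    @pytest.mark.parametrize("speed", [0.1, 0.5, 1.0, 2.0, 3.0])
    def test_slope_fidelity_across_speed_range(self, speed):
        optics = OpticsModel()
        mt = Microtubule(id=0, start=(2.0, 5.0), end=(23.0, 5.0))
        duration = min(12.0, 18.0 / speed)
        run = RunSpec(id=0, mt_id=0, speed=speed, start_time=0.0,
                      duration=duration, start_s=0.5,
                      end_behaviour="reach_end_stop")
        n_frames = int(duration) + 4
        movie, _ = make_invitro_movie([mt], [run], optics, 1.0, n_frames,
                                      (128, 256), seed=3)
        # near the default 0.1 um/s threshold the operator would lower it
        cfg = AnalysisConfig(speed_threshold=0.05 if speed <= 0.2 else 0.1)
        runs, _ = analyse_invitro_movie(movie, [mt], cfg)
        assert len(runs) == 1
        tol = max(0.03, 0.25 / (duration * speed))  # localisation floor
        assert runs[0].velocity == pytest.approx(speed, rel=tol)


class TestRates:
    def test_rate_arithmetic(self):
        assert motility_rate(10, 5.0, 2.0) == pytest.approx(1.0)
        assert motility_rate(0, 7.0, 3.0) == 0.0

    def test_rate_validation(self):
        with pytest.raises(ValidationError):
            motility_rate(1, 0.0, 1.0)
        with pytest.raises(ValidationError):
            motility_rate(1, 1.0, 0.0)

    def test_rate_additivity_over_fields(self):
        # two fields pooled: counts add, minutes x mm add
        n1, n2 = 12, 5
        m1, m2 = 10.0, 4.0
        l1, l2 = 1.5, 0.5
        pooled = (n1 + n2) / (m1 * l1 + m2 * l2)
        r1 = motility_rate(n1, m1, l1)
        r2 = motility_rate(n2, m2, l2)
        combined = (r1 * m1 * l1 + r2 * m2 * l2) / (m1 * l1 + m2 * l2)
        assert combined == pytest.approx(pooled)

    def test_planted_run_count_rate(self):
        assert motility_rate(12, 10.0, 1.5) == pytest.approx(0.8)


class TestSummaries:
    def test_all_plus_runs_are_100_percent_plus(self):
        runs = [Run(virion_id=i, velocity=0.6, run_length=5.0,
                    direction="plus", end_fate="not_reached")
                for i in range(5)]
        assert summarize_runs(runs)["percent_plus"] == 100.0

    def test_96_of_100_plus_directed(self):
        runs = [Run(virion_id=i, velocity=0.6, run_length=5.0,
                    direction="plus" if i < 96 else "minus",
                    end_fate="not_reached") for i in range(100)]
        assert summarize_runs(runs)["percent_plus"] == pytest.approx(96.0)

    def test_unknown_polarity_gives_nan_percent_plus(self):
        runs = [Run(virion_id=0, velocity=0.6, run_length=5.0,
                    direction="unknown", end_fate="not_discernible")]
        out = summarize_runs(runs)
        assert np.isnan(out["percent_plus"])
        assert out["percent_not_discernible"] == 100.0

    def test_no_runs_status(self):
        assert summarize_runs([])["status"] == "no runs"


class TestTraces:
    def test_detections_project_onto_correct_microtubule(self):
        mts = [Microtubule(id=0, start=(0.0, 0.0), end=(10.0, 0.0)),
               Microtubule(id=1, start=(0.0, 5.0), end=(10.0, 5.0))]
        det = pd.DataFrame(dict(
            frame=[0, 0, 1, 1],
            x_um=[2.0, 3.0, 2.5, 3.5],
            y_um=[0.05, 5.02, -0.04, 4.98]))
        traces = traces_from_detections(det, mts, 1.0)
        assert set(traces) == {0, 1}
        assert np.allclose(traces[0]["s_um"], [2.0, 2.5])
        assert np.allclose(traces[1]["s_um"], [3.0, 3.5])
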