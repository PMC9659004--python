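"""End-to-end workflows with config, seed control and provenance.

Two workflows tie the stages together:

* :func:`run_motor_counting` — nanocage standards → calibration curve →
  virion intensity cohorts → molecule / complex counts →
  expression-corrected means → surface densities.
* :func:`run_motility` — in vitro movie → traces → runs → velocity /
  motility-rate summaries, and in-cell trajectories → linking → filtering
  → motion-state segmentation → active-transport statistics.

Both are deterministic given the config seed and write a manifest
(parameters, seed, package version) alongside every report.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calibration as cal
from . import geometry, kymograph, spots, tracking
from .errors import ValidationError
from .synthetic import (Microtubule, OpticsModel, RunSpec, SegmentSpec,
                        TrajectoryPlan, make_invitro_movie, make_spot_scene,
                        make_trajectory_set)

__all__ = ["AnalysisConfig", "run_motor_counting", "run_motility"]

__version__ = "0.1.0"


@dataclass
class AnalysisConfig:
    """All tunable parameters of the pipeline with their defaults.

    Distance/time defaults follow the acquisition they model: 0.8 µm
    linking distance with 5-frame gap closing and a >1 µm track
    displacement filter for 10 Hz in-cell tracking; 8/10 px concentric
    measurement discs; the >3 µm-in-60 s motile rule; a 5 µm peripheral
    band. Simulation cohort sizes default to the study's n.
    """

    seed: int = 0
    out_dir: str | None = None

    # optics / camera for all simulated scenes
    optics: OpticsModel = field(default_factory=OpticsModel)

    # detection + concentric-ROI measurement
    spot_diameter_px: float = 5.0
    detection_threshold: float = 30.0
    inner_diameter_px: float = 8.0
    outer_diameter_px: float = 10.0

    # calibration standards and virion cohorts
    standard_copy_numbers: tuple[float, ...] = (24.0, 60.0, 120.0, 180.0)
    n_spots_per_standard: int = 50
    imv_molecules: float = 130.0
    iev_molecules: float = 230.0
    n_imv: int = 84
    n_iev: int = 121
    cohort_copy_number_cv: float = 0.5
    imv_fold: float = 2.14
    iev_fold: float = 2.78
    n_expression_cohort: int = 100

    # virion geometry (full axes, nm)
    imv_dims: tuple[float, float, float] = (350.0, 280.0, 200.0)
    iev_dims: tuple[float, float, float] = (440.0, 380.0, 260.0)

    # in-cell tracking (10 Hz)
    dt_cell: float = 0.1
    max_link_um: float = 0.8
    max_gap_frames: int = 5
    min_track_displacement_um: float = 1.0
    motile_min_displacement_um: float = 3.0
    motile_window_s: float = 60.0
    classify_window: int = 15
    min_segment_frames: int = 5
    localization_noise_sd_um: float = 0.02
    cell_active_speed: float = 0.61
    cell_diffusion_D: float = 0.01
    n_cell_tracks: int = 40

    # in vitro motility (1 frame/s)
    frame_interval_invitro: float = 1.0
    invitro_speed_mean: float = 0.66
    invitro_speed_sd: float = 0.14
    n_invitro_runs: int = 20
    run_duration_s: float = 12.0
    speed_threshold: float = 0.1
    min_run_duration_s: float = 3.0
    smooth_frames: int = 3
    line_width_px: int = 3
    end_tolerance_um: float = 0.5

    # peripheral spread
    band_um: float = 5.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        if isinstance(d.get("optics"), dict):
            d["optics"] = OpticsModel(**d["optics"])
        for key in ("standard_copy_numbers", "imv_dims", "iev_dims"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        d = self.to_dict()
        for key in ("standard_copy_numbers", "imv_dims", "iev_dims"):
            d[key] = list(d[key])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# shared measurement helper
# ---------------------------------------------------------------------------

def measure_scene_cohort(image: np.ndarray, config: AnalysisConfig
                         ) -> np.ndarray:
    """Detect spots in one field and return their corrected intensities.

    Border-clipped and crowded spots are dropped, matching how calibration
    cohorts are curated.
    """
    det = spots.detect_spots(image, config.spot_diameter_px,
                             config.detection_threshold)
    if det.empty:
        return np.array([])
    meas = spots.measure_spots(image, det, config.inner_diameter_px,
                               config.outer_diameter_px)
    ok = meas[meas["valid"] & ~meas["crowded"]]
    return ok["corrected_intensity"].to_numpy(dtype=float)


def _simulated_intensity_cohort(copy_number: float, n: int, cv: float,
                                config: AnalysisConfig, seed_seq) -> np.ndarray:
    """Simulate fields of one species and measure them; splits large
    cohorts over several fields."""
    per_field = 50
    out = []
    remaining = n
    children = seed_seq.spawn(int(np.ceil(n / per_field)))
    for child in children:
        k = min(per_field, remaining)
        images, _ = make_spot_scene([(copy_number, k, 0)], config.optics,
                                    field_size=(256, 256), seed=child,
                                    copy_number_cv=cv)
        out.append(measure_scene_cohort(images[0], config))
        remaining -= k
    return np.concatenate(out) if out else np.array([])


# ---------------------------------------------------------------------------
# motor-counting workflow
# ---------------------------------------------------------------------------

def run_motor_counting(config: AnalysisConfig) -> dict:
    """Simulate standards and virion cohorts, then count motors end to end.

    Returns a report dict with the calibration curve, per-cohort molecule
    and complex counts, expression-corrected means, and surface densities.
    Deterministic given ``config.seed``.
    """
    ss = np.random.SeedSequence(config.seed)
    (ss_std, ss_imv, ss_iev, ss_ref_imv, ss_tag_imv,
     ss_ref_iev, ss_tag_iev) = ss.spawn(7)

    # 1. calibration standards, one species per field batch
    standards = []
    for cn, child in zip(config.standard_copy_numbers,
                         ss_std.spawn(len(config.standard_copy_numbers))):
        vals = _simulated_intensity_cohort(cn, config.n_spots_per_standard,
                                           0.0, config, child)
        standards.append((cn, vals))
    curve = cal.fit_calibration(standards)

    # 2. virion cohorts (tagged knock-in line)
    cohorts = {}
    for name, molecules, n, child, fold, fold_child_ref, fold_child_tag in (
        ("IMV", config.imv_molecules, config.n_imv, ss_imv,
         config.imv_fold, ss_ref_imv, ss_tag_imv),
        ("IEV", config.iev_molecules, config.n_iev, ss_iev,
         config.iev_fold, ss_ref_iev, ss_tag_iev),
    ):
        intens = _simulated_intensity_cohort(
            molecules, n, config.cohort_copy_number_cv, config, child)
        # antibody cohorts: parental reference is `fold`-fold brighter
        tag = _simulated_intensity_cohort(
            100.0, config.n_expression_cohort,
            config.cohort_copy_number_cv, config, fold_child_tag)
        ref = _simulated_intensity_cohort(
            100.0 * fold, config.n_expression_cohort,
            config.cohort_copy_number_cv, config, fold_child_ref)
        factor = cal.expression_correction_factor(ref, tag)
        cohorts[name] = cal.summarize_motor_counts(intens, curve, factor)

    dens = {}
    for name, dims in (("IMV", config.imv_dims), ("IEV", config.iev_dims)):
        area = geometry.ellipsoid_surface_area(
            geometry.EllipsoidDims(*dims))
        n_cpx = cohorts[name].corrected_mean_complexes
        dens[name] = dict(surface_area_nm2=area,
                          n_complexes=n_cpx,
                          nm2_per_complex=geometry.area_per_motor(area,
                                                                  n_cpx))

    report = dict(
        calibration=dict(
            slope=curve.slope, r_squared=curve.r_squared,
            species=curve.species.to_dict(orient="records")),
        cohorts={
            name: dict(
                n=len(r.molecules),
                mean_molecules=r.mean_molecules,
                sem_molecules=r.sem_molecules,
                mean_complexes=r.mean_complexes,
                sem_complexes=r.sem_complexes,
                correction_factor=r.correction_factor,
                corrected_mean_complexes=r.corrected_mean_complexes,
                n_negative=r.n_negative)
            for name, r in cohorts.items()},
        geometry=dens,
        manifest=_manifest(config, "motor_counting"),
    )
    _maybe_write(report, config, "motor_counting_report.json")
    return report


# ---------------------------------------------------------------------------
# motility workflow
# ---------------------------------------------------------------------------

def default_invitro_scene(config: AnalysisConfig, speeds=None,
                          seed_seq=None):
    """Build the default in vitro field: one run per horizontal microtubule.

    ``speeds`` overrides the per-run speeds (default: normal around
    ``invitro_speed_mean``). Returns (movie, truth, mts).
    """
    ss = seed_seq or np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    px = config.optics.pixel_size
    field = (256, 256)
    mt_len = (field[1] - 40) * px  # leave margin for PSF and ROIs
    n = config.n_invitro_runs
    spacing = (field[0] - 40) * px / max(n, 1)
    mts = [Microtubule(id=i, start=(20 * px, (20 + i * spacing / px) * px),
                       end=(20 * px + mt_len, (20 + i * spacing / px) * px))
           for i in range(n)]
    if speeds is None:
        speeds = np.clip(rng.normal(config.invitro_speed_mean,
                                    config.invitro_speed_sd, n), 0.05, None)
    runs = [RunSpec(id=i, mt_id=i, speed=float(speeds[i]), start_time=0.0,
                    duration=config.run_duration_s, direction="plus",
                    end_behaviour="reach_end_stop",
                    start_s=float(rng.uniform(0.5, 2.0)))
            for i in range(n)]
    n_frames = int(np.ceil(config.run_duration_s /
                           config.frame_interval_invitro)) + 4
    movie, truth = make_invitro_movie(mts, runs, config.optics,
                                      config.frame_interval_invitro,
                                      n_frames, field,
                                      seed=int(rng.integers(2 ** 31)))
    return movie, truth, mts


def analyse_invitro_movie(movie: np.ndarray, mts, config: AnalysisConfig
                          ) -> tuple[list, dict]:
    """Detect → project → extract runs for one in vitro movie."""
    det_rows = []
    for k in range(movie.shape[0]):
        d = spots.detect_spots(movie[k], config.spot_diameter_px,
                               config.detection_threshold)
        d["frame"] = k
        d["x_um"] = d["x"] * config.optics.pixel_size
        d["y_um"] = d["y"] * config.optics.pixel_size
        det_rows.append(d)
    detections = pd.concat(det_rows, ignore_index=True) \
        if det_rows else pd.DataFrame(columns=["frame", "x_um", "y_um"])
    traces = kymograph.traces_from_detections(
        detections, mts, config.frame_interval_invitro)
    movie_duration = (movie.shape[0] - 1) * config.frame_interval_invitro
    mt_by_id = {m.id: m for m in mts}
    all_runs = []
    for mt_id, trace in traces.items():
        all_runs.extend(kymograph.extract_runs(
            trace, config.frame_interval_invitro,
            config.min_run_duration_s, config.speed_threshold,
            config.smooth_frames, virion_id=mt_id, mt=mt_by_id[mt_id],
            end_tolerance=config.end_tolerance_um,
            movie_duration=movie_duration))
    summary = kymograph.summarize_runs(all_runs)
    return all_runs, summary


def default_cell_plan(config: AnalysisConfig, n_cycles: int = 5
                      ) -> TrajectoryPlan:
    """Alternating active (3 s) / normal diffusion (3 s) plan at 10 Hz."""
    segs = []
    for _ in range(n_cycles):
        segs.append(SegmentSpec("active", 3.0,
                                dict(v=config.cell_active_speed)))
        segs.append(SegmentSpec("normal_diffusion", 3.0,
                                dict(D=config.cell_diffusion_D)))
    return TrajectoryPlan(dt=config.dt_cell, segments=tuple(segs),
                          localization_noise_sd=config.localization_noise_sd_um)


def analyse_cell_tracks(observations: pd.DataFrame, config: AnalysisConfig
                        ) -> dict:
    """Link → filter → classify → summarise in-cell detections."""
    tracks = tracking.link_spots(
        observations[["frame", "x_um", "y_um"]],
        config.max_link_um, config.max_gap_frames)
    tracks = tracking.filter_by_displacement(
        tracks, config.min_track_displacement_um)
    if tracks.empty:
        return dict(active=tracking.active_transport_stats([]),
                    n_tracks=0, n_motile=0)
    labelled, segments = tracking.classify_tracks(
        tracks, config.dt_cell, window=config.classify_window,
        min_segment=config.min_segment_frames,
        localization_sd=config.localization_noise_sd_um)
    active = tracking.active_transport_stats(segments)
    n_motile = tracking.count_motile(
        tracks, config.dt_cell, config.motile_min_displacement_um,
        config.motile_window_s)
    return dict(active=active, n_tracks=int(tracks["track_id"].nunique()),
                n_motile=n_motile, segments=segments, tracks=labelled)


def run_motility(config: AnalysisConfig) -> dict:
    """Full motility workflow on default synthetic scenes.

    In vitro: one field of constant-speed runs → run extraction, velocity
    summary and motility rate. In cells: alternating active/diffusive
    trajectories → tracking, segmentation, active-run statistics and the
    >3 µm/60 s motile count. Deterministic given ``config.seed``.
    """
    ss = np.random.SeedSequence(config.seed)
    ss_vitro, ss_cell = ss.spawn(2)

    movie, truth, mts = default_invitro_scene(config, seed_seq=ss_vitro)
    runs, vitro_summary = analyse_invitro_movie(movie, mts, config)
    minutes = (movie.shape[0] - 1) * config.frame_interval_invitro / 60.0
    mt_mm = sum(m.length for m in mts) / 1000.0
    rate = kymograph.motility_rate(vitro_summary["n"], minutes, mt_mm)

    plan = default_cell_plan(config)
    obs, cell_truth = make_trajectory_set(
        plan, config.n_cell_tracks,
        seed=int(np.random.default_rng(ss_cell).integers(2 ** 31)),
        origin_span_um=10.0 * config.n_cell_tracks)
    cell = analyse_cell_tracks(obs, config)

    report = dict(
        in_vitro=dict(summary={k: v for k, v in vitro_summary.items()},
                      motility_rate_per_min_per_mm=rate,
                      imaging_minutes=minutes,
                      total_mt_length_mm=mt_mm),
        in_cells=dict(
            n_tracks=cell["n_tracks"], n_motile=cell["n_motile"],
            mean_active_velocity=cell["active"]["mean_velocity"],
            sd_active_velocity=cell["active"]["sd_velocity"],
            mean_run_length=cell["active"]["mean_run_length"],
            sd_run_length=cell["active"]["sd_run_length"],
            n_active_runs=cell["active"]["n"],
            status=cell["active"]["status"]),
        manifest=_manifest(config, "motility"),
    )
    _maybe_write(report, config, "motility_report.json")
    return report


# ---------------------------------------------------------------------------
# provenance
# ---------------------------------------------------------------------------

def _manifest(config: AnalysisConfig, workflow: str) -> dict:
    return dict(workflow=workflow, seed=config.seed,
                package="virocount", version=__version__,
                parameters=config.to_dict())


def _maybe_write(report: dict, config: AnalysisConfig, name: str) -> None:
    if config.out_dir is None:
        return
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / name).write_text(json.dumps(report, indent=2, sort_keys=True,
                                       default=_json_default))
    config.to_yaml(out / "config.yaml")


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"cannot serialise {type(obj)!r}")
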