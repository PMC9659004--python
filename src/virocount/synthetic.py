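"""Synthetic microscopy scenes with ground truth.

Four generators cover the stages of the pipeline:

* :func:`make_spot_scene` — fields of diffraction-limited spots whose
  integrated flux encodes a known fluorophore copy number (nanocage
  calibration standards, virion cohorts), over flat or sloped backgrounds.
* :func:`make_invitro_movie` — time-lapse movies of virions translocating at
  constant speed along straight microtubules (in vitro motility assay).
* :func:`make_trajectory_set` — 2-D point trajectories alternating active
  transport, normal diffusion, subdiffusion and confinement (in-cell
  tracking at ~10 Hz).
* :func:`make_cell_scene` — rasterised cell masks with interior/peripheral
  virion point patterns (peripheral-spread assay).

Every rendered object has exactly one record in the returned
:class:`SceneTruth`, so downstream detection, calibration, tracking,
kymograph and spread analyses can all be scored against known truth.

Conventions: pixel centres sit at integer pixel coordinates, origin at the
top-left pixel centre, 0-based; positions are stored in µm with
``pixel_size`` converting to px. Images are float64 arrays in camera counts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import erf

from .errors import PlacementError, ValidationError

__all__ = [
    "OpticsModel",
    "SceneTruth",
    "Microtubule",
    "RunSpec",
    "SegmentSpec",
    "TrajectoryPlan",
    "make_spot_scene",
    "make_virion_scene",
    "make_invitro_movie",
    "make_trajectory_set",
    "make_cell_scene",
]

MOTION_STATES = ("active", "normal_diffusion", "subdiffusion", "confined")


# ---------------------------------------------------------------------------
# camera / optics model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OpticsModel:
    """Minimal camera + PSF model for rendering diffraction-limited spots.

    Parameters
    ----------
    pixel_size:
        Object-space pixel size, µm/px.
    psf_sigma:
        Isotropic Gaussian PSF standard deviation, px.
    photons_per_fluorophore:
        Expected integrated flux per fluorophore, photons.
    background_level:
        Uniform background, photons/px.
    background_gradient:
        Linear background ramp along x, photons/px per px (0 for flat).
    camera_offset:
        Constant camera offset added after gain, counts.
    read_noise_sd:
        Gaussian read noise standard deviation, counts.
    gain:
        Conversion factor, counts per photon.
    shot_noise:
        Apply per-pixel Poisson shot noise to the photon image. Disable for
        exact flux-conservation checks.
    """

    pixel_size: float = 0.1
    psf_sigma: float = 1.0
    photons_per_fluorophore: float = 100.0
    background_level: float = 50.0
    background_gradient: float = 0.0
    camera_offset: float = 100.0
    read_noise_sd: float = 2.0
    gain: float = 1.0
    shot_noise: bool = True

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValidationError("pixel_size must be > 0")
        if self.psf_sigma <= 0:
            raise ValidationError("psf_sigma must be > 0")
        if self.photons_per_fluorophore < 0:
            raise ValidationError("photons_per_fluorophore must be >= 0")
        if self.read_noise_sd < 0:
            raise ValidationError("read_noise_sd must be >= 0")
        if self.gain <= 0:
            raise ValidationError("gain must be > 0")

    @property
    def counts_per_fluorophore(self) -> float:
        """Expected integrated counts per fluorophore (gain × photons)."""
        return self.gain * self.photons_per_fluorophore

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SceneTruth:
    """Ground truth emitted by every generator.

    Attributes
    ----------
    spots:
        One row per rendered spot: id, channel, x_px, y_px, x_um, y_um,
        copy_number and any scene-specific labels.
    runs:
        One row per planted in vitro transport event.
    positions:
        Per-frame true positions of moving objects (in vitro movies).
    points:
        Per-point motion-state labels for simulated trajectories.
    segments:
        Per-segment state parameters for simulated trajectories.
    meta:
        Generator parameters recorded for provenance (camera gain/offset
        included, since real instruments rarely report them).
    """

    spots: pd.DataFrame = field(default_factory=pd.DataFrame)
    runs: pd.DataFrame = field(default_factory=pd.DataFrame)
    positions: pd.DataFrame = field(default_factory=pd.DataFrame)
    points: pd.DataFrame = field(default_factory=pd.DataFrame)
    segments: pd.DataFrame = field(default_factory=pd.DataFrame)
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# rendering primitives
# ---------------------------------------------------------------------------

def _add_gaussian_spot(image: np.ndarray, x: float, y: float, flux: float,
                       sigma: float) -> None:
    """Add an integrated 2-D Gaussian of total ``flux`` photons in place.

    The flux in each pixel is the exact integral of the Gaussian over the
    pixel area (difference of error functions at the pixel edges), so the
    total rendered flux is unbiased on the pixel grid.
    """
    h, w = image.shape
    r = int(np.ceil(5.0 * sigma + 1.0))
    x0, x1 = max(0, int(np.floor(x)) - r), min(w - 1, int(np.ceil(x)) + r)
    y0, y1 = max(0, int(np.floor(y)) - r), min(h - 1, int(np.ceil(y)) + r)
    if x1 < x0 or y1 < y0:
        return
    s = sigma * np.sqrt(2.0)
    xs = np.arange(x0, x1 + 1, dtype=float)
    ys = np.arange(y0, y1 + 1, dtype=float)
    fx = 0.5 * (erf((xs + 0.5 - x) / s) - erf((xs - 0.5 - x) / s))
    fy = 0.5 * (erf((ys + 0.5 - y) / s) - erf((ys - 0.5 - y) / s))
    image[y0:y1 + 1, x0:x1 + 1] += flux * np.outer(fy, fx)


def _background(shape: tuple[int, int], optics: OpticsModel) -> np.ndarray:
    h, w = shape
    bg = np.full((h, w), float(optics.background_level))
    if optics.background_gradient:
        bg += optics.background_gradient * np.arange(w, dtype=float)[None, :]
    return bg


def _camera(photons: np.ndarray, optics: OpticsModel,
            rng: np.random.Generator) -> np.ndarray:
    """Apply shot noise, gain, offset and read noise; return counts."""
    if optics.shot_noise:
        photons = rng.poisson(np.clip(photons, 0, None)).astype(float)
    counts = optics.gain * photons + optics.camera_offset
    if optics.read_noise_sd > 0:
        counts = counts + rng.normal(0.0, optics.read_noise_sd, photons.shape)
    return counts


def _place_points(n: int, field_size: tuple[int, int], min_separation: float,
                  margin: float, rng: np.random.Generator,
                  existing: np.ndarray | None = None) -> np.ndarray:
    """Rejection-sample ``n`` (x, y) px positions with pairwise separation."""
    h, w = field_size
    if w - 2 * margin <= 0 or h - 2 * margin <= 0:
        raise PlacementError(
            f"field {w}x{h} px too small for margin {margin} px")
    pts: list[np.ndarray] = [] if existing is None else list(existing)
    placed: list[np.ndarray] = []
    max_tries = 2000 * max(n, 1)
    tries = 0
    while len(placed) < n:
        tries += 1
        if tries > max_tries:
            raise PlacementError(
                f"could not place {n} spots with min_separation="
                f"{min_separation} px in a {w}x{h} px field "
                f"(margin {margin} px): field too crowded")
        p = np.array([rng.uniform(margin, w - 1 - margin),
                      rng.uniform(margin, h - 1 - margin)])
        if pts:
            d = np.min(np.linalg.norm(np.asarray(pts) - p, axis=1))
            if d < min_separation:
                continue
        pts.append(p)
        placed.append(p)
    return np.asarray(placed).reshape(n, 2)


# ---------------------------------------------------------------------------
# spot scenes (calibration standards, virion cohorts)
# ---------------------------------------------------------------------------

def make_spot_scene(
    species_spec: Sequence[tuple[float, int, int]],
    optics: OpticsModel,
    field_size: tuple[int, int] = (256, 256),
    min_separation: float = 12.0,
    seed: int | np.random.SeedSequence = 0,
    copy_number_cv: float = 0.0,
    margin: float | None = None,
) -> tuple[dict[int, np.ndarray], SceneTruth]:
    """Render fields of spots with known fluorophore copy numbers.

    Parameters
    ----------
    species_spec:
        List of ``(copy_number, n_spots, channel)``. All spots of one scene
        share a coordinate frame; spots within a channel are separated by at
        least ``min_separation`` px.
    optics:
        Camera/PSF model.
    field_size:
        ``(height, width)`` of the field in px.
    min_separation:
        Minimum pairwise centre distance within a channel, px.
    seed:
        RNG seed; identical seeds give byte-identical scenes.
    copy_number_cv:
        Coefficient of variation for per-spot lognormal jitter of the true
        copy number (0 = monodisperse standards).

    Returns
    -------
    images, truth
        ``images`` maps channel → float64 count image; ``truth.spots`` has
        one row per spot (id, channel, x_px, y_px, x_um, y_um, copy_number).
    """
    ss = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    place_rng, jitter_rng, noise_rng = (
        np.random.default_rng(s) for s in ss.spawn(3))
    if margin is None:
        margin = max(8.0, 4.0 * optics.psf_sigma + 2.0)
    channels = sorted({ch for _, _, ch in species_spec})
    images = {ch: _background(field_size, optics) for ch in channels}
    rows = []
    spot_id = 0
    placed_by_channel: dict[int, list] = {ch: [] for ch in channels}
    for copy_number, n_spots, channel in species_spec:
        existing = (np.asarray(placed_by_channel[channel])
                    if placed_by_channel[channel] else None)
        pts = _place_points(n_spots, field_size, min_separation, margin,
                            place_rng, existing)
        placed_by_channel[channel].extend(pts)
        for x, y in pts:
            cn = float(copy_number)
            if copy_number_cv > 0:
                sd = np.sqrt(np.log1p(copy_number_cv ** 2))
                cn *= jitter_rng.lognormal(-0.5 * sd ** 2, sd)
            flux = cn * optics.photons_per_fluorophore
            _add_gaussian_spot(images[channel], x, y, flux, optics.psf_sigma)
            rows.append(dict(id=spot_id, channel=channel, x_px=x, y_px=y,
                             x_um=x * optics.pixel_size,
                             y_um=y * optics.pixel_size,
                             copy_number=cn))
            spot_id += 1
    for ch in channels:
        images[ch] = _camera(images[ch], optics, noise_rng)
    truth = SceneTruth(
        spots=pd.DataFrame(rows),
        meta=dict(generator="make_spot_scene", optics=optics.to_dict(),
                  field_size=tuple(field_size),
                  min_separation=min_separation,
                  copy_number_cv=copy_number_cv),
    )
    return images, truth


def make_virion_scene(
    n_virions: int,
    n_with_motor: int,
    motor_copy_number: float,
    optics: OpticsModel,
    virion_copy_number: float = 300.0,
    field_size: tuple[int, int] = (256, 256),
    min_separation: float = 12.0,
    seed: int = 0,
    copy_number_cv: float = 0.0,
) -> tuple[dict[int, np.ndarray], SceneTruth]:
    """Two-channel scene: virions in channel 0, motor signal in channel 1.

    ``n_with_motor`` of the ``n_virions`` virions carry a colocalised motor
    spot of ``motor_copy_number`` fluorophores; the rest have no channel-1
    signal. ``truth.spots`` (channel 0 rows) carries a ``has_motor`` column.
    """
    if not 0 <= n_with_motor <= n_virions:
        raise ValidationError("need 0 <= n_with_motor <= n_virions")
    ss = np.random.SeedSequence(seed)
    place_rng, jitter_rng, noise_rng, pick_rng = (
        np.random.default_rng(s) for s in ss.spawn(4))
    margin = max(8.0, 4.0 * optics.psf_sigma + 2.0)
    pts = _place_points(n_virions, field_size, min_separation, margin,
                        place_rng)
    with_motor = np.zeros(n_virions, dtype=bool)
    with_motor[pick_rng.choice(n_virions, n_with_motor, replace=False)] = True
    im0 = _background(field_size, optics)
    im1 = _background(field_size, optics)
    rows = []
    for i, (x, y) in enumerate(pts):
        _add_gaussian_spot(im0, x, y, virion_copy_number *
                           optics.photons_per_fluorophore, optics.psf_sigma)
        cn = 0.0
        if with_motor[i]:
            cn = float(motor_copy_number)
            if copy_number_cv > 0:
                sd = np.sqrt(np.log1p(copy_number_cv ** 2))
                cn *= jitter_rng.lognormal(-0.5 * sd ** 2, sd)
            _add_gaussian_spot(im1, x, y, cn * optics.photons_per_fluorophore,
                               optics.psf_sigma)
        rows.append(dict(id=i, channel=0, x_px=x, y_px=y,
                         x_um=x * optics.pixel_size,
                         y_um=y * optics.pixel_size,
                         copy_number=cn, has_motor=bool(with_motor[i])))
    images = {0: _camera(im0, optics, noise_rng),
              1: _camera(im1, optics, noise_rng)}
    truth = SceneTruth(
        spots=pd.DataFrame(rows),
        meta=dict(generator="make_virion_scene", optics=optics.to_dict(),
                  n_virions=n_virions, n_with_motor=n_with_motor),
    )
    return images, truth


# ---------------------------------------------------------------------------
# in vitro motility movies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Microtubule:
    """A straight microtubule segment in the field, µm coordinates.

    ``start`` is the minus end and ``end`` the plus end unless ``polarity``
    is flipped; arclength s runs from 0 at ``start`` to ``length`` at
    ``end``.
    """

    id: int
    start: tuple[float, float]
    end: tuple[float, float]
    polarity: Literal["plus_at_end", "plus_at_start"] = "plus_at_end"

    @property
    def length(self) -> float:
        return float(np.hypot(self.end[0] - self.start[0],
                              self.end[1] - self.start[1]))

    def point_at(self, s: float) -> tuple[float, float]:
        """Position (µm) at arclength ``s`` from ``start``."""
        t = s / self.length
        return (self.start[0] + t * (self.end[0] - self.start[0]),
                self.start[1] + t * (self.end[1] - self.start[1]))


@dataclass(frozen=True)
class RunSpec:
    """One planted transport event along a microtubule.

    ``direction`` is relative to the microtubule plus end; speed is µm/s.
    ``end_behaviour`` controls what happens if the virion reaches a tip:
    ``reach_end_stop`` parks it there for the rest of the movie,
    ``detach`` removes it. ``None`` asserts the run fits on the lattice.
    """

    id: int
    mt_id: int
    speed: float
    start_time: float
    duration: float
    direction: Literal["plus", "minus"] = "plus"
    end_behaviour: Literal["reach_end_stop", "detach"] | None = None
    start_s: float = 0.0
    copy_number: float = 200.0

    def __post_init__(self) -> None:
        if self.speed < 0:
            raise ValidationError("speed must be >= 0")
        if self.duration <= 0:
            raise ValidationError("duration must be > 0")


def _run_position(run: RunSpec, mt: Microtubule, t: float):
    """True arclength of the run's virion at time ``t`` (None if absent)."""
    if t < run.start_time:
        return None, False
    plus_is_forward = (mt.polarity == "plus_at_end")
    sign = 1.0 if (run.direction == "plus") == plus_is_forward else -1.0
    t_move = min(t - run.start_time, run.duration)
    s = run.start_s + sign * run.speed * t_move
    moving = (t - run.start_time) <= run.duration
    if s < 0 or s > mt.length:
        if run.end_behaviour == "reach_end_stop":
            return float(np.clip(s, 0.0, mt.length)), False
        if run.end_behaviour == "detach":
            return None, False
        raise ValidationError(
            f"run {run.id} leaves microtubule {mt.id} "
            f"(s={s:.2f} µm, length {mt.length:.2f} µm) and has no "
            "end_behaviour")
    if not moving and run.end_behaviour == "detach":
        return None, False
    return float(s), moving


def make_invitro_movie(
    mt_layout: Sequence[Microtubule],
    run_plan: Sequence[RunSpec],
    optics: OpticsModel,
    frame_interval: float = 1.0,
    n_frames: int = 20,
    field_size: tuple[int, int] = (256, 256),
    seed: int = 0,
) -> tuple[np.ndarray, SceneTruth]:
    """Render a movie of virions moving at constant speed along microtubules.

    Returns ``(movie, truth)`` with movie shaped ``(n_frames, h, w)`` in
    counts. ``truth.runs`` holds the planted run parameters and
    ``truth.positions`` the per-frame true positions (µm and arclength).
    A planted speed of 0 emulates the AMPPNP rigor control.
    """
    if frame_interval <= 0:
        raise ValidationError("frame_interval must be > 0")
    mts = {mt.id: mt for mt in mt_layout}
    for run in run_plan:
        if run.mt_id not in mts:
            raise ValidationError(f"run {run.id} references unknown mt "
                                  f"{run.mt_id}")
        # validate full kinematics up front so errors fire before rendering
        _run_position(run, mts[run.mt_id],
                      run.start_time + run.duration)
    ss = np.random.SeedSequence(seed)
    noise_rng = np.random.default_rng(ss.spawn(1)[0])
    movie = np.empty((n_frames, *field_size))
    pos_rows = []
    for k in range(n_frames):
        t = k * frame_interval
        frame = _background(field_size, optics)
        for run in run_plan:
            mt = mts[run.mt_id]
            s, moving = _run_position(run, mt, t)
            if s is None:
                continue
            x_um, y_um = mt.point_at(s)
            _add_gaussian_spot(frame, x_um / optics.pixel_size,
                               y_um / optics.pixel_size,
                               run.copy_number * optics.photons_per_fluorophore,
                               optics.psf_sigma)
            pos_rows.append(dict(frame=k, t=t, run_id=run.id, mt_id=mt.id,
                                 x_um=x_um, y_um=y_um, s_um=s, moving=moving))
        movie[k] = _camera(frame, optics, noise_rng)
    runs_df = pd.DataFrame([dataclasses.asdict(r) for r in run_plan])
    truth = SceneTruth(
        runs=runs_df,
        positions=pd.DataFrame(pos_rows),
        meta=dict(generator="make_invitro_movie", optics=optics.to_dict(),
                  frame_interval=frame_interval, n_frames=n_frames,
                  field_size=tuple(field_size),
                  total_mt_length_um=float(sum(m.length for m in mt_layout))),
    )
    return movie, truth


# ---------------------------------------------------------------------------
# in-cell trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegmentSpec:
    """One motion regime within a trajectory plan.

    ``params`` per state: active → ``v`` (µm/s, straight line, random
    heading); normal_diffusion → ``D`` (µm²/s); subdiffusion → ``D`` and
    Hurst ``H`` < 0.5 (fractional Brownian motion); confined → radius ``L``
    (µm) and step diffusivity ``D`` (reflected Brownian motion in a disc).
    """

    state: str
    duration: float
    params: dict

    def __post_init__(self) -> None:
        if self.state not in MOTION_STATES:
            raise ValidationError(f"unknown motion state {self.state!r}")
        if self.duration <= 0:
            raise ValidationError("segment duration must be > 0")
        p = self.params
        if self.state == "active" and p.get("v", 1.0) <= 0:
            raise ValidationError("active v must be > 0")
        if self.state in ("normal_diffusion", "subdiffusion", "confined") \
                and p.get("D", 1.0) <= 0:
            raise ValidationError("D must be > 0")
        if self.state == "subdiffusion" and not 0 < p.get("H", 0.3) < 0.5:
            raise ValidationError("subdiffusion requires 0 < H < 0.5")
        if self.state == "confined" and p.get("L", 1.0) <= 0:
            raise ValidationError("confinement radius L must be > 0")


@dataclass(frozen=True)
class TrajectoryPlan:
    """Ordered motion segments sampled at interval ``dt`` (s)."""

    dt: float
    segments: tuple[SegmentSpec, ...]
    localization_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValidationError("dt must be > 0")
        if self.localization_noise_sd < 0:
            raise ValidationError("localization_noise_sd must be >= 0")
        object.__setattr__(self, "segments", tuple(self.segments))


def _fgn_increments(n: int, hurst: float, rng: np.random.Generator
                    ) -> np.ndarray:
    """Fractional Gaussian noise of unit-time variance 1, length n."""
    k = np.arange(n, dtype=float)
    g = 0.5 * (np.abs(k + 1) ** (2 * hurst) - 2 * np.abs(k) ** (2 * hurst)
               + np.abs(k - 1) ** (2 * hurst))
    cov = g[np.abs(k[:, None] - k[None, :]).astype(int)]
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(n))
    return chol @ rng.standard_normal(n)


def _gen_segment(state: str, n_steps: int, dt: float, params: dict,
                 start: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """True positions for one segment: n_steps new points after ``start``."""
    if state == "active":
        v = params["v"]
        theta = params.get("heading")
        if theta is None:
            theta = rng.uniform(0, 2 * np.pi)
        step = v * dt * np.array([np.cos(theta), np.sin(theta)])
        return start + step * np.arange(1, n_steps + 1)[:, None]
    if state == "normal_diffusion":
        sd = np.sqrt(2.0 * params["D"] * dt)
        steps = rng.normal(0.0, sd, (n_steps, 2))
        return start + np.cumsum(steps, axis=0)
    if state == "subdiffusion":
        hurst = params.get("H", 0.3)
        # per-axis MSD = 2 D t^{2H}
        scale = np.sqrt(2.0 * params["D"]) * dt ** hurst
        dx = scale * _fgn_increments(n_steps, hurst, rng)
        dy = scale * _fgn_increments(n_steps, hurst, rng)
        return start + np.column_stack([np.cumsum(dx), np.cumsum(dy)])
    if state == "confined":
        radius = params["L"]
        sd = np.sqrt(2.0 * params.get("D", 0.05) * dt)
        centre = start.copy()
        out = np.empty((n_steps, 2))
        p = start.copy()
        for i in range(n_steps):
            p = p + rng.normal(0.0, sd, 2)
            r = np.linalg.norm(p - centre)
            while r > radius:  # radial reflection at the disc boundary
                p = centre + (p - centre) * max(2 * radius - r, 0.0) / r
                r = np.linalg.norm(p - centre)
            out[i] = p
        return out
    raise ValidationError(f"unknown motion state {state!r}")


def make_trajectory_set(
    plans: TrajectoryPlan | Sequence[TrajectoryPlan],
    n_tracks: int,
    seed: int = 0,
    origin_span_um: float = 0.0,
) -> tuple[pd.DataFrame, SceneTruth]:
    """Simulate labelled 2-D trajectories from motion-segment plans.

    ``plans`` is one plan for all tracks or a sequence cycled over tracks.
    ``origin_span_um`` scatters track origins uniformly over a square of
    that side (0 = all tracks start at the origin); scatter them when the
    tracks will be fed through detection-style linking so that distinct
    tracks stay resolvable. Returns ``(observations, truth)``:
    observations have columns ``track_id, frame, t, x_um, y_um``
    (localisation noise applied); ``truth.points`` holds per-point true
    positions and state labels, ``truth.segments`` the per-segment
    parameters.
    """
    if isinstance(plans, TrajectoryPlan):
        plans = [plans]
    if not plans:
        raise ValidationError("need at least one TrajectoryPlan")
    ss = np.random.SeedSequence(seed)
    obs_rows, pt_rows, seg_rows = [], [], []
    for tid, child in enumerate(ss.spawn(n_tracks)):
        rng = np.random.default_rng(child)
        plan = plans[tid % len(plans)]
        dt = plan.dt
        origin = (rng.uniform(0.0, origin_span_um, 2) if origin_span_um > 0
                  else np.zeros(2))
        pos = [origin]
        states = ["__origin__"]
        seg_ids = [-1]
        for si, seg in enumerate(plan.segments):
            n_steps = int(round(seg.duration / dt))
            pts = _gen_segment(seg.state, n_steps, dt, seg.params,
                               pos[-1], rng)
            pos.extend(pts)
            states.extend([seg.state] * n_steps)
            seg_ids.extend([si] * n_steps)
            seg_rows.append(dict(track_id=tid, segment_index=si,
                                 state=seg.state, duration=seg.duration,
                                 start_frame=len(pos) - n_steps - 1,
                                 end_frame=len(pos) - 1,
                                 **{f"param_{k}": v
                                    for k, v in seg.params.items()
                                    if np.isscalar(v)}))
        # the origin point belongs to the first segment's state
        if len(states) > 1:
            states[0] = states[1]
            seg_ids[0] = seg_ids[1]
        true = np.asarray(pos)
        noisy = true + rng.normal(0.0, plan.localization_noise_sd,
                                  true.shape)
        for k in range(len(true)):
            obs_rows.append(dict(track_id=tid, frame=k, t=k * dt,
                                 x_um=noisy[k, 0], y_um=noisy[k, 1]))
            pt_rows.append(dict(track_id=tid, frame=k, state=states[k],
                                segment_index=seg_ids[k],
                                x_um=true[k, 0], y_um=true[k, 1]))
    truth = SceneTruth(
        points=pd.DataFrame(pt_rows),
        segments=pd.DataFrame(seg_rows),
        meta=dict(generator="make_trajectory_set", n_tracks=n_tracks,
                  dt=plans[0].dt,
                  localization_noise_sd=plans[0].localization_noise_sd),
    )
    return pd.DataFrame(obs_rows), truth


# ---------------------------------------------------------------------------
# cell scenes (peripheral spread)
# ---------------------------------------------------------------------------

def make_cell_scene(
    cell_polygon: Sequence[tuple[float, float]],
    spot_placement: dict,
    pixel_size: float = 0.1,
    band_um: float = 5.0,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame, SceneTruth]:
    """Rasterise a cell outline and scatter virions inside it.

    Parameters
    ----------
    cell_polygon:
        Simple closed polygon, µm vertices.
    spot_placement:
        ``{"uniform": n}`` for uniform placement, or
        ``{"interior": n_i, "peripheral": n_p}`` to plant exact counts in
        the interior (> ``band_um`` from the edge) and the peripheral band.
        ``{"at": [(x, y), ...]}`` plants explicit positions.
    pixel_size:
        Mask raster resolution, µm/px.
    band_um:
        Peripheral band width used for truth labels, µm.

    Returns
    -------
    mask, spots, truth
        Boolean cell mask, spot table (x_um, y_um, region) and truth.
    """
    import shapely

    from shapely.geometry import Polygon

    poly = Polygon(cell_polygon)
    if not (poly.is_valid and poly.is_simple):
        raise ValidationError("cell polygon must be simple and closed "
                              "(self-intersection detected)")
    if pixel_size <= 0:
        raise ValidationError("pixel_size must be > 0")
    rng = np.random.default_rng(seed)
    minx, miny, maxx, maxy = poly.bounds

    # rasterise: pixel (i, j) is inside if its centre is inside the polygon
    from skimage.draw import polygon as draw_polygon
    w = int(np.ceil(maxx / pixel_size)) + 2
    h = int(np.ceil(maxy / pixel_size)) + 2
    verts = np.asarray(cell_polygon) / pixel_size
    rr, cc = draw_polygon(verts[:, 1], verts[:, 0], shape=(h, w))
    mask = np.zeros((h, w), dtype=bool)
    mask[rr, cc] = True

    boundary = poly.exterior

    def _dist(xy: np.ndarray) -> np.ndarray:
        return shapely.distance(shapely.points(xy), boundary)

    def _sample(n: int, region: str | None) -> np.ndarray:
        if n == 0:
            return np.empty((0, 2))
        got: list[np.ndarray] = []
        tries = 0
        while sum(len(g) for g in got) < n:
            tries += 1
            if tries > 10000:
                raise PlacementError(
                    f"could not place {n} spots in region {region!r}")
            m = max(4 * n, 64)
            xy = np.column_stack([rng.uniform(minx, maxx, m),
                                  rng.uniform(miny, maxy, m)])
            inside = shapely.contains_xy(poly, xy[:, 0], xy[:, 1])
            xy = xy[inside]
            if region is not None and len(xy):
                d = _dist(xy)
                xy = xy[d >= band_um] if region == "interior" \
                    else xy[d < band_um]
            got.append(xy)
        return np.concatenate(got)[:n]

    if "at" in spot_placement:
        xy = np.asarray(spot_placement["at"], dtype=float).reshape(-1, 2)
    elif "uniform" in spot_placement:
        xy = _sample(int(spot_placement["uniform"]), None)
    else:
        n_i = int(spot_placement.get("interior", 0))
        n_p = int(spot_placement.get("peripheral", 0))
        parts = []
        if n_i:
            parts.append(_sample(n_i, "interior"))
        if n_p:
            parts.append(_sample(n_p, "peripheral"))
        xy = (np.concatenate(parts) if parts
              else np.empty((0, 2)))
    if len(xy):
        d = _dist(xy)
        region = np.where(d < band_um, "peripheral", "interior")
    else:
        region = np.array([], dtype=object)
    spots = pd.DataFrame(dict(x_um=xy[:, 0] if len(xy) else [],
                              y_um=xy[:, 1] if len(xy) else [],
                              region=region))
    truth = SceneTruth(
        spots=spots.copy(),
        meta=dict(generator="make_cell_scene", pixel_size=pixel_size,
                  band_um=band_um, polygon=list(map(tuple, cell_polygon))),
    )
    return mask, spots, truth
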