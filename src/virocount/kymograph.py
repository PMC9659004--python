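"""In vitro motility: kymographs, run extraction, rates and summaries.

A kymograph resamples a movie along a polyline path (one row per frame,
one column per ``pixel_size`` of arclength, averaged over ``line_width_px``
perpendicular to the path). Transport events are extracted not from the
kymograph image but from along-path position-vs-time traces (tracked
centroids projected onto the path): maximal stretches where the smoothed
along-path speed exceeds a threshold become runs, each with a
least-squares velocity, a net run length, a direction relative to
microtubule polarity, and an end fate (whether the virion reached the
microtubule tip — virions that do sometimes park there rather than
detach, and the stationary tail is not part of the run).

The field-level motility rate normalises the number of motile virions to
the imaging duration (minutes) and the summed microtubule length (mm).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ValidationError
from .synthetic import Microtubule

__all__ = [
    "Kymograph",
    "Run",
    "build_kymograph",
    "extract_runs",
    "traces_from_detections",
    "motility_rate",
    "summarize_runs",
]


@dataclass
class Kymograph:
    """Position-along-path vs time image (rows = frames)."""

    data: np.ndarray          # (n_frames, n_samples)
    path_um: np.ndarray       # (n_samples, 2) resampled path, µm
    line_width_px: int
    frame_interval: float     # s
    pixel_size: float         # µm


@dataclass
class Run:
    """One extracted transport event along a microtubule."""

    virion_id: int
    velocity: float           # µm/s, > 0
    run_length: float         # µm, net |Δs|
    direction: str            # plus / minus / unknown
    end_fate: str             # reached_end / not_reached / not_discernible
    t_start: float = 0.0
    t_end: float = 0.0
    mt_id: int | None = None


# ---------------------------------------------------------------------------
# kymograph reconstruction
# ---------------------------------------------------------------------------

def _resample_path(path_um: np.ndarray, step_um: float) -> np.ndarray:
    seg = np.diff(path_um, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    arclen = np.concatenate([[0.0], np.cumsum(seglen)])
    total = arclen[-1]
    if total <= 0:
        raise ValidationError("path has zero length")
    n = max(2, int(round(total / step_um)) + 1)
    s = np.linspace(0.0, total, n)
    x = np.interp(s, arclen, path_um[:, 0])
    y = np.interp(s, arclen, path_um[:, 1])
    return np.column_stack([x, y])


def build_kymograph(
    movie: np.ndarray,
    path_um: Sequence[tuple[float, float]],
    line_width_px: int = 3,
    pixel_size: float = 0.1,
    frame_interval: float = 1.0,
) -> Kymograph:
    """Resample a movie along a path into a kymograph.

    Each column is the transverse mean over ``line_width_px`` samples
    perpendicular to the path at that arclength, bilinearly interpolated.
    Raises if any sampling point (path ± half the line width) leaves the
    image, naming the offending path sample.
    """
    movie = np.asarray(movie, dtype=float)
    if movie.ndim == 2:
        movie = movie[None]
    path = np.asarray(path_um, dtype=float)
    if path.ndim != 2 or len(path) < 2:
        raise ValidationError("path needs at least two (x, y) vertices")
    samples = _resample_path(path, pixel_size)
    # unit tangents and normals per sample
    tang = np.gradient(samples, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    norm = np.column_stack([-tang[:, 1], tang[:, 0]])
    offsets = (np.arange(line_width_px) - (line_width_px - 1) / 2.0) \
        * pixel_size
    # sampling coordinates in px: (n_samples, line_width, 2)
    pts_um = samples[:, None, :] + offsets[None, :, None] * norm[:, None, :]
    pts_px = pts_um / pixel_size
    h, w = movie.shape[1:]
    bad = ((pts_px[..., 0] < 0) | (pts_px[..., 0] > w - 1)
           | (pts_px[..., 1] < 0) | (pts_px[..., 1] > h - 1))
    if bad.any():
        i = int(np.argwhere(bad.any(axis=1))[0, 0])
        raise ValidationError(
            f"kymograph path leaves the image near sample {i} at "
            f"({samples[i, 0]:.2f}, {samples[i, 1]:.2f}) µm")
    coords = np.stack([pts_px[..., 1].ravel(), pts_px[..., 0].ravel()])
    data = np.empty((movie.shape[0], len(samples)))
    for k in range(movie.shape[0]):
        vals = ndimage.map_coordinates(movie[k], coords, order=1)
        data[k] = vals.reshape(len(samples), line_width_px).mean(axis=1)
    return Kymograph(data=data, path_um=samples,
                     line_width_px=line_width_px,
                     frame_interval=frame_interval, pixel_size=pixel_size)


# ---------------------------------------------------------------------------
# trace building and run extraction
# ---------------------------------------------------------------------------

def traces_from_detections(
    detections: pd.DataFrame,
    mts: Sequence[Microtubule],
    frame_interval: float,
    max_offpath_um: float = 0.3,
) -> dict[int, pd.DataFrame]:
    """Project per-frame detections onto microtubule paths.

    ``detections`` needs columns ``frame, x_um, y_um``. For each
    microtubule, detections whose perpendicular distance to the segment is
    at most ``max_offpath_um`` are assigned to it (nearest detection per
    frame) and reduced to an along-path trace with columns ``frame, t,
    s_um``. Arclength s is measured from the microtubule ``start``.
    """
    traces: dict[int, pd.DataFrame] = {}
    if detections.empty:
        return traces
    xy = detections[["x_um", "y_um"]].to_numpy(dtype=float)
    frames = detections["frame"].to_numpy()
    for mt in mts:
        p0 = np.asarray(mt.start, dtype=float)
        d = np.asarray(mt.end, dtype=float) - p0
        length = np.hypot(*d)
        u = d / length
        rel = xy - p0
        s = rel @ u
        perp = np.abs(rel @ np.array([-u[1], u[0]]))
        sel = (perp <= max_offpath_um) & (s >= -max_offpath_um) \
            & (s <= length + max_offpath_um)
        if not sel.any():
            continue
        df = pd.DataFrame(dict(frame=frames[sel], s_um=np.clip(s[sel], 0.0,
                                                               length),
                               perp=perp[sel]))
        # nearest detection per frame
        df = df.sort_values(["frame", "perp"]).drop_duplicates("frame")
        df["t"] = df["frame"] * frame_interval
        traces[mt.id] = df[["frame", "t", "s_um"]].reset_index(drop=True)
    return traces


def extract_runs(
    trace: pd.DataFrame,
    frame_interval: float,
    min_duration: float = 3.0,
    speed_threshold: float = 0.1,
    smooth_frames: int = 3,
    virion_id: int = 0,
    mt: Microtubule | None = None,
    end_tolerance: float = 0.5,
    movie_duration: float | None = None,
) -> list[Run]:
    """Split an along-path trace into constant-velocity runs.

    A run is a maximal stretch where the instantaneous along-path speed
    (position smoothed over ``smooth_frames``) exceeds ``speed_threshold``
    for at least ``min_duration`` seconds. Velocity is the magnitude of the
    least-squares slope of position vs time over the stretch; run length is
    the net |Δs|. Direction is resolved against the microtubule polarity
    when one is supplied, else "unknown". End fate: ``reached_end`` when
    the trace's final position sits within ``end_tolerance`` µm of the tip
    the run was heading for; ``not_discernible`` when the run is censored
    by the end of the movie; otherwise ``not_reached``.
    """
    if trace.empty or len(trace) < 2:
        return []
    t = trace["t"].to_numpy(dtype=float)
    s = trace["s_um"].to_numpy(dtype=float)
    if t[-1] - t[0] < min_duration:
        return []
    s_smooth = ndimage.uniform_filter1d(s, size=max(1, smooth_frames),
                                        mode="nearest")
    speed = np.gradient(s_smooth, t)
    moving = np.abs(speed) > speed_threshold
    runs: list[Run] = []
    i = 0
    n = len(t)
    while i < n:
        if not moving[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and moving[j + 1]:
            j += 1
        if t[j] - t[i] >= min_duration:
            # the position smoothing smears the run edges; trim its
            # half-width from both ends before the velocity fit so parked
            # boundary frames cannot deflate the slope
            trim = smooth_frames // 2
            fi, fj = i, j
            if fj - fi + 1 > 2 * trim + 2:
                fi, fj = i + trim, j - trim
            slope = np.polyfit(t[fi:fj + 1], s[fi:fj + 1], 1)[0]
            direction = "unknown"
            if mt is not None:
                plus_at_end = mt.polarity == "plus_at_end"
                direction = ("plus" if (slope > 0) == plus_at_end
                             else "minus")
            end_fate = "not_reached"
            if mt is not None:
                tip = mt.length if slope > 0 else 0.0
                final = s[-1]
                if abs(final - tip) <= end_tolerance:
                    end_fate = "reached_end"
                elif (movie_duration is not None
                      and j == n - 1
                      and t[j] >= movie_duration - 1.5 * frame_interval):
                    end_fate = "not_discernible"
            elif movie_duration is not None and j == n - 1:
                end_fate = "not_discernible"
            runs.append(Run(virion_id=virion_id,
                            velocity=float(abs(slope)),
                            run_length=float(abs(s[j] - s[i])),
                            direction=direction, end_fate=end_fate,
                            t_start=float(t[i]), t_end=float(t[j]),
                            mt_id=mt.id if mt is not None else None))
        i = j + 1
    return runs


# ---------------------------------------------------------------------------
# field-level summaries
# ---------------------------------------------------------------------------

def motility_rate(n_motile_runs: int, imaging_minutes: float,
                  total_mt_length_mm: float) -> float:
    """Motile virions per minute per millimetre of microtubule."""
    if imaging_minutes <= 0:
        raise ValidationError("imaging_minutes must be > 0")
    if total_mt_length_mm <= 0:
        raise ValidationError("total_mt_length_mm must be > 0")
    return n_motile_runs / (imaging_minutes * total_mt_length_mm)


def summarize_runs(runs: Sequence[Run]) -> dict:
    """Cohort summary of extracted runs.

    Velocity/run-length means ± s.d.; percentage of plus-end-directed runs
    among those with discernible direction; end-fate breakdown (percent
    reached end / not reached / not discernible).
    """
    runs = list(runs)
    if not runs:
        return dict(n=0, status="no runs", mean_velocity=np.nan,
                    sd_velocity=np.nan, mean_run_length=np.nan,
                    sd_run_length=np.nan, percent_plus=np.nan,
                    percent_reached_end=np.nan,
                    percent_not_reached=np.nan,
                    percent_not_discernible=np.nan)
    vel = np.array([r.velocity for r in runs])
    rl = np.array([r.run_length for r in runs])
    directed = [r for r in runs if r.direction in ("plus", "minus")]
    pct_plus = (100.0 * sum(r.direction == "plus" for r in directed)
                / len(directed)) if directed else np.nan
    n = len(runs)
    fate = lambda f: 100.0 * sum(r.end_fate == f for r in runs) / n
    sd = lambda a: float(np.std(a, ddof=1)) if len(a) > 1 else 0.0
    return dict(n=n, status="ok",
                mean_velocity=float(vel.mean()), sd_velocity=sd(vel),
                mean_run_length=float(rl.mean()), sd_run_length=sd(rl),
                percent_plus=pct_plus,
                percent_reached_end=fate("reached_end"),
                percent_not_reached=fate("not_reached"),
                percent_not_discernible=fate("not_discernible"))
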