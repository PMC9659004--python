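"""In-cell trajectory analysis: linking, filtering, motion-state segmentation.

The pipeline mirrors standard single-particle tracking practice:

1. :func:`link_spots` — per-frame detections are linked frame-to-frame by
   optimal (Hungarian) assignment within a maximum linking distance
   (default 0.8 µm), then track fragments are joined across gaps of up to
   5 missing frames; gap frames are linearly interpolated and marked.
2. :func:`filter_by_displacement` — tracks whose net start-to-end
   displacement does not exceed 1 µm are discarded.
3. :func:`classify_segments` — each track is segmented into active
   transport, normal diffusion, subdiffusion or confined motion from
   sliding-window features: the log-log MSD slope α over short lags and
   the straightness (net/path length). Defaults: 15-frame window, active
   if α ≥ 1.5 and straightness ≥ 0.6, confined if α ≤ 0.4, subdiffusive if
   0.4 < α < 0.9, otherwise normal diffusion; segments shorter than
   5 frames are absorbed into their neighbours.
4. :func:`active_transport_stats` / :func:`count_motile` — cohort
   summaries (velocity = net displacement / duration; motile = net
   displacement > 3 µm within a 60 s window).

When the localisation precision σ is known, pass ``localization_sd``: the
textbook offset 4σ² is subtracted from every windowed MSD before the
log-log fit, removing the noise floor that otherwise biases α downward at
short lags.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.special import psi
from scipy.spatial import cKDTree

from .errors import ValidationError

__all__ = [
    "MotionSegment",
    "DEFAULT_THRESHOLDS",
    "link_spots",
    "filter_by_displacement",
    "classify_segments",
    "classify_tracks",
    "active_transport_stats",
    "count_motile",
]

DEFAULT_THRESHOLDS = dict(
    alpha_active=1.5,
    straightness_active=0.6,
    alpha_confined=0.4,
    alpha_subdiffusive=0.9,
)


@dataclass
class MotionSegment:
    """A contiguous sub-trajectory sharing one motion state."""

    track_id: int
    start_frame: int
    end_frame: int  # inclusive
    state: str
    velocity: float | None = None   # µm/s, active segments only
    run_length: float | None = None  # µm, net displacement

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


# ---------------------------------------------------------------------------
# linking
# ---------------------------------------------------------------------------

_BIG = 1e12


def _assign(costs: np.ndarray, max_cost: float) -> list[tuple[int, int]]:
    """Optimal assignment on a cost matrix; entries above max_cost unlinked."""
    if costs.size == 0:
        return []
    blocked = costs > max_cost
    c = np.where(blocked, _BIG, costs)
    rows, cols = linear_sum_assignment(c)
    return [(r, k) for r, k in zip(rows, cols) if not blocked[r, k]]


def link_spots(
    detections: pd.DataFrame,
    max_link: float = 0.8,
    max_gap: int = 5,
) -> pd.DataFrame:
    """Link per-frame detections into tracks (frame-to-frame LAP + gaps).

    Parameters
    ----------
    detections:
        DataFrame with columns ``frame`` (int) and ``x_um, y_um``.
    max_link:
        Maximum frame-to-frame linking distance, µm.
    max_gap:
        Maximum number of consecutive missing frames bridged by gap
        closing; the allowed gap-closing distance scales linearly with the
        gap, ``max_link × (n_missing + 1)``.

    Returns
    -------
    DataFrame ``track_id, frame, x_um, y_um, interpolated`` where
    interpolated marks gap-closed frames. Every detection belongs to
    exactly one track; unlinked detections become singleton tracks.
    """
    for col in ("frame", "x_um", "y_um"):
        if col not in detections.columns:
            raise ValidationError(f"detections lack required column {col!r}")
    if detections.empty:
        return pd.DataFrame(columns=["track_id", "frame", "x_um", "y_um",
                                     "interpolated"])
    det = detections.sort_values(["frame"], kind="stable",
                                 ignore_index=True)
    frames = sorted(det["frame"].unique())
    by_frame = {f: g[["x_um", "y_um"]].to_numpy(dtype=float)
                for f, g in det.groupby("frame")}

    # stage 1: frame-to-frame assignment → fragments
    fragments: list[list[tuple[int, float, float]]] = []
    open_frag: dict[int, int] = {}  # detection row in prev frame → fragment
    prev_frame = None
    for f in frames:
        pts = by_frame[f]
        new_open: dict[int, int] = {}
        if prev_frame is not None and f == prev_frame + 1 and open_frag:
            prev_pts = by_frame[prev_frame]
            prev_idx = sorted(open_frag)
            costs = np.linalg.norm(
                prev_pts[prev_idx][:, None, :] - pts[None, :, :], axis=2)
            for r, k in _assign(costs, max_link):
                frag = open_frag[prev_idx[r]]
                fragments[frag].append((f, pts[k, 0], pts[k, 1]))
                new_open[k] = frag
        for k in range(len(pts)):
            if k not in new_open:
                fragments.append([(f, pts[k, 0], pts[k, 1])])
                new_open[k] = len(fragments) - 1
        open_frag = new_open
        prev_frame = f

    # stage 2: gap closing between fragment ends and starts
    ends = np.array([frag[-1] for frag in fragments])
    starts = np.array([frag[0] for frag in fragments])
    n = len(fragments)
    costs = np.full((n, n), _BIG)
    for i in range(n):
        fe, xe, ye = ends[i]
        for j in range(n):
            if i == j:
                continue
            fs, xs_, ys_ = starts[j]
            n_missing = int(fs - fe) - 1
            if not 1 <= n_missing <= max_gap:
                continue
            d = np.hypot(xs_ - xe, ys_ - ye)
            if d <= max_link * (n_missing + 1):
                costs[i, j] = d ** 2
    links = _assign(costs, _BIG / 2) if n > 1 else []

    # merge fragments along gap links (follow chains)
    succ = dict(links)
    has_pred = set(j for _, j in links)
    rows = []
    track_id = 0
    for i in range(n):
        if i in has_pred:
            continue
        chain = [i]
        while chain[-1] in succ:
            chain.append(succ[chain[-1]])
        pts: list[tuple[int, float, float, bool]] = []
        for ci, frag in enumerate(chain):
            if ci > 0:  # interpolate across the gap
                f0, x0, y0 = fragments[chain[ci - 1]][-1]
                f1, x1, y1 = fragments[frag][0]
                for f in range(int(f0) + 1, int(f1)):
                    w = (f - f0) / (f1 - f0)
                    pts.append((f, x0 + w * (x1 - x0), y0 + w * (y1 - y0),
                                True))
            pts.extend((int(f), x, y, False) for f, x, y in fragments[frag])
        for f, x, y, interp in pts:
            rows.append(dict(track_id=track_id, frame=f, x_um=x, y_um=y,
                             interpolated=interp))
        track_id += 1
    return pd.DataFrame(rows)


def filter_by_displacement(tracks: pd.DataFrame,
                           min_total_displacement: float = 1.0
                           ) -> pd.DataFrame:
    """Keep tracks whose net start-to-end displacement strictly exceeds
    ``min_total_displacement`` µm; a threshold of 0 disables the filter."""
    if tracks.empty or min_total_displacement <= 0:
        return tracks
    keep = []
    for tid, g in tracks.groupby("track_id"):
        g = g.sort_values("frame")
        net = np.hypot(g["x_um"].iloc[-1] - g["x_um"].iloc[0],
                       g["y_um"].iloc[-1] - g["y_um"].iloc[0])
        if net > min_total_displacement:
            keep.append(tid)
    return tracks[tracks["track_id"].isin(keep)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# motion-state segmentation
# ---------------------------------------------------------------------------

def _alpha_correction(m: np.ndarray, lags: np.ndarray) -> np.ndarray:
    """Bias correction for the mean of log windowed MSD.

    A windowed MSD at lag ℓ averages ``m`` overlapping 2-D squared
    displacements, roughly χ²-distributed with effective dof ν ≈ 2·m/ℓ
    (two axes, displacements decorrelate over one lag). The log of such a
    mean is biased by ψ(ν/2) − ln(ν/2); subtracting it removes the
    systematic downward tilt of the fitted exponent on diffusive data.
    """
    nu = np.maximum(2.0 * m / lags, 1.0)
    return psi(nu / 2.0) - np.log(nu / 2.0)


def _alpha_slope(log_msd: np.ndarray, lags: np.ndarray, m: np.ndarray
                 ) -> np.ndarray:
    """Weighted log-log slope; weights ∝ effective dof per lag."""
    lx = np.log(lags.astype(float))
    w = np.ones_like(lx)
    w = w / w.sum()
    mx = float(w @ lx)
    wy = w @ log_msd
    return ((w * (lx - mx)) @ log_msd - 0.0 * wy) / float(w @ (lx - mx) ** 2)


def _window_features(xy: np.ndarray, window: int, n_lags: int,
                     noise_floor: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-point log-log MSD slope α and straightness over sliding windows.

    The window is centred on each point and shifted inside the track at the
    ends so every point sees a full window.
    """
    n = len(xy)
    lags = np.arange(1, n_lags + 1)
    starts = np.clip(np.arange(n) - window // 2, 0, n - window)
    msd = np.empty((n_lags, n))
    for li, lag in enumerate(lags):
        d2 = np.sum((xy[lag:] - xy[:-lag]) ** 2, axis=1)
        c = np.concatenate([[0.0], np.cumsum(d2)])
        m = window - lag  # displacements of this lag inside the window
        a = starts
        msd[li] = (c[a + m] - c[a]) / m
    msd = np.clip(msd - noise_floor, 1e-12, None)
    m = (window - lags).astype(float)
    log_msd = np.log(msd) - _alpha_correction(m, lags)[:, None]
    alpha = _alpha_slope(log_msd, lags, m)

    steps = np.hypot(*(xy[1:] - xy[:-1]).T)
    cpath = np.concatenate([[0.0], np.cumsum(steps)])
    a = starts
    b = starts + window - 1
    net = np.hypot(xy[b, 0] - xy[a, 0], xy[b, 1] - xy[a, 1])
    path = cpath[b] - cpath[a]
    with np.errstate(invalid="ignore", divide="ignore"):
        straight = np.where(path > 0, net / path, 0.0)
    return alpha, straight


def _span_features(xy: np.ndarray, noise_floor: float,
                   max_lags: int = 20) -> tuple[float, float]:
    """α and straightness computed over one whole span of points."""
    n = len(xy)
    n_lags = int(np.clip(n // 3, 2, max_lags))
    lags = np.arange(1, n_lags + 1)
    msd = np.empty(n_lags)
    for li, lag in enumerate(lags):
        d2 = np.sum((xy[lag:] - xy[:-lag]) ** 2, axis=1)
        msd[li] = d2.mean()
    msd = np.clip(msd - noise_floor, 1e-12, None)
    m = (n - lags).astype(float)
    log_msd = np.log(msd) - _alpha_correction(m, lags)
    alpha = float(_alpha_slope(log_msd, lags, m))
    net = float(np.hypot(*(xy[-1] - xy[0])))
    path = float(np.sum(np.hypot(*(xy[1:] - xy[:-1]).T)))
    straight = net / path if path > 0 else 0.0
    return alpha, straight


def _labels_from_features(alpha: np.ndarray, straight: np.ndarray,
                          thresholds: dict) -> np.ndarray:
    th = thresholds
    labels = np.full(len(alpha), "normal_diffusion", dtype=object)
    labels[alpha <= th["alpha_confined"]] = "confined"
    sub = (alpha > th["alpha_confined"]) & (alpha < th["alpha_subdiffusive"])
    labels[sub] = "subdiffusion"
    active = (alpha >= th["alpha_active"]) & \
             (straight >= th["straightness_active"])
    labels[active] = "active"
    return labels


def _runs_of(labels: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of equal labels as (start, end) inclusive index pairs."""
    runs = []
    s = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[s]:
            runs.append((s, i - 1))
            s = i
    return runs


def _merge_short(labels: np.ndarray, min_len: int) -> np.ndarray:
    """Absorb label runs shorter than min_len into the longer neighbour."""
    labels = labels.copy()
    changed = True
    while changed:
        changed = False
        runs = []
        s = 0
        for i in range(1, len(labels) + 1):
            if i == len(labels) or labels[i] != labels[s]:
                runs.append((s, i - 1))
                s = i
        if len(runs) <= 1:
            break
        for ri, (a, b) in enumerate(runs):
            if b - a + 1 >= min_len:
                continue
            left = runs[ri - 1] if ri > 0 else None
            right = runs[ri + 1] if ri + 1 < len(runs) else None
            if left is None and right is None:
                continue
            if right is None or (left is not None and
                                 (left[1] - left[0]) >= (right[1] - right[0])):
                labels[a:b + 1] = labels[left[1]]
            else:
                labels[a:b + 1] = labels[right[0]]
            changed = True
            break
    return labels


def classify_segments(
    track: pd.DataFrame,
    dt: float,
    window: int = 15,
    thresholds: dict | None = None,
    min_segment: int = 5,
    localization_sd: float = 0.0,
    exclude_interpolated_from_msd: bool = True,
) -> tuple[np.ndarray, list[MotionSegment]]:
    """Segment one track into motion states.

    Parameters
    ----------
    track:
        Points of a single track (columns ``frame, x_um, y_um``), sorted or
        sortable by frame.
    dt:
        Frame interval, s.
    window:
        Sliding-window length in frames; MSD is fitted over lags
        1..⌊window/3⌋. Tracks shorter than the window get a single global
        classification.
    localization_sd:
        Known localisation precision σ (µm); 4σ² is subtracted from the
        windowed MSD before the α fit.

    Returns
    -------
    labels, segments
        Per-point state labels and the merged :class:`MotionSegment` list;
        active segments carry velocity (net displacement / duration) and
        run length (net displacement).
    """
    if dt <= 0:
        raise ValidationError("dt must be > 0")
    th = dict(DEFAULT_THRESHOLDS, **(thresholds or {}))
    g = track.sort_values("frame")
    xy = g[["x_um", "y_um"]].to_numpy(dtype=float)
    frames = g["frame"].to_numpy()
    n = len(xy)
    noise_floor = 4.0 * localization_sd ** 2
    tid = int(g["track_id"].iloc[0]) if "track_id" in g else 0
    if n < 2:
        raise ValidationError("track needs at least 2 points")
    if n < window:
        w = n
        n_lags = max(2, w // 3)
        alpha, straight = _window_features(xy, w, n_lags, noise_floor)
        label = _labels_from_features(alpha[:1], straight[:1], th)[0]
        labels = np.full(n, label, dtype=object)
    else:
        n_lags = max(2, window // 3)
        alpha, straight = _window_features(xy, window, n_lags, noise_floor)
        labels = _labels_from_features(alpha, straight, th)
        labels = _merge_short(labels, min_segment)
        # refine: re-classify each merged segment from features over its
        # whole span (many more displacements -> far tighter α), iterating
        # until the labelling is stable
        for _ in range(10):
            prev = labels.copy()
            for a, b in _runs_of(labels):
                if b - a + 1 < 4:  # too short for an MSD fit
                    continue
                al, st = _span_features(xy[a:b + 1], noise_floor)
                labels[a:b + 1] = _labels_from_features(
                    np.array([al]), np.array([st]), th)[0]
            labels = _merge_short(labels, min_segment)
            if np.array_equal(labels, prev):
                break
        # agglomerate ambiguous passive neighbours: the α of short spans of
        # confined/sub-diffusive/normal motion is noisy, so adjacent
        # passive segments with different labels are joined whenever their
        # union's own span features confirm one of the two labels. Active
        # segments never take part, so active/diffusive alternation is
        # preserved.
        passive = {"confined", "subdiffusion", "normal_diffusion"}
        changed = True
        while changed:
            changed = False
            runs = _runs_of(labels)
            for ri in range(len(runs) - 1):
                a0, b0 = runs[ri]
                a1, b1 = runs[ri + 1]
                l0, l1 = labels[a0], labels[a1]
                if l0 == l1 or l0 not in passive or l1 not in passive:
                    continue
                al, st = _span_features(xy[a0:b1 + 1], noise_floor)
                lab = _labels_from_features(np.array([al]), np.array([st]),
                                            th)[0]
                if lab in (l0, l1):
                    labels[a0:b1 + 1] = lab
                    changed = True
                    break
        labels = _merge_short(labels, min_segment)
    segments = []
    s = 0
    for i in range(1, n + 1):
        if i == n or labels[i] != labels[s]:
            seg = MotionSegment(track_id=tid,
                                start_frame=int(frames[s]),
                                end_frame=int(frames[i - 1]),
                                state=str(labels[s]))
            if seg.state == "active" and i - 1 > s:
                net = float(np.hypot(xy[i - 1, 0] - xy[s, 0],
                                     xy[i - 1, 1] - xy[s, 1]))
                duration = (frames[i - 1] - frames[s]) * dt
                seg.velocity = net / duration
                seg.run_length = net
            segments.append(seg)
            s = i
    return labels, segments


def classify_tracks(tracks: pd.DataFrame, dt: float, **kwargs
                    ) -> tuple[pd.DataFrame, list[MotionSegment]]:
    """Run :func:`classify_segments` per track; returns labelled points and
    the concatenated segment list."""
    all_segments: list[MotionSegment] = []
    labelled = []
    for tid, g in tracks.groupby("track_id"):
        labels, segs = classify_segments(g, dt, **kwargs)
        gg = g.sort_values("frame").copy()
        gg["state"] = labels
        labelled.append(gg)
        all_segments.extend(segs)
    out = (pd.concat(labelled, ignore_index=True) if labelled
           else tracks.assign(state=pd.Series(dtype=object)))
    return out, all_segments


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def active_transport_stats(segments: list[MotionSegment]) -> dict:
    """Velocity and run-length summaries over active segments.

    Returns a dict with ``velocities``, ``run_lengths`` (arrays),
    ``mean_velocity``, ``sd_velocity``, ``mean_run_length``,
    ``sd_run_length``, ``n`` and a ``status`` of ``"ok"`` or
    ``"no active runs"``.
    """
    vel = np.array([s.velocity for s in segments
                    if s.state == "active" and s.velocity is not None])
    rl = np.array([s.run_length for s in segments
                   if s.state == "active" and s.run_length is not None])
    if len(vel) == 0:
        return dict(velocities=vel, run_lengths=rl, mean_velocity=np.nan,
                    sd_velocity=np.nan, mean_run_length=np.nan,
                    sd_run_length=np.nan, n=0, status="no active runs")
    sd = lambda a: float(np.std(a, ddof=1)) if len(a) > 1 else 0.0
    return dict(velocities=vel, run_lengths=rl,
                mean_velocity=float(vel.mean()), sd_velocity=sd(vel),
                mean_run_length=float(rl.mean()), sd_run_length=sd(rl),
                n=len(vel), status="ok")


def count_motile(tracks: pd.DataFrame, dt: float,
                 min_displacement: float = 3.0,
                 window: float = 60.0) -> int:
    """Number of tracks travelling more than ``min_displacement`` µm within
    the first ``window`` seconds of imaging."""
    if tracks.empty:
        return 0
    count = 0
    for _, g in tracks.groupby("track_id"):
        g = g.sort_values("frame")
        t = g["frame"].to_numpy() * dt
        in_win = g[(t - t[0]) <= window]
        if len(in_win) < 2:
            continue
        xy = in_win[["x_um", "y_um"]].to_numpy(dtype=float)
        net = np.hypot(xy[-1, 0] - xy[0, 0], xy[-1, 1] - xy[0, 1])
        if net > min_displacement:
            count += 1
    return count
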