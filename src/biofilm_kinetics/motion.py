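"""Landmark-motion analytics: step sizes, trajectory components,
origin-normalised tracks and distance-to-edge dynamics.

Landmarks are visually recognisable structures in the expanding biomass
marked with point ROIs and followed frame by frame.  From their tracks
we derive per-interval step sizes (Euclidean, and the x-axis component
along the direction of radial growth), the x/y range of motion of each
track, tracks re-origined to (0, 0) for overlay plots, and — combined
with the edge trace of the same movie — each landmark's distance to the
advancing colony edge over time.  The slope of that distance change
classifies a landmark as keeping pace with the edge, falling behind, or
catching up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .edge import EdgeTrace
from .io import PointTrack

#: |slope| of the distance-change series (μm/min) below which a landmark
#: counts as keeping pace with the edge.
KEEP_PACE_TOLERANCE_UM_MIN = 0.1

CLASS_KEEPING_PACE = "keeping pace"
CLASS_FALLING_BEHIND = "falling behind"
CLASS_CATCHING_UP = "catching up"


@dataclass
class EdgeDistanceResult:
    """Distance-to-edge series for one landmark.

    ``dist_change_um`` is ``dist − dist[first frame]``: positive values
    mean the landmark is falling behind the edge, negative that it is
    catching up.
    """

    track_id: str
    t_min: np.ndarray
    dist_to_edge_um: np.ndarray
    dist_change_um: np.ndarray
    slope_um_min: float
    classification: str


def truncate_tracks(tracks: list[PointTrack]) -> list[PointTrack]:
    """Cut every track to the length of the shortest, keeping early frames.

    Pooled comparisons across landmarks and movies require a common
    observation window, so downstream analysis is limited to the length
    of the shortest track.
    """
    if not tracks:
        raise ValueError("no tracks given")
    n = min(len(t) for t in tracks)
    return [
        PointTrack(t.track_id, t.frames[:n], t.x_px[:n], t.y_px[:n]) for t in tracks
    ]


def step_sizes(track: PointTrack, pixel_size_um: float) -> np.ndarray:
    """Euclidean displacement (μm) between consecutive track points."""
    if len(track) < 2:
        raise ValueError(f"track {track.track_id}: need ≥ 2 points for steps")
    dx = np.diff(track.x_px)
    dy = np.diff(track.y_px)
    return np.hypot(dx, dy) * pixel_size_um


def x_step_sizes(track: PointTrack, pixel_size_um: float) -> np.ndarray:
    """|Δx| (μm) between consecutive points — the radial-direction step."""
    if len(track) < 2:
        raise ValueError(f"track {track.track_id}: need ≥ 2 points for steps")
    return np.abs(np.diff(track.x_px)) * pixel_size_um


def normalise_trajectories(
    tracks: list[PointTrack], pixel_size_um: float
) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """Shift each track so it starts at (0, 0); coordinates in μm.

    Returns ``(track_id, x_um, y_um)`` triples suitable for overlaying
    trajectories from different movies on a common origin.
    """
    out = []
    for t in tracks:
        if len(t) < 1:
            raise ValueError(f"track {t.track_id}: empty")
        out.append(
            (
                t.track_id,
                (t.x_px - t.x_px[0]) * pixel_size_um,
                (t.y_px - t.y_px[0]) * pixel_size_um,
            )
        )
    return out


def xy_components(
    tracks: list[PointTrack], pixel_size_um: float
) -> pd.DataFrame:
    """Per-track range of motion: ``max − min`` of x and of y, in μm.

    The x component is the range along the radial direction of biofilm
    growth; the y component is the range of deviation perpendicular to
    it.
    """
    rows = []
    for t in tracks:
        rows.append(
            {
                "track_id": t.track_id,
                "x_range_um": (t.x_px.max() - t.x_px.min()) * pixel_size_um,
                "y_range_um": (t.y_px.max() - t.y_px.min()) * pixel_size_um,
            }
        )
    return pd.DataFrame(rows)


def distance_to_edge(
    track: PointTrack,
    trace: EdgeTrace,
    pixel_size_um: float,
    pace_tolerance_um_min: float = KEEP_PACE_TOLERANCE_UM_MIN,
) -> EdgeDistanceResult:
    """Distance from a landmark to the advancing edge, frame by frame.

    ``d(t) = edge_x(t) − x(t)`` in μm; the change series ``d(t) − d(t₀)``
    starts at 0 by construction.  The OLS slope of the change series
    classifies the track: within ``±pace_tolerance`` it keeps pace with
    the edge, a positive slope means falling behind, negative catching
    up.
    """
    valid = set(trace.valid_frames.tolist())
    if not set(track.frames.tolist()) <= valid:
        bad = sorted(set(track.frames.tolist()) - valid)
        raise ValueError(
            f"track {track.track_id}: frames {bad} outside the valid edge frames"
        )
    t_min = trace.t_min[track.frames]
    dist = trace.edge_x_um[track.frames] - track.x_px * pixel_size_um
    change = dist - dist[0]
    if len(track) >= 2 and np.std(t_min) > 0:
        slope = float(stats.linregress(t_min, change).slope)
    else:
        slope = 0.0
    if abs(slope) <= pace_tolerance_um_min:
        cls = CLASS_KEEPING_PACE
    elif slope > 0:
        cls = CLASS_FALLING_BEHIND
    else:
        cls = CLASS_CATCHING_UP
    return EdgeDistanceResult(track.track_id, t_min, dist, change, slope, cls)


def step_histogram(steps_um: np.ndarray, bin_width_um: float = 2.0) -> pd.DataFrame:
    """Histogram of pooled step sizes with half-open bins ``[lo, hi)``.

    Bins cover ``[0, max step]``; the final bin is widened to include
    the maximum itself.
    """
    steps_um = np.asarray(steps_um, dtype=float)
    if steps_um.size == 0:
        raise ValueError("no steps to histogram")
    if bin_width_um <= 0:
        raise ValueError("bin_width_um must be > 0")
    top = max(float(steps_um.max()), bin_width_um)
    n_bins = int(np.ceil(top / bin_width_um)) or 1
    edges = np.arange(n_bins + 1) * bin_width_um
    if edges[-1] <= steps_um.max():
        edges = np.append(edges, edges[-1] + bin_width_um)
    counts, edges = np.histogram(steps_um, bins=edges)
    return pd.DataFrame(
        {"bin_lo_um": edges[:-1], "bin_hi_um": edges[1:], "count": counts}
    )


def track_metrics(
    tracks: list[PointTrack],
    pixel_size_um: float,
    dt_min: float,
    trace: EdgeTrace | None = None,
) -> pd.DataFrame:
    """Tidy per-track summary of the motion analytics.

    Tracks are truncated to a common length first.  Columns: step
    statistics (μm), x/y ranges (μm), mean speed (μm/min), and — when an
    edge trace is supplied — the distance-change slope and its
    classification.
    """
    tracks = truncate_tracks(tracks)
    rows = []
    for t in tracks:
        steps = step_sizes(t, pixel_size_um)
        row = {
            "track_id": t.track_id,
            "n_points": len(t),
            "mean_step_um": steps.mean(),
            "max_step_um": steps.max(),
            "total_path_um": steps.sum(),
            "mean_speed_um_min": steps.mean() / dt_min,
            "x_range_um": (t.x_px.max() - t.x_px.min()) * pixel_size_um,
            "y_range_um": (t.y_px.max() - t.y_px.min()) * pixel_size_um,
        }
        if trace is not None:
            res = distance_to_edge(t, trace, pixel_size_um)
            row["edge_slope_um_min"] = res.slope_um_min
            row["edge_class"] = res.classification
        rows.append(row)
    return pd.DataFrame(rows)
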