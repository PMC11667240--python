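"""Per-track kinematic statistics used to classify microbubble behaviour.

Three dimensionless statistics drive the glomerulus/vessel separation:

* **normalized distance** (ND, "w.u."): cumulative path length over the
  first-to-last chord. Straight transits give 1; swirling confined tracks
  give large values, capped when the chord collapses below one
  super-resolved grid cell.
* **dispersity** ("a.u."): the number of consecutive direction pairs that
  agree within +/-20 deg (directions taken between distinct grid-rounded
  positions), divided by the track's point count. Near 1 for long straight
  tracks, near 0 for tracks that keep turning.
* **normalized speed** ("w.u."): mean speed scaled by the acquisition's 99th
  percentile track speed, clipped to [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .frames import ROIMask
from .tracking import Track

__all__ = [
    "TrackMetrics",
    "normalized_distance",
    "dispersity",
    "mean_speed",
    "normalized_speed",
    "compute_track_metrics",
    "roi_track_summary",
]

ND_CAP = 100.0


@dataclass
class TrackMetrics:
    track_id: int
    population: str
    path_length_mm: float
    chord_length_mm: float
    normalized_distance: float
    duration_s: float
    mean_speed_cm_s: float
    dispersity: float
    normalized_speed: float = np.nan  # acquisition-level, filled later


def _path_and_chord(points: np.ndarray) -> tuple[float, float]:
    steps = np.diff(points, axis=0)
    path = float(np.hypot(steps[:, 0], steps[:, 1]).sum())
    chord = float(np.hypot(*(points[-1] - points[0])))
    return path, chord


def normalized_distance(
    points: np.ndarray, *, min_chord: float = 0.0, cap: float = ND_CAP
) -> float:
    """Cumulative path length divided by the first-to-last chord.

    ``points`` is an (n, 2) coordinate array (any consistent unit). When the
    chord falls below ``min_chord`` — a track that closes on itself to within
    one super-resolved grid cell — the ratio is replaced by ``cap`` instead of
    blowing up, preserving "large ND = swirling" without infinities.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        raise ValueError("normalized distance needs >= 2 points")
    path, chord = _path_and_chord(points)
    if chord <= max(min_chord, 0.0) or chord == 0.0:
        return cap
    return min(path / chord, cap)


def dispersity(points: np.ndarray, *, angle_tol_deg: float = 20.0, grid_spacing: float = 1.0) -> float:
    """Fraction of consecutive same-direction steps over the point count.

    Points are rounded to ``grid_spacing``; consecutive duplicates are
    dropped; each remaining displacement gets a direction angle, and the
    number of consecutive angle pairs within +/-``angle_tol_deg`` (circular
    difference) is divided by the *original* number of points.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n < 3:
        raise ValueError("dispersity needs >= 3 points")
    rounded = np.round(points / grid_spacing) * grid_spacing
    keep = np.ones(len(rounded), dtype=bool)
    keep[1:] = np.any(np.diff(rounded, axis=0) != 0, axis=1)
    dedup = rounded[keep]
    if len(dedup) < 3:
        warnings.warn("track collapses to < 3 distinct grid positions", stacklevel=2)
        return 0.0
    steps = np.diff(dedup, axis=0)
    angles = np.degrees(np.arctan2(steps[:, 1], steps[:, 0]))
    diff = np.abs(np.diff(angles))
    circ = np.minimum(diff, 360.0 - diff)
    count = int((circ <= angle_tol_deg).sum())
    return count / n


def mean_speed(points_mm: np.ndarray, frame_rate: float) -> float:
    """Path length over elapsed time, in cm/s (points in mm, consecutive frames)."""
    points_mm = np.asarray(points_mm, dtype=float)
    if len(points_mm) < 2:
        raise ValueError("mean speed needs >= 2 points")
    path, _ = _path_and_chord(points_mm)
    dt = (len(points_mm) - 1) / frame_rate
    return (path / dt) / 10.0  # mm/s -> cm/s


def normalized_speed(speeds_cm_s: np.ndarray, *, reference_percentile: float = 99.0) -> np.ndarray:
    """Scale each track's mean speed by the acquisition's reference speed.

    The reference is the given percentile (default 99th) of all track speeds
    in the acquisition, which pins the fastest flows near 1 while staying
    robust to a single outlier; results are clipped to [0, 1]. All-zero
    speeds map to all zeros.
    """
    speeds = np.asarray(speeds_cm_s, dtype=float)
    if speeds.size == 0:
        raise ValueError("need at least one track")
    ref = float(np.percentile(speeds, reference_percentile))
    if ref <= 0:
        return np.zeros_like(speeds)
    return np.clip(speeds / ref, 0.0, 1.0)


def compute_track_metrics(
    tracks: list[Track],
    pixel_spacing: float,
    frame_rate: float,
    *,
    nd_min_chord_mm: float = 0.0,
    nd_cap: float = ND_CAP,
    dispersity_grid_px: float = 1.0,
    angle_tol_deg: float = 20.0,
) -> pd.DataFrame:
    """Metrics table for all tracks of an acquisition.

    ``nd_min_chord_mm`` should be one super-resolved grid cell when the table
    feeds the glomerulus detector. Dispersity is computed on pixel
    coordinates rounded to ``dispersity_grid_px``.
    """
    records = []
    for t in tracks:
        pts_mm = t.points_mm(pixel_spacing)
        path, chord = _path_and_chord(pts_mm)
        nd = normalized_distance(pts_mm, min_chord=nd_min_chord_mm, cap=nd_cap)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            disp = dispersity(
                t.points_px, angle_tol_deg=angle_tol_deg, grid_spacing=dispersity_grid_px
            )
        spd = mean_speed(pts_mm, frame_rate)
        records.append(
            TrackMetrics(
                track_id=t.track_id,
                population=t.population,
                path_length_mm=path,
                chord_length_mm=chord,
                normalized_distance=nd,
                duration_s=(len(t) - 1) / frame_rate,
                mean_speed_cm_s=spd,
                dispersity=disp,
            )
        )
    df = pd.DataFrame([r.__dict__ for r in records])
    if len(df):
        df["normalized_speed"] = normalized_speed(df["mean_speed_cm_s"].to_numpy())
    return df


def roi_track_summary(
    tracks: list[Track],
    metrics: pd.DataFrame,
    mask: ROIMask,
    *,
    min_inside_fraction: float = 0.5,
) -> dict:
    """Mean track metrics over the tracks belonging to one ROI.

    A track is a member when at least half of its points fall inside the
    mask. An ROI with no member tracks is flagged empty so callers exclude it
    from group statistics.
    """
    if mask.mask.sum() == 0:
        raise ValueError("mask is empty")
    member_ids = []
    for t in tracks:
        pts = t.points_mm(mask.pixel_spacing)
        frac = mask.contains(pts[:, 0], pts[:, 1]).mean()
        if frac >= min_inside_fraction:
            member_ids.append(t.track_id)
    sub = metrics[metrics["track_id"].isin(member_ids)]
    if len(sub) == 0:
        return {"roi_label": mask.label, "n_tracks": 0, "empty": True}
    return {
        "roi_label": mask.label,
        "n_tracks": len(sub),
        "empty": False,
        "normalized_distance": float(sub["normalized_distance"].mean()),
        "dispersity": float(sub["dispersity"].mean()),
        "mean_speed_cm_s": float(sub["mean_speed_cm_s"].mean()),
        "normalized_speed": float(sub["normalized_speed"].mean()),
    }
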