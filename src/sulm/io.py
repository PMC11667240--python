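"""File formats: TIFF stacks with YAML calibration sidecars, CSV tables for
detections / tracks / metrics / densities, ROI masks, and the composite
slow/fast density-map rendering."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from skimage import draw

from .frames import FrameStack, ROIMask
from .localization import Detection
from .tracking import Track

__all__ = [
    "write_stack",
    "read_stack",
    "write_ground_truth",
    "read_ground_truth",
    "write_mask",
    "read_mask",
    "read_polygon_mask",
    "detections_to_frame",
    "frame_to_detections",
    "tracks_to_frame",
    "frame_to_tracks",
    "CompositeMap",
    "render_density_maps",
]


def write_stack(path: str | Path, stack: FrameStack) -> None:
    """Multi-page float32 TIFF plus a ``<name>.yaml`` calibration sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.float32), photometric="minisblack")
    sidecar = path.with_suffix(".yaml")
    with open(sidecar, "w") as fh:
        yaml.safe_dump(
            {"pixel_spacing_mm": float(stack.pixel_spacing), "frame_rate_hz": float(stack.frame_rate)},
            fh,
        )


def read_stack(path: str | Path) -> FrameStack:
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    with open(path.with_suffix(".yaml")) as fh:
        meta = yaml.safe_load(fh)
    return FrameStack(frames, meta["pixel_spacing_mm"], meta["frame_rate_hz"])


def write_ground_truth(path: str | Path, trajectories: pd.DataFrame) -> None:
    trajectories.to_csv(path, index=False, columns=["frame", "x_mm", "y_mm", "bubble_id", "structure_id", "kind"])


def read_ground_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_mask(path: str | Path, mask: ROIMask) -> None:
    """Single-page binary TIFF with a YAML sidecar (label, pixel spacing)."""
    path = Path(path)
    tifffile.imwrite(path, mask.mask.astype(np.uint8), photometric="minisblack")
    with open(path.with_suffix(".yaml"), "w") as fh:
        yaml.safe_dump({"label": mask.label, "pixel_spacing_mm": float(mask.pixel_spacing)}, fh)


def read_mask(path: str | Path) -> ROIMask:
    path = Path(path)
    arr = tifffile.imread(path).astype(bool)
    with open(path.with_suffix(".yaml")) as fh:
        meta = yaml.safe_load(fh)
    return ROIMask(meta["label"], arr, meta["pixel_spacing_mm"])


def read_polygon_mask(path: str | Path, shape_px: tuple[int, int]) -> ROIMask:
    """ROI from a YAML closed polygon (vertices in mm, x then y)."""
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    verts = np.asarray(spec["polygon_mm"], dtype=float)
    spacing = float(spec["pixel_spacing_mm"])
    rr, cc = draw.polygon(verts[:, 1] / spacing, verts[:, 0] / spacing, shape=shape_px)
    mask = np.zeros(shape_px, dtype=bool)
    mask[rr, cc] = True
    return ROIMask(spec["label"], mask, spacing)


# ---------------------------------------------------------------------------
# Tabular round-trips

_DET_COLS = ["frame", "row_px", "col_px", "x_mm", "y_mm", "intensity", "population"]
_TRACK_COLS = ["track_id", "block_id", "population", "frame", "row_px", "col_px", "x_mm", "y_mm"]


def detections_to_frame(detections: list[list[Detection]], pixel_spacing: float) -> pd.DataFrame:
    rows = [
        (d.frame, d.row, d.col, d.col * pixel_spacing, d.row * pixel_spacing, d.intensity, d.population)
        for per_frame in detections
        for d in per_frame
    ]
    return pd.DataFrame(rows, columns=_DET_COLS)


def frame_to_detections(df: pd.DataFrame) -> list[list[Detection]]:
    n_frames = int(df["frame"].max()) + 1 if len(df) else 0
    out: list[list[Detection]] = [[] for _ in range(n_frames)]
    for row in df.itertuples(index=False):
        out[int(row.frame)].append(
            Detection(int(row.frame), float(row.row_px), float(row.col_px), float(row.intensity), row.population)
        )
    return out


def tracks_to_frame(tracks: list[Track], pixel_spacing: float) -> pd.DataFrame:
    rows = []
    for t in tracks:
        for f, r, c in zip(t.frames, t.rows, t.cols):
            rows.append((t.track_id, t.block_id, t.population, int(f), float(r), float(c),
                         float(c * pixel_spacing), float(r * pixel_spacing)))
    return pd.DataFrame(rows, columns=_TRACK_COLS)


def frame_to_tracks(df: pd.DataFrame) -> list[Track]:
    tracks = []
    for tid, g in df.groupby("track_id", sort=True):
        g = g.sort_values("frame")
        tracks.append(
            Track(
                frames=g["frame"].to_numpy(int),
                rows=g["row_px"].to_numpy(float),
                cols=g["col_px"].to_numpy(float),
                population=g["population"].iloc[0],
                block_id=int(g["block_id"].iloc[0]),
                track_id=int(tid),
            )
        )
    return tracks


# ---------------------------------------------------------------------------
# Composite density rendering

_VIOLET = np.array([0.55, 0.0, 0.8])
_GREEN = np.array([0.0, 1.0, 0.0])


@dataclass
class CompositeMap:
    """Two-channel track-traversal density plus its violet/green rendering.

    Channel values are per-cell counts of distinct tracks traversing the
    cell; slow flows render violet and fast flows green.
    """

    slow: np.ndarray
    fast: np.ndarray
    grid_spacing: float

    def to_rgb(self) -> np.ndarray:
        def norm(ch: np.ndarray) -> np.ndarray:
            top = ch.max()
            return ch / top if top > 0 else ch
        rgb = norm(self.slow)[..., None] * _VIOLET + norm(self.fast)[..., None] * _GREEN
        return np.clip(rgb, 0.0, 1.0)


def render_density_maps(
    tracks: list[Track],
    pixel_spacing: float,
    *,
    grid_spacing: float | None = None,
    field_shape_px: tuple[int, int] | None = None,
) -> CompositeMap:
    """Accumulate per-population track traversals per super-resolved cell.

    Each track increments every cell its interpolated trajectory crosses, at
    most once per track (traversal count, not dwell time), accumulated over
    all blocks.
    """
    from .glomeruli import _trajectory_cells

    if grid_spacing is None:
        grid_spacing = pixel_spacing / 8
    scale = pixel_spacing / grid_spacing
    if field_shape_px is None:
        max_r = max((t.rows.max() for t in tracks), default=0)
        max_c = max((t.cols.max() for t in tracks), default=0)
        field_shape_px = (int(np.ceil(max_r)) + 1, int(np.ceil(max_c)) + 1)
    h = int(np.ceil(field_shape_px[0] * scale))
    w = int(np.ceil(field_shape_px[1] * scale))
    channels = {"slow": np.zeros((h, w)), "fast": np.zeros((h, w))}
    for t in tracks:
        rr, cc = _trajectory_cells(t.rows * scale, t.cols * scale, h, w)
        cells = np.unique(np.stack([rr, cc], axis=1), axis=0)
        channels[t.population][cells[:, 0], cells[:, 1]] += 1
    return CompositeMap(channels["slow"], channels["fast"], grid_spacing)
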