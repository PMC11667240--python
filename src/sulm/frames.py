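"""Core spatial containers: calibrated frame stacks and region-of-interest masks.

Coordinate conventions used throughout the package:

* pixel coordinates are 0-based with pixel-center convention; ``row`` is the
  axial (depth) axis, ``col`` the lateral axis;
* physical coordinates are in millimetres, ``x`` along columns and ``y`` along
  rows, so ``x_mm = col * pixel_spacing`` and ``y_mm = row * pixel_spacing``;
* time is in seconds, speeds are reported in cm/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class FrameStack:
    """A time-ordered sequence of 2D intensity frames with physical calibration.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, height, width)``.
    pixel_spacing
        Isotropic pixel spacing in mm/pixel.
    frame_rate
        Acquisition rate in Hz.
    """

    frames: np.ndarray
    pixel_spacing: float
    frame_rate: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, height, width) array")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of a single frame."""
        return self.frames.shape[1:]

    @property
    def duration(self) -> float:
        """Acquisition duration in seconds."""
        return self.n_frames / self.frame_rate

    def with_frames(self, frames: np.ndarray) -> "FrameStack":
        """A new stack sharing this stack's calibration."""
        return FrameStack(frames, self.pixel_spacing, self.frame_rate)


@dataclass
class ROIMask:
    """A labelled binary region of interest on the imaging grid.

    The mask lives on the frame-stack pixel grid; ``area_cm2`` is derived from
    the pixel count and spacing and re-derivable from the geometry.
    """

    label: str
    mask: np.ndarray
    pixel_spacing: float
    area_cm2: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2D")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")
        derived = self._compute_area_cm2()
        if self.area_cm2 is None:
            self.area_cm2 = derived
        elif abs(self.area_cm2 - derived) > 1e-6:
            raise ValueError(
                f"stored area {self.area_cm2} cm^2 disagrees with geometry {derived} cm^2"
            )
        if self.area_cm2 <= 0:
            raise ValueError("ROI must have positive area")

    def _compute_area_cm2(self) -> float:
        # 1 cm^2 = 100 mm^2
        return float(self.mask.sum()) * self.pixel_spacing**2 / 100.0

    def contains(self, x_mm: np.ndarray, y_mm: np.ndarray) -> np.ndarray:
        """Vectorized membership test for physical points (mm)."""
        col = np.rint(np.asarray(x_mm) / self.pixel_spacing).astype(int)
        row = np.rint(np.asarray(y_mm) / self.pixel_spacing).astype(int)
        h, w = self.mask.shape
        inside = (row >= 0) & (row < h) & (col >= 0) & (col < w)
        out = np.zeros(np.shape(x_mm), dtype=bool)
        out[inside] = self.mask[row[inside], col[inside]]
        return out
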