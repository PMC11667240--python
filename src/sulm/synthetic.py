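"""Synthetic contrast-enhanced ultrasound (CEUS) acquisitions with ground truth.

The simulator emulates bolus-phase microbubble kinematics in renal tissue at
clinical frame rates: fast, quasi-linear transits along vessel centerlines
(order 1-6 cm/s) and slow, confined, swirling transits inside glomeruli —
capillary bundles of roughly 150-300 um in which bubbles loop at sub-cm/s
speed. Each bubble is rendered as an isotropic Gaussian blob at the
diffraction scale of a clinical convex probe, on top of additive Gaussian
noise. No tissue speckle, nonlinear acoustics or out-of-plane motion is
modelled: the stacks exercise the localization / tracking / metric stages,
not the scanner physics.

Every rendered bubble position is recorded in a :class:`GroundTruth` table so
recovery of positions, identities, speeds and glomerular counts can be
checked exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .frames import FrameStack, ROIMask

__all__ = [
    "Vessel",
    "Glomerulus",
    "SimScene",
    "GroundTruth",
    "simulate_scene",
    "make_two_roi_phantom",
]


@dataclass
class Vessel:
    """A vessel centerline carrying fast bubble traffic.

    ``path_mm`` is an (N, 2) polyline of (x, y) vertices in mm; bubbles enter
    at the first vertex and advance along the polyline at ``speed`` (cm/s),
    expiring when they reach the end. ``width_mm`` gives the vessel a finite
    lumen: each bubble rides a line parallel to the centerline at a constant
    perpendicular offset drawn uniformly within the half-width, so repeated
    transits paint a band rather than a single line, as real vessels do on
    ULM maps.
    """

    path_mm: np.ndarray
    speed: float  # cm/s
    rate: float  # bubble arrivals per second
    width_mm: float = 0.0

    def __post_init__(self) -> None:
        self.path_mm = np.asarray(self.path_mm, dtype=float)
        if self.path_mm.ndim != 2 or self.path_mm.shape[0] < 2:
            raise ValueError("vessel path needs >= 2 vertices")
        if self.speed <= 0:
            raise ValueError("vessel speed must be positive")
        if self.rate < 0:
            raise ValueError("arrival rate must be non-negative")
        if self.width_mm < 0:
            raise ValueError("width must be non-negative")


@dataclass
class Glomerulus:
    """A confined capillary bundle in which bubbles swirl slowly."""

    center_mm: tuple[float, float]
    radius_mm: float
    swirl_speed: float  # cm/s, tangential
    rate: float  # bubble arrivals per second

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("glomerulus radius must be positive")
        if self.swirl_speed <= 0:
            raise ValueError("swirl speed must be positive")
        if self.rate < 0:
            raise ValueError("arrival rate must be non-negative")


@dataclass
class SimScene:
    """Full description of a synthetic acquisition.

    Defaults mirror a clinical renal CEUS bolus acquisition: 0.2 mm pixels,
    40 Hz frame rate, blob width at the diffraction scale of a 3 MHz convex
    probe, and bubble lifetimes of a couple of seconds.
    """

    field_size: tuple[float, float] = (20.0, 10.0)  # (x, y) extent in mm
    pixel_spacing: float = 0.2  # mm / pixel
    frame_rate: float = 40.0  # Hz
    n_frames: int = 800
    vessels: list[Vessel] = field(default_factory=list)
    glomeruli: list[Glomerulus] = field(default_factory=list)
    noise_sigma: float = 0.05  # intensity units (bubble amplitude = 1)
    psf_sigma: float = 0.3  # mm
    bubble_amplitude: float = 1.0
    bubble_lifetime: float = 2.0  # s, for glomerular bubbles
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0 or self.pixel_spacing <= 0 or self.psf_sigma <= 0:
            raise ValueError("frame_rate, pixel_spacing and psf_sigma must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        fx, fy = self.field_size
        for g in self.glomeruli:
            cx, cy = g.center_mm
            if not (0 <= cx <= fx and 0 <= cy <= fy):
                raise ValueError("glomerulus center outside field")

    @property
    def grid_shape(self) -> tuple[int, int]:
        """(height, width) in pixels."""
        fx, fy = self.field_size
        return (int(round(fy / self.pixel_spacing)), int(round(fx / self.pixel_spacing)))


@dataclass
class GroundTruth:
    """True bubble trajectories and glomerulus geometry of a simulated scene.

    ``trajectories`` columns: frame, x_mm, y_mm, bubble_id, structure_id, kind
    (``vessel`` or ``glomerulus``), one row per rendered position.
    """

    trajectories: pd.DataFrame
    glomerulus_centers: np.ndarray  # (n, 2) in mm
    glomerulus_count: int
    roi_density: dict[str, float] = field(default_factory=dict)  # expected per cm^2

    def bubble_paths(self) -> dict[int, pd.DataFrame]:
        return {int(b): g for b, g in self.trajectories.groupby("bubble_id")}


def _polyline_point(path: np.ndarray, arclen: float) -> np.ndarray:
    """Point at a given arc length along a polyline (mm)."""
    seg = np.diff(path, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    s = min(max(arclen, 0.0), cum[-1])
    i = int(np.searchsorted(cum, s, side="right") - 1)
    i = min(i, len(seg_len) - 1)
    frac = (s - cum[i]) / seg_len[i] if seg_len[i] > 0 else 0.0
    return path[i] + frac * seg[i]


def _vessel_trajectories(
    vessel: Vessel, sid: int, scene: SimScene, rng: np.random.Generator, next_bid: int
) -> tuple[list[tuple], int]:
    """Poisson arrivals advancing along the centerline at exactly the set speed."""
    dt = 1.0 / scene.frame_rate
    step_mm = vessel.speed * 10.0 * dt  # cm/s -> mm/frame
    seg = np.diff(vessel.path_mm, axis=0)
    total_len = float(np.hypot(seg[:, 0], seg[:, 1]).sum())
    rows: list[tuple] = []
    n_transit = int(np.floor(total_len / step_mm)) + 1
    fx, fy = scene.field_size
    # unit normal of the overall direction, for the constant lumen offset
    direction = vessel.path_mm[-1] - vessel.path_mm[0]
    norm = np.hypot(*direction)
    normal = np.array([-direction[1], direction[0]]) / norm if norm > 0 else np.zeros(2)
    for f0 in range(scene.n_frames):
        for _ in range(rng.poisson(vessel.rate * dt)):
            bid = next_bid
            next_bid += 1
            offset = rng.uniform(-0.5, 0.5) * vessel.width_mm * normal
            for k in range(n_transit):
                f = f0 + k
                if f >= scene.n_frames:
                    break
                x, y = _polyline_point(vessel.path_mm, k * step_mm) + offset
                if not (0 <= x <= fx and 0 <= y <= fy):
                    break
                rows.append((f, x, y, bid, sid, "vessel"))
    return rows, next_bid


def _glomerulus_trajectories(
    glom: Glomerulus, sid: int, scene: SimScene, rng: np.random.Generator, next_bid: int
) -> tuple[list[tuple], int]:
    """Swirling confined orbits: per-bubble random orbit radius in
    [0.3, 1.0] x R, random direction, small radial jitter, clipped to stay
    strictly inside the bundle radius."""
    dt = 1.0 / scene.frame_rate
    cx, cy = glom.center_mm
    lifetime_frames = max(int(round(scene.bubble_lifetime * scene.frame_rate)), 1)
    rows: list[tuple] = []
    fx, fy = scene.field_size
    for f0 in range(scene.n_frames):
        for _ in range(rng.poisson(glom.rate * dt)):
            bid = next_bid
            next_bid += 1
            r_orbit = glom.radius_mm * rng.uniform(0.3, 1.0)
            direction = rng.choice([-1.0, 1.0])
            theta = rng.uniform(0.0, 2.0 * np.pi)
            omega = direction * (glom.swirl_speed * 10.0) / r_orbit  # rad/s
            n_pts = min(lifetime_frames, scene.n_frames - f0)
            jitter = rng.normal(0.0, 0.03 * glom.radius_mm, size=n_pts)
            for k in range(n_pts):
                r = np.clip(r_orbit + jitter[k], 0.05 * glom.radius_mm, glom.radius_mm)
                ang = theta + omega * k * dt
                x = cx + r * np.cos(ang)
                y = cy + r * np.sin(ang)
                x = float(np.clip(x, 0.0, fx))
                y = float(np.clip(y, 0.0, fy))
                rows.append((f0 + k, x, y, bid, sid, "glomerulus"))
    return rows, next_bid


def _render(scene: SimScene, traj: pd.DataFrame, rng: np.random.Generator) -> np.ndarray:
    h, w = scene.grid_shape
    frames = np.zeros((scene.n_frames, h, w), dtype=np.float64)
    sig_px = scene.psf_sigma / scene.pixel_spacing
    half = int(np.ceil(4.0 * sig_px))
    if len(traj):
        rows_px = traj["y_mm"].to_numpy() / scene.pixel_spacing
        cols_px = traj["x_mm"].to_numpy() / scene.pixel_spacing
        f_idx = traj["frame"].to_numpy()
        for f, r, c in zip(f_idx, rows_px, cols_px):
            r0, r1 = max(int(r) - half, 0), min(int(r) + half + 1, h)
            c0, c1 = max(int(c) - half, 0), min(int(c) + half + 1, w)
            if r0 >= r1 or c0 >= c1:
                continue
            yy, xx = np.mgrid[r0:r1, c0:c1]
            frames[f, r0:r1, c0:c1] += scene.bubble_amplitude * np.exp(
                -((yy - r) ** 2 + (xx - c) ** 2) / (2.0 * sig_px**2)
            )
    if scene.noise_sigma > 0:
        frames += rng.normal(0.0, scene.noise_sigma, size=frames.shape)
    return frames


def simulate_scene(scene: SimScene) -> tuple[FrameStack, GroundTruth]:
    """Render a scene into a calibrated frame stack plus its ground truth.

    Bubble arrivals are Poisson per structure; the same seed always yields a
    bit-identical stack and truth table. Overlapping glomeruli are legal but
    warned about, because downstream component counting cannot split them.
    """
    rng = np.random.default_rng(scene.seed)
    centers = np.array([g.center_mm for g in scene.glomeruli], dtype=float).reshape(-1, 2)
    for i in range(len(scene.glomeruli)):
        for j in range(i + 1, len(scene.glomeruli)):
            d = np.hypot(*(centers[i] - centers[j]))
            if d < scene.glomeruli[i].radius_mm + scene.glomeruli[j].radius_mm:
                warnings.warn(
                    f"glomeruli {i} and {j} overlap (separation {d:.3f} mm); "
                    "counts may merge them",
                    stacklevel=2,
                )
    rows: list[tuple] = []
    next_bid = 0
    for sid, vessel in enumerate(scene.vessels):
        new, next_bid = _vessel_trajectories(vessel, sid, scene, rng, next_bid)
        rows.extend(new)
    n_vessels = len(scene.vessels)
    for gi, glom in enumerate(scene.glomeruli):
        new, next_bid = _glomerulus_trajectories(glom, n_vessels + gi, scene, rng, next_bid)
        rows.extend(new)
    traj = pd.DataFrame(
        rows, columns=["frame", "x_mm", "y_mm", "bubble_id", "structure_id", "kind"]
    )
    traj = traj.astype({"frame": int, "bubble_id": int, "structure_id": int})
    traj = traj.sort_values(["bubble_id", "frame"], kind="stable").reset_index(drop=True)
    frames = _render(scene, traj, rng)
    stack = FrameStack(frames, scene.pixel_spacing, scene.frame_rate)
    truth = GroundTruth(traj, centers, len(scene.glomeruli))
    return stack, truth


def _default_vessels(x0: float, x1: float, y_levels: list[float], speeds: list[float],
                     rate: float, width_mm: float) -> list[Vessel]:
    return [
        Vessel(np.array([[x0, y], [x1, y]]), speed=s, rate=rate, width_mm=width_mm)
        for y, s in zip(y_levels, speeds)
    ]


def make_two_roi_phantom(
    seed: int,
    glomerular_density: float = 26.0,
    *,
    field_size: tuple[float, float] = (20.0, 10.0),
    pixel_spacing: float = 0.2,
    frame_rate: float = 40.0,
    duration_s: float = 20.0,
    glom_radius_mm: float = 0.15,
    swirl_speed: float = 0.3,
    glom_rate: float = 0.5,
    vessel_rate: float = 2.0,
    vessel_width_mm: float = 0.3,
    vessels_per_roi: int = 7,
    noise_sigma: float = 0.05,
) -> tuple[FrameStack, GroundTruth, list[ROIMask]]:
    """A cortex-vs-lesion phantom mimicking the clinical contrast.

    The left half of the field is a "cortex" ROI seeded with glomeruli at the
    requested density (per cm^2) plus vessels; the right half is a "lesion"
    ROI with vessels only. Glomeruli are placed by rejection sampling with a
    minimum center separation of 4x their radius and a standoff from vessel
    centerlines, so each bundle is individually resolvable; a density too
    high to satisfy those constraints raises ``ValueError``.
    """
    if glomerular_density < 0:
        raise ValueError("density must be non-negative")
    rng = np.random.default_rng(seed)
    fx, fy = field_size
    half_x = fx / 2.0
    margin = 0.6
    cortex_area_cm2 = (half_x * fy) / 100.0
    n_glom = int(round(glomerular_density * cortex_area_cm2))

    # an interlobular-artery-like bed: evenly spaced horizontal vessels of
    # finite width at renal cortical speeds (2-6 cm/s)
    y_levels = [fy * (i + 1) / (vessels_per_roi + 1) for i in range(vessels_per_roi)]
    speeds = list(np.linspace(2.0, 6.0, vessels_per_roi))
    vessels = _default_vessels(0.0, half_x - 0.2, y_levels, speeds, vessel_rate, vessel_width_mm) + \
        _default_vessels(half_x + 0.2, fx, y_levels, speeds, vessel_rate, vessel_width_mm)

    centers: list[tuple[float, float]] = []
    min_sep = 4.0 * glom_radius_mm
    vessel_standoff = vessel_width_mm / 2 + glom_radius_mm + 0.05
    attempts = 0
    while len(centers) < n_glom:
        attempts += 1
        if attempts > 20000:
            raise ValueError(
                f"cannot place {n_glom} glomeruli at separation {min_sep} mm: density too high"
            )
        x = rng.uniform(margin, half_x - margin)
        y = rng.uniform(margin, fy - margin)
        if any(abs(y - yl) < vessel_standoff for yl in y_levels):
            continue
        if any(np.hypot(x - cx, y - cy) < min_sep for cx, cy in centers):
            continue
        centers.append((x, y))

    glomeruli = [
        Glomerulus(c, radius_mm=glom_radius_mm, swirl_speed=swirl_speed, rate=glom_rate)
        for c in centers
    ]
    scene = SimScene(
        field_size=field_size,
        pixel_spacing=pixel_spacing,
        frame_rate=frame_rate,
        n_frames=int(round(duration_s * frame_rate)),
        vessels=vessels,
        glomeruli=glomeruli,
        noise_sigma=noise_sigma,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    stack, truth = simulate_scene(scene)

    h, w = scene.grid_shape
    cortex_mask = np.zeros((h, w), dtype=bool)
    lesion_mask = np.zeros((h, w), dtype=bool)
    split_col = int(round(half_x / pixel_spacing))
    cortex_mask[:, :split_col] = True
    lesion_mask[:, split_col:] = True
    masks = [
        ROIMask("cortex", cortex_mask, pixel_spacing),
        ROIMask("lesion", lesion_mask, pixel_spacing),
    ]
    truth.roi_density = {
        "cortex": n_glom / masks[0].area_cm2,
        "lesion": 0.0,
    }
    return stack, truth, masks
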