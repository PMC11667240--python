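import numpy as np
import pytest

from sulm.frames import FrameStack
from sulm.synthetic import Glomerulus, SimScene, Vessel, make_two_roi_phantom


def render_blob(shape, row, col, sigma):
    """Noiseless isotropic Gaussian blob at a sub-pixel position."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return np.exp(-((yy - row) ** 2 + (xx - col) ** 2) / (2.0 * sigma**2))


@pytest.fixture(scope="session")
def short_phantom():
    """A 5 s two-ROI phantom (one processing block) shared across tests."""
    return make_two_roi_phantom(seed=7, glomerular_density=26.0, duration_s=5.0)


@pytest.fixture
def simple_scene():
    """One straight vessel and one glomerulus, deterministic seed."""
    return SimScene(
        field_size=(10.0, 5.0),
        pixel_spacing=0.2,
        frame_rate=40.0,
        n_frames=200,
        vessels=[Vessel(np.array([[0.0, 1.0], [10.0, 1.0]]), speed=2.0, rate=1.0)],
        glomeruli=[Glomerulus((5.0, 3.5), radius_mm=0.15, swirl_speed=0.3, rate=1.0)],
        noise_sigma=0.02,
        seed=11,
    )


@pytest.fixture
def constant_stack():
    return FrameStack(np.full((200, 8, 8), 7.3), pixel_spacing=0.2, frame_rate=40.0)
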