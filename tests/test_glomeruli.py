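"""ND grid construction, percentile segmentation and area-normalized counts."""

import numpy as np
import pandas as pd
import pytest

from sulm.frames import ROIMask
from sulm.glomeruli import GlomerulusSet, NDGrid, build_nd_grid, density_per_roi, detect_glomeruli
from sulm.metrics import compute_track_metrics
from sulm.tracking import Track


def make_track(pts_px, track_id):
    return Track(frames=np.arange(len(pts_px)), rows=pts_px[:, 0], cols=pts_px[:, 1],
                 track_id=track_id)


def straight(row, c0, c1, n, track_id):
    return make_track(np.column_stack([np.full(n, row), np.linspace(c0, c1, n)]), track_id)


class TestBuildNDGrid:
    def test_straight_track_paints_its_nd_everywhere(self):
        t = straight(5.0, 2.0, 20.0, 10, 0)
        metrics = pd.DataFrame({"track_id": [0], "normalized_distance": [1.0]})
        grid = build_nd_grid([t], metrics, pixel_spacing=0.2, field_shape_px=(16, 32))
        assert grid.values[grid.visited].min() == 1.0
        assert grid.values[grid.visited].max() == 1.0
        assert grid.values[~grid.visited].sum() == 0.0

    def test_max_aggregation_on_shared_cells(self):
        a = straight(5.0, 2.0, 20.0, 10, 0)
        b = straight(5.0, 2.0, 20.0, 10, 1)  # same trajectory, higher ND
        metrics = pd.DataFrame({"track_id": [0, 1], "normalized_distance": [1.0, 10.0]})
        grid = build_nd_grid([a, b], metrics, 0.2, field_shape_px=(16, 32))
        assert grid.values[grid.visited].max() == 10.0
        assert grid.values[grid.visited].min() == 10.0

    def test_trajectory_interpolation_paints_between_points(self):
        # two points 4 px apart: at x8 super-resolution the line between
        # them (32 cells) must be visited, not just the endpoints
        t = make_track(np.array([[5.0, 2.0], [5.0, 6.0], [5.0, 10.0]]), 0)
        metrics = pd.DataFrame({"track_id": [0], "normalized_distance": [1.0]})
        grid = build_nd_grid([t], metrics, 0.2, field_shape_px=(16, 16))
        assert grid.visited.sum() >= 60

    def test_empty_tracks_rejected(self):
        with pytest.raises(ValueError):
            build_nd_grid([], pd.DataFrame(), 0.2)


class TestDetectGlomeruli:
    def _grid_with_blob(self, hot=50.0, base=1.0):
        values = np.zeros((200, 200))
        visited = np.zeros((200, 200), dtype=bool)
        visited[20, :] = True  # a "vessel" line
        values[20, :] = base
        values[100:108, 100:108] = hot
        visited[100:108, 100:108] = True
        return NDGrid(values, visited, grid_spacing=0.025)

    def test_single_hot_blob_detected_at_center(self):
        gset = detect_glomeruli(self._grid_with_blob(), smooth_sigma_mm=0.05)
        assert gset.count == 1
        x, y = gset.centers_mm[0]
        assert x == pytest.approx(103.5 * 0.025, abs=0.05)
        assert y == pytest.approx(103.5 * 0.025, abs=0.05)

    def test_all_equal_visited_values_give_nothing(self):
        values = np.zeros((50, 50))
        visited = np.zeros((50, 50), dtype=bool)
        visited[10:40, 25] = True
        values[10:40, 25] = 3.0
        gset = detect_glomeruli(NDGrid(values, visited, 0.025), smooth_sigma_mm=0.0)
        assert gset.count == 0  # strict ">" at a degenerate percentile

    def test_empty_grid_empty_set(self):
        grid = NDGrid(np.zeros((10, 10)), np.zeros((10, 10), dtype=bool), 0.025)
        assert detect_glomeruli(grid).count == 0

    def test_min_area_filter(self):
        grid = self._grid_with_blob()
        gset = detect_glomeruli(grid, smooth_sigma_mm=0.05, min_area_mm2=10.0)
        assert gset.count == 0

    def test_percentile_monotonicity(self):
        # isolated unimodal peaks: a higher cut can only shrink or drop a
        # component, never split one (splitting is possible on ridge-shaped
        # fields, which the glomerular regime does not produce)
        rng = np.random.default_rng(12)
        values = np.zeros((100, 100))
        for _ in range(12):
            r0, c0 = rng.uniform(10, 90, 2)
            amp = rng.uniform(1, 30)
            yy, xx = np.mgrid[0:100, 0:100]
            values += amp * np.exp(-((yy - r0) ** 2 + (xx - c0) ** 2) / (2 * 3.0**2))
        visited = values > 0.05
        grid = NDGrid(values * visited, visited, 0.025)
        counts = [
            detect_glomeruli(grid, smooth_sigma_mm=0.05, percentile=p, min_area_mm2=0.0).count
            for p in (50, 70, 90, 97)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_translation_equivariance(self):
        grid = self._grid_with_blob()
        shift = 24
        values = np.roll(grid.values, shift, axis=1)
        visited = np.roll(grid.visited, shift, axis=1)
        a = detect_glomeruli(grid, smooth_sigma_mm=0.05)
        b = detect_glomeruli(NDGrid(values, visited, grid.grid_spacing), smooth_sigma_mm=0.05)
        np.testing.assert_allclose(
            b.centers_mm, a.centers_mm + [shift * grid.grid_spacing, 0.0], atol=1e-9
        )


class TestDensityPerROI:
    def _mask(self, label, area_px, shape=(100, 100), col0=0):
        m = np.zeros(shape, dtype=bool)
        m[:, col0 : col0 + area_px] = True
        return ROIMask(label, m, pixel_spacing=1.0)

    def test_lesion_density_convention(self):
        # 7 centers in a 2.9 cm^2 mask -> 7/2.9 per cm^2
        mask = ROIMask("tumor", np.ones((17, 17), dtype=bool), pixel_spacing=1.0)
        assert mask.area_cm2 == pytest.approx(2.89)
        rng = np.random.default_rng(4)
        centers = rng.uniform(1, 16, size=(7, 2))
        gset = GlomerulusSet(centers, np.full(7, 0.01), 7)
        table = density_per_roi(gset, [mask]).set_index("roi_label")
        assert table.loc["tumor", "density_per_cm2"] == pytest.approx(7 / 2.89)

    def test_zero_centers_zero_density(self):
        gset = GlomerulusSet(np.empty((0, 2)), np.empty(0), 0)
        table = density_per_roi(gset, [self._mask("cortex", 50)]).set_index("roi_label")
        assert table.loc["cortex", "density_per_cm2"] == 0.0

    def test_doubling_area_halves_density(self):
        centers = np.array([[5.0, 5.0], [10.0, 10.0]])
        gset = GlomerulusSet(centers, np.full(2, 0.01), 2)
        d1 = density_per_roi(gset, [self._mask("a", 50)]).set_index("roi_label")
        d2 = density_per_roi(gset, [self._mask("a", 100)]).set_index("roi_label")
        assert d2.loc["a", "density_per_cm2"] == pytest.approx(
            d1.loc["a", "density_per_cm2"] / 2
        )

    def test_centers_outside_rois_counted_as_background(self):
        gset = GlomerulusSet(np.array([[5.0, 5.0], [80.0, 80.0]]), np.full(2, 0.01), 2)
        table = density_per_roi(gset, [self._mask("a", 50)]).set_index("roi_label")
        assert table.loc["a", "count"] == 1
        assert table.loc["background", "count"] == 1

    def test_overlapping_rois_rejected(self):
        gset = GlomerulusSet(np.empty((0, 2)), np.empty(0), 0)
        with pytest.raises(ValueError, match="overlap"):
            density_per_roi(gset, [self._mask("a", 60), self._mask("b", 60)])


def test_grid_maxima_colocate_with_true_glomeruli(short_phantom):
    """On the phantom, the hottest smoothed ND cells sit inside true bundles."""
    from scipy import ndimage

    from sulm.pipeline import PipelineConfig, run_pipeline

    stack, truth, masks = short_phantom
    res = run_pipeline(stack, PipelineConfig.bolus(), masks)
    grid = res.nd_grid
    sm = ndimage.gaussian_filter(grid.values, 0.05 / grid.grid_spacing)
    k = 20
    idx = np.argsort(sm[grid.visited])[-k:]
    cells = np.argwhere(grid.visited)[idx]
    xy = cells[:, ::-1] * grid.grid_spacing
    centers = truth.glomerulus_centers
    d = np.min(np.linalg.norm(xy[:, None, :] - centers[None, :, :], axis=2), axis=1)
    assert (d <= 0.3).mean() >= 0.8
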