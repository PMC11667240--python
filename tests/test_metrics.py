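"""Track-metric analytics: hand-computed values and geometric invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sulm.frames import ROIMask
from sulm.metrics import (
    compute_track_metrics,
    dispersity,
    mean_speed,
    normalized_distance,
    normalized_speed,
    roi_track_summary,
)
from sulm.tracking import Track


def rot(points, deg):
    th = np.radians(deg)
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    return points @ R.T


class TestNormalizedDistance:
    def test_straight_line_is_one(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        assert normalized_distance(pts) == pytest.approx(1.0)

    def test_dense_semicircle_approaches_half_pi(self):
        th = np.linspace(0, np.pi, 5000)
        pts = np.column_stack([np.cos(th), np.sin(th)])
        assert normalized_distance(pts) == pytest.approx(np.pi / 2, abs=1e-6)

    def test_near_closed_square_loop(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0], [0.0, 0.1]])
        assert normalized_distance(pts) == pytest.approx(39.0)

    def test_cap_when_chord_below_grid_cell(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0], [0.0, 0.001]])
        assert normalized_distance(pts, min_chord=0.01, cap=100.0) == 100.0

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            normalized_distance(np.array([[0.0, 0.0]]))

    @given(st.floats(min_value=0.1, max_value=100), st.floats(min_value=0, max_value=360))
    @settings(max_examples=50, deadline=None)
    def test_scale_and_rotation_invariance(self, scale, angle):
        rng = np.random.default_rng(77)
        pts = rng.uniform(0, 10, size=(8, 2))
        base = normalized_distance(pts)
        assert normalized_distance(rot(pts * scale, angle)) == pytest.approx(base, rel=1e-9)


class TestDispersity:
    def test_straight_five_point_track(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0], [3.0, 0.0], [4.0, 0.0]])
        assert dispersity(pts) == pytest.approx(0.6)  # 3 same-direction pairs / 5 points

    def test_right_angle_square_path_is_zero(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0], [0.0, 0.0]])
        assert dispersity(pts) == 0.0

    @pytest.mark.parametrize("n", [5, 10, 50])
    def test_straight_track_limit(self, n):
        pts = np.column_stack([np.arange(n, dtype=float), np.zeros(n)])
        assert dispersity(pts) == pytest.approx((n - 2) / n)

    def test_duplicate_rounded_points_dropped(self):
        # sub-grid wiggle collapses to 3 distinct rounded points -> 1 pair / 6 points
        pts = np.array([[0.0, 0.0], [0.1, 0.0], [1.0, 0.0], [1.1, 0.0], [2.0, 0.0], [2.1, 0.0]])
        assert dispersity(pts) == pytest.approx(1 / 6)

    def test_collapsed_track_warns_and_returns_zero(self):
        pts = np.full((5, 2), 0.2)
        with pytest.warns(UserWarning):
            assert dispersity(pts) == 0.0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            dispersity(np.array([[0.0, 0.0], [1.0, 0.0]]))

    def test_scale_invariance_with_matched_grid(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 20, size=(10, 2))
        base = dispersity(pts, grid_spacing=1.0)
        assert dispersity(pts * 7.3, grid_spacing=7.3) == pytest.approx(base)


class TestSpeeds:
    def test_two_points_at_40hz(self):
        pts = np.array([[0.0, 0.0], [0.5, 0.0]])  # mm
        assert mean_speed(pts, 40.0) == pytest.approx(2.0)  # cm/s

    def test_stationary_track(self):
        assert mean_speed(np.zeros((5, 2)), 40.0) == 0.0

    def test_normalized_speed_single_track_is_one(self):
        assert normalized_speed(np.array([3.7])) == pytest.approx([1.0])

    def test_normalized_speed_all_equal(self):
        np.testing.assert_allclose(normalized_speed(np.full(10, 2.0)), 1.0)

    def test_normalized_speed_all_zero(self):
        np.testing.assert_array_equal(normalized_speed(np.zeros(5)), 0.0)

    def test_normalized_speed_percentile_reference(self):
        speeds = np.arange(1.0, 101.0)
        ns = normalized_speed(speeds)
        assert ns[49] == pytest.approx(50 / 99.01, rel=1e-6)
        assert ns.max() == 1.0  # clipped above the 99th percentile


class TestMetricsTableAndRotation:
    def _track(self, pts_px, track_id=0):
        return Track(
            frames=np.arange(len(pts_px)),
            rows=pts_px[:, 0],
            cols=pts_px[:, 1],
            track_id=track_id,
        )

    def test_rotation_invariance_of_all_metrics(self):
        rng = np.random.default_rng(8)
        pts = rng.uniform(5, 20, size=(12, 2))
        a = compute_track_metrics([self._track(pts)], 0.2, 40.0, dispersity_grid_px=1e-9)
        b = compute_track_metrics([self._track(rot(pts, 33.0))], 0.2, 40.0, dispersity_grid_px=1e-9)
        for col in ["normalized_distance", "mean_speed_cm_s", "dispersity", "path_length_mm"]:
            assert a[col][0] == pytest.approx(b[col][0], rel=1e-9)

    def test_roi_membership_majority_rule(self):
        mask = np.zeros((50, 50), dtype=bool)
        mask[:, :25] = True
        roi = ROIMask("cortex", mask, 0.2)
        # 40% of points inside -> excluded; 60% inside -> included
        t_out = self._track(np.column_stack([np.full(10, 10.0), np.arange(21.0, 31.0)]), 0)
        t_in = self._track(np.column_stack([np.full(10, 10.0), np.arange(19.0, 29.0)]), 1)
        metrics = compute_track_metrics([t_out, t_in], 0.2, 40.0)
        summary = roi_track_summary([t_out, t_in], metrics, roi)
        assert summary["n_tracks"] == 1

    def test_empty_roi_flagged(self):
        mask = np.zeros((50, 50), dtype=bool)
        mask[0, 0] = True
        roi = ROIMask("lesion", mask, 0.2)
        t = self._track(np.column_stack([np.full(5, 40.0), np.arange(40.0, 45.0)]))
        metrics = compute_track_metrics([t], 0.2, 40.0)
        assert roi_track_summary([t], metrics, roi)["empty"]


def test_glomerular_tracks_swirl_more_and_move_less(short_phantom):
    """Direction-of-effect on the simulator: swirling confined tracks have
    higher normalized distance and lower speed than vessel transits."""
    from sulm.pipeline import PipelineConfig, run_pipeline

    stack, truth, masks = short_phantom
    res = run_pipeline(stack, PipelineConfig.bolus(), masks)
    centers = truth.glomerulus_centers
    glom_nd, glom_sp, ves_nd, ves_sp = [], [], [], []
    for t in res.tracks:
        c = t.points_mm(stack.pixel_spacing).mean(axis=0)
        row = res.metrics[res.metrics.track_id == t.track_id].iloc[0]
        if np.hypot(centers[:, 0] - c[0], centers[:, 1] - c[1]).min() < 0.3:
            glom_nd.append(row.normalized_distance)
            glom_sp.append(row.mean_speed_cm_s)
        else:
            ves_nd.append(row.normalized_distance)
            ves_sp.append(row.mean_speed_cm_s)
    assert np.median(glom_nd) > np.median(ves_nd)
    assert np.median(glom_sp) < np.median(ves_sp)
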