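"""Tubeness, trainable segmentation, LVD, reconnection, area fraction."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from nirflow.pumping import ImageStack, ROI
from nirflow.simulate import (
    CameraParams,
    ContractionParams,
    VesselGeometry,
    WoundSpec,
    make_ihc_phantom,
    simulate_stack,
    simulate_wound_series,
)
from nirflow.vasculature import (
    DegenerateTrainingError,
    NormalizationRoi,
    SegmentationModel,
    VesselnessParams,
    area_fraction,
    average_projection,
    compute_lvd,
    dice,
    reconnection_day,
    segment,
    train_segmenter,
    tubeness,
)

from conftest import bfs_connected


def gaussian_ridge(shape=(101, 101), width=3.0, angle_deg=0.0, amplitude=100.0):
    """Analytic bright ridge through the image center at a given angle."""
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    theta = np.deg2rad(angle_deg)
    # signed distance to the line through the center with direction theta
    d = -(rr - h // 2) * np.cos(theta) + (cc - w // 2) * np.sin(theta)
    return amplitude * np.exp(-(d**2) / (2.0 * width**2))


def fd_hessian_response(image, sigma, at):
    """Finite-difference oracle: smooth at sigma, central-difference
    Hessian at one pixel, sigma^2-normalized bright-tube response."""
    g = gaussian_filter(np.asarray(image, dtype=float), sigma)
    r, c = at
    hrr = g[r + 1, c] - 2 * g[r, c] + g[r - 1, c]
    hcc = g[r, c + 1] - 2 * g[r, c] + g[r, c - 1]
    hrc = (g[r + 1, c + 1] - g[r + 1, c - 1] - g[r - 1, c + 1] + g[r - 1, c - 1]) / 4.0
    eigs = np.linalg.eigvalsh(np.array([[hrr, hrc], [hrc, hcc]]))
    lam2 = eigs[np.argmax(np.abs(eigs))]
    return sigma**2 * max(0.0, -lam2)


class TestAverageProjection:
    def test_identical_frames(self):
        frame = np.arange(100, dtype=float).reshape(10, 10)
        stack = ImageStack(frames=np.stack([frame] * 4), fps=5.0)
        np.testing.assert_allclose(average_projection(stack), frame)

    def test_two_constant_frames(self):
        stack = ImageStack(
            frames=np.stack([np.full((5, 5), 2.0), np.full((5, 5), 4.0)]), fps=5.0
        )
        np.testing.assert_allclose(average_projection(stack), 3.0)

    def test_matches_loop_oracle(self, rng):
        frames = rng.uniform(0, 10, size=(4, 6, 6))
        stack = ImageStack(frames=frames, fps=5.0)
        proj = average_projection(stack)
        for r in range(6):
            for c in range(6):
                assert proj[r, c] == pytest.approx(
                    sum(frames[t, r, c] for t in range(4)) / 4
                )


class TestTubeness:
    def test_constant_image_zero_response(self):
        assert np.all(tubeness(np.full((32, 32), 9.0)) == 0)

    def test_dark_ridge_zero_in_bright_mode(self):
        img = 100.0 - gaussian_ridge(width=3.0)
        center = tubeness(img, VesselnessParams(scales=(3.0,)))[50, 50]
        assert center == 0.0

    def test_centerline_response_matches_fd_hessian_oracle(self):
        img = gaussian_ridge(width=3.0)
        got = tubeness(img, VesselnessParams(scales=(3.0,)))[50, 50]
        expected = fd_hessian_response(img, 3.0, (50, 50))
        assert got == pytest.approx(expected, rel=0.05)

    def test_response_maximized_on_centerline(self):
        img = gaussian_ridge(width=3.0)
        vmap = tubeness(img, VesselnessParams(scales=(1.5, 3.0, 6.0)))
        assert np.argmax(vmap[:, 50]) == 50

    def test_scale_selection_follows_closed_form(self):
        # sigma^2-normalized response of a Gaussian ridge of width w peaks
        # at sigma = sqrt(2) * w; the matching candidate must win
        w = 3.0
        img = gaussian_ridge(width=w)
        best = w * np.sqrt(2.0)
        scales = (w / 2.0, best, 4.0 * w)
        responses = [
            tubeness(img, VesselnessParams(scales=(s,)))[50, 50] for s in scales
        ]
        assert int(np.argmax(responses)) == 1
        # and each agrees with the finite-difference oracle
        for s, resp in zip(scales, responses):
            assert resp == pytest.approx(
                fd_hessian_response(img, s, (50, 50)), rel=0.05
            )

    def test_rotation_invariance_within_2_percent(self):
        p = VesselnessParams(scales=(3.0,))
        r0 = tubeness(gaussian_ridge(angle_deg=0.0), p)[50, 50]
        for angle in (30.0, 45.0, 75.0):
            r = tubeness(gaussian_ridge(angle_deg=angle), p)[50, 50]
            assert r == pytest.approx(r0, rel=0.02)

    def test_scale_covariance_within_5_percent(self):
        r1 = tubeness(
            gaussian_ridge(width=2.0), VesselnessParams(scales=(2.0,))
        )[50, 50]
        r2 = tubeness(
            gaussian_ridge(width=4.0), VesselnessParams(scales=(4.0,))
        )[50, 50]
        assert r2 == pytest.approx(r1, rel=0.05)

    def test_non_finite_pixels_rejected(self):
        img = np.ones((16, 16))
        img[3, 3] = np.nan
        with pytest.raises(ValueError):
            tubeness(img)


@pytest.fixture(scope="module")
def vessel_scene():
    geom = VesselGeometry(
        centerline=((20.0, 10.0), (60.0, 50.0), (90.0, 110.0)),
        radius_px=3.0,
        image_shape=(128, 128),
    )
    stack, mask, _ = simulate_stack(
        geom, ContractionParams(true_rate=8.0), CameraParams(), 20.0, seed=5
    )
    return average_projection(stack), mask


def _sample_labels(mask, n, rng):
    fg = np.argwhere(mask)
    bg = np.argwhere(~mask)
    fg = fg[rng.choice(len(fg), n, replace=False)]
    bg = bg[rng.choice(len(bg), n, replace=False)]
    rows = np.concatenate([fg[:, 0], bg[:, 0]])
    cols = np.concatenate([fg[:, 1], bg[:, 1]])
    classes = np.concatenate([np.ones(n, int), np.zeros(n, int)])
    return rows, cols, classes


class TestSegmentation:
    def test_training_accuracy_on_separable_phantom(self, vessel_scene, rng):
        proj, mask = vessel_scene
        rows, cols, classes = _sample_labels(mask, 200, rng)
        model = train_segmenter(proj, rows, cols, classes, seed=0)
        pred = segment(proj, model)
        acc = (pred[rows, cols] == classes.astype(bool)).mean()
        assert acc >= 0.99

    def test_conflicting_labels_train_but_cannot_separate(self):
        img = np.full((16, 16), 5.0)
        rows = np.array([4, 4, 8, 8])
        cols = np.array([4, 4, 8, 8])
        classes = np.array([1, 0, 1, 0])
        model = train_segmenter(img, rows, cols, classes, seed=0)
        pred = segment(img, model)
        acc = (pred[rows, cols] == classes.astype(bool)).mean()
        assert acc <= 0.5

    def test_same_seed_identical_predictions(self, vessel_scene, rng):
        proj, mask = vessel_scene
        rows, cols, classes = _sample_labels(mask, 100, rng)
        m1 = train_segmenter(proj, rows, cols, classes, seed=9)
        m2 = train_segmenter(proj, rows, cols, classes, seed=9)
        np.testing.assert_array_equal(segment(proj, m1), segment(proj, m2))

    def test_single_class_labels_rejected(self):
        with pytest.raises(DegenerateTrainingError):
            train_segmenter(
                np.ones((8, 8)), np.array([1]), np.array([1]), np.array([1])
            )

    def test_untrained_fallback_dice(self, vessel_scene):
        proj, mask = vessel_scene
        assert dice(segment(proj), mask) >= 0.80

    def test_trained_dice(self, vessel_scene, rng):
        proj, mask = vessel_scene
        rows, cols, classes = _sample_labels(mask, 200, rng)
        model = train_segmenter(proj, rows, cols, classes, seed=0)
        assert dice(segment(proj, model), mask) >= 0.80

    def test_all_background_phantom_segments_empty(self, rng):
        img = 50.0 + 2.0 * rng.standard_normal((96, 96))
        assert segment(img).mean() < 0.01

    def test_mask_is_binary_and_same_shape(self, vessel_scene):
        proj, _ = vessel_scene
        out = segment(proj)
        assert out.dtype == bool and out.shape == proj.shape


class TestLvd:
    NORM = NormalizationRoi("WT", ear_to_tail_mm=8.0, back_to_belly_mm=12.0)

    def test_norm_roi_area_is_square_of_mean_length(self):
        assert self.NORM.side_mm == 10.0
        assert self.NORM.area_mm2 == 100.0

    def test_empty_mask_zero_density(self):
        res = compute_lvd(np.zeros((50, 50), dtype=bool), 100.0, self.NORM)
        assert res.density == 0.0

    def test_full_mask_unit_density(self):
        # 100x100 px at 100 um/px -> (10 mm)^2 = ROI area
        res = compute_lvd(np.ones((100, 100), dtype=bool), 100.0, self.NORM)
        assert res.density == pytest.approx(1.0)

    def test_half_mask_half_density(self):
        mask = np.zeros((100, 100), dtype=bool)
        mask[:50] = True
        res = compute_lvd(mask, 100.0, self.NORM)
        assert res.density == pytest.approx(0.5)

    def test_pixel_units_mode(self):
        mask = np.ones((10, 10), dtype=bool)
        res = compute_lvd(mask, norm=400.0)
        assert res.units == "px2" and res.density == pytest.approx(0.25)

    def test_monotone_in_foreground(self, rng):
        mask = rng.random((40, 40)) < 0.1
        d0 = compute_lvd(mask, norm=1600.0).density
        mask2 = mask.copy()
        mask2[0, 0] = True
        mask2[20, 20] = True
        assert compute_lvd(mask2, norm=1600.0).density >= d0

    def test_zero_roi_area_rejected(self):
        with pytest.raises(ValueError):
            compute_lvd(np.ones((4, 4), dtype=bool), norm=0.0)


class TestReconnection:
    ROI_A = ROI.circle(12, 12, 8)
    ROI_B = ROI.circle(84, 84, 8)

    def test_straight_vessel_connects_day_one(self):
        mask = np.zeros((96, 96), dtype=bool)
        rr = np.arange(96)
        mask[rr, rr] = True
        res = reconnection_day({1: mask}, self.ROI_A, self.ROI_B)
        assert res.reconnection_day == 1

    def test_all_empty_masks_never_reconnect(self):
        series = {d: np.zeros((96, 96), dtype=bool) for d in (1, 5, 9)}
        res = reconnection_day(series, self.ROI_A, self.ROI_B)
        assert not res.reconnected and res.reconnection_day is None

    def test_truth_masks_recover_truth_day(self):
        geom = VesselGeometry(
            centerline=((12.0, 12.0), (48.0, 40.0), (84.0, 84.0)),
            radius_px=2.5,
            image_shape=(96, 96),
        )
        spec = WoundSpec(
            node_roi_a=(12, 12, 8), node_roi_b=(84, 84, 8),
            truth_reconnection_day=12, collateral_paths=2,
        )
        series = simulate_wound_series(spec, geom, list(range(1, 25)), seed=3)
        masks = {d: m for d, (_, m) in series.items()}
        res = reconnection_day(masks, self.ROI_A, self.ROI_B)
        assert res.reconnection_day == 12

    def test_decision_equals_bfs_oracle(self, rng):
        a_mask = self.ROI_A.mask((96, 96))
        b_mask = self.ROI_B.mask((96, 96))
        for i in range(10):
            mask = rng.random((96, 96)) < 0.25
            res = reconnection_day({1: mask}, self.ROI_A, self.ROI_B)
            assert res.connected[0] == bfs_connected(mask, a_mask, b_mask)

    def test_overlapping_rois_rejected(self):
        with pytest.raises(ValueError):
            reconnection_day(
                {1: np.zeros((96, 96), dtype=bool)},
                ROI.circle(40, 40, 10),
                ROI.circle(45, 45, 10),
            )


class TestAreaFraction:
    def test_phantom_half_fraction(self):
        _, mask = make_ihc_phantom(0.5, seed=3)
        assert 0.48 <= area_fraction(mask) <= 0.52

    def test_empty_and_full(self):
        assert area_fraction(np.zeros((10, 10), dtype=bool)) == 0.0
        assert area_fraction(np.ones((10, 10), dtype=bool)) == 1.0

    def test_restricted_region(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[:10] = True
        region = ROI.from_polygon([(0, 0), (0, 19), (9, 19), (9, 0)])
        assert area_fraction(mask, region) == 1.0
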