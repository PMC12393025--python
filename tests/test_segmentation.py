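"""Segmentation and 13-marker midline extraction."""

import numpy as np
import pytest
from skimage import measure

from wormtrace.errors import (
    AmbiguousHeadError,
    SegmentationError,
    UnusableMaskError,
)
from wormtrace.segmentation import (
    SegmentationConfig,
    binarize,
    detect_head_tail,
    extract_outline,
    fit_frame,
    fit_midline,
    remove_debris,
)
from wormtrace.synth import WormPose, render_worm


class TestBinarize:
    def test_worm_dark_matches_renderer_mask(self, rendered_worm):
        _, image, truth = rendered_worm
        mask = binarize(image, 120.0, "worm-dark")
        agreement = (mask == truth.mask).mean()
        assert agreement >= 0.99

    def test_uniform_image_flagged(self):
        with pytest.raises(UnusableMaskError, match="all-foreground"):
            binarize(np.full((20, 20), 100.0), 150.0, "worm-dark")

    def test_threshold_below_everything_flagged(self):
        pose = WormPose(amplitude_um=60.0)
        image, _ = render_worm(pose, seed=0, noise_sigma=0.0)
        with pytest.raises(UnusableMaskError, match="all-background"):
            binarize(image, 30.0, "worm-dark")

    def test_polarities_are_complements(self, rendered_worm):
        _, image, _ = rendered_worm
        dark = binarize(image, 120.0, "worm-dark")
        bright = binarize(image, 120.0, "worm-bright")
        assert not np.any(dark & bright) and np.all(dark | bright)


class TestRemoveDebris:
    def test_boundary_at_min_area(self):
        # 2,999 px object removed; 3,001 px object kept
        mask = np.zeros((200, 200), dtype=bool)
        mask[:30, :100] = True  # 3000 px block
        mask[0, 99] = False  # 2999
        mask[100:131, 100:197] = True  # 31*97 = 3007
        out = remove_debris(mask, min_area=3000)
        labels = measure.label(out, connectivity=2)
        assert labels.max() == 1
        assert out[110, 110] and not out[10, 10]

    def test_exact_min_area_is_kept(self):
        mask = np.zeros((100, 100), dtype=bool)
        mask[:30, :100] = True  # exactly 3000
        assert remove_debris(mask, 3000).sum() == 3000

    def test_empty_mask_flagged(self):
        with pytest.raises(UnusableMaskError):
            remove_debris(np.zeros((10, 10), dtype=bool))

    def test_matches_bruteforce_component_filter(self, rng):
        # random blob fields against an explicit per-component area filter
        for _ in range(200):
            mask = rng.random((48, 48)) < 0.35
            min_area = int(rng.integers(2, 40))
            labels = measure.label(mask, connectivity=2)
            expected = np.zeros_like(mask)
            for lab in range(1, labels.max() + 1):
                comp = labels == lab
                if comp.sum() >= min_area:
                    expected |= comp
            if not expected.any():
                with pytest.raises(UnusableMaskError):
                    remove_debris(mask, min_area)
            else:
                assert np.array_equal(remove_debris(mask, min_area), expected)


class TestExtractOutline:
    def test_disk_perimeter(self):
        yy, xx = np.mgrid[0:120, 0:120]
        mask = (xx - 60) ** 2 + (yy - 60) ** 2 <= 50**2
        outline = extract_outline(mask)
        assert outline.perimeter == pytest.approx(2 * np.pi * 50, rel=0.03)

    def test_outline_encloses_body(self, rendered_worm):
        from skimage.draw import polygon

        _, image, truth = rendered_worm
        mask = remove_debris(binarize(image, 120.0), 3000)
        outline = extract_outline(mask)
        rr, cc = polygon(outline.vertices[:, 1], outline.vertices[:, 0], truth.mask.shape)
        filled = np.zeros_like(truth.mask)
        filled[rr, cc] = True
        assert (filled & truth.mask).sum() / truth.mask.sum() >= 0.98

    def test_tiny_component_rejected(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[5, 5] = True
        with pytest.raises(SegmentationError):
            extract_outline(mask)

    def test_multiple_components_uses_largest(self, rendered_worm):
        _, image, truth = rendered_worm
        mask = binarize(image, 120.0).copy()
        mask[:3, :3] = True  # spurious blob
        with pytest.warns(UserWarning, match="largest"):
            outline = extract_outline(mask)
        assert len(outline) >= 40


class TestHeadTail:
    def test_tail_is_sharper_and_near_true_tail(self):
        rng = np.random.default_rng(21)
        hits = 0
        n_poses = 10
        for k in range(n_poses):
            pose = WormPose(
                amplitude_um=rng.uniform(0, 90),
                wavelength_um=rng.uniform(900, 1300),
                phase=rng.uniform(0, 2 * np.pi),
                heading_rad=rng.uniform(0, 2 * np.pi),
            )
            image, truth = render_worm(pose, seed=100 + k, noise_sigma=5.0)
            mask = remove_debris(binarize(image, 120.0), 3000)
            outline = extract_outline(mask)
            ht = detect_head_tail(outline, prev_head=truth.markers_px[0])
            # tail within 5% of body length of the true tail tip
            if np.linalg.norm(ht.tail - truth.markers_px[-1]) <= 0.05 * truth.length_um / 5.0:
                hits += 1
        assert hits == n_poses

    def test_symmetric_ellipse_is_ambiguous(self):
        yy, xx = np.mgrid[0:160, 0:300]
        mask = ((xx - 150) / 130.0) ** 2 + ((yy - 80) / 40.0) ** 2 <= 1
        outline = extract_outline(mask)
        with pytest.raises(AmbiguousHeadError):
            detect_head_tail(outline)

    def test_prev_head_fixes_assignment(self, rendered_worm):
        _, image, truth = rendered_worm
        mask = remove_debris(binarize(image, 120.0), 3000)
        outline = extract_outline(mask)
        ht = detect_head_tail(outline, prev_head=truth.markers_px[0])
        assert ht.confirmed
        assert np.linalg.norm(ht.head - truth.markers_px[0]) < np.linalg.norm(
            ht.head - truth.markers_px[-1]
        )

    def test_unseeded_assignment_unconfirmed(self, rendered_worm):
        _, image, _ = rendered_worm
        mask = remove_debris(binarize(image, 120.0), 3000)
        outline = extract_outline(mask)
        ht = detect_head_tail(outline)
        assert not ht.confirmed


class TestFitMidline:
    def test_straight_worm_length_and_collinearity(self):
        pose = WormPose(amplitude_um=0.0)
        image, truth = render_worm(pose, seed=0, noise_sigma=0.0)
        mask = remove_debris(binarize(image, 120.0), 3000)
        outline = extract_outline(mask)
        spline = fit_midline(outline, truth.markers_px[0], truth.markers_px[-1])
        assert spline.length_px == pytest.approx(200.0, rel=0.02)
        # markers collinear within 1 px of the true midline
        assert np.abs(spline.markers[:, 1] - truth.markers_px[0, 1]).max() <= 1.0

    def test_marker_count_and_equal_spacing(self, rendered_worm):
        _, image, truth = rendered_worm
        result = fit_frame(image, SegmentationConfig(head_seed=tuple(truth.markers_px[0])))
        assert result.ok
        spacing = np.linalg.norm(np.diff(result.spline.markers, axis=0), axis=1)
        assert len(result.spline.markers) == 13
        assert (spacing.max() - spacing.min()) / spacing.mean() < 0.02
        centroid = result.spline.markers.mean(axis=0)
        assert np.allclose(result.spline.centroid, centroid)

    def test_coiled_posture_fails(self):
        # near-closed annulus: the worm touching itself; midline cannot be fitted
        yy, xx = np.mgrid[0:200, 0:200]
        r = np.hypot(xx - 100, yy - 100)
        mask = (r > 55) & (r < 95)
        theta = np.arctan2(yy - 100, xx - 100)
        mask &= ~((np.abs(theta) < 0.05) & (r > 55))  # tiny gap
        outline = extract_outline(mask)
        with pytest.raises(SegmentationError):
            ht = detect_head_tail(outline)
            fit_midline(outline, ht.head, ht.tail)


class TestFitFrame:
    def test_good_frame_single_attempt(self, rendered_worm):
        _, image, truth = rendered_worm
        result = fit_frame(image, SegmentationConfig(head_seed=tuple(truth.markers_px[0])))
        assert result.ok and result.attempts == 1 and result.head_confirmed

    def test_noise_frame_exhausts_all_eleven_thresholds(self, rng):
        noise = rng.uniform(0, 255, (120, 120))
        result = fit_frame(noise, SegmentationConfig(threshold=128.0))
        assert not result.ok
        assert result.attempts == 11  # initial + 10 automatic adjustments

    def test_threshold_retry_finds_working_level(self, rendered_worm):
        # only thresholds above the body intensity work; initial is too low
        _, image, truth = rendered_worm
        cfg = SegmentationConfig(threshold=30.0, head_seed=tuple(truth.markers_px[0]))
        result = fit_frame(image, cfg)
        assert result.ok
        # alternating schedule 30, 35, 25, 40, 20, 45: first usable level is 45
        assert result.attempts == 6
        assert result.threshold_used == 45.0

    def test_midline_recovery_within_tolerance(self):
        rng = np.random.default_rng(7)
        errors, length_err = [], []
        for k in range(10):
            pose = WormPose(
                amplitude_um=rng.uniform(0, 120),
                wavelength_um=rng.uniform(800, 1400),
                phase=rng.uniform(0, 2 * np.pi),
                heading_rad=rng.uniform(0, 2 * np.pi),
            )
            image, truth = render_worm(pose, seed=k, noise_sigma=5.0)
            cfg = SegmentationConfig(head_seed=tuple(truth.markers_px[0]))
            result = fit_frame(image, cfg)
            assert result.ok
            err = np.linalg.norm(result.spline.markers - truth.markers_px, axis=1)
            errors.append(err)
            length_err.append(abs(result.spline.length_px - 200.0) / 200.0)
        errors = np.array(errors)
        assert errors.mean() <= 2.0
        assert errors.max() <= 5.0
        assert max(length_err) <= 0.03
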