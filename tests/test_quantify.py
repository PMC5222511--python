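"""Per-ROI metrics: averaging, binarisation, skeleton topology, SNR,
density and intercapillary distance."""

import dataclasses
import warnings

import numpy as np
import pytest

from octavg import (
    DegenerateImageError,
    EnFaceImage,
    ROISpec,
    ScaleModel,
    SyntheticScene,
    average_frames,
    binarize_roi,
    capillary_density,
    compute_snr,
    dilate_to_mask,
    generate_capillary_map,
    icd_sampling_box,
    intercapillary_distance,
    quantify_roi,
    simulate_stack,
    skeletonize_roi,
)
from octavg.geometry import SamplingBox
from octavg.image import stack_from_arrays
from octavg.quantify import mean_segment_length_um, records_to_dataframe
from conftest import brute_force_endpoint_branch


def interior_roi(margin=10, size=60, orientation=0.0):
    return ROISpec(
        label="T",
        box=(margin, margin + size, margin, margin + size),
        vessel_orientation_deg=orientation,
    )


def registered(stack):
    stack.registered = True
    return stack


class TestAverageFrames:
    def test_single_frame_is_reference_roi(self, noisy_scene, scale):
        stack, _ = simulate_stack(noisy_scene, scale, n_frames=3)
        roi = interior_roi(margin=5, size=50)
        avg, excluded, _ = average_frames(stack, 1, roi)
        assert not excluded
        r0, r1, c0, c1 = roi.box
        np.testing.assert_array_equal(avg.data, stack.reference.data[r0:r1, c0:c1])

    def test_identical_frames_average_to_themselves(self, scale):
        frame = np.random.default_rng(0).random((70, 70))
        stack = stack_from_arrays([frame] * 10, scale)
        avg, excluded, _ = average_frames(stack, 10, interior_roi(5, 60))
        np.testing.assert_allclose(avg.data, frame[5:65, 5:65])

    def test_variance_shrinks_like_one_over_n(self, scale):
        # i.i.d. per-frame speckle on a mid-gray scene (no [0,1] clipping):
        # the 10-frame average variance is the single-frame variance / 10
        from octavg import FrameStack, GroundTruth
        from octavg.synthetic import render_frame

        scene = SyntheticScene(image_size_px=(80, 80), speckle_sigma=0.3,
                               additive_sigma=0.0, motion_line_prob=0.0,
                               shift_range_px=0.0, rot_range_deg=0.0, seed=17)
        clean = EnFaceImage(np.full((80, 80), 0.5), scale)
        truth = GroundTruth(
            centerline_map=np.zeros((80, 80), bool), clean_image=clean,
            true_density_mm_inv=0.0, true_icd_um=scene.true_icd_um,
            scene=scene, scale=scale,
        )
        frames = [render_frame(truth, scene, i) for i in range(10)]
        stack = FrameStack(frames, registered=True)
        roi = interior_roi(10, 60)
        avg10, _, _ = average_frames(stack, 10, roi)
        avg1, _, _ = average_frames(stack, 1, roi)
        v1 = np.mean((avg1.data - 0.5) ** 2)
        v10 = np.mean((avg10.data - 0.5) ** 2)
        assert v10 == pytest.approx(v1 / 10, rel=0.2)

    def test_invalid_pixels_exclude_roi(self, scale):
        frames = [EnFaceImage(np.ones((50, 50)), scale) for _ in range(3)]
        bad_valid = np.ones((50, 50), bool)
        bad_valid[20, 20] = False
        frames[2] = EnFaceImage(np.ones((50, 50)), scale, bad_valid)
        stack = stack_from_arrays([f.data for f in frames], scale)
        stack.frames[2] = frames[2]
        roi = interior_roi(5, 40)
        _, excluded2, reason = average_frames(stack, 3, roi)
        assert excluded2 and "frame_2" in reason
        _, excluded1, _ = average_frames(stack, 2, roi)
        assert not excluded1

    def test_bad_n_rejected(self, scale):
        stack = stack_from_arrays([np.ones((20, 20))] * 2, scale)
        roi = interior_roi(2, 10)
        with pytest.raises(ValueError):
            average_frames(stack, 0, roi)
        with pytest.raises(ValueError):
            average_frames(stack, 3, roi)


class TestBinarize:
    def test_output_resized_by_factor_six(self, clean_scene, scale):
        truth = generate_capillary_map(clean_scene, scale)
        roi_img = truth.clean_image.crop((10, 70, 10, 70))
        out = binarize_roi(roi_img, scale)
        assert out.shape == (360, 360)
        assert out.dtype == bool

    def test_constant_roi_warns_and_returns_empty(self, scale):
        img = EnFaceImage(np.full((60, 60), 0.5), scale)
        with pytest.warns(UserWarning, match="constant"):
            out = binarize_roi(img, scale)
        assert not out.any()

    def test_stripe_width_close_to_true_diameter(self, scale):
        # noise-free stripes: binarised width per stripe should be within
        # 2 resized px of the half-max width of the rendered profile
        scene = SyntheticScene(image_size_px=(60, 60), true_icd_um=38.3,
                               icd_jitter_frac=0.0, tortuosity_amp_um=0.0,
                               anastomosis_rate=0.0, speckle_sigma=0.0,
                               additive_sigma=0.0, motion_line_prob=0.0,
                               shift_range_px=0.0, rot_range_deg=0.0, seed=1)
        truth = generate_capillary_map(scene, scale)
        out = binarize_roi(truth.clean_image, scale)
        n_lines = len(np.unique(np.argwhere(truth.centerline_map)[:, 0]))
        width_px = out.sum(axis=0).mean() / n_lines  # resized px per stripe
        # half-max width of a Gaussian profile of FWHM 9 um, in resized px;
        # the zero-offset local-mean threshold sits below half-max, so the
        # segmented stripe is moderately wider (within half a native pixel)
        expected = 9.0 / scale.um_per_resized_px
        assert width_px == pytest.approx(expected, abs=3.0)


class TestSkeleton:
    def test_thick_line_reduces_to_single_segment(self):
        img = np.zeros((20, 30), bool)
        img[9:12, 5:25] = True
        g = skeletonize_roi(img)
        assert g.n_endpoints == 2
        assert g.n_branch_clusters == 0
        assert g.n_segments == 1

    def test_crossing_lines_make_four_segments(self):
        img = np.zeros((31, 31), bool)
        img[15, 5:26] = True
        img[5:26, 15] = True
        g = skeletonize_roi(img)
        assert g.n_endpoints == 4
        assert g.n_branch_clusters == 1
        assert g.n_segments == 4

    def test_empty_image(self):
        g = skeletonize_roi(np.zeros((10, 10), bool))
        assert g.n_endpoints == 0
        assert g.n_segments == 0
        assert g.total_length_px_units == 0.0

    def test_matches_brute_force_neighbor_count_oracle(self):
        # endpoint/branch labels equal an independent 3x3 neighbour count
        # on 100 random thinned images
        rng = np.random.default_rng(100)
        for _ in range(100):
            blob = rng.random((24, 24)) > 0.6
            g = skeletonize_roi(blob)
            ep_oracle, br_oracle = brute_force_endpoint_branch(g.skeleton)
            assert {tuple(p) for p in g.endpoints} == ep_oracle
            from octavg.quantify import _neighbor_counts

            counts = _neighbor_counts(g.skeleton)
            br_impl = {tuple(p) for p in np.argwhere(g.skeleton & (counts >= 3))}
            assert br_impl == br_oracle

    def test_length_lower_bound_invariant(self):
        from scipy import ndimage as ndi

        rng = np.random.default_rng(5)
        for _ in range(20):
            g = skeletonize_roi(rng.random((30, 30)) > 0.55)
            n_px = int(g.skeleton.sum())
            _, n_comp = ndi.label(g.skeleton, structure=np.ones((3, 3)))
            assert g.total_length_px_units >= n_px - n_comp - 1e-9

    def test_diagonal_line_length_uses_sqrt2_steps(self):
        img = np.zeros((20, 20), bool)
        idx = np.arange(3, 17)
        img[idx, idx] = True
        g = skeletonize_roi(img)
        assert g.total_length_px_units == pytest.approx(13 * np.sqrt(2))

    def test_segments_partition_skeleton_minus_branches(self):
        rng = np.random.default_rng(9)
        g = skeletonize_roi(rng.random((40, 40)) > 0.55)
        seg_px = sum(len(s) for s in g.segments)
        from octavg.quantify import _neighbor_counts

        counts = _neighbor_counts(g.skeleton)
        n_branch_px = int((g.skeleton & (counts >= 3)).sum())
        assert seg_px == int(g.skeleton.sum()) - n_branch_px


class TestMaskAndSNR:
    def test_default_dilation_is_nine_pixels(self, scale):
        skel = np.zeros((60, 60), bool)
        skel[30, 10:50] = True
        mask = dilate_to_mask(skel, scale, diameter_um=15.0)
        # 15 um / 1.595 um-per-resized-px = 9.4 -> nearest odd 9
        assert mask.diameter_px == 9
        col = mask.mask[:, 30]
        assert col.sum() == 9

    def test_tiny_diameter_keeps_skeleton(self, scale):
        skel = np.zeros((20, 20), bool)
        skel[10, 5:15] = True
        mask = dilate_to_mask(skel, scale, diameter_um=scale.um_per_resized_px)
        np.testing.assert_array_equal(mask.mask, skel)

    def test_empty_skeleton_empty_mask(self, scale):
        mask = dilate_to_mask(np.zeros((20, 20), bool), scale)
        assert not mask.mask.any()

    def test_mask_always_contains_skeleton(self, scale):
        rng = np.random.default_rng(2)
        for _ in range(10):
            g = skeletonize_roi(rng.random((40, 40)) > 0.6)
            mask = dilate_to_mask(g, scale)
            assert (mask.mask | ~g.skeleton).all()

    def test_snr_hand_arithmetic(self):
        # signal {1,3}, background {0,2}: (2-1)/sqrt(1+1) with population SD
        img = np.array([[1.0, 3.0], [0.0, 2.0]])
        mask = np.array([[True, True], [False, False]])
        snr, stats = compute_snr(img, mask)
        assert snr == pytest.approx(1.0 / np.sqrt(2.0))
        assert stats.mu_signal == 2.0 and stats.sigma_signal == 1.0

    def test_identical_regions_give_zero(self):
        img = np.tile([0.0, 1.0], (4, 2))
        mask = np.zeros((4, 4), bool)
        mask[:2] = True
        snr, _ = compute_snr(img, mask)
        assert snr == pytest.approx(0.0)

    def test_degenerate_input_rejected(self):
        img = np.ones((4, 4))
        mask = np.zeros((4, 4), bool)
        mask[0, 0] = True
        with pytest.raises(DegenerateImageError):
            compute_snr(img, mask)

    def test_snr_decreases_when_noise_added(self, scale):
        # fixed mask, clean vs noisy image, 20 seeds: noise always hurts
        scene = SyntheticScene(image_size_px=(60, 60), speckle_sigma=0.0,
                               additive_sigma=0.0, motion_line_prob=0.0,
                               icd_jitter_frac=0.0, tortuosity_amp_um=0.0,
                               anastomosis_rate=0.0, shift_range_px=0.0,
                               rot_range_deg=0.0, seed=3)
        truth = generate_capillary_map(scene, scale)
        from octavg.quantify import upsample_roi

        resized = upsample_roi(truth.clean_image, scale)
        mask = dilate_to_mask(skeletonize_roi(binarize_roi(truth.clean_image, scale)), scale)
        snr_clean, _ = compute_snr(resized, mask)
        for seed in range(20):
            noisy = resized + np.random.default_rng(seed).normal(0, 0.1, resized.shape)
            snr_noisy, _ = compute_snr(noisy, mask)
            assert snr_noisy < snr_clean


class TestDensityAndSegments:
    def test_single_vessel_density_arithmetic(self, scale):
        # one horizontal vessel across a 60 px ROI: length 60 px = 574 um,
        # area (574 um)^2 -> about 1.74 mm^-1
        skel = np.zeros((360, 360), bool)
        skel[180, :] = True
        g = skeletonize_roi(skel)
        roi = interior_roi(0, 60)
        d = capillary_density(g, roi, scale)
        assert d == pytest.approx(1.742, rel=0.01)

    def test_pixel_count_length_metric(self, scale):
        # a diagonal skeleton: step length is sqrt(2) x pixel count
        skel = np.zeros((360, 360), bool)
        idx = np.arange(360)
        skel[idx, idx] = True
        g = skeletonize_roi(skel)
        roi = interior_roi(0, 60)
        d_steps = capillary_density(g, roi, scale, length_metric="steps")
        d_px = capillary_density(g, roi, scale, length_metric="pixels")
        assert d_steps / d_px == pytest.approx(np.sqrt(2) * 359 / 360, rel=1e-6)
        with pytest.raises(ValueError):
            capillary_density(g, roi, scale, length_metric="euclid")

    def test_empty_skeleton_zero_density(self, scale):
        g = skeletonize_roi(np.zeros((360, 360), bool))
        assert capillary_density(g, interior_roi(0, 60), scale) == 0.0

    def test_parallel_vessels_additive(self, scale):
        one = np.zeros((360, 360), bool)
        one[12, :] = True
        many = np.zeros((360, 360), bool)
        for k in range(15):
            many[12 + 24 * k, :] = True
        roi = interior_roi(0, 60)
        d1 = capillary_density(skeletonize_roi(one), roi, scale)
        d15 = capillary_density(skeletonize_roi(many), roi, scale)
        assert d15 == pytest.approx(15 * d1, rel=0.001)

    def test_density_recovery_on_noise_free_scene(self, scale):
        scene = SyntheticScene(image_size_px=(60, 60), icd_jitter_frac=0.05,
                               speckle_sigma=0.0, additive_sigma=0.0,
                               motion_line_prob=0.0, shift_range_px=0.0,
                               rot_range_deg=0.0, seed=23)
        truth = generate_capillary_map(scene, scale)
        g = skeletonize_roi(binarize_roi(truth.clean_image, scale))
        d = capillary_density(g, interior_roi(0, 60), scale)
        assert d == pytest.approx(truth.true_density_mm_inv, rel=0.10)

    def test_mean_segment_length(self, scale):
        skel = np.zeros((50, 50), bool)
        skel[10, 5:45] = True
        skel[30, 5:25] = True
        g = skeletonize_roi(skel)
        expected_px = (39 + 19) / 2
        assert mean_segment_length_um(g, scale) == pytest.approx(
            expected_px * scale.um_per_resized_px
        )
        empty = skeletonize_roi(np.zeros((5, 5), bool))
        assert np.isnan(mean_segment_length_um(empty, scale))


class TestICD:
    def test_sinusoid_period_four_pixels(self, scale):
        rr = np.arange(60)
        img = np.tile(0.5 + 0.5 * np.sin(2 * np.pi * rr[:, None] / 4.0), (1, 60))
        box = SamplingBox(center_px=(30.0, 30.0), long_axis_deg=90.0,
                          length_px=30, width_px=3)
        res = intercapillary_distance(img, box, scale)
        assert res.measurable
        assert res.icd_um == pytest.approx(4 * scale.um_per_px, rel=0.01)

    def test_flat_profile_unmeasurable(self, scale):
        img = np.full((60, 60), 0.3)
        box = SamplingBox(center_px=(30.0, 30.0), long_axis_deg=90.0,
                          length_px=30, width_px=3)
        res = intercapillary_distance(img, box, scale)
        assert not res.measurable and res.reason == "flat_profile"
        assert np.isnan(res.icd_um)

    def test_recovery_on_synthetic_capillaries(self, scale):
        scene = SyntheticScene(image_size_px=(60, 60), true_icd_um=35.0,
                               icd_jitter_frac=0.05, speckle_sigma=0.0,
                               additive_sigma=0.0, motion_line_prob=0.0,
                               shift_range_px=0.0, rot_range_deg=0.0, seed=31)
        truth = generate_capillary_map(scene, scale)
        roi = interior_roi(0, 60)
        res = intercapillary_distance(
            truth.clean_image, icd_sampling_box(roi, scale), scale
        )
        assert res.measurable
        assert res.icd_um == pytest.approx(35.0, rel=0.10)


class TestQuantifyROI:
    def test_noise_free_stack_constant_metrics(self, clean_scene, scale):
        stack, _ = simulate_stack(clean_scene, scale, n_frames=5)
        roi = interior_roi(10, 60)
        records = registered(stack) and quantify_roi(stack, roi, scale, subject_id="a")
        df = records_to_dataframe(records)
        assert len(df) == 5
        for col in ("snr", "n_endpoints", "density_mm_inv", "icd_um"):
            assert df[col].nunique() == 1, col

    def test_excluded_roi_produces_flagged_records(self, clean_scene, scale):
        stack, _ = simulate_stack(clean_scene, scale, n_frames=3)
        roi = dataclasses.replace(interior_roi(), excluded=True, exclusion_reason="off_image")
        records = quantify_roi(registered(stack), roi, scale)
        assert all(r.excluded for r in records)
        assert all(r.exclusion_reason == "off_image" for r in records)

    def test_requesting_more_frames_than_available(self, clean_scene, scale):
        stack, _ = simulate_stack(clean_scene, scale, n_frames=3)
        with pytest.raises(ValueError):
            quantify_roi(registered(stack), interior_roi(10, 60), scale,
                         n_values=range(1, 11))

    def test_unregistered_stack_warns(self, clean_scene, scale):
        stack, _ = simulate_stack(clean_scene, scale, n_frames=2)
        with pytest.warns(UserWarning, match="not registered"):
            quantify_roi(stack, interior_roi(10, 60), scale)
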