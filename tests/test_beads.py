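"""Bead phantom simulation, segmentation, detection, target rendering."""

import numpy as np
import pytest

from lsfmrestore import errors
from lsfmrestore.beads import (
    BeadDetection,
    BeadPhantomSpec,
    build_distortion_corpus,
    detect_beads,
    kmeans_segment_slice,
    render_target_stack,
    simulate_bead_stack,
)
from lsfmrestore.imgio import ImageStack
from lsfmrestore.metrics import measure_elongation


@pytest.fixture(scope="module")
def small_phantom():
    spec = BeadPhantomSpec(volume_shape=(48, 96, 96), n_beads=4, elongation=3.0, seed=2)
    distorted, truth, table = simulate_bead_stack(spec)
    return spec, distorted, truth, table


class TestSimulate:
    def test_unit_elongation_means_identical_stacks(self):
        spec = BeadPhantomSpec(volume_shape=(32, 64, 64), n_beads=3, elongation=1.0, seed=1)
        distorted, truth, _ = simulate_bead_stack(spec)
        np.testing.assert_array_equal(distorted.data, truth.data)

    def test_no_beads_gives_constant_background(self):
        spec = BeadPhantomSpec(volume_shape=(32, 64, 64), n_beads=0, elongation=2.0, seed=1)
        distorted, truth, table = simulate_bead_stack(spec)
        assert table == []
        np.testing.assert_allclose(distorted.data, spec.background, atol=1e-6)

    def test_measured_elongation_matches_spec(self, small_phantom):
        spec, distorted, truth, table = small_phantom
        for det in table:
            assert abs(measure_elongation(distorted, det.center).ratio - spec.elongation) / spec.elongation < 0.05
            assert abs(measure_elongation(truth, det.center).ratio - 1.0) < 0.05

    def test_min_separation_respected(self, small_phantom):
        # separation holds in the elongation-normalised metric, where the
        # distorted bead footprints are round
        spec, _, _, table = small_phantom
        centers = np.array([d.center for d in table])
        scale = np.array([1.0 / spec.elongation, 1.0, 1.0])
        for i in range(len(centers)):
            for j in range(i + 1, len(centers)):
                assert np.linalg.norm((centers[i] - centers[j]) * scale) >= 16.0

    def test_infeasible_packing_raises(self):
        spec = BeadPhantomSpec(
            volume_shape=(48, 64, 64), n_beads=100, elongation=1.5, min_separation=30.0, seed=0
        )
        with pytest.raises(errors.PackingError):
            simulate_bead_stack(spec)


class TestKMeansSegmentation:
    def test_constant_slice_gives_empty_mask(self):
        mask = kmeans_segment_slice(np.full((32, 32), 0.3))
        assert mask.sum() == 0

    def test_mask_is_binary(self):
        rng = np.random.default_rng(0)
        mask = kmeans_segment_slice(rng.random((32, 32)))
        assert set(np.unique(mask)) <= {0, 1}

    def test_bimodal_disk_matches_midpoint_threshold_oracle(self):
        yy, xx = np.mgrid[0:64, 0:64]
        disk = (yy - 32) ** 2 + (xx - 32) ** 2 < 10**2
        img = np.where(disk, 0.8, 0.05)
        mask = kmeans_segment_slice(img)
        # bimodal case: K-means equals thresholding at the centroid midpoint,
        # which lands strictly between the two levels
        np.testing.assert_array_equal(mask.astype(bool), disk)


class TestDetection:
    def test_blank_stack_gives_no_detections(self):
        assert detect_beads(ImageStack(np.full((8, 32, 32), 0.05))) == []

    def test_detects_all_simulated_beads_near_truth(self, small_phantom):
        _, distorted, _, table = small_phantom
        detections = detect_beads(distorted)
        assert len(detections) == len(table)
        truth = np.array([d.center for d in table])
        for det in detections:
            # centre-slice estimates carry up to ~2 voxels of z jitter from
            # per-slice segmentation thresholds
            assert np.min(np.linalg.norm(truth - np.array(det.center), axis=1)) < 2.0

    def test_lateral_sigma_estimate_close_to_truth(self, small_phantom):
        spec, distorted, _, _ = small_phantom
        for det in detect_beads(distorted):
            assert abs(det.lateral_sigma_vox - spec.sigma_lateral) / spec.sigma_lateral < 0.15


class TestRenderTarget:
    def test_empty_detections_give_background(self):
        out = render_target_stack([], (8, 16, 16), background=0.07)
        np.testing.assert_allclose(out.data, 0.07, atol=1e-6)

    def test_rendered_beads_are_isotropic(self, small_phantom):
        spec, distorted, _, _ = small_phantom
        detections = detect_beads(distorted)
        target = render_target_stack(detections, spec.volume_shape)
        for det in detections:
            assert abs(measure_elongation(target, det.center).ratio - 1.0) < 0.05

    def test_profile_matches_formula(self):
        det = BeadDetection(center=(16.0, 32.0, 32.0), center_slice=16, lateral_radius_vox=4.0, lateral_sigma_vox=2.0)
        peak, bg = 0.8, 0.05
        out = render_target_stack([det], (33, 65, 65), peak=peak, background=bg)
        r = 4
        expected = bg + (peak - bg) * np.exp(-(r**2) / (2 * 2.0**2))
        assert abs(out.data[16, 32, 32 + r] - expected) < 1e-6

    def test_detection_outside_volume_rejected(self):
        det = BeadDetection(center=(50.0, 5.0, 5.0), center_slice=50, lateral_radius_vox=2.0)
        with pytest.raises(errors.CoordinateError):
            render_target_stack([det], (8, 16, 16))

    def test_bead_count_conserved_through_render(self, small_phantom):
        spec, distorted, _, _ = small_phantom
        detections = detect_beads(distorted)
        rendered = render_target_stack(detections, spec.volume_shape)
        assert len(detect_beads(rendered)) == len(detections)


class TestDistortionCorpus:
    def test_sequence_mode_block_geometry(self):
        rng = np.random.default_rng(4)
        stack = ImageStack(np.clip(rng.random((31, 64, 64)), 0, 1))
        corpus = build_distortion_corpus(stack, stack, "seq31x32", presence=None)
        assert corpus.inputs.shape == (4, 31, 32, 32)

    def test_presence_filter_drops_blank_blocks(self):
        # one bright bead-like cube in the top-left 128x128 tile; the other
        # three tiles of each 256x256 slice are background only
        data = np.full((4, 256, 256), 0.02, dtype=np.float32)
        data[:, 40:60, 40:60] = 0.8
        stack = ImageStack(data)
        full = build_distortion_corpus(stack, stack, "patch128", presence=None)
        filtered = build_distortion_corpus(stack, stack, "patch128")
        assert full.n_blocks == 16 and filtered.n_blocks == 4
        assert all(origin[1:] == (0, 0) for origin in filtered.origins)

    def test_deterministic_manifest(self, small_phantom):
        _, distorted, truth, _ = small_phantom
        a = build_distortion_corpus(distorted, truth, "patch128", seed=3)
        b = build_distortion_corpus(distorted, truth, "patch128", seed=3)
        assert a.manifest == b.manifest
        np.testing.assert_array_equal(a.inputs, b.inputs)

    def test_shape_mismatch_rejected(self):
        a = ImageStack(np.zeros((4, 32, 32)))
        b = ImageStack(np.zeros((5, 32, 32)))
        with pytest.raises(errors.ShapeError):
            build_distortion_corpus(a, b, "patch128")
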