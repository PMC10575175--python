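"""Heatmap rendering against brute-force oracles, plus crop/sampling
contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import skelact as sk
from skelact.heatmap import CropBox, subject_centered_crop, uniform_sample
from skelact.skeleton import ValidationError


def joint_frame_oracle(joints, h, w, sigma):
    """Double loop over pixels and joints, straight from the definition."""
    out = np.zeros((h, w))
    for i in range(h):       # row = y
        for j in range(w):   # col = x
            for x, y in joints:
                d2 = (j - x) ** 2 + (i - y) ** 2
                out[i, j] += np.exp(-d2 / sigma**2)
    return out


def segment_distance_oracle(p, a, b, samples=100_000):
    t = np.linspace(0.0, 1.0, samples)[:, None]
    pts = np.asarray(a) + t * (np.asarray(b) - np.asarray(a))
    return float(np.min(np.linalg.norm(pts - np.asarray(p), axis=1)))


class TestPointSegmentDistance:
    def test_perpendicular_foot_inside_segment(self):
        assert sk.point_segment_distance((5, 5), (0, 0), (10, 0)) == 5.0

    def test_nearest_point_is_endpoint(self):
        d = sk.point_segment_distance((12, 1), (0, 0), (10, 0))
        assert abs(d - np.sqrt(5)) < 1e-12

    def test_degenerate_segment_is_point_distance(self):
        assert sk.point_segment_distance((3, 4), (0, 0), (0, 0)) == 5.0

    def test_matches_dense_sampling_oracle(self, rng):
        for _ in range(1000):
            p, a, b = rng.uniform(-20, 20, (3, 2))
            exact = sk.point_segment_distance(p, a, b)
            assert abs(exact - segment_distance_oracle(p, a, b)) < 1e-4


class TestJointHeatmap:
    def test_joint_at_pixel_center_gives_one(self):
        frame = sk.joint_heatmap_frame(np.array([[3.0, 5.0]]), (8, 8), 2.0)
        assert frame[5, 3] == 1.0

    def test_value_at_distance_two(self):
        frame = sk.joint_heatmap_frame(np.array([[3.0, 5.0]]), (10, 10), 2.0)
        assert abs(frame[5, 5] - np.exp(-4.0 / 4.0)) < 1e-12

    def test_coincident_joints_sum(self):
        frame = sk.joint_heatmap_frame(
            np.array([[4.0, 4.0], [4.0, 4.0]]), (8, 8), 1.5
        )
        assert abs(frame[4, 4] - 2.0) < 1e-12

    def test_matches_double_loop_oracle(self, rng):
        joints = rng.uniform(0, 15, (16, 2))
        frame = sk.joint_heatmap_frame(joints, (16, 16), 1.5)
        np.testing.assert_allclose(
            frame, joint_frame_oracle(joints, 16, 16, 1.5), atol=1e-10
        )

    def test_radially_monotone_around_isolated_joint(self):
        frame = sk.joint_heatmap_frame(np.array([[8.0, 8.0]]), (17, 17), 2.0)
        radii = np.arange(0, 8)
        values = frame[8, 8 + radii]
        assert np.all(np.diff(values) < 0)

    def test_gaussian_mass_approaches_pi_sigma_squared(self):
        sigma = 2.0
        frame = sk.joint_heatmap_frame(np.array([[30.0, 30.0]]), (61, 61), sigma)
        assert abs(frame.sum() - np.pi * sigma**2) / (np.pi * sigma**2) < 0.02


class TestBoneHeatmap:
    def test_pixel_on_bone_contributes_one(self, topology):
        joints = np.zeros((16, 2))
        joints[:, 0] = np.arange(16)
        joints[:, 1] = 5.0
        frame = sk.bone_heatmap_frame(joints, topology, (11, 20), 1.0)
        assert frame[5, 3] >= 1.0  # on at least one horizontal bone

    def test_degenerate_bones_match_joint_gaussian(self, topology):
        joints = np.full((16, 2), 7.0)  # all bones collapse to one point
        bone = sk.bone_heatmap_frame(joints, topology, (15, 15), 1.5)
        single = sk.joint_heatmap_frame(joints[:1], (15, 15), 1.5)
        np.testing.assert_allclose(bone, 15 * single, atol=1e-10)

    def test_matches_brute_force_oracle(self, topology, rng):
        joints = rng.uniform(1, 13, (16, 2))
        frame = sk.bone_heatmap_frame(joints, topology, (14, 14), 1.5)
        oracle = np.zeros((14, 14))
        for i in range(14):
            for j in range(14):
                for a, b in topology.bones:
                    d = segment_distance_oracle(
                        (j, i), joints[a], joints[b], samples=20_000
                    )
                    oracle[i, j] += np.exp(-d**2 / 1.5**2)
        np.testing.assert_allclose(frame, oracle, atol=1e-4)


class TestCrop:
    def _seq(self, pixels):
        return sk.Skeleton2DSequence(pixels, 0.0, (64, 64), "projected")

    def test_exact_span_is_identity(self):
        pts = np.array([[[0.0, 0.0], [63.0, 63.0], [30.0, 12.0]]])
        out, box = subject_centered_crop(self._seq(pts), 0.0, (64, 64))
        np.testing.assert_allclose(out.pixels, pts, atol=1e-9)
        assert box.scale == pytest.approx(1.0)

    def test_output_always_within_grid(self, rng):
        for _ in range(20):
            pts = rng.uniform(-200, 500, (4, 16, 2))
            out, _ = subject_centered_crop(self._seq(pts), 0.1, (48, 32))
            assert out.pixels[..., 0].min() >= -1e-9
            assert out.pixels[..., 0].max() <= 31 + 1e-9
            assert out.pixels[..., 1].min() >= -1e-9
            assert out.pixels[..., 1].max() <= 47 + 1e-9

    def test_translation_invariance(self, rng):
        pts = rng.uniform(0, 100, (5, 16, 2))
        ref, _ = subject_centered_crop(self._seq(pts), 0.1, (64, 64))
        shifted, _ = subject_centered_crop(
            self._seq(pts + np.array([100.0, 37.0])), 0.1, (64, 64)
        )
        np.testing.assert_allclose(ref.pixels, shifted.pixels, atol=1e-9)

    def test_single_point_clip_rejected(self):
        pts = np.full((3, 16, 2), 5.0)
        with pytest.raises(ValidationError):
            subject_centered_crop(self._seq(pts), 0.1, (64, 64))

    def test_zero_width_clip_letterboxes(self):
        pts = np.zeros((1, 3, 2))
        pts[0, :, 1] = [0.0, 10.0, 20.0]  # vertical line
        out, _ = subject_centered_crop(self._seq(pts), 0.0, (21, 21))
        np.testing.assert_allclose(out.pixels[0, :, 0], 10.0, atol=1e-9)
        np.testing.assert_allclose(out.pixels[0, :, 1], [0, 10, 20], atol=1e-9)


class TestUniformSample:
    def test_bin_centers(self):
        assert uniform_sample(100, 10, "center") == [5, 15, 25, 35, 45,
                                                     55, 65, 75, 85, 95]

    def test_identity_when_equal(self):
        assert uniform_sample(10, 10, "center") == list(range(10))

    def test_random_mode_one_index_per_bin(self):
        idx = uniform_sample(100, 10, "random", seed=42)
        assert idx == uniform_sample(100, 10, "random", seed=42)
        for b, i in enumerate(idx):
            assert 10 * b <= i < 10 * (b + 1)

    @settings(deadline=None, max_examples=100)
    @given(t_in=st.integers(1, 500), t_out=st.integers(1, 64))
    def test_indices_sorted_and_in_range(self, t_in, t_out):
        idx = uniform_sample(t_in, t_out, "center")
        assert len(idx) == t_out
        assert idx == sorted(idx)
        assert 0 <= idx[0] and idx[-1] < t_in


class TestBuildVolume:
    def test_shape_contract(self, tiny_dataset, topology):
        seq2d = sk.project_sequence(
            tiny_dataset[0], sk.CameraIntrinsics(), sk.OrbitConfig(), 0.0
        )
        cfg = sk.HeatmapConfig(out_height=64, out_width=64, num_frames_out=12)
        vol = sk.build_volume(seq2d, topology, cfg)
        assert vol.values.shape == (12, 64, 64)

    def test_joint_map_bounded_by_joint_count(self, tiny_dataset, topology,
                                              desk_heatmap_config):
        seq2d = sk.project_sequence(
            tiny_dataset[0], sk.CameraIntrinsics(), sk.OrbitConfig(), 90.0
        )
        vol = sk.build_volume(seq2d, topology, desk_heatmap_config)
        assert vol.values.max() <= 16.0
        assert vol.values.min() >= 0.0

    def test_center_mode_deterministic(self, tiny_dataset, topology,
                                       desk_heatmap_config):
        seq2d = sk.project_sequence(
            tiny_dataset[1], sk.CameraIntrinsics(), sk.OrbitConfig(), 45.0
        )
        a = sk.build_volume(seq2d, topology, desk_heatmap_config)
        b = sk.build_volume(seq2d, topology, desk_heatmap_config)
        np.testing.assert_array_equal(a.values, b.values)

    def test_bone_volume_carries_metadata(self, tiny_dataset, topology):
        seq2d = sk.project_sequence(
            tiny_dataset[2], sk.CameraIntrinsics(), sk.OrbitConfig(), 30.0
        )
        cfg = sk.HeatmapConfig(out_height=16, out_width=16, num_frames_out=4,
                               map_type="bone")
        vol = sk.build_volume(seq2d, topology, cfg)
        assert vol.map_type == "bone"
        assert vol.viewpoint_deg == 30.0
        assert vol.action_label == tiny_dataset[2].action_label
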