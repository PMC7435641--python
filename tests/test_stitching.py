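import numpy as np
import pytest

from kiwicount.stitching import (
    CompositeSizeError,
    EstimationError,
    MatchPair,
    detect_and_describe,
    estimate_homography,
    match,
    stitch_sequence,
    warp_and_composite,
)
from kiwicount.synthetic import SceneSpec, generate_pair, generate_scene


@pytest.fixture(scope="module")
def scene_image():
    return generate_scene(SceneSpec(n_fruits=15, seed=41))[0]


class TestDetectAndDescribe:
    def test_constant_image_has_no_keypoints(self):
        flat = np.full((128, 128, 3), 90, dtype=np.uint8)
        assert detect_and_describe(flat) == []

    def test_descriptors_are_unit_64_vectors(self, scene_image):
        kps = detect_and_describe(scene_image, max_keypoints=100)
        assert len(kps) > 10
        for kp in kps:
            assert kp.descriptor.shape == (64,)
            assert np.linalg.norm(kp.descriptor) == pytest.approx(1.0)
            assert 0 <= kp.x < scene_image.shape[1]
            assert 0 <= kp.y < scene_image.shape[0]

    def test_rotation_invariance_at_90_degrees(self, scene_image):
        kps = detect_and_describe(scene_image, max_keypoints=60)
        rotated = np.rot90(scene_image, k=-1).copy()  # clockwise
        kps_rot = detect_and_describe(rotated, max_keypoints=60)
        h = scene_image.shape[0]
        matched = 0
        good = 0
        for kp in kps[:25]:
            # clockwise rotation maps (x, y) -> (h - 1 - y, x)
            rx, ry = h - 1 - kp.y, kp.x
            partners = [q for q in kps_rot
                        if np.hypot(q.x - rx, q.y - ry) < 3.0]
            if not partners:
                continue
            matched += 1
            dist = min(np.linalg.norm(kp.descriptor - q.descriptor)
                       for q in partners)
            if dist < 0.5:  # random unit vectors sit near sqrt(2)
                good += 1
        assert matched >= 10
        assert good / matched >= 0.7

    def test_brightness_shift_keeps_positions(self, scene_image):
        shifted = np.clip(scene_image.astype(int) + 30, 0, 255).astype(
            np.uint8)
        kps = detect_and_describe(scene_image, max_keypoints=50)
        kps_b = detect_and_describe(shifted, max_keypoints=50)
        pts_b = np.array([[q.x, q.y] for q in kps_b])
        moved = 0
        for kp in kps[:30]:
            d = np.hypot(pts_b[:, 0] - kp.x, pts_b[:, 1] - kp.y).min()
            if d > 1.0:
                moved += 1
        assert moved <= 6


class TestMatch:
    def test_identical_sets_match_with_zero_distance(self, rng):
        desc = rng.normal(size=(20, 64))
        desc /= np.linalg.norm(desc, axis=1, keepdims=True)
        pairs = match(desc, desc.copy())
        assert len(pairs) == 20
        assert all(p.index_a == p.index_b and p.distance == pytest.approx(0.0)
                   for p in pairs)

    def test_singleton_sets_skip_ratio_test(self, rng):
        a = rng.normal(size=(1, 64))
        pairs = match(a, a + 0.01)
        assert len(pairs) == 1

    def test_empty_input_gives_empty_output(self, rng):
        assert match(np.empty((0, 64)), rng.normal(size=(4, 64))) == []

    def test_symmetry(self, rng):
        a = rng.normal(size=(30, 64))
        b = rng.normal(size=(25, 64))
        ab = {(p.index_a, p.index_b) for p in match(a, b)}
        ba = {(p.index_b, p.index_a) for p in match(b, a)}
        assert ab == ba

    def test_planted_correspondences_recovered_under_noise(self, rng):
        base = rng.normal(size=(60, 64))
        base /= np.linalg.norm(base, axis=1, keepdims=True)
        noisy = base + rng.normal(0, 0.05, size=base.shape)
        pairs = match(base, noisy)
        correct = sum(p.index_a == p.index_b for p in pairs)
        assert correct >= 0.9 * 60

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            MatchPair(0, 0, -1.0)


def _planted_homography_instance(rng, n=40, outlier_frac=0.3, noise=1.0):
    H = np.array([[1.02, 0.01, 30.0], [-0.015, 0.99, 8.0], [1e-5, -2e-5, 1.0]])
    pts_b = rng.uniform(20, 600, size=(n, 2))
    homog = np.c_[pts_b, np.ones(n)] @ H.T
    pts_a = homog[:, :2] / homog[:, 2:3]
    pts_a += rng.normal(0, noise, size=pts_a.shape)
    n_out = int(outlier_frac * n)
    outliers = rng.choice(n, size=n_out, replace=False)
    pts_a[outliers] = rng.uniform(0, 640, size=(n_out, 2))
    matches = [MatchPair(i, i, 0.0) for i in range(n)]
    return H, matches, pts_a, pts_b, outliers


class TestEstimateHomography:
    def test_exact_translation_recovered(self):
        pts_b = np.array([[0, 0], [100, 0], [0, 100], [100, 100],
                          [30, 70], [70, 30], [10, 50], [90, 60]], float)
        pts_a = pts_b + [25.0, -13.0]
        matches = [MatchPair(i, i, 0.0) for i in range(8)]
        H, inliers = estimate_homography(matches, pts_a, pts_b, seed=0)
        expected = np.eye(3)
        expected[0, 2], expected[1, 2] = 25.0, -13.0
        assert np.allclose(H, expected, atol=1e-6)
        assert inliers.all()

    def test_fewer_than_four_matches_rejected(self, rng):
        pts = rng.uniform(0, 100, size=(3, 2))
        matches = [MatchPair(i, i, 0.0) for i in range(3)]
        with pytest.raises(EstimationError):
            estimate_homography(matches, pts, pts, seed=0)

    def test_outlier_contamination_recovered(self, rng):
        H_true, matches, pts_a, pts_b, outliers = \
            _planted_homography_instance(rng, noise=0.0)
        H, inliers = estimate_homography(matches, pts_a, pts_b, seed=3)
        inlier_idx = np.flatnonzero(inliers)
        true_in = np.setdiff1d(np.arange(40), outliers)
        assert set(true_in).issubset(set(inlier_idx))
        src = np.c_[pts_b[true_in], np.ones(len(true_in))]
        proj = src @ H.T
        proj = proj[:, :2] / proj[:, 2:3]
        err = np.hypot(*(proj - pts_a[true_in]).T)
        assert err.max() < 3.0

    def test_recovery_accuracy_over_seeded_trials(self, rng):
        corners = np.array([[0, 0], [640, 0], [0, 480], [640, 480]], float)
        errors = []
        for trial in range(25):
            H_true, matches, pts_a, pts_b, _ = \
                _planted_homography_instance(rng)
            H, _ = estimate_homography(matches, pts_a, pts_b, seed=trial)
            src = np.c_[corners, np.ones(4)]
            t = src @ H_true.T
            e = src @ H.T
            t = t[:, :2] / t[:, 2:3]
            e = e[:, :2] / e[:, 2:3]
            errors.append(np.hypot(*(t - e).T).mean())
        assert np.median(errors) < 2.0


class TestWarpAndComposite:
    def test_identity_keeps_image_a(self, scene_image):
        out = warp_and_composite(scene_image, scene_image, np.eye(3))
        assert np.array_equal(out.image, scene_image)
        assert out.a_origin == (0, 0)

    def test_half_width_translation_geometry(self, scene_image):
        h, w = scene_image.shape[:2]
        H = np.eye(3)
        H[0, 2] = w / 2.0
        out = warp_and_composite(scene_image, scene_image, H)
        assert out.image.shape[1] == w + w // 2
        assert out.image.shape[0] == h

    def test_canvas_cap_guards_runaway_homography(self, scene_image):
        H = np.eye(3)
        H[0, 2] = 1e6
        with pytest.raises(CompositeSizeError):
            warp_and_composite(scene_image, scene_image, H, canvas_cap=4000)


class TestStitchSequence:
    def test_single_image_returned_unchanged(self, scene_image):
        panoramas, notes = stitch_sequence([scene_image])
        assert len(panoramas) == 1 and notes == []
        assert np.array_equal(panoramas[0].image, scene_image)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            stitch_sequence([])

    def test_overlapping_pair_recovers_true_translation(self):
        pair = generate_pair(SceneSpec(n_fruits=20, seed=17), 0.5, jitter=0.0)
        panoramas, notes = stitch_sequence([pair.frame_a, pair.frame_b],
                                           seed=2)
        assert len(panoramas) == 1 and notes == []
        record = panoramas[0].pair_records[0]
        H = np.array(record["homography"])
        assert np.allclose(H, pair.homography, atol=1.0)
        assert record["n_inliers"] >= 8

    def test_unrelated_frames_split_into_two_panoramas(self):
        img_a = generate_scene(SceneSpec(n_fruits=15, seed=51))[0]
        img_b = generate_scene(SceneSpec(n_fruits=15, seed=52))[0]
        with pytest.warns(UserWarning):
            panoramas, notes = stitch_sequence([img_a, img_b], seed=2)
        assert len(panoramas) == 2
        assert len(notes) == 1
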