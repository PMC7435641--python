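import dataclasses

import numpy as np
import pytest

from kiwicount.imgio import to_grayscale
from kiwicount.synthetic import (
    LABEL_TIP,
    PlacementError,
    SceneSpec,
    generate_pair,
    generate_scene,
    generate_sequence,
    generate_training_windows,
    write_scene,
)


def test_empty_scene_has_no_fruit_and_zero_count():
    image, truth = generate_scene(SceneSpec(n_fruits=0, seed=3))
    assert truth.count == 0
    # no brown fruit pixels: the whole raster stays on the green side of a*
    from kiwicount.imgio import rgb_to_lab
    assert rgb_to_lab(image).A.mean() < 0
    assert not np.any(truth.labels)


def test_seeded_determinism_is_byte_identical():
    spec = SceneSpec(n_fruits=25, seed=7)
    image_a, truth_a = generate_scene(spec)
    image_b, truth_b = generate_scene(spec)
    assert np.array_equal(image_a, image_b)
    assert np.array_equal(truth_a.boxes, truth_b.boxes)


def test_unoccluded_scene_has_disjoint_tip_boxes():
    _, truth = generate_scene(SceneSpec(n_fruits=25, occlusion_prob=0.0,
                                        seed=7))
    assert truth.count == 25
    assert not truth.occluded.any()
    boxes = truth.boxes
    for i in range(len(boxes)):
        for j in range(i + 1, len(boxes)):
            xi, yi, wi, hi = boxes[i]
            xj, yj, wj, hj = boxes[j]
            overlap_x = min(xi + wi, xj + wj) - max(xi, xj)
            overlap_y = min(yi + hi, yj + hj) - max(yi, yj)
            assert overlap_x <= 0 or overlap_y <= 0
    h, w = truth.labels.shape
    assert np.all(boxes[:, 0] >= 0) and np.all(boxes[:, 1] >= 0)
    assert np.all(boxes[:, 0] + boxes[:, 2] <= w)
    assert np.all(boxes[:, 1] + boxes[:, 3] <= h)


def test_impossible_placement_raises_with_count():
    spec = SceneSpec(width=120, height=120, n_fruits=60, seed=1)
    with pytest.raises(PlacementError, match=r"place \d+ of 60"):
        generate_scene(spec)


def test_spec_validation_rejects_bad_parameters():
    with pytest.raises(ValueError):
        SceneSpec(n_fruits=-1)
    with pytest.raises(ValueError):
        SceneSpec(fruit_radius_range=(10.0, 5.0))
    with pytest.raises(ValueError):
        SceneSpec(occlusion_prob=1.5)


class TestPairs:
    def test_zero_jitter_pair_is_pure_translation_with_zero_residual(self):
        spec = SceneSpec(seed=11)
        pair = generate_pair(spec, overlap_fraction=0.5, jitter=0.0)
        dx = int(round(0.5 * spec.width))
        expected = np.eye(3)
        expected[0, 2] = dx
        assert np.allclose(pair.homography, expected)
        # warping frame b by H onto frame a's grid is an exact overlay of
        # the shared region in the noiseless setting
        shared_a = pair.frame_a[:, dx:]
        shared_b = pair.frame_b[:, : spec.width - dx]
        assert np.array_equal(shared_a, shared_b)

    def test_pair_determinism(self):
        spec = SceneSpec(seed=5)
        h1 = generate_pair(spec, 0.5, jitter=2.0).homography
        h2 = generate_pair(spec, 0.5, jitter=2.0).homography
        assert np.array_equal(h1, h2)

    def test_overlap_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            generate_pair(SceneSpec(seed=1), overlap_fraction=0.05)
        with pytest.raises(ValueError):
            generate_pair(SceneSpec(seed=1), overlap_fraction=0.95)

    def test_jittered_frame_matches_warp_through_true_homography(self):
        from skimage.transform import ProjectiveTransform, warp

        spec = SceneSpec(seed=13)
        pair = generate_pair(spec, 0.5, jitter=3.0)
        canvas_spec = dataclasses.replace(
            spec, width=spec.width + int(round(0.5 * spec.width)))
        canvas, _ = generate_scene(canvas_spec)
        redone = warp(canvas.astype(float),
                      ProjectiveTransform(matrix=pair.homography),
                      output_shape=(spec.height, spec.width), order=1,
                      preserve_range=True)
        redone = np.clip(np.round(redone), 0, 255).astype(np.uint8)
        assert np.array_equal(redone, pair.frame_b)


def test_sequence_frames_cover_canvas_truth():
    spec = SceneSpec(n_fruits=20, seed=9)
    seq = generate_sequence(spec, 3, overlap_fraction=0.5)
    assert len(seq.frames) == 3
    assert len(seq.pair_homographies) == 2
    total_frame_tips = sum(t.count for t in seq.frame_truths)
    # overlap means tips are seen more than once across frames
    assert total_frame_tips >= seq.canvas_truth.count


class TestTrainingWindows:
    def test_zero_positives_is_valid(self):
        tw = generate_training_windows(0, 5, window=24, seed=2)
        assert tw.positives.shape == (0, 24, 24)
        assert tw.negatives.shape == (5, 24, 24)

    def test_window_too_small_rejected(self):
        with pytest.raises(ValueError):
            generate_training_windows(1, 1, window=8, seed=0)

    def test_positive_crops_have_dark_center_cluster(self):
        tw = generate_training_windows(40, 5, window=24, seed=3)
        for crop in tw.positives:
            center = crop[8:16, 8:16]
            assert center.min() < crop.mean() - 10

    def test_negative_centers_avoid_tip_boxes(self):
        spec = SceneSpec(occlusion_prob=0.2)
        tw = generate_training_windows(5, 60, window=24, seed=4,
                                       scene_spec=spec)
        scenes = {}
        from kiwicount.synthetic import _derive_seed, _inside_any_box

        for scene_idx, cx, cy, _side in tw.negative_info:
            if scene_idx not in scenes:
                s = dataclasses.replace(spec, seed=_derive_seed(4, scene_idx))
                scenes[scene_idx] = generate_scene(s)[1]
            assert not _inside_any_box(cx, cy, scenes[scene_idx].boxes)

    def test_exhausting_available_crops_raises(self):
        with pytest.raises(RuntimeError, match="exceed"):
            generate_training_windows(10, 50, window=24, seed=5,
                                      max_scenes=1,
                                      scene_spec=SceneSpec(n_fruits=2))


def test_scene_export_writes_png_csv_manifest(tmp_path):
    spec = SceneSpec(n_fruits=6, seed=21)
    image, truth = generate_scene(spec)
    write_scene(tmp_path, "s0", image, truth, spec)
    assert (tmp_path / "s0.png").exists()
    csv = (tmp_path / "s0_truth.csv").read_text().splitlines()
    assert csv[0] == "x,y,w,h,occluded"
    assert len(csv) == truth.count + 1
    import json

    manifest = json.loads((tmp_path / "s0_manifest.json").read_text())
    assert manifest["seed"] == 21 and manifest["count"] == truth.count


def test_tip_label_darker_than_fruit_on_average(sample_scene):
    _, image, truth = sample_scene
    gray = to_grayscale(image)
    assert gray[truth.labels == LABEL_TIP].mean() < gray[truth.labels == 1].mean()
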