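"""High-level wiring: training at config scale, scene/panorama evaluation,
and row counting.  The CLI and the ablation harness compose these helpers.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from kiwicount.cascade import Cascade, count, detect_multiscale, train_cascade
from kiwicount.config import PipelineConfig
from kiwicount.counting import EvalRecord, YieldReport
from kiwicount.haar import generate_feature_pool
from kiwicount.preprocess import suppress_background
from kiwicount.stitching import StitchResult, stitch_sequence
from kiwicount.synthetic import (
    SceneSpec,
    generate_pair,
    generate_scene,
    generate_training_windows,
    _derive_seed,
)


def default_feature_pool(config: PipelineConfig):
    return generate_feature_pool(
        window=config.window,
        position_stride=config.feature_position_stride,
        size_stride=config.feature_size_stride,
        min_size=config.feature_min_size,
        full=config.full_feature_pool,
    )


def mine_negative_pool(config: PipelineConfig, seed: int = 0,
                       n_scenes: int = 3,
                       scene_spec: SceneSpec | None = None,
                       stride: int = 6,
                       scales=(1.0, 1.5, 2.0)) -> np.ndarray:
    """Dense sliding-window negatives for cascade bootstrapping.

    Every window on a strided multi-scale grid over raw and
    background-suppressed scenes, excluding windows centered on a tip --
    i.e. the actual negative distribution detection scans, which is what
    later cascade stages must learn to reject."""
    from skimage.transform import resize
    from skimage.util import view_as_windows

    from kiwicount.imgio import to_grayscale

    base = scene_spec or SceneSpec(occlusion_prob=0.2)
    win = config.window
    crops = []
    for i in range(n_scenes):
        spec = dataclasses.replace(base, seed=_derive_seed(seed, 900 + i))
        image, truth = generate_scene(spec)
        sources = [to_grayscale(image),
                   to_grayscale(suppress_background(image).image)]
        centers = truth.tip_centers
        radii = truth.tip_radii
        for gray in sources:
            for s in scales:
                g = resize(gray, (int(gray.shape[0] / s),
                                  int(gray.shape[1] / s)),
                           order=1, anti_aliasing=s > 1,
                           preserve_range=True) if s != 1 else gray
                if min(g.shape) < win:
                    continue
                views = view_as_windows(g, (win, win), step=stride)
                ny, nx = views.shape[:2]
                ys = np.arange(ny) * stride + win / 2.0
                xs = np.arange(nx) * stride + win / 2.0
                gx, gy = np.meshgrid(xs, ys)
                keep = np.ones((ny, nx), dtype=bool)
                for (tx, ty), tr in zip(centers, radii):
                    d2 = ((gx - tx / s) ** 2 + (gy - ty / s) ** 2)
                    keep &= d2 > (tr / s + win / 3.0) ** 2
                crops.append(views[keep].astype(np.float32))
    pool = np.concatenate(crops)
    if len(pool) > config.bootstrap_negatives:
        rng = np.random.default_rng(_derive_seed(seed, 999))
        pool = pool[rng.choice(len(pool), config.bootstrap_negatives,
                               replace=False)]
    return pool


def make_training_windows(config: PipelineConfig, seed: int = 0,
                          scene_spec: SceneSpec | None = None):
    """Positive, negative and mined bootstrap-negative window stacks."""
    scene_spec = scene_spec or SceneSpec(occlusion_prob=0.2)
    tw = generate_training_windows(
        n_pos=config.train_positives, n_neg=config.train_negatives,
        window=config.window, seed=seed, scene_spec=scene_spec)
    bootstrap = mine_negative_pool(config, seed=seed, scene_spec=scene_spec)
    return tw.positives, tw.negatives, bootstrap


def _mining_scenes(config: PipelineConfig, seed: int, n_scenes: int,
                   scene_spec: SceneSpec | None):
    from kiwicount.imgio import to_grayscale

    base = scene_spec or SceneSpec(occlusion_prob=0.2)
    scenes = []
    for i in range(n_scenes):
        spec = dataclasses.replace(base, seed=_derive_seed(seed, 900 + i))
        image, truth = generate_scene(spec)
        masked = suppress_background(image).image
        scenes.append((to_grayscale(masked), truth))
    return scenes


def _mine_false_positives(partial: Cascade, scenes, config: PipelineConfig,
                          per_scene: int = 400) -> np.ndarray:
    """Highest-scoring surviving windows of the partial cascade that do not
    cover a true tip, cropped and resized to the base window."""
    from kiwicount.cascade import scan_multiscale
    from skimage.transform import resize

    win = config.window
    crops = []
    for gray, truth in scenes:
        boxes, scores, _scales = scan_multiscale(
            gray, partial, scale_factor=config.scale_factor,
            stride=config.stride, max_scales=config.max_scales)
        order = np.argsort(scores)[::-1]
        taken = 0
        for k in order:
            if taken >= per_scene:
                break
            x, y, w, h = boxes[k]
            cx, cy = x + w / 2.0, y + h / 2.0
            if truth.count and np.any(
                np.hypot(truth.tip_centers[:, 0] - cx,
                         truth.tip_centers[:, 1] - cy)
                    < truth.tip_radii + w / 3.0):
                continue
            patch = gray[y:y + h, x:x + w]
            if w != win:
                patch = resize(patch, (win, win), order=1, mode="reflect",
                               anti_aliasing=w > win, preserve_range=True)
            crops.append(patch.astype(np.float32))
            taken += 1
    if not crops:
        return np.empty((0, win, win), dtype=np.float32)
    return np.stack(crops)


def train_default_cascade(
    config: PipelineConfig,
    seed: int = 0,
    n_stages: int | None = None,
    rejection_rate: float | None = None,
    windows=None,
    scene_spec: SceneSpec | None = None,
    n_mining_scenes: int = 5,
) -> Cascade:
    """Train a cascade stage by stage with scene-level hard-negative mining.

    Each stage is a calibrated AdaBoost classifier (via
    :func:`kiwicount.cascade.train_cascade` with a single stage).  Between
    stages the partial cascade scans background-suppressed training scenes;
    its actual surviving false-positive windows -- the mistakes the final
    detector would make -- join the surviving negatives and the mined
    bootstrap pool as the next stage's training negatives.
    """
    import warnings as _warnings

    from kiwicount.cascade import CascadeTrainingWarning

    if windows is None:
        windows = make_training_windows(config, seed=seed,
                                        scene_spec=scene_spec)
    positives, negatives, bootstrap = windows
    n_stages = n_stages if n_stages is not None else config.n_stages
    rejection = (rejection_rate if rejection_rate is not None
                 else config.rejection_rate)
    pool = default_feature_pool(config)
    scenes = _mining_scenes(config, seed, n_mining_scenes, scene_spec)
    rounds = list(config.stage_rounds)
    if len(rounds) < n_stages:
        rounds += [rounds[-1]] * (n_stages - len(rounds))

    rng = np.random.default_rng(_derive_seed(seed, 77))
    bootstrap = bootstrap[rng.permutation(len(bootstrap))]
    cursor = 0
    target = config.train_negatives
    current = np.asarray(negatives, dtype=np.float32)
    stages, stats = [], []
    partial = None
    for si in range(n_stages):
        if partial is not None:
            mined = _mine_false_positives(partial, scenes, config)
            keep_pool = []
            while (len(current) + len(mined) + sum(map(len, keep_pool))
                   < target and cursor < len(bootstrap)):
                chunk = bootstrap[cursor:cursor + 4096]
                cursor += len(chunk)
                passed = chunk[partial.classify_windows(chunk)]
                if len(passed):
                    keep_pool.append(passed)
            current = np.concatenate(
                [current, mined, *keep_pool]) if len(mined) or keep_pool \
                else current
            if len(current) > 2 * target:
                current = current[rng.permutation(len(current))[: 2 * target]]
        if len(current) == 0:
            _warnings.warn(
                f"negatives exhausted after {si} stages; returning a shorter "
                f"cascade", CascadeTrainingWarning)
            break
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", CascadeTrainingWarning)
            try:
                one = train_cascade(
                    positives, current, n_stages=1,
                    rejection_rate=rejection,
                    stage_rounds_schedule=[rounds[si]], d_min=config.d_min,
                    feature_pool=pool, seed=seed,
                    variance_normalize=config.variance_normalize)
            except RuntimeError:
                _warnings.warn(
                    f"stage {si} unlearnable; returning a {len(stages)}-stage "
                    f"cascade", CascadeTrainingWarning)
                break
        stage = one.stages[0]
        stat = one.stage_stats[0]
        stat["stage"] = si
        stages.append(stage)
        stats.append(stat)
        partial = Cascade(stages, config.window, rejection,
                          variance_normalized=config.variance_normalize)
        margins = stage.margins(current)
        current = current[margins >= stage.stage_threshold]

    if not stages:
        raise RuntimeError("cascade training produced no stages")
    return Cascade(stages=stages, base_window=config.window,
                   rejection_rate=rejection,
                   variance_normalized=config.variance_normalize,
                   stage_stats=stats)


def detect_in_image(image: np.ndarray, cascade: Cascade,
                    config: PipelineConfig, preprocessing: bool = True):
    """Background-suppress (optionally) then scan one image."""
    if preprocessing:
        image = suppress_background(
            image, median_window=config.median_window,
            dilation_radius=config.dilation_radius).image
    return detect_multiscale(
        image, cascade, scale_factor=config.scale_factor,
        stride=config.stride, max_scales=config.max_scales,
        group_iou=config.group_iou)


def evaluate_counting(
    cascade: Cascade,
    config: PipelineConfig,
    n_scenes: int = 6,
    seed: int = 0,
    preprocessing: bool = True,
    scene_spec: SceneSpec | None = None,
) -> EvalRecord:
    """Count fruits in seeded single scenes and compare with ground truth."""
    base = scene_spec or SceneSpec(occlusion_prob=0.2)
    pairs = []
    for i in range(n_scenes):
        spec = dataclasses.replace(base, seed=_derive_seed(seed, 100 + i))
        image, truth = generate_scene(spec)
        detections = detect_in_image(image, cascade, config, preprocessing)
        pairs.append((count(detections), truth.count))
    return EvalRecord(pairs=pairs)


def make_panorama(spec: SceneSpec, config: PipelineConfig,
                  overlap_fraction: float = 0.5, jitter: float = 0.0,
                  seed: int = 0):
    """Generate an overlapping frame pair, stitch it, and return the
    panorama with the scene's true fruit count."""
    pair = generate_pair(spec, overlap_fraction=overlap_fraction,
                         jitter=jitter)
    panoramas, _notes = stitch_sequence(
        [pair.frame_a, pair.frame_b], seed=seed,
        max_keypoints=config.max_keypoints, ratio=config.ratio_test,
        ransac_threshold=config.ransac_threshold,
        max_trials=config.ransac_max_trials, canvas_cap=config.canvas_cap)
    return panoramas, pair.canvas_truth.count


def evaluate_panoramas(
    cascade: Cascade,
    config: PipelineConfig,
    n_panoramas: int = 10,
    seed: int = 0,
    preprocessing: bool = True,
    scene_spec: SceneSpec | None = None,
    overlap_fraction: float = 0.5,
) -> EvalRecord:
    """End-to-end: stitch seeded frame pairs, detect, count, score APE."""
    base = scene_spec or SceneSpec(occlusion_prob=0.2)
    pairs = []
    for i in range(n_panoramas):
        spec = dataclasses.replace(base, seed=_derive_seed(seed, 500 + i))
        panoramas, actual = make_panorama(
            spec, config, overlap_fraction=overlap_fraction, seed=seed)
        estimated = sum(
            count(detect_in_image(p.image, cascade, config, preprocessing))
            for p in panoramas)
        pairs.append((estimated, actual))
    return EvalRecord(pairs=pairs)


def count_row(
    images: list[np.ndarray],
    cascade: Cascade,
    config: PipelineConfig,
    metadata: dict | None = None,
) -> tuple[YieldReport, list[StitchResult], list[str]]:
    """Stitch a row of frames, detect on each panorama, report the yield."""
    frames = images[:: config.frame_stride]
    panoramas, notes = stitch_sequence(
        frames, seed=config.seed, max_keypoints=config.max_keypoints,
        ratio=config.ratio_test, ransac_threshold=config.ransac_threshold,
        max_trials=config.ransac_max_trials, canvas_cap=config.canvas_cap)
    counts = [
        count(detect_in_image(p.image, cascade, config,
                              preprocessing=config.detect_on_masked))
        for p in panoramas
    ]
    meta = dict(metadata or {})
    meta.setdefault("config_hash", config.hash())
    report = YieldReport(per_panorama_counts=counts,
                         representative_weight=config.representative_weight,
                         metadata=meta)
    return report, panoramas, notes
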