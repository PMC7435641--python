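"""Synthetic kiwifruit-canopy scenes with exact ground truth.

The generator emulates what a camera pointed up into a kiwifruit canopy sees:
a green textured leaf background, brown elliptical fruits each bearing the
small dark circular blossom-end "tip" that the detector targets, optional
leaf occluders, and a vertical illumination gradient (artificial lighting
from below).  Every output is a pure, bit-reproducible function of its
arguments: one integer seed feeds a single counter-based (Philox) stream.

Colors are fixture conventions chosen so the CIE LAB polarity matches real
canopies: fruit skin around RGB (139, 115, 85) has a* > 0, leaves around
(60, 120, 50) have a* < 0, so Otsu on the A channel separates them by
construction.  Sparse dark "shadow" blobs (a* < 0) are mixed into the
background; they look tip-like in grayscale but are removed by background
suppression, which is what makes the preprocessing ablation meaningful.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse
from skimage.transform import ProjectiveTransform, resize, warp

from kiwicount.imgio import to_grayscale, write_image

# Fixture color conventions (RGB). See module docstring.
FRUIT_RGB = np.array([139.0, 115.0, 85.0])
TIP_RGB = np.array([40.0, 30.0, 25.0])
LEAF_RGB = np.array([60.0, 120.0, 50.0])
SHADOW_RGB = np.array([28.0, 36.0, 24.0])

LABEL_BACKGROUND = 0
LABEL_FRUIT = 1
LABEL_TIP = 2

_PLACEMENT_RETRIES = 200


class PlacementError(RuntimeError):
    """Raised when fruits cannot be placed within the retry budget."""


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic canopy scene.

    ``fruit_radius_range`` is the (min, max) semi-major axis of the fruit
    ellipse in pixels; ``tip_radius_fraction`` sets the tip disc radius as a
    fraction of the fruit radius; ``leaf_density`` is leaf blobs per
    megapixel; ``illumination_gradient`` in [0, 1] scales a vertical
    brightness ramp (bottom brighter, as with upward artificial lighting).
    """

    width: int = 640
    height: int = 480
    n_fruits: int = 25
    fruit_radius_range: tuple[float, float] = (14.0, 22.0)
    tip_radius_fraction: float = 0.35
    occlusion_prob: float = 0.0
    leaf_density: float = 120.0
    illumination_gradient: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("scene dimensions must be positive")
        if self.n_fruits < 0:
            raise ValueError("n_fruits must be >= 0")
        lo, hi = self.fruit_radius_range
        if lo <= 0 or hi < lo:
            raise ValueError("fruit_radius_range must be 0 < min <= max")
        if not 0.0 < self.tip_radius_fraction < 1.0:
            raise ValueError("tip_radius_fraction must be in (0, 1)")
        if not 0.0 <= self.occlusion_prob <= 1.0:
            raise ValueError("occlusion_prob must be in [0, 1]")
        if self.leaf_density < 0:
            raise ValueError("leaf_density must be >= 0")
        if not 0.0 <= self.illumination_gradient <= 1.0:
            raise ValueError("illumination_gradient must be in [0, 1]")


@dataclass
class GroundTruth:
    """Per-scene truth: tip boxes, count, fruit geometry, label raster.

    Boxes are axis-aligned (x, y, w, h), 0-based, half-open.  ``count``
    always equals ``len(boxes)`` and includes occluded tips; ``occluded[i]``
    is True when less than half of tip i's rendered area remains visible.
    ``labels`` assigns each pixel background/leaf (0), fruit (1) or tip (2);
    occluding leaves relabel the pixels they cover as background.
    """

    boxes: np.ndarray  # (N, 4) int
    occluded: np.ndarray  # (N,) bool
    visible_fraction: np.ndarray  # (N,) float, tip area left uncovered
    fruit_ellipses: list[tuple[tuple[float, float], tuple[float, float], float]]
    labels: np.ndarray  # (H, W) uint8
    tip_centers: np.ndarray  # (N, 2) float, (x, y)
    tip_radii: np.ndarray  # (N,) float

    @property
    def count(self) -> int:
        return len(self.boxes)


@dataclass
class FramePair:
    """Two overlapping frames of one scene plus the true relating homography.

    ``homography`` maps homogeneous frame-b pixel coordinates (x, y, 1) into
    frame-a coordinates: warping frame b by it reproduces frame a over the
    shared region.  ``canvas_truth`` is the ground truth of the full
    underlying scene (frame-a coordinates coincide with canvas coordinates).
    """

    frame_a: np.ndarray
    frame_b: np.ndarray
    homography: np.ndarray
    truth_a: GroundTruth
    truth_b: GroundTruth
    canvas_truth: GroundTruth


@dataclass
class FrameSequence:
    """An ordered strip of overlapping frames cut from one wide scene."""

    frames: list[np.ndarray]
    pair_homographies: list[np.ndarray]  # frame i+1 -> frame i coordinates
    frame_truths: list[GroundTruth]
    canvas_truth: GroundTruth


@dataclass
class TrainingWindows:
    """Positive / negative detector-training windows with provenance.

    Windows are grayscale float32 arrays in [0, 255].  ``positive_info`` and
    ``negative_info`` record (scene index, center x, center y, crop side) for
    each window so geometric properties can be audited against the scenes.
    """

    positives: np.ndarray  # (n_pos, w, w) float32
    negatives: np.ndarray  # (n_neg, w, w) float32
    window: int
    positive_info: list[tuple[int, float, float, int]] = field(default_factory=list)
    negative_info: list[tuple[int, float, float, int]] = field(default_factory=list)

    def __iter__(self):
        return iter((self.positives, self.negatives))


def _rng(seed, *spawn_key: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(spawn_key))
    return np.random.Generator(np.random.Philox(ss))


def _value_noise(rng: np.random.Generator, h: int, w: int) -> np.ndarray:
    """Multi-octave smooth value noise in [0, 1]."""
    out = np.zeros((h, w))
    total = 0.0
    for cell, weight in ((96, 1.0), (48, 0.5), (24, 0.25)):
        gh, gw = max(2, h // cell + 2), max(2, w // cell + 2)
        coarse = rng.random((gh, gw))
        out += weight * resize(coarse, (h, w), order=3, mode="reflect",
                               anti_aliasing=False)
        total += weight
    out /= total
    lo, hi = out.min(), out.max()
    return (out - lo) / (hi - lo) if hi > lo else np.zeros_like(out)


def _paint_ellipse(img, label, rng, cy, cx, ry, rx, angle, color, jitter,
                   new_label=None):
    rr, cc = draw_ellipse(cy, cx, ry, rx, shape=img.shape[:2], rotation=angle)
    col = color + rng.uniform(-jitter, jitter, size=3)
    img[rr, cc] = col + rng.normal(0.0, 2.0, size=(len(rr), 3))
    if new_label is not None:
        label[rr, cc] = new_label
    return rr, cc


def _render_scene(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    rng = _rng(spec.seed)
    h, w = spec.height, spec.width
    img = np.empty((h, w, 3))
    labels = np.zeros((h, w), dtype=np.uint8)

    # Background: shaded leaf green with smooth texture + per-pixel grain.
    shade = 0.65 + 0.7 * _value_noise(rng, h, w)
    img[:] = LEAF_RGB * shade[..., None]
    img += rng.normal(0.0, 6.0, size=img.shape)

    # Leaf blobs and dark shadow spots.
    n_blobs = int(round(spec.leaf_density * (h * w) / 1e6))
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        ry, rx = rng.uniform(8, 30), rng.uniform(8, 30)
        _paint_ellipse(img, labels, rng, cy, cx, ry, rx,
                       rng.uniform(0, np.pi), LEAF_RGB, 20.0)
    for _ in range(int(round(0.8 * n_blobs))):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        r = rng.uniform(3, 10)
        _paint_ellipse(img, labels, rng, cy, cx, r, r * rng.uniform(0.7, 1.0),
                       rng.uniform(0, np.pi), SHADOW_RGB * rng.uniform(0.8, 1.3),
                       8.0)

    # Fruit placement: tip boxes must stay inside the image and disjoint,
    # fruit centers must not crowd (so no tip is buried by a later fruit).
    placed: list[dict] = []
    unplaced = 0
    for _ in range(spec.n_fruits):
        for _attempt in range(_PLACEMENT_RETRIES):
            r = rng.uniform(*spec.fruit_radius_range)
            aspect = rng.uniform(0.65, 0.85)
            angle = rng.uniform(0, np.pi)
            margin = r + 2
            if w <= 2 * margin or h <= 2 * margin:
                continue
            cx = rng.uniform(margin, w - margin)
            cy = rng.uniform(margin, h - margin)
            tip_r = spec.tip_radius_fraction * r
            max_off = max(0.0, 0.4 * aspect * r - tip_r)
            off = rng.uniform(0, max_off)
            off_ang = rng.uniform(0, 2 * np.pi)
            tx, ty = cx + off * np.cos(off_ang), cy + off * np.sin(off_ang)
            ok = all(
                np.hypot(cx - p["cx"], cy - p["cy"]) >= 0.9 * (r + p["r"])
                for p in placed
            )
            if ok:
                placed.append(dict(cx=cx, cy=cy, r=r, aspect=aspect,
                                   angle=angle, tx=tx, ty=ty, tip_r=tip_r))
                break
        else:
            unplaced += 1
    if unplaced:
        raise PlacementError(
            f"could not place {unplaced} of {spec.n_fruits} fruits within "
            f"{_PLACEMENT_RETRIES} retries each"
        )

    tip_pixels: list[tuple[np.ndarray, np.ndarray]] = []
    boxes = []
    for p in placed:
        _paint_ellipse(img, labels, rng, p["cy"], p["cx"],
                       p["aspect"] * p["r"], p["r"], p["angle"],
                       FRUIT_RGB, 15.0, new_label=LABEL_FRUIT)
        # Skin blemishes: small dark spots on the fruit body (russet marks,
        # lenticels).  They survive background suppression and are the
        # irreducible confusers that bound what any tip detector can do.
        for _ in range(int(rng.integers(0, 3))):
            ba = rng.uniform(0, 2 * np.pi)
            bd = rng.uniform(0.35, 0.75) * p["r"]
            bx = p["cx"] + bd * np.cos(ba)
            by = p["cy"] + bd * np.sin(ba)
            if np.hypot(bx - p["tx"], by - p["ty"]) < 1.6 * p["tip_r"]:
                continue
            br = rng.uniform(0.25, 0.55) * p["tip_r"]
            brr, bcc = draw_disk((by, bx), br, shape=(h, w))
            bcol = TIP_RGB * rng.uniform(1.1, 1.7) + rng.uniform(-5, 5, 3)
            img[brr, bcc] = bcol + rng.normal(0.0, 2.0, size=(len(brr), 3))
        rr, cc = draw_disk((p["ty"], p["tx"]), p["tip_r"], shape=(h, w))
        # Tip darkness varies fruit to fruit (maturity, viewing angle); the
        # lighter end overlaps the shadow-blob intensity range.
        col = TIP_RGB * rng.uniform(0.8, 1.6) + rng.uniform(-6, 6, size=3)
        img[rr, cc] = col + rng.normal(0.0, 2.0, size=(len(rr), 3))
        labels[rr, cc] = LABEL_TIP
        tip_pixels.append((rr, cc))
        x0, x1 = int(cc.min()), int(cc.max()) + 1
        y0, y1 = int(rr.min()), int(rr.max()) + 1
        boxes.append((x0, y0, x1 - x0, y1 - y0))

    # Occluders: leaf-colored ellipses drawn over fruits after placement.
    occluder_mask = np.zeros((h, w), dtype=bool)
    for p in placed:
        if rng.random() < spec.occlusion_prob:
            # A leaf overlaps a random part of the fruit; whether the tip is
            # buried depends on where the occluder happens to land.
            oa = rng.uniform(0, 2 * np.pi)
            od = rng.uniform(0.3, 1.0) * p["r"]
            ocy = p["cy"] + od * np.sin(oa)
            ocx = p["cx"] + od * np.cos(oa)
            orr = rng.uniform(0.4, 0.8) * p["r"]
            rr, cc = _paint_ellipse(img, labels, rng, ocy, ocx,
                                    orr * rng.uniform(0.7, 1.0), orr,
                                    rng.uniform(0, np.pi), LEAF_RGB, 20.0,
                                    new_label=LABEL_BACKGROUND)
            occluder_mask[rr, cc] = True

    occluded = np.zeros(len(placed), dtype=bool)
    visible_fraction = np.ones(len(placed))
    for i, (rr, cc) in enumerate(tip_pixels):
        if len(rr):
            visible_fraction[i] = 1.0 - occluder_mask[rr, cc].mean()
            occluded[i] = visible_fraction[i] < 0.5

    # Mild defocus blur (canopy depth varies around the focal plane).
    img = ndimage.gaussian_filter(img, sigma=(rng.uniform(0.4, 1.2),) * 2 + (0,))

    # Vertical illumination gradient: bottom of the frame brighter.
    if spec.illumination_gradient > 0:
        ramp = 1.0 + spec.illumination_gradient * (
            np.linspace(0, 1, h) - 0.5
        )
        img *= ramp[:, None, None]

    image = np.clip(np.round(img), 0, 255).astype(np.uint8)
    truth = GroundTruth(
        boxes=np.array(boxes, dtype=int).reshape(-1, 4),
        occluded=occluded,
        visible_fraction=visible_fraction,
        fruit_ellipses=[
            ((p["cx"], p["cy"]), (p["r"], p["aspect"] * p["r"]), p["angle"])
            for p in placed
        ],
        labels=labels,
        tip_centers=np.array([(p["tx"], p["ty"]) for p in placed]).reshape(-1, 2),
        tip_radii=np.array([p["tip_r"] for p in placed]),
    )
    return image, truth


def generate_scene(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one canopy scene and its exact ground truth.

    Deterministic: identical ``spec`` (including seed) yields a
    byte-identical image.  Raises :class:`PlacementError` when the requested
    fruits cannot be placed without overlapping tip regions.
    """
    return _render_scene(spec)


def _restrict_truth(truth: GroundTruth, transform: np.ndarray | None,
                    width: int, height: int,
                    labels: np.ndarray) -> GroundTruth:
    """Ground truth of a frame cut/warped from the canvas."""
    if truth.count == 0:
        return GroundTruth(boxes=np.empty((0, 4), int),
                           occluded=np.empty(0, bool),
                           visible_fraction=np.empty(0),
                           fruit_ellipses=[], labels=labels,
                           tip_centers=np.empty((0, 2)),
                           tip_radii=np.empty(0))
    centers = truth.tip_centers
    if transform is not None:
        homog = np.c_[centers, np.ones(len(centers))] @ transform.T
        centers = homog[:, :2] / homog[:, 2:3]
    radii = truth.tip_radii
    keep = (
        (centers[:, 0] - radii >= 0) & (centers[:, 0] + radii < width)
        & (centers[:, 1] - radii >= 0) & (centers[:, 1] + radii < height)
    )
    cx, cy, r = centers[keep, 0], centers[keep, 1], radii[keep]
    x0 = np.floor(cx - r).astype(int)
    y0 = np.floor(cy - r).astype(int)
    x1 = np.ceil(cx + r).astype(int) + 1
    y1 = np.ceil(cy + r).astype(int) + 1
    boxes = np.c_[x0, y0, np.minimum(x1, width) - x0,
                  np.minimum(y1, height) - y0]
    return GroundTruth(
        boxes=boxes,
        occluded=truth.occluded[keep],
        visible_fraction=truth.visible_fraction[keep],
        fruit_ellipses=[e for e, k in zip(truth.fruit_ellipses, keep) if k],
        labels=labels,
        tip_centers=np.c_[cx, cy],
        tip_radii=r,
    )


def generate_pair(spec: SceneSpec, overlap_fraction: float = 0.5,
                  jitter: float = 0.0) -> FramePair:
    """Two consecutive frames of one scene related by a known homography.

    The scene is rendered once on a wide canvas; frame a is the left crop
    and frame b views the canvas through the true homography (a translation
    by the non-overlapping width, composed with a small random
    rotation/scale when ``jitter`` > 0 pixels of corner displacement).
    """
    if not 0.2 <= overlap_fraction <= 0.9:
        raise ValueError("overlap_fraction must be in [0.2, 0.9]")
    if jitter < 0:
        raise ValueError("jitter must be >= 0")
    w, h = spec.width, spec.height
    dx = int(round((1.0 - overlap_fraction) * w))
    canvas_spec = dataclasses.replace(spec, width=w + dx)
    canvas, truth = _render_scene(canvas_spec)

    homography = np.eye(3)
    homography[0, 2] = dx
    if jitter > 0:
        jrng = _rng(spec.seed, 1)
        half_diag = 0.5 * float(np.hypot(w, h))
        angle = jrng.uniform(-1.0, 1.0) * jitter / half_diag
        scale = 1.0 + jrng.uniform(-1.0, 1.0) * jitter / half_diag
        cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
        cos_a, sin_a = np.cos(angle), np.sin(angle)
        about_center = (
            np.array([[1, 0, cx], [0, 1, cy], [0, 0, 1.0]])
            @ np.array([[scale * cos_a, -scale * sin_a, 0],
                        [scale * sin_a, scale * cos_a, 0], [0, 0, 1.0]])
            @ np.array([[1, 0, -cx], [0, 1, -cy], [0, 0, 1.0]])
        )
        homography = homography @ about_center

    frame_a = canvas[:, :w].copy()
    if jitter == 0:
        frame_b = canvas[:, dx:dx + w].copy()
        labels_b = truth.labels[:, dx:dx + w].copy()
    else:
        tform = ProjectiveTransform(matrix=homography)
        frame_b = np.clip(np.round(
            warp(canvas.astype(float), tform, output_shape=(h, w),
                 order=1, preserve_range=True, cval=0.0)
        ), 0, 255).astype(np.uint8)
        labels_b = warp(truth.labels.astype(float), tform,
                        output_shape=(h, w), order=0,
                        preserve_range=True).astype(np.uint8)

    inv = np.linalg.inv(homography)
    truth_a = _restrict_truth(truth, None, w, h, truth.labels[:, :w].copy())
    truth_b = _restrict_truth(truth, inv, w, h, labels_b)
    return FramePair(frame_a, frame_b, homography, truth_a, truth_b, truth)


def generate_sequence(spec: SceneSpec, n_frames: int,
                      overlap_fraction: float = 0.5) -> FrameSequence:
    """An ordered strip of ``n_frames`` translated crops of one wide scene."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if not 0.2 <= overlap_fraction <= 0.9:
        raise ValueError("overlap_fraction must be in [0.2, 0.9]")
    w, h = spec.width, spec.height
    dx = int(round((1.0 - overlap_fraction) * w))
    canvas_spec = dataclasses.replace(spec, width=w + (n_frames - 1) * dx)
    canvas, truth = _render_scene(canvas_spec)
    frames, truths = [], []
    for i in range(n_frames):
        x0 = i * dx
        frames.append(canvas[:, x0:x0 + w].copy())
        shift = np.eye(3)
        shift[0, 2] = -x0
        truths.append(_restrict_truth(
            truth, shift, w, h, truth.labels[:, x0:x0 + w].copy()))
    pair_h = np.eye(3)
    pair_h[0, 2] = dx
    return FrameSequence(frames, [pair_h.copy() for _ in range(n_frames - 1)],
                         truths, truth)


def generate_training_windows(
    n_pos: int,
    n_neg: int,
    window: int = 24,
    seed: int = 0,
    scene_spec: SceneSpec | None = None,
    masked_negative_fraction: float = 0.5,
    max_scenes: int = 60,
) -> TrainingWindows:
    """Tip-centered positive crops and background negative crops.

    Positives are square crops of side 4x the tip radius centered on
    unoccluded tips, resized to ``window`` x ``window`` grayscale.  Negatives
    are crops whose centers avoid every ground-truth tip box; a
    ``masked_negative_fraction`` share of them is cut from the
    background-suppressed rendering of the scene (mostly black, with mask
    remnants), because detection runs on masked panoramas and the cascade
    must learn to reject that appearance too.
    """
    from kiwicount.preprocess import suppress_background

    if window < 12:
        raise ValueError("window must be >= 12")
    if n_pos < 0 or n_neg < 0:
        raise ValueError("window counts must be >= 0")
    base = scene_spec or SceneSpec()
    positives, negatives = [], []
    pos_info, neg_info = [], []
    neg_per_scene = max(20, int(np.ceil(n_neg / max(1, max_scenes // 2))))
    scene_idx = 0
    while (len(positives) < n_pos or len(negatives) < n_neg):
        if scene_idx >= max_scenes:
            raise RuntimeError(
                f"requested {n_pos} positives / {n_neg} negatives exceed the "
                f"distinct crops available from {max_scenes} scenes "
                f"(got {len(positives)} / {len(negatives)})"
            )
        spec = dataclasses.replace(base, seed=_derive_seed(seed, scene_idx))
        image, truth = _render_scene(spec)
        gray = to_grayscale(image)
        masked_gray = None
        boundary_rows = boundary_cols = None
        rng = _rng(seed, 2, scene_idx)

        for i in range(truth.count):
            if len(positives) >= n_pos:
                break
            # Tips with at least a tenth of their area visible are kept as
            # positives: a real annotation set contains partially occluded
            # (ambiguous) examples, and they are what makes the detection-
            # rate / rejection-rate trade-off meaningful.
            if truth.visible_fraction[i] < 0.1:
                continue
            tx, ty = truth.tip_centers[i]
            # Crop-extraction jitter emulates imprecise annotation: the tip
            # stays central but its apparent size and offset vary.
            side = max(window // 2,
                       int(round(rng.uniform(3.4, 4.6) * truth.tip_radii[i])))
            jx = tx + rng.uniform(-0.1, 0.1) * side
            jy = ty + rng.uniform(-0.1, 0.1) * side
            crop = _crop_resized(gray, jx, jy, side, window)
            if crop is not None:
                positives.append(crop)
                pos_info.append((scene_idx, float(jx), float(jy), side))

        # Half of the unmasked negatives are "hard": centered on the darkest
        # background pixels (shadow blobs), the confusers sliding windows
        # actually meet.
        dark_rows, dark_cols = _dark_background_pixels(gray, truth.boxes,
                                                       spec, window)
        for _ in range(neg_per_scene):
            if len(negatives) >= n_neg:
                break
            use_masked = rng.random() < masked_negative_fraction
            if use_masked and masked_gray is None:
                suppressed = suppress_background(image)
                masked_gray = to_grayscale(suppressed.image)
                eroded = ndimage.binary_erosion(suppressed.mask,
                                                iterations=3)
                boundary_rows, boundary_cols = np.nonzero(
                    suppressed.mask & ~eroded)
            hard = rng.random() < 0.5
            if use_masked and hard and boundary_rows is not None \
                    and len(boundary_rows):
                # Mask-boundary windows: part black, part foreground -- the
                # confusers a detector scanning masked panoramas meets.
                k = int(rng.integers(len(boundary_rows)))
                cx = float(boundary_cols[k]) + rng.uniform(-6, 6)
                cy = float(boundary_rows[k]) + rng.uniform(-6, 6)
            elif not use_masked and hard and len(dark_rows):
                k = int(rng.integers(len(dark_rows)))
                cx = float(dark_cols[k]) + rng.uniform(-2, 2)
                cy = float(dark_rows[k]) + rng.uniform(-2, 2)
            else:
                cx = rng.uniform(window, spec.width - window)
                cy = rng.uniform(window, spec.height - window)
            if _inside_any_box(cx, cy, truth.boxes):
                continue
            side = int(rng.integers(window, 3 * window + 1))
            if hard:
                side = int(rng.integers(window, 3 * window // 2 + 1))
            src = masked_gray if use_masked else gray
            crop = _crop_resized(src, cx, cy, side, window)
            if crop is not None:
                negatives.append(crop)
                neg_info.append((scene_idx, float(cx), float(cy), side))
        scene_idx += 1

    return TrainingWindows(
        positives=np.array(positives[:n_pos], dtype=np.float32).reshape(
            (-1, window, window)),
        negatives=np.array(negatives[:n_neg], dtype=np.float32).reshape(
            (-1, window, window)),
        window=window,
        positive_info=pos_info[:n_pos],
        negative_info=neg_info[:n_neg],
    )


def _derive_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence(
        entropy=int(seed), spawn_key=(k,)).generate_state(1)[0] % (2**31))


def _dark_background_pixels(gray: np.ndarray, boxes: np.ndarray,
                            spec: SceneSpec, window: int):
    """Coordinates of the darkest 2% of pixels away from tips and borders."""
    h, w = gray.shape
    ok = np.zeros_like(gray, dtype=bool)
    ok[window:h - window, window:w - window] = True
    for x, y, bw, bh in boxes:
        x0 = max(0, x - window)
        y0 = max(0, y - window)
        ok[y0:y + bh + window, x0:x + bw + window] = False
    cutoff = np.percentile(gray[ok], 2.0) if ok.any() else 0.0
    rows, cols = np.nonzero(ok & (gray <= cutoff))
    return rows, cols


def _inside_any_box(x: float, y: float, boxes: np.ndarray) -> bool:
    if len(boxes) == 0:
        return False
    return bool(np.any(
        (boxes[:, 0] <= x) & (x < boxes[:, 0] + boxes[:, 2])
        & (boxes[:, 1] <= y) & (y < boxes[:, 1] + boxes[:, 3])
    ))


def _crop_resized(gray: np.ndarray, cx: float, cy: float, side: int,
                  window: int) -> np.ndarray | None:
    h, w = gray.shape
    half = side / 2.0
    x0, y0 = int(round(cx - half)), int(round(cy - half))
    x1, y1 = x0 + side, y0 + side
    if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
        return None
    patch = gray[y0:y1, x0:x1]
    if side != window:
        patch = resize(patch, (window, window), order=1, mode="reflect",
                       anti_aliasing=side > window, preserve_range=True)
    return patch.astype(np.float32)


def write_scene(directory: str | Path, name: str, image: np.ndarray,
                truth: GroundTruth, spec: SceneSpec) -> None:
    """Persist a scene as PNG + ground-truth CSV + JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_image(image, directory / f"{name}.png")
    df = pd.DataFrame(truth.boxes, columns=["x", "y", "w", "h"])
    df["occluded"] = truth.occluded.astype(int)
    df.to_csv(directory / f"{name}_truth.csv", index=False)
    manifest = dataclasses.asdict(spec)
    manifest["count"] = truth.count
    with open(directory / f"{name}_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
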