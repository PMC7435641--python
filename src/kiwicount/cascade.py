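"""Cascaded detection: stage training, rejection-rate calibration,
multi-scale sliding-window scanning, and detection grouping.

A cascade is an ordered list of AdaBoost strong classifiers.  A window must
pass every stage to become a detection; windows failing any stage are
dropped immediately, which is what keeps scanning cheap.  Each stage's
threshold is calibrated in two moves: lowered from the natural half-vote
point until the stage passes at least ``d_min`` of the training positives,
then raised if necessary so it rejects at least the configured rejection
rate of the negatives reaching it (plus a fixed two-percentage-point
calibration margin absorbing quantile-estimation noise on finite samples).
Negatives surviving a stage train the next one, topped up from a bootstrap
pool when survivors run low.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from kiwicount.haar import (
    HaarFeature,
    StrongClassifier,
    WeakClassifier,
    adaboost,
    generate_feature_pool,
    integral_image,
)
from kiwicount.imgio import to_grayscale

CASCADE_FORMAT_VERSION = 1

# Extra rejection enforced at calibration time so the configured minimum
# still holds on held-out negatives (percentage points).
CALIBRATION_MARGIN_PP = 2.0


@dataclass(frozen=True)
class Detection:
    """One grouped detection: half-open box, final-stage margin, scale."""

    box: tuple[int, int, int, int]
    score: float
    scale: float


@dataclass
class Cascade:
    """Ordered strong classifiers sharing one base window."""

    stages: list[StrongClassifier]
    base_window: int
    rejection_rate: float
    variance_normalized: bool = False
    stage_stats: list[dict] = field(default_factory=list)

    @property
    def n_stages(self) -> int:
        return len(self.stages)

    def classify_windows(self, samples: np.ndarray) -> np.ndarray:
        """Boolean pass/fail of window stacks through every stage."""
        samples = np.asarray(samples)
        alive = np.ones(len(samples), dtype=bool)
        for stage in self.stages:
            if not alive.any():
                break
            margins = stage.margins(samples[alive])
            keep = margins >= stage.stage_threshold
            idx = np.flatnonzero(alive)
            alive[idx[~keep]] = False
        return alive

    def to_dict(self) -> dict:
        return {
            "format_version": CASCADE_FORMAT_VERSION,
            "base_window": self.base_window,
            "rejection_rate": self.rejection_rate,
            "variance_normalized": self.variance_normalized,
            "stage_stats": self.stage_stats,
            "stages": [
                {
                    "stage_threshold": s.stage_threshold,
                    "alphas": list(s.alphas),
                    "window": s.window,
                    "stumps": [
                        {
                            "kind": wc.feature.kind,
                            "x": wc.feature.x,
                            "y": wc.feature.y,
                            "width": wc.feature.width,
                            "height": wc.feature.height,
                            "threshold": wc.threshold,
                            "parity": wc.parity,
                        }
                        for wc in s.weak
                    ],
                }
                for s in self.stages
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "Cascade":
        if data.get("format_version") != CASCADE_FORMAT_VERSION:
            raise ValueError(
                f"unsupported cascade format {data.get('format_version')!r}")
        stages = []
        for sd in data["stages"]:
            weak = [
                WeakClassifier(
                    HaarFeature(st["kind"], st["x"], st["y"], st["width"],
                                st["height"]),
                    st["threshold"], st["parity"])
                for st in sd["stumps"]
            ]
            stages.append(StrongClassifier(
                weak=weak, alphas=list(sd["alphas"]),
                stage_threshold=sd["stage_threshold"], window=sd["window"],
                variance_normalize=bool(data.get("variance_normalized",
                                                 False))))
        return cls(stages=stages, base_window=data["base_window"],
                   rejection_rate=data["rejection_rate"],
                   variance_normalized=bool(data.get("variance_normalized",
                                                     False)),
                   stage_stats=list(data.get("stage_stats", [])))

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path: str | Path) -> "Cascade":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


class CascadeTrainingWarning(UserWarning):
    pass


def _calibrate_threshold(pos_margins: np.ndarray, neg_margins: np.ndarray,
                         default_threshold: float, d_min: float,
                         rejection_rate: float) -> float:
    """Two-step stage-threshold calibration (see module docstring)."""
    sorted_pos = np.sort(pos_margins)
    k = int(np.floor((1.0 - d_min / 100.0) * len(sorted_pos)))
    t_detect = float(sorted_pos[min(k, len(sorted_pos) - 1)])
    threshold = min(default_threshold, t_detect)

    target = min(0.995, (rejection_rate + CALIBRATION_MARGIN_PP) / 100.0)
    sorted_neg = np.sort(neg_margins)
    k_neg = int(np.ceil(target * len(sorted_neg)))
    if k_neg >= 1:
        t_reject = float(sorted_neg[min(k_neg, len(sorted_neg)) - 1])
        t_reject = np.nextafter(t_reject, np.inf)
        threshold = max(threshold, t_reject)
    return float(threshold)


def train_cascade(
    positives: np.ndarray,
    negatives: np.ndarray,
    n_stages: int = 6,
    rejection_rate: float = 20.0,
    stage_rounds_schedule: list[int] | int = 6,
    d_min: float = 99.5,
    feature_pool: list[HaarFeature] | None = None,
    bootstrap_negatives: np.ndarray | None = None,
    seed: int = 0,
    variance_normalize: bool = False,
) -> Cascade:
    """Train an ``n_stages`` cascade of calibrated AdaBoost classifiers.

    ``rejection_rate`` (percent, exclusive 0..100) is the minimum fraction
    of negative windows each stage must reject; ``d_min`` (percent) the
    minimum fraction of positives each stage must keep.  Negatives that
    survive a stage train the next; when they run low the ``bootstrap_negatives``
    pool is filtered through the existing stages to replenish them.  If
    negatives are exhausted before ``n_stages``, the shorter cascade is
    returned with a warning.
    """
    positives = np.asarray(positives, dtype=np.float64)
    negatives = np.asarray(negatives, dtype=np.float64)
    if len(positives) == 0 or len(negatives) == 0:
        raise ValueError("need non-empty positive and negative sets")
    if not 0.0 < rejection_rate < 100.0:
        raise ValueError("rejection_rate must be in (0, 100)")
    if n_stages < 1:
        raise ValueError("n_stages must be >= 1")
    window = positives.shape[-1]
    if feature_pool is None:
        feature_pool = generate_feature_pool(window)
    if isinstance(stage_rounds_schedule, int):
        stage_rounds_schedule = [stage_rounds_schedule] * n_stages
    if len(stage_rounds_schedule) < n_stages:
        stage_rounds_schedule = list(stage_rounds_schedule) + [
            stage_rounds_schedule[-1]
        ] * (n_stages - len(stage_rounds_schedule))

    rng = np.random.default_rng(seed)
    pool = (np.asarray(bootstrap_negatives, dtype=np.float64)
            if bootstrap_negatives is not None else np.empty((0, window, window)))
    pool = pool[rng.permutation(len(pool))] if len(pool) else pool
    pool_cursor = 0
    target_negs = len(negatives)
    current_negs = negatives

    stages: list[StrongClassifier] = []
    stats: list[dict] = []
    for si in range(n_stages):
        if len(current_negs) < max(20, target_negs // 4) and pool_cursor < len(pool):
            needed = target_negs - len(current_negs)
            refill = []
            while needed > 0 and pool_cursor < len(pool):
                chunk = pool[pool_cursor:pool_cursor + 4 * needed]
                pool_cursor += len(chunk)
                if stages:
                    partial = Cascade(stages, window, rejection_rate,
                                      variance_normalized=variance_normalize)
                    chunk = chunk[partial.classify_windows(chunk)]
                if len(chunk):
                    refill.append(chunk[:needed])
                    needed -= len(chunk[:needed])
            if refill:
                current_negs = np.concatenate([current_negs, *refill])
        if len(current_negs) == 0:
            warnings.warn(
                f"negatives exhausted after {si} stages; returning a shorter "
                f"cascade", CascadeTrainingWarning)
            break

        samples = np.concatenate([positives, current_negs])
        labels = np.concatenate([
            np.ones(len(positives), dtype=int),
            np.zeros(len(current_negs), dtype=int),
        ])
        try:
            clf = adaboost(samples, labels, stage_rounds_schedule[si],
                           feature_pool, variance_normalize=variance_normalize)
        except RuntimeError as exc:
            warnings.warn(
                f"stage {si} training aborted ({exc}); returning a "
                f"{len(stages)}-stage cascade", CascadeTrainingWarning)
            break
        pos_margins = clf.margins(positives)
        neg_margins = clf.margins(current_negs)
        clf.stage_threshold = _calibrate_threshold(
            pos_margins, neg_margins, clf.default_threshold, d_min,
            rejection_rate)
        keep = neg_margins >= clf.stage_threshold
        stats.append({
            "stage": si,
            "n_negatives": int(len(current_negs)),
            "training_rejection": float(1.0 - keep.mean()),
            "detection_rate": float(
                (pos_margins >= clf.stage_threshold).mean()),
            "rounds": len(clf.weak),
        })
        stages.append(clf)
        current_negs = current_negs[keep]

    if not stages:
        raise RuntimeError("cascade training produced no stages")
    return Cascade(stages=stages, base_window=window,
                   rejection_rate=rejection_rate,
                   variance_normalized=variance_normalize, stage_stats=stats)


def _grid_feature_values(ii: np.ndarray, rects, xs: np.ndarray,
                         ys: np.ndarray) -> np.ndarray:
    shaded = np.zeros(len(xs))
    white = np.zeros(len(xs))
    sa = wa = 0
    for rx, ry, rw, rh, sign in rects:
        s = (ii[ys + ry + rh, xs + rx + rw] - ii[ys + ry, xs + rx + rw]
             - ii[ys + ry + rh, xs + rx] + ii[ys + ry, xs + rx])
        if sign > 0:
            shaded += s
            sa += rw * rh
        else:
            white += s
            wa += rw * rh
    return shaded / sa - white / wa


def scan_multiscale(
    image: np.ndarray,
    cascade: Cascade,
    scale_factor: float = 1.25,
    stride: int = 2,
    max_scales: int = 4,
) -> tuple[list[tuple[int, int, int, int]], list[float], list[float]]:
    """Raw (ungrouped) windows surviving every cascade stage.

    Returns parallel lists of boxes, final-stage margins minus the final
    stage threshold, and scales.  Used by detection (after grouping) and by
    hard-negative mining (which wants every surviving window).
    """
    image = np.asarray(image)
    gray = to_grayscale(image) if image.ndim == 3 else image.astype(np.float64)
    H, W = gray.shape
    if min(H, W) < cascade.base_window:
        return [], [], []
    ii = integral_image(gray)
    ii2 = integral_image(gray * gray) if cascade.variance_normalized else None

    boxes: list[tuple[int, int, int, int]] = []
    scores: list[float] = []
    scales: list[float] = []
    scale = 1.0
    for _ in range(max_scales):
        win = int(round(cascade.base_window * scale))
        if win > min(H, W):
            break
        step = max(1, int(round(stride * scale)))
        xs0 = np.arange(0, W - win + 1, step)
        ys0 = np.arange(0, H - win + 1, step)
        gx, gy = np.meshgrid(xs0, ys0)
        xs, ys = gx.ravel(), gy.ravel()
        if ii2 is not None:
            area = win * win
            s1 = (ii[ys + win, xs + win] - ii[ys, xs + win]
                  - ii[ys + win, xs] + ii[ys, xs])
            s2 = (ii2[ys + win, xs + win] - ii2[ys, xs + win]
                  - ii2[ys + win, xs] + ii2[ys, xs])
            stds = np.maximum(
                np.sqrt(np.maximum(s2 / area - (s1 / area) ** 2, 0.0)), 1.0)
        else:
            stds = None
        margins = np.zeros(len(xs))
        for stage in cascade.stages:
            if len(xs) == 0:
                break
            margins = np.zeros(len(xs))
            for alpha, wc in zip(stage.alphas, stage.weak):
                vals = _grid_feature_values(
                    ii, wc.feature.rects(scale), xs, ys)
                if stds is not None:
                    vals = vals / stds
                h = wc.parity * vals < wc.parity * wc.threshold
                margins += alpha * h
            keep = margins >= stage.stage_threshold
            xs, ys, margins = xs[keep], ys[keep], margins[keep]
            if stds is not None:
                stds = stds[keep]
        final_scores = margins - cascade.stages[-1].stage_threshold
        for x, y, s in zip(xs, ys, final_scores):
            boxes.append((int(x), int(y), win, win))
            scores.append(float(s))
            scales.append(scale)
        scale *= scale_factor
    return boxes, scores, scales


def detect_multiscale(
    image: np.ndarray,
    cascade: Cascade,
    scale_factor: float = 1.25,
    stride: int = 2,
    max_scales: int = 4,
    group_iou: float = 0.3,
) -> list[Detection]:
    """Scan an image with the cascade over a geometric scale sequence.

    Features are scaled, not the image, so one integral image serves every
    scale; the base stride grows proportionally with the scale.  Candidate
    windows surviving all stages are merged greedily: the highest-scoring
    candidate absorbs every candidate overlapping it above ``group_iou`` or
    centered inside it.  Deterministic: no randomness at inference.
    """
    boxes, scores, scales = scan_multiscale(
        image, cascade, scale_factor=scale_factor, stride=stride,
        max_scales=max_scales)
    return group_detections(boxes, scores, scales, iou_threshold=group_iou)


def box_iou(a: tuple[int, int, int, int], b: tuple[int, int, int, int]) -> float:
    """Intersection-over-union of two half-open (x, y, w, h) boxes."""
    ax0, ay0, aw, ah = a
    bx0, by0, bw, bh = b
    ix = max(0, min(ax0 + aw, bx0 + bw) - max(ax0, bx0))
    iy = max(0, min(ay0 + ah, by0 + bh) - max(ay0, by0))
    inter = ix * iy
    union = aw * ah + bw * bh - inter
    return inter / union if union > 0 else 0.0


def _same_target(a, b) -> bool:
    """Whether two candidate boxes plausibly cover the same tip: IoU above
    the grouping threshold, or the smaller box's center inside the larger
    (cross-scale duplicates have low IoU but concentric centers)."""
    small, large = (a, b) if a[2] * a[3] <= b[2] * b[3] else (b, a)
    cx, cy = small[0] + small[2] / 2.0, small[1] + small[3] / 2.0
    return (large[0] <= cx < large[0] + large[2]
            and large[1] <= cy < large[1] + large[3])


def group_detections(boxes, scores, scales=None, iou_threshold: float = 0.3,
                     max_detections: int = 1000) -> list[Detection]:
    """Greedy grouping keeping the highest-score representative.

    A candidate is absorbed by an already-kept detection when their IoU
    exceeds ``iou_threshold`` or when the smaller box is centered inside the
    larger one (the cross-scale duplicate case).  Grouping stops at
    ``max_detections`` kept boxes -- far beyond the number of fruits a frame
    can physically hold -- which bounds the cost when a weak detector floods
    the scan with candidates."""
    if scales is None:
        scales = [1.0] * len(boxes)
    order = sorted(range(len(boxes)),
                   key=lambda i: (-scores[i], boxes[i]))
    taken: list[Detection] = []
    tx0 = np.empty(0)
    ty0 = np.empty(0)
    tx1 = np.empty(0)
    ty1 = np.empty(0)
    for i in order:
        if len(taken) >= max_detections:
            break
        x, y, w, h = boxes[i]
        if taken:
            ix = np.minimum(tx1, x + w) - np.maximum(tx0, x)
            iy = np.minimum(ty1, y + h) - np.maximum(ty0, y)
            inter = np.maximum(ix, 0) * np.maximum(iy, 0)
            union = (tx1 - tx0) * (ty1 - ty0) + w * h - inter
            if np.any(inter / np.maximum(union, 1) > iou_threshold):
                continue
            # smaller-box center inside the larger box
            cx, cy = x + w / 2.0, y + h / 2.0
            tcx, tcy = (tx0 + tx1) / 2.0, (ty0 + ty1) / 2.0
            small_in_large = ((tx0 <= cx) & (cx < tx1)
                              & (ty0 <= cy) & (cy < ty1)
                              & ((tx1 - tx0) * (ty1 - ty0) >= w * h))
            large_in_small = ((x <= tcx) & (tcx < x + w)
                              & (y <= tcy) & (tcy < y + h)
                              & ((tx1 - tx0) * (ty1 - ty0) < w * h))
            if np.any(small_in_large | large_in_small):
                continue
        taken.append(Detection(box=tuple(boxes[i]), score=scores[i],
                               scale=scales[i]))
        tx0 = np.append(tx0, x)
        ty0 = np.append(ty0, y)
        tx1 = np.append(tx1, x + w)
        ty1 = np.append(ty1, y + h)
    return taken


def count(detections) -> int:
    """Fruit count: the number of grouped detections."""
    return len(list(detections))
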