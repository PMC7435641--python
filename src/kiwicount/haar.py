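"""Viola-Jones building blocks: integral images, Haar features, decision
stumps, and AdaBoost.

A Haar feature is the difference between the mean intensity under its shaded
rectangles and under its white rectangles.  Working with per-region means
(rather than raw box-sum differences) makes the value invariant to the
integer rounding that scaling a feature entails, so stump thresholds learned
at the base window transfer across detection scales.  All sums come from a
single integral image in O(1) per rectangle.

The boosting loop is the classic discrete-AdaBoost weight-update: sample
weights start at 1/(2m) for the m negatives and 1/(2l) for the l positives,
are renormalized each round, the lowest-weighted-error stump is selected,
and correctly classified samples are downweighted by beta_t = e_t/(1-e_t);
the strong classifier is the alpha-weighted stump vote thresholded at half
the total vote, with alpha_t = log(1/beta_t).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

FEATURE_KINDS = (
    "two_rect_horizontal",
    "two_rect_vertical",
    "three_rect_horizontal",
    "three_rect_vertical",
    "four_rect",
)

_DIVISORS = {
    "two_rect_horizontal": (2, 1),
    "two_rect_vertical": (1, 2),
    "three_rect_horizontal": (3, 1),
    "three_rect_vertical": (1, 3),
    "four_rect": (2, 2),
}

_MIN_ERROR = 1e-10


def integral_image(image: np.ndarray) -> np.ndarray:
    """Padded cumulative-sum table of a single-channel raster.

    Entry (y, x) of the (H+1) x (W+1) result is the sum of all source
    pixels with row < y and column < x; the zero top row / left column make
    box sums four lookups with no boundary cases.
    """
    image = np.asarray(image)
    if image.ndim != 2 or image.shape[0] < 1 or image.shape[1] < 1:
        raise ValueError("integral_image expects a non-empty 2-D raster")
    dtype = np.int64 if np.issubdtype(image.dtype, np.integer) else np.float64
    ii = np.zeros((image.shape[0] + 1, image.shape[1] + 1), dtype=dtype)
    np.cumsum(np.cumsum(image.astype(dtype), axis=0), axis=1, out=ii[1:, 1:])
    return ii


def box_sum(ii: np.ndarray, x: int, y: int, w: int, h: int) -> float:
    """Sum of the half-open rectangle [x, x+w) x [y, y+h) via 4 lookups."""
    H, W = ii.shape[0] - 1, ii.shape[1] - 1
    if w <= 0 or h <= 0 or x < 0 or y < 0 or x + w > W or y + h > H:
        raise ValueError(
            f"rectangle ({x},{y},{w},{h}) outside {W}x{H} image bounds")
    return float(ii[y + h, x + w] - ii[y, x + w] - ii[y + h, x] + ii[y, x])


@dataclass(frozen=True)
class HaarFeature:
    """One rectangular feature inside the base detection window.

    ``kind`` selects the layout (adjacent halves, thirds, or a 2x2
    checkerboard); (x, y, width, height) is the footprint, which must sit
    inside the base window and divide evenly as the kind requires.
    """

    kind: str
    x: int
    y: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        dw, dh = _DIVISORS[self.kind]
        if self.width <= 0 or self.height <= 0:
            raise ValueError("feature dimensions must be positive")
        if self.width % dw or self.height % dh:
            raise ValueError(
                f"{self.kind} requires width divisible by {dw} and height "
                f"by {dh}, got {self.width}x{self.height}")
        if self.x < 0 or self.y < 0:
            raise ValueError("feature origin must be non-negative")

    def rects(self, scale: float = 1.0):
        """(x, y, w, h, sign) rectangles; +1 shaded, -1 white.

        Under scaling each internal edge is rounded independently, so the
        rectangles always tile the scaled footprint exactly.
        """
        def edges(lo: int, n_parts: int, size: int) -> list[int]:
            return [int(round((lo + size * k / n_parts) * scale))
                    for k in range(n_parts + 1)]

        kind = self.kind
        xs = edges(self.x, _DIVISORS[kind][0], self.width)
        ys = edges(self.y, _DIVISORS[kind][1], self.height)
        out = []
        if kind == "four_rect":
            signs = {(0, 0): 1, (1, 1): 1, (0, 1): -1, (1, 0): -1}
            for (i, j), s in signs.items():
                out.append((xs[i], ys[j], xs[i + 1] - xs[i],
                            ys[j + 1] - ys[j], s))
        elif kind.startswith("three"):
            parts = xs if len(xs) == 4 else ys
            for k in range(3):
                sign = 1 if k == 1 else -1
                if len(xs) == 4:
                    out.append((xs[k], ys[0], xs[k + 1] - xs[k],
                                ys[1] - ys[0], sign))
                else:
                    out.append((xs[0], ys[k], xs[1] - xs[0],
                                ys[k + 1] - ys[k], sign))
        else:  # two-rect: first half white, second shaded
            for k in range(2):
                sign = -1 if k == 0 else 1
                if len(xs) == 3:
                    out.append((xs[k], ys[0], xs[k + 1] - xs[k],
                                ys[1] - ys[0], sign))
                else:
                    out.append((xs[0], ys[k], xs[1] - xs[0],
                                ys[k + 1] - ys[k], sign))
        return out


def feature_value(ii: np.ndarray, feature: HaarFeature,
                  window_origin: tuple[int, int] = (0, 0),
                  window_scale: float = 1.0) -> float:
    """Mean(shaded) - mean(white) of the (scaled) feature at one window."""
    ox, oy = window_origin
    shaded_sum = white_sum = 0.0
    shaded_area = white_area = 0
    for rx, ry, rw, rh, sign in feature.rects(window_scale):
        if rw <= 0 or rh <= 0:
            raise ValueError("scaled feature rectangle collapsed to zero area")
        s = box_sum(ii, ox + rx, oy + ry, rw, rh)
        if sign > 0:
            shaded_sum += s
            shaded_area += rw * rh
        else:
            white_sum += s
            white_area += rw * rh
    return shaded_sum / shaded_area - white_sum / white_area


def generate_feature_pool(window: int = 24, position_stride: int = 3,
                          size_stride: int = 3, min_size: int = 6,
                          full: bool = False) -> list[HaarFeature]:
    """Enumerate Haar features on a position/size grid inside the window.

    The default grid keeps training desk-scale; ``full=True`` enumerates
    every admissible position and size (stride 1, minimum size one split
    unit), which is substantially larger.
    """
    if full:
        position_stride = size_stride = 1
        min_size = 2
    pool: list[HaarFeature] = []
    for kind in FEATURE_KINDS:
        dw, dh = _DIVISORS[kind]
        widths = [w for w in range(max(dw, min_size), window + 1)
                  if w % dw == 0 and (w - max(dw, min_size)) % size_stride == 0]
        heights = [h for h in range(max(dh, min_size), window + 1)
                   if h % dh == 0 and (h - max(dh, min_size)) % size_stride == 0]
        for w in widths:
            for h in heights:
                for x in range(0, window - w + 1, position_stride):
                    for y in range(0, window - h + 1, position_stride):
                        pool.append(HaarFeature(kind, x, y, w, h))
    return pool


def window_std(samples: np.ndarray) -> np.ndarray:
    """Per-window intensity standard deviation, floored at 1."""
    samples = np.asarray(samples, dtype=np.float64)
    flat = samples.reshape(len(samples), -1)
    return np.maximum(flat.std(axis=1), 1.0)


def feature_value_matrix(samples: np.ndarray, features: list[HaarFeature],
                         variance_normalize: bool = False) -> np.ndarray:
    """(F, n) matrix of feature values over a stack of equal-size windows.

    With ``variance_normalize`` each window's values are divided by its
    intensity standard deviation (classic Viola-Jones lighting correction;
    off by default).
    """
    samples = np.asarray(samples, dtype=np.float64)
    n, h, w = samples.shape
    iis = np.zeros((n, h + 1, w + 1))
    np.cumsum(np.cumsum(samples, axis=1), axis=2, out=iis[:, 1:, 1:])
    out = np.empty((len(features), n))
    for fi, feat in enumerate(features):
        shaded = np.zeros(n)
        white = np.zeros(n)
        sa = wa = 0
        for rx, ry, rw, rh, sign in feat.rects():
            s = (iis[:, ry + rh, rx + rw] - iis[:, ry, rx + rw]
                 - iis[:, ry + rh, rx] + iis[:, ry, rx])
            if sign > 0:
                shaded += s
                sa += rw * rh
            else:
                white += s
                wa += rw * rh
        out[fi] = shaded / sa - white / wa
    if variance_normalize:
        out /= window_std(samples)[None, :]
    return out


@dataclass(frozen=True)
class WeakClassifier:
    """Decision stump h(x) = 1 iff parity * f(x) < parity * threshold."""

    feature: HaarFeature
    threshold: float
    parity: int

    def __post_init__(self) -> None:
        if self.parity not in (-1, 1):
            raise ValueError("parity must be +1 or -1")

    def evaluate(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values)
        return (self.parity * values < self.parity * self.threshold).astype(
            np.uint8)


def train_stump(feature_values: np.ndarray, labels: np.ndarray,
                weights: np.ndarray) -> tuple[float, int, float]:
    """Optimal (threshold, parity, weighted error) for one feature.

    A single sorted scan of cumulative class weights visits every distinct
    midpoint threshold for both parities, exactly reproducing an exhaustive
    search.  With both classes present the returned error is <= half the
    total weight (the worse parity is simply flipped).

    Raises
    ------
    ValueError
        If only one class is present (no threshold is meaningful).
    """
    v = np.asarray(feature_values, dtype=np.float64)
    y = np.asarray(labels)
    w = np.asarray(weights, dtype=np.float64)
    if v.ndim != 1 or v.shape != y.shape or v.shape != w.shape:
        raise ValueError("feature_values, labels, weights must be equal-length 1-D")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to train a stump")

    order = np.argsort(v, kind="stable")
    vs, ys, ws = v[order], y[order], w[order]
    total = ws.sum()
    s_pos = float(ws[ys == 1].sum())
    cpos = np.cumsum(ws * (ys == 1))
    cneg = np.cumsum(ws * (ys == 0))
    # err_plus[k]: error of (parity=+1, threshold between vs[k-1] and vs[k])
    # i.e. predict 1 for the first k sorted samples; k = 0..n.
    err_plus = np.concatenate(([s_pos], cneg + (s_pos - cpos)))
    valid = np.ones(len(err_plus), dtype=bool)
    valid[1:-1] = vs[1:] > vs[:-1]  # thresholds need a gap between values

    thresholds = np.concatenate((
        [vs[0] - 1.0], (vs[1:] + vs[:-1]) / 2.0, [vs[-1] + 1.0]))
    err_plus_masked = np.where(valid, err_plus, np.inf)
    err_minus_masked = np.where(valid, total - err_plus, np.inf)
    k_plus = int(np.argmin(err_plus_masked))
    k_minus = int(np.argmin(err_minus_masked))
    if err_plus_masked[k_plus] <= err_minus_masked[k_minus]:
        return float(thresholds[k_plus]), 1, float(err_plus_masked[k_plus])
    return float(thresholds[k_minus]), -1, float(err_minus_masked[k_minus])


def _best_stump_over_features(values: np.ndarray, sort_idx: np.ndarray,
                              labels: np.ndarray, weights: np.ndarray,
                              block: int = 512) -> tuple[int, float]:
    """Index and error of the lowest-weighted-error feature (vectorized)."""
    n = values.shape[1]
    total = float(weights.sum())
    best_err = np.inf
    best_fi = 0
    for lo in range(0, values.shape[0], block):
        idx = sort_idx[lo:lo + block]
        vs = np.take_along_axis(values[lo:lo + block], idx, axis=1)
        ws = weights[idx]
        ys = labels[idx]
        s_pos = (ws * (ys == 1)).sum(axis=1, keepdims=True)
        cpos = np.cumsum(ws * (ys == 1), axis=1)
        cneg = np.cumsum(ws * (ys == 0), axis=1)
        err_plus = np.concatenate(
            (s_pos, cneg + (s_pos - cpos)), axis=1)
        valid = np.ones_like(err_plus, dtype=bool)
        valid[:, 1:-1] = vs[:, 1:] > vs[:, :-1]
        err = np.minimum(np.where(valid, err_plus, np.inf),
                         np.where(valid, total - err_plus, np.inf))
        row_best = err.min(axis=1)
        fi = int(np.argmin(row_best))
        if row_best[fi] < best_err:
            best_err = float(row_best[fi])
            best_fi = lo + fi
    return best_fi, best_err


@dataclass
class StrongClassifier:
    """AdaBoost vote of decision stumps with an adjustable stage threshold.

    ``stage_threshold`` defaults to half the total vote (the natural
    operating point); cascade training recalibrates it.  ``history`` keeps
    the per-round weighted errors and post-normalization weight sums for
    auditing the training contract.
    """

    weak: list[WeakClassifier]
    alphas: list[float]
    stage_threshold: float
    window: int
    variance_normalize: bool = False
    history: dict = field(default_factory=dict)

    @property
    def default_threshold(self) -> float:
        return 0.5 * float(np.sum(self.alphas))

    def margins(self, samples: np.ndarray) -> np.ndarray:
        """Sum of alpha-weighted stump votes for a stack of windows."""
        values = feature_value_matrix(
            np.asarray(samples), [wc.feature for wc in self.weak],
            variance_normalize=self.variance_normalize)
        votes = np.zeros(values.shape[1])
        for alpha, wc, row in zip(self.alphas, self.weak, values):
            votes += alpha * wc.evaluate(row)
        return votes

    def classify(self, samples: np.ndarray) -> np.ndarray:
        return (self.margins(samples) >= self.stage_threshold).astype(np.uint8)


def initial_weights(labels: np.ndarray) -> np.ndarray:
    """AdaBoost initialization: 1/(2m) per negative, 1/(2l) per positive."""
    labels = np.asarray(labels)
    m = int((labels == 0).sum())
    l = int((labels == 1).sum())
    if m == 0 or l == 0:
        raise ValueError("need at least one positive and one negative sample")
    return np.where(labels == 1, 1.0 / (2 * l), 1.0 / (2 * m)).astype(np.float64)


def adaboost(samples: np.ndarray, labels: np.ndarray, T: int,
             feature_pool: list[HaarFeature],
             variance_normalize: bool = False,
             _value_matrix: np.ndarray | None = None) -> StrongClassifier:
    """Train a strong classifier of up to T boosted decision stumps.

    Rounds with zero weighted error stop training early (that stump alone
    separates the data; its vote is made large but finite by flooring the
    error at 1e-10).  A round whose best error reaches 0.5 aborts with
    diagnostics: the feature pool no longer contains any informative stump.
    """
    samples = np.asarray(samples)
    labels = np.asarray(labels)
    if T < 1:
        raise ValueError("T must be >= 1")
    values = (feature_value_matrix(samples, feature_pool, variance_normalize)
              if _value_matrix is None else _value_matrix)
    n = values.shape[1]
    if labels.shape != (n,):
        raise ValueError("labels must match the number of samples")
    sort_idx = np.argsort(values, axis=1, kind="stable")
    w = initial_weights(labels)

    weak: list[WeakClassifier] = []
    alphas: list[float] = []
    errors: list[float] = []
    weight_sums: list[float] = []
    for _t in range(T):
        w = w / w.sum()
        weight_sums.append(float(w.sum()))
        fi, _ = _best_stump_over_features(values, sort_idx, labels, w)
        theta, parity, err = train_stump(values[fi], labels, w)
        if err >= 0.5:
            raise RuntimeError(
                f"boosting round {_t}: best stump error {err:.4f} >= 0.5 "
                f"(pool of {len(feature_pool)} features, {n} samples); "
                "the remaining weight distribution is unlearnable")
        stump = WeakClassifier(feature_pool[fi], theta, parity)
        predictions = stump.evaluate(values[fi])
        correct = predictions == labels
        separated = err <= 0.0
        err = max(err, _MIN_ERROR)
        beta = err / (1.0 - err)
        weak.append(stump)
        alphas.append(float(np.log(1.0 / beta)))
        errors.append(float(err))
        if separated:
            break
        w = w * np.where(correct, beta, 1.0)

    clf = StrongClassifier(
        weak=weak, alphas=alphas, stage_threshold=0.0, window=samples.shape[-1],
        variance_normalize=variance_normalize,
        history={"errors": errors, "weight_sums": weight_sums})
    clf.stage_threshold = clf.default_threshold
    return clf
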