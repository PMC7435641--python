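"""Row panorama construction: keypoints, matching, RANSAC homography, warping.

Consecutive frames along an orchard row overlap; chaining pairwise
homographies composites them into one non-repetitive panorama so each fruit
is counted once.  Keypoints are Hessian-determinant blobs (integral-image
box-filter approximation) described by a 64-component SURF-style vector:
4x4 spatial subregions, each contributing the sums and absolute sums of
oriented gradient samples, L2-normalized for illumination invariance and
measured in a frame rotated to the keypoint's dominant gradient direction
for rotation invariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist
from skimage.feature import hessian_matrix_det, peak_local_max
from skimage.filters import gaussian
from skimage.measure import ransac as sk_ransac
from skimage.transform import ProjectiveTransform, warp

from kiwicount.imgio import to_grayscale

DESCRIPTOR_LENGTH = 64
_SIGMAS = (2.0, 3.2, 5.0, 8.0)


class EstimationError(RuntimeError):
    """Homography estimation failed (too few matches or inliers)."""


class CompositeSizeError(RuntimeError):
    """The warped canvas would exceed the configured size cap."""


@dataclass
class Keypoint:
    """Blob keypoint with subpixel-free position, scale, orientation and a
    64-component descriptor."""

    x: float
    y: float
    scale: float
    orientation: float
    descriptor: np.ndarray
    response: float = 0.0


@dataclass(frozen=True)
class MatchPair:
    index_a: int
    index_b: int
    distance: float

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValueError("distance must be >= 0")


def detect_and_describe(image: np.ndarray,
                        max_keypoints: int = 500) -> list[Keypoint]:
    """Detect blob keypoints and compute their descriptors.

    A uniform (textureless) image yields an empty list.  The strongest
    ``max_keypoints`` responses across the scale stack are kept.
    """
    image = np.asarray(image)
    gray = (to_grayscale(image) if image.ndim == 3 else
            image.astype(np.float64))
    gray = gray / 255.0
    h, w = gray.shape
    candidates: list[tuple[float, float, float, float]] = []  # response,x,y,s
    for sigma in _SIGMAS:
        if 10 * sigma >= min(h, w):
            break
        resp = hessian_matrix_det(gray, sigma=sigma, approximate=True)
        peaks = peak_local_max(resp, min_distance=max(2, int(sigma)),
                               threshold_abs=1e-4, exclude_border=True)
        for py, px in peaks:
            candidates.append((float(resp[py, px]), float(px), float(py),
                               sigma))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    candidates = candidates[: 2 * max_keypoints]

    grad_cache: dict[float, tuple[np.ndarray, np.ndarray]] = {}

    def grads(sigma: float):
        if sigma not in grad_cache:
            sm = gaussian(gray, sigma=sigma, preserve_range=True)
            gy, gx = np.gradient(sm)
            grad_cache[sigma] = (gx, gy)
        return grad_cache[sigma]

    keypoints: list[Keypoint] = []
    for response, px, py, sigma in candidates:
        if len(keypoints) >= max_keypoints:
            break
        kp = _describe(px, py, sigma, response, *grads(sigma), h, w)
        if kp is not None:
            keypoints.append(kp)
    return keypoints


def _describe(px, py, sigma, response, gx, gy, h, w) -> Keypoint | None:
    # Dominant orientation from Gaussian-weighted gradient vector sum.
    rad = 4.0 * sigma
    if px - rad - 1 < 0 or py - rad - 1 < 0 or px + rad + 1 >= w \
            or py + rad + 1 >= h:
        pass  # orientation window may clip; descriptor grid decides below
    x0, x1 = int(max(0, px - rad)), int(min(w, px + rad + 1))
    y0, y1 = int(max(0, py - rad)), int(min(h, py + rad + 1))
    sub_gx, sub_gy = gx[y0:y1, x0:x1], gy[y0:y1, x0:x1]
    yy, xx = np.mgrid[y0:y1, x0:x1]
    weight = np.exp(-((xx - px) ** 2 + (yy - py) ** 2) / (2 * (2.5 * sigma) ** 2))
    sx, sy = float((weight * sub_gx).sum()), float((weight * sub_gy).sum())
    orientation = float(np.arctan2(sy, sx))

    # 4x4 subregions x 5x5 samples, spacing sigma, rotated by orientation.
    u = (np.arange(20) - 9.5) * sigma
    uu, vv = np.meshgrid(u, u)
    cos_o, sin_o = np.cos(orientation), np.sin(orientation)
    sample_x = px + cos_o * uu - sin_o * vv
    sample_y = py + sin_o * uu + cos_o * vv
    if (sample_x.min() < 0 or sample_y.min() < 0 or sample_x.max() > w - 1
            or sample_y.max() > h - 1):
        return None
    coords = np.stack([sample_y.ravel(), sample_x.ravel()])
    s_gx = ndimage.map_coordinates(gx, coords, order=1).reshape(20, 20)
    s_gy = ndimage.map_coordinates(gy, coords, order=1).reshape(20, 20)
    du = cos_o * s_gx + sin_o * s_gy
    dv = -sin_o * s_gx + cos_o * s_gy
    gweight = np.exp(-(uu ** 2 + vv ** 2) / (2 * (6.6 * sigma) ** 2))
    du, dv = du * gweight, dv * gweight

    desc = np.empty(DESCRIPTOR_LENGTH)
    k = 0
    for by in range(4):
        for bx in range(4):
            bu = du[5 * by:5 * by + 5, 5 * bx:5 * bx + 5]
            bv = dv[5 * by:5 * by + 5, 5 * bx:5 * bx + 5]
            desc[k:k + 4] = (bu.sum(), bv.sum(),
                             np.abs(bu).sum(), np.abs(bv).sum())
            k += 4
    norm = np.linalg.norm(desc)
    if norm < 1e-12:
        return None
    return Keypoint(x=px, y=py, scale=sigma, orientation=orientation,
                    descriptor=desc / norm, response=response)


def match(desc_a: np.ndarray, desc_b: np.ndarray,
          ratio: float = 0.75) -> list[MatchPair]:
    """Mutual-nearest-neighbor matches under the Euclidean distance.

    Lowe's ratio test (applied on both sides) discards ambiguous matches;
    it is skipped when a side offers no second neighbor.  Pairs are sorted
    by ascending distance.  Symmetric: swapping the inputs swaps indices.
    """
    A = np.asarray(desc_a, dtype=np.float64)
    B = np.asarray(desc_b, dtype=np.float64)
    if A.size == 0 or B.size == 0:
        return []
    if A.ndim != 2 or B.ndim != 2 or A.shape[1] != B.shape[1]:
        raise ValueError("descriptor arrays must be 2-D with equal width")
    D = cdist(A, B)
    nn_ab = np.argmin(D, axis=1)
    nn_ba = np.argmin(D, axis=0)
    pairs = []
    for i, j in enumerate(nn_ab):
        if nn_ba[j] != i:
            continue
        d1 = D[i, j]
        ok = True
        if D.shape[1] > 1:
            second = np.partition(D[i], 1)[1]
            ok = ok and d1 <= ratio * second
        if D.shape[0] > 1:
            second = np.partition(D[:, j], 1)[1]
            ok = ok and d1 <= ratio * second
        if ok:
            pairs.append(MatchPair(int(i), int(j), float(d1)))
    pairs.sort(key=lambda p: (p.distance, p.index_a))
    return pairs


def estimate_homography(
    matches: list[MatchPair],
    points_a: np.ndarray,
    points_b: np.ndarray,
    seed: int = 0,
    threshold: float = 3.0,
    max_trials: int = 2000,
) -> tuple[np.ndarray, np.ndarray]:
    """RANSAC projective fit mapping frame-b points onto frame-a points.

    The consensus model is refit on all inliers by normalized DLT.  Returns
    the 3x3 matrix (normalized so H[2,2] == 1) and the boolean inlier mask
    over ``matches``.

    Raises
    ------
    EstimationError
        With fewer than 4 matches, or when no model gathers 4 inliers.
    """
    if len(matches) < 4:
        raise EstimationError(f"need >= 4 matches, got {len(matches)}")
    src = np.asarray(points_b, dtype=float)[[m.index_b for m in matches]]
    dst = np.asarray(points_a, dtype=float)[[m.index_a for m in matches]]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model, inliers = sk_ransac(
            (src, dst), ProjectiveTransform, min_samples=4,
            residual_threshold=threshold, max_trials=max_trials,
            stop_probability=0.99, rng=seed)
    if model is None or inliers is None or inliers.sum() < 4:
        raise EstimationError("no homography supported by >= 4 inliers")
    refined = ProjectiveTransform.from_estimate(src[inliers], dst[inliers])
    if not refined:
        raise EstimationError("inlier refit is degenerate")
    H = refined.params.copy()
    if abs(H[2, 2]) > 1e-12:
        H = H / H[2, 2]
    if not np.all(np.isfinite(H)) or abs(np.linalg.det(H)) < 1e-12:
        raise EstimationError("estimated homography is singular")
    return H, np.asarray(inliers, dtype=bool)


@dataclass
class CompositeResult:
    """Panorama canvas plus the record mapping canvas to frame-a coords."""

    image: np.ndarray
    a_origin: tuple[int, int]  # frame-a (0,0) in canvas pixel coords
    homography: np.ndarray     # frame-b -> frame-a


def warp_and_composite(image_a: np.ndarray, image_b: np.ndarray,
                       H: np.ndarray,
                       canvas_cap: int = 8000) -> CompositeResult:
    """Warp frame b through H onto a canvas covering both frames.

    Overlap resolves first-image-wins: frame a's pixels are authoritative
    wherever its footprint lies (blending would perturb detector scores).
    """
    H = np.asarray(H, dtype=float)
    ha, wa = image_a.shape[:2]
    hb, wb = image_b.shape[:2]
    corners_b = np.array([[0, 0, 1], [wb, 0, 1], [0, hb, 1], [wb, hb, 1]],
                         dtype=float)
    mapped = corners_b @ H.T
    if np.any(np.abs(mapped[:, 2]) < 1e-9):
        raise CompositeSizeError("homography sends frame corners to infinity")
    mapped = mapped[:, :2] / mapped[:, 2:3]
    xs = np.concatenate([mapped[:, 0], [0, wa]])
    ys = np.concatenate([mapped[:, 1], [0, ha]])
    x_min, y_min = int(np.floor(xs.min())), int(np.floor(ys.min()))
    x_max, y_max = int(np.ceil(xs.max())), int(np.ceil(ys.max()))
    cw, ch = x_max - x_min, y_max - y_min
    if cw > canvas_cap or ch > canvas_cap:
        raise CompositeSizeError(
            f"canvas {cw}x{ch} exceeds the {canvas_cap} px cap")

    offset = np.array([[1, 0, x_min], [0, 1, y_min], [0, 0, 1]], dtype=float)
    canvas_to_b = np.linalg.inv(H) @ offset
    tform = ProjectiveTransform(matrix=canvas_to_b)
    warped = warp(image_b.astype(float), tform, output_shape=(ch, cw),
                  order=1, preserve_range=True, cval=0.0)
    canvas = np.clip(np.round(warped), 0, 255).astype(np.uint8)
    ax, ay = -x_min, -y_min
    canvas[ay:ay + ha, ax:ax + wa] = image_a
    return CompositeResult(image=canvas, a_origin=(ax, ay), homography=H)


@dataclass
class StitchResult:
    """One panorama plus its per-pair estimation records."""

    image: np.ndarray
    pair_records: list[dict] = field(default_factory=list)


def stitch_sequence(
    images: list[np.ndarray],
    seed: int = 0,
    max_keypoints: int = 500,
    ratio: float = 0.75,
    ransac_threshold: float = 3.0,
    max_trials: int = 2000,
    min_inliers: int = 8,
    canvas_cap: int = 8000,
) -> tuple[list[StitchResult], list[str]]:
    """Chain frames left-to-right into panoramas.

    On a pairwise failure (too few confident matches or inliers, or a
    runaway canvas) the sequence splits: the current panorama is closed and
    a fresh one starts at the failing frame, so one bad frame never aborts
    counting for a whole row.  Returns the panoramas and any warnings.
    """
    if len(images) == 0:
        raise ValueError("stitch_sequence needs at least one image")
    panoramas: list[StitchResult] = []
    notes: list[str] = []
    current = StitchResult(image=np.asarray(images[0]))
    for idx, nxt in enumerate(images[1:], start=1):
        nxt = np.asarray(nxt)
        try:
            kp_a = detect_and_describe(current.image, max_keypoints)
            kp_b = detect_and_describe(nxt, max_keypoints)
            if len(kp_a) < 4 or len(kp_b) < 4:
                raise EstimationError("too few keypoints")
            desc_a = np.array([k.descriptor for k in kp_a])
            desc_b = np.array([k.descriptor for k in kp_b])
            pairs = match(desc_a, desc_b, ratio)
            pts_a = np.array([[k.x, k.y] for k in kp_a])
            pts_b = np.array([[k.x, k.y] for k in kp_b])
            H, inliers = estimate_homography(
                pairs, pts_a, pts_b, seed=seed, threshold=ransac_threshold,
                max_trials=max_trials)
            if int(inliers.sum()) < min_inliers:
                raise EstimationError(
                    f"only {int(inliers.sum())} inliers (< {min_inliers})")
            composite = warp_and_composite(current.image, nxt, H, canvas_cap)
            current.pair_records.append({
                "frame": idx,
                "homography": H.tolist(),
                "n_matches": len(pairs),
                "n_inliers": int(inliers.sum()),
                "a_origin": list(composite.a_origin),
            })
            current = StitchResult(image=composite.image,
                                   pair_records=current.pair_records)
        except (EstimationError, CompositeSizeError) as exc:
            notes.append(f"frame {idx}: {exc}; starting a new panorama")
            panoramas.append(current)
            current = StitchResult(image=nxt)
    panoramas.append(current)
    for note in notes:
        warnings.warn(note, UserWarning)
    return panoramas, notes
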