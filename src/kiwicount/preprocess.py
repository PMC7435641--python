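"""Five-stage canopy background suppression.

The chain mirrors how green foliage is removed before fruit detection:
(1) RGB -> CIE LAB, (2) Otsu thresholding of the 8-bit A (green-red)
channel, (3) 25x25 majority (median) filtering of the binary mask,
(4) morphological dilation by a disc so the mask accommodates whole fruits,
(5) applying the mask to the source image, zeroing the background.

Fruits sit on the positive (red) side of the A axis and leaves on the
negative (green) side, so foreground is "A8 strictly greater than the Otsu
threshold".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from kiwicount.imgio import rgb_to_lab


class DegenerateChannelError(ValueError):
    """The channel has a single distinct value; no threshold separates it."""


def otsu_threshold(channel: np.ndarray) -> int:
    """Otsu's threshold of an 8-bit channel over its 256-bin histogram.

    Returns the integer t in [0, 255] maximizing the between-class variance
    of the split {values <= t} / {values > t}; ties resolve to the lowest
    maximizing t.  Foreground is defined by the caller as ``channel > t``.

    Raises
    ------
    DegenerateChannelError
        If the channel is constant (callers map this to "all background").
    """
    channel = np.asarray(channel)
    if channel.dtype != np.uint8:
        raise ValueError("otsu_threshold expects a uint8 channel")
    hist = np.bincount(channel.ravel(), minlength=256).astype(np.float64)
    if np.count_nonzero(hist) < 2:
        raise DegenerateChannelError("channel is constant; Otsu is undefined")
    p = hist / hist.sum()
    omega = np.cumsum(p)                      # class-0 mass for t = 0..255
    mu = np.cumsum(p * np.arange(256))        # class-0 first moment
    mu_total = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_total * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[~np.isfinite(sigma_b)] = -1.0
    return int(np.argmax(sigma_b))


def median_filter(mask: np.ndarray, window: int = 25) -> np.ndarray:
    """Majority filter of a binary mask over an odd square window.

    Each output pixel is the majority value of its window; borders reflect.
    Implemented as an exact integral-image count (625 samples at the default
    window cannot tie), which matches a rank-order median filter.
    """
    mask = _validate_mask(mask)
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    pad = window // 2
    padded = np.pad(mask.astype(np.int64), pad, mode="reflect")
    ii = np.zeros((padded.shape[0] + 1, padded.shape[1] + 1), dtype=np.int64)
    np.cumsum(np.cumsum(padded, axis=0), axis=1, out=ii[1:, 1:])
    h, w = mask.shape
    counts = (
        ii[window:window + h, window:window + w]
        - ii[:h, window:window + w]
        - ii[window:window + h, :w]
        + ii[:h, :w]
    )
    return counts * 2 > window * window


def dilate(mask: np.ndarray, radius: int) -> np.ndarray:
    """Binary dilation by a disc structuring element of the given radius."""
    mask = _validate_mask(mask)
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if radius == 0:
        return mask.copy()
    yy, xx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    selem = (xx * xx + yy * yy) <= radius * radius
    return ndimage.binary_dilation(mask, structure=selem)


@dataclass
class SuppressionResult:
    """Masked image, final mask, and each inspectable intermediate stage."""

    image: np.ndarray          # source with background zeroed
    mask: np.ndarray           # final boolean foreground mask
    threshold: int | None      # Otsu threshold on A8 (None if degenerate)
    stages: dict = field(default_factory=dict)
    warning: str | None = None


def suppress_background(
    image: np.ndarray,
    median_window: int = 25,
    dilation_radius: int = 12,
    keep_stages: bool = False,
) -> SuppressionResult:
    """Run the full five-stage background-suppression chain.

    A constant A channel (e.g. a pure-green frame) degenerates Otsu; the
    result is then an empty mask plus a warning rather than an error.
    """
    lab = rgb_to_lab(image)
    a8 = lab.a8
    stages: dict = {}
    if keep_stages:
        stages["a8"] = a8
    try:
        threshold = otsu_threshold(a8)
    except DegenerateChannelError:
        mask = np.zeros(a8.shape, dtype=bool)
        return SuppressionResult(
            image=np.zeros_like(image), mask=mask, threshold=None,
            stages=stages,
            warning="constant A channel; treating the whole frame as background",
        )
    raw_mask = a8 > threshold
    filtered = median_filter(raw_mask, median_window)
    dilated = dilate(filtered, dilation_radius)
    if keep_stages:
        stages["otsu_mask"] = raw_mask
        stages["median_mask"] = filtered
        stages["dilated_mask"] = dilated
    masked = np.where(dilated[..., None], image, 0).astype(np.uint8)
    return SuppressionResult(image=masked, mask=dilated, threshold=threshold,
                             stages=stages)


def _validate_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2 or mask.dtype != bool:
        raise ValueError("mask must be a 2-D boolean array")
    return mask
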