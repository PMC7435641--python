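"""Image I/O and the RGB -> CIE LAB conversion the preprocessing relies on.

Rasters are plain ``numpy`` arrays: H x W x 3, ``uint8``, RGB channel order,
origin at the top-left corner, x rightward, y downward, 0-based indices.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError
from skimage.color import rgb2lab


@dataclass(frozen=True)
class LabImage:
    """CIE L*a*b* decomposition of an RGB raster (sRGB primaries, D65 white).

    ``L`` is lightness in [0, 100]; ``A`` is the green-red opponent channel
    (foliage negative, kiwifruit skin positive); ``B`` is blue-yellow.
    ``a8`` exposes the A channel rescaled to 8 bits (A + 128, clamped), the
    representation Otsu's 256-bin histogram thresholding operates on.
    """

    L: np.ndarray
    A: np.ndarray
    B: np.ndarray

    @property
    def a8(self) -> np.ndarray:
        return np.clip(np.round(self.A + 128.0), 0, 255).astype(np.uint8)


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG or JPEG file as an H x W x 3 uint8 RGB raster.

    Grayscale inputs are promoted to three identical channels; an alpha
    channel, if present, is dropped.

    Raises
    ------
    IOError
        If the file is absent, truncated, or not a decodable image; the
        message names the offending path.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            arr = np.asarray(im.convert("RGB"))
    except (FileNotFoundError, UnidentifiedImageError, OSError) as exc:
        raise IOError(f"cannot read image {path}: {exc}") from exc
    return np.ascontiguousarray(arr, dtype=np.uint8)


def write_image(image: np.ndarray, path: str | Path) -> None:
    """Write an RGB raster as PNG (lossless) or JPEG, chosen by suffix."""
    image = _validate_raster(image)
    Image.fromarray(image).save(Path(path))


def rgb_to_lab(image: np.ndarray) -> LabImage:
    """Convert an 8-bit RGB raster to CIE L*a*b*.

    Pixelwise (no spatial coupling): the standard sRGB -> linear RGB ->
    XYZ (D65) -> L*a*b* chain.
    """
    image = _validate_raster(image)
    lab = rgb2lab(image)
    return LabImage(L=lab[..., 0], A=lab[..., 1], B=lab[..., 2])


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Luma (ITU-R 601) grayscale as float64 in [0, 255]."""
    image = _validate_raster(image)
    return image @ np.array([0.299, 0.587, 0.114])


def _validate_raster(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 RGB raster, got shape {image.shape}")
    if image.shape[0] < 1 or image.shape[1] < 1:
        raise ValueError("raster must have positive height and width")
    if image.dtype != np.uint8:
        raise ValueError(f"expected uint8 raster, got dtype {image.dtype}")
    return image
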