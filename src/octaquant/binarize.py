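"""Otsu histogram thresholding and vessel binarization.

Vessel density analysis requires a black/white image in which white pixels
are vessels. The threshold is chosen by Otsu's method on the 256-bin
intensity histogram of the 8-bit angiogram: the cut ``t`` (background ≤ t,
vessels > t) that maximizes the between-class variance

    sigma_B^2(t) = w0(t) * w1(t) * (mu0(t) - mu1(t))^2

where ``w`` are the class probabilities and ``mu`` the class mean
intensities. Ties are broken toward the smallest threshold (reference
implementations differ here; the choice is documented for determinism).
The histogram is used as-is — no smoothing or pre-filtering.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .image_io import Angiogram

__all__ = [
    "DegenerateHistogramError",
    "VesselMask",
    "histogram256",
    "otsu_threshold",
    "binarize",
    "write_mask_tiff",
]


class DegenerateHistogramError(ValueError):
    """Histogram has fewer than two occupied intensity levels."""


@dataclass(frozen=True)
class VesselMask:
    """Binary vessel raster plus the threshold that produced it.

    ``mask[p]`` is true exactly when the source intensity at ``p`` exceeds
    ``threshold``.
    """

    mask: np.ndarray
    threshold: int
    source_shape: tuple[int, int]

    @property
    def vessel_count(self) -> int:
        return int(np.count_nonzero(self.mask))


def histogram256(pixels: np.ndarray) -> np.ndarray:
    """256-bin intensity histogram of an 8-bit raster."""
    pixels = np.asarray(pixels)
    if pixels.dtype != np.uint8:
        raise ValueError(f"expected uint8 raster, got {pixels.dtype}")
    return np.bincount(pixels.ravel(), minlength=256)


def otsu_threshold(hist: np.ndarray) -> int:
    """Threshold in [0, 254] maximizing between-class variance.

    Classes are intensities ``<= t`` versus ``> t``; among thresholds with
    equal between-class variance the smallest is returned.

    Raises
    ------
    DegenerateHistogramError
        If fewer than two intensity levels are occupied.
    """
    hist = np.asarray(hist, dtype=np.float64)
    if hist.shape != (256,):
        raise ValueError(f"expected a 256-bin histogram, got shape {hist.shape}")
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError(
            "histogram has a single occupied intensity level; no threshold separates it"
        )
    total = hist.sum()
    levels = np.arange(256, dtype=np.float64)
    # cumulative class probability and cumulative mean for class 0 (<= t)
    w0 = np.cumsum(hist)[:-1] / total
    cum_mean = np.cumsum(hist * levels)[:-1] / total
    grand_mean = (hist * levels).sum() / total
    w1 = 1.0 - w0
    valid = (w0 > 0) & (w1 > 0)
    sigma_b = np.zeros(255)
    sigma_b[valid] = (grand_mean * w0[valid] - cum_mean[valid]) ** 2 / (
        w0[valid] * w1[valid]
    )
    return int(np.argmax(sigma_b))  # argmax returns the first (smallest) maximizer


def binarize(image: Angiogram | np.ndarray, invert: bool = False) -> VesselMask:
    """Binarize an angiogram: white (true) = vessel.

    Vessels are assumed brighter than background; ``invert=True`` handles
    atypical exports with dark vessels by working on the inverted
    intensities, so that inverting an image and setting the flag reproduces
    the original mask exactly.
    """
    pixels = image.pixels if isinstance(image, Angiogram) else np.asarray(image)
    if invert:
        pixels = (255 - pixels.astype(np.int16)).astype(np.uint8)
    t = otsu_threshold(histogram256(pixels))
    return VesselMask(mask=pixels > t, threshold=t, source_shape=pixels.shape)


def write_mask_tiff(mask: VesselMask | np.ndarray, path: str | Path) -> Path:
    """Persist a binary mask as an 8-bit 0/255 TIFF."""
    arr = mask.mask if isinstance(mask, VesselMask) else np.asarray(mask)
    path = Path(path)
    tifffile.imwrite(path, (arr.astype(np.uint8) * 255))
    return path
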