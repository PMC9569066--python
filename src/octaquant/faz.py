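"""Foveal avascular zone (FAZ) delimitation and shape metrics.

The FAZ is the capillary-free region at the center of the fovea. It is
delimited on the raw grayscale macular crop (not on the binarized image) by
a region-based level-set evolution: starting from a small disc at the seed
(the frame center by default, since the scan is centered on the fovea), the
region grows into neighboring pixels whose intensity differs from the
evolving region's mean by less than a propagation tolerance, with periodic
morphological curvature regularization (a closing/opening pass that smooths
the boundary and removes thin protrusions). Evolution stops when the pixel
set no longer changes, or when ``max_iterations`` is reached. The bright
perifoveal capillary ring halts the growth; on an image without such a
boundary the region reaches the frame border, which is reported as a
segmentation failure.

Metrics follow the standard planimetric definitions: area is the pixel count
times the squared pixel pitch; the perimeter is the length of the sub-pixel
iso-contour polygon of the (lightly smoothed) mask, which avoids the large
systematic overestimate of staircase pixel-edge perimeters; circularity is

    circularity = 4 * pi * area / perimeter**2

equal to 1 for a perfect circle and decreasing toward 0 with boundary
irregularity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import tifffile
from scipy import ndimage
from skimage import measure

from .geometry import ScaleSpec
from .image_io import Angiogram

__all__ = [
    "ContourParams",
    "FazRegion",
    "FazResult",
    "SegmentationFailureError",
    "segment_faz",
    "faz_metrics",
    "circularity",
    "segment_and_measure",
    "write_faz_overlay",
    "write_faz_mask",
]


class SegmentationFailureError(RuntimeError):
    """The evolving region reached the frame border (no closed boundary)."""


@dataclass(frozen=True)
class ContourParams:
    """Tunables of the region-based level-set evolution.

    propagation_tolerance:
        Maximum absolute difference (8-bit intensity units) between a
        candidate pixel and the evolving region mean for the region to
        propagate into it. Default 60 admits the noisy dark FAZ interior
        while rejecting bright capillary signal.
    curvature_weight:
        Radius (px) of the disc used for the morphological closing/opening
        smoothing pass; 0 disables regularization.
    smooth_interval:
        Apply the smoothing pass every this many iterations.
    max_iterations:
        Evolution cap; the region grows by at most one pixel ring per
        iteration.
    seed_radius:
        Radius (px) of the initial disc around the seed.
    """

    propagation_tolerance: float = 60.0
    curvature_weight: int = 1
    smooth_interval: int = 5
    max_iterations: int = 500
    seed_radius: int = 4


@dataclass(frozen=True)
class FazRegion:
    """Segmented FAZ: a single connected pixel set containing the seed."""

    mask: np.ndarray
    seed: tuple[int, int]
    iterations_run: int
    converged: bool


@dataclass(frozen=True)
class FazResult:
    """FAZ morphometry in physical units."""

    area_mm2: float
    perimeter_mm: float
    circularity: float


_N8 = np.ones((3, 3), dtype=bool)


def _disc(radius: int) -> np.ndarray:
    if radius <= 0:
        return np.ones((1, 1), dtype=bool)
    r = int(radius)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy * yy + xx * xx) <= r * r


def _seed_component(mask: np.ndarray, seed: tuple[int, int]) -> np.ndarray:
    labels, _ = ndimage.label(mask, structure=_N8)
    lab = labels[seed]
    if lab == 0:
        return np.zeros_like(mask)
    return labels == lab


def segment_faz(
    image: Angiogram | np.ndarray,
    params: ContourParams = ContourParams(),
    seed: tuple[int, int] | None = None,
) -> FazRegion:
    """Evolve a region-based contour from the seed and return the FAZ region.

    Raises
    ------
    SegmentationFailureError
        If the region reaches the frame border (the image offers no closed
        intensity boundary around the seed, e.g. a constant image).
    """
    pixels = image.pixels if isinstance(image, Angiogram) else np.asarray(image)
    img = pixels.astype(np.float64)
    n_rows, n_cols = img.shape
    if seed is None:
        seed = (n_rows // 2, n_cols // 2)
    seed = (int(seed[0]), int(seed[1]))

    region = np.zeros(img.shape, dtype=bool)
    r0 = max(1, params.seed_radius)
    yy, xx = np.mgrid[0:n_rows, 0:n_cols]
    region[(yy - seed[0]) ** 2 + (xx - seed[1]) ** 2 <= r0 * r0] = True

    smooth_se = _disc(params.curvature_weight)
    converged = False
    iterations = 0
    for iterations in range(1, params.max_iterations + 1):
        prev = region
        # work on a window around the current region for efficiency
        rows = np.flatnonzero(prev.any(axis=1))
        cols = np.flatnonzero(prev.any(axis=0))
        pad = 2 + params.curvature_weight
        r1, r2 = max(rows[0] - pad, 0), min(rows[-1] + pad + 1, n_rows)
        c1, c2 = max(cols[0] - pad, 0), min(cols[-1] + pad + 1, n_cols)
        win = np.s_[r1:r2, c1:c2]

        sub = prev[win]
        sub_img = img[win]
        mean = sub_img[sub].mean()
        cand = ndimage.binary_dilation(sub, structure=_N8) & ~sub
        accept = cand & (np.abs(sub_img - mean) < params.propagation_tolerance)

        new_sub = sub | accept
        if params.curvature_weight > 0 and iterations % params.smooth_interval == 0:
            new_sub = ndimage.binary_opening(
                ndimage.binary_closing(new_sub, structure=smooth_se),
                structure=smooth_se,
            )
            new_sub[seed[0] - r1, seed[1] - c1] = True

        # the region lives entirely inside the window, so the connected
        # component containing the seed can be extracted there
        new_sub = _seed_component(new_sub, (seed[0] - r1, seed[1] - c1))
        region = np.zeros_like(prev)
        region[win] = new_sub

        if (
            region[0, :].any()
            or region[-1, :].any()
            or region[:, 0].any()
            or region[:, -1].any()
        ):
            raise SegmentationFailureError(
                "region reached the frame border: no closed boundary around the seed"
            )
        if np.array_equal(region, prev):
            converged = True
            break

    region = ndimage.binary_fill_holes(region)
    return FazRegion(mask=region, seed=seed, iterations_run=iterations, converged=converged)


_CONTOUR_SIGMA = 2.0  # light smoothing before iso-contouring, px


def mask_perimeter_px(mask: np.ndarray, sigma: float = _CONTOUR_SIGMA) -> float:
    """Sub-pixel perimeter (in px) of a binary mask.

    The mask is smoothed with a small Gaussian and the 0.5 iso-contour
    extracted as a polygon; its length is returned. On a rasterized disc
    this is within a fraction of a percent of the true circumference,
    whereas counting pixel edges overestimates by up to ~27%.
    """
    mask = np.asarray(mask, dtype=float)
    pad = int(4 * sigma) + 2
    padded = np.pad(mask, pad)
    smoothed = ndimage.gaussian_filter(padded, sigma)
    contours = measure.find_contours(smoothed, 0.5)
    if not contours:
        raise ValueError("mask has no 0.5 iso-contour (empty or degenerate region)")
    contour = max(contours, key=len)
    diffs = np.diff(contour, axis=0)
    return float(np.hypot(diffs[:, 0], diffs[:, 1]).sum())


def circularity(area: float, perimeter: float) -> float:
    """Shape circularity ``4*pi*area/perimeter**2`` (perfect circle = 1)."""
    if perimeter <= 0:
        raise ValueError("perimeter must be positive")
    return 4.0 * math.pi * area / (perimeter * perimeter)


def faz_metrics(region: FazRegion | np.ndarray, scale: ScaleSpec) -> FazResult:
    """Area (mm²), perimeter (mm) and circularity of a segmented FAZ."""
    mask = region.mask if isinstance(region, FazRegion) else np.asarray(region, bool)
    count = int(np.count_nonzero(mask))
    if count == 0:
        raise ValueError("empty FAZ region")
    s = scale.mm_per_px
    area = count * s * s
    perimeter = mask_perimeter_px(mask) * s
    return FazResult(
        area_mm2=area, perimeter_mm=perimeter, circularity=circularity(area, perimeter)
    )


def segment_and_measure(
    image: Angiogram,
    params: ContourParams = ContourParams(),
    scale: ScaleSpec | None = None,
    seed: tuple[int, int] | None = None,
) -> tuple[FazRegion, FazResult]:
    """Segment the FAZ of a macular angiogram and measure it."""
    if scale is None:
        scale = ScaleSpec(fov_deg=image.fov_deg, frame_px=image.frame_px,
                          mm_per_deg=image.mm_per_px * image.frame_px / image.fov_deg)
    region = segment_faz(image, params=params, seed=seed)
    return region, faz_metrics(region, scale)


def write_faz_overlay(image: Angiogram, region: FazRegion, path) -> None:
    """Burn the FAZ contour (white, 1 px ring) onto the input and save as TIFF."""
    boundary = region.mask & ~ndimage.binary_erosion(region.mask, structure=_N8)
    out = image.pixels.copy()
    out[ndimage.binary_dilation(boundary)] = 255
    tifffile.imwrite(path, out)


def write_faz_mask(image: Angiogram, region: FazRegion, path) -> None:
    """Save the input with everything beyond the FAZ removed (set to 0)."""
    out = np.where(region.mask, image.pixels, 0).astype(np.uint8)
    tifffile.imwrite(path, out)
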