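"""Vessel density: percentage of vessel pixels per region and per sector."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .binarize import VesselMask, binarize
from .geometry import RegionKind, SectorSet, map_laterality
from .image_io import Angiogram, Eye

__all__ = ["DensityReport", "vessel_density", "density_report"]


@dataclass(frozen=True)
class DensityReport:
    """Vessel density of one angiogram, globally and per anatomical sector.

    ``global_pct`` is computed over the union of the sectors: the full
    cropped frame for macular quadrants, the 360° annulus for the
    peripapillary ring (pixels outside the annulus, including the inner disc
    area, are excluded).
    """

    global_pct: float
    per_sector: Mapping[str, float]
    eye: Eye
    region_kind: RegionKind
    threshold_used: int


def vessel_density(mask: VesselMask | np.ndarray, region: np.ndarray) -> float:
    """Percentage of region pixels that are vessel (white).

    ``region`` is a boolean raster of the same shape as the mask.
    """
    arr = mask.mask if isinstance(mask, VesselMask) else np.asarray(mask)
    region = np.asarray(region, dtype=bool)
    if region.shape != arr.shape:
        raise ValueError(f"region shape {region.shape} != mask shape {arr.shape}")
    total = int(np.count_nonzero(region))
    if total == 0:
        raise ValueError("empty analysis region")
    white = int(np.count_nonzero(arr & region))
    return 100.0 * white / total


def density_report(
    image: Angiogram, sectors: SectorSet, invert: bool = False
) -> DensityReport:
    """Binarize once and report global plus per-sector vessel density.

    Macular quadrant sectors carry positional names (top/bottom/...) and are
    renamed anatomically here using the image's laterality; ring sectors are
    already anatomical.
    """
    if sectors.labels.shape != image.pixels.shape:
        raise ValueError(
            f"sector raster {sectors.labels.shape} does not match image "
            f"{image.pixels.shape}"
        )
    vmask = binarize(image, invert=invert)
    per_sector: dict[str, float] = {}
    for sector_id, name in sectors.names.items():
        if sectors.region_kind is RegionKind.MACULAR_QUADRANTS:
            name = map_laterality(name, image.eye)
        per_sector[name] = vessel_density(vmask, sectors.labels == sector_id)
    global_pct = vessel_density(vmask, sectors.union_mask())
    return DensityReport(
        global_pct=global_pct,
        per_sector=per_sector,
        eye=image.eye,
        region_kind=sectors.region_kind,
        threshold_used=vmask.threshold,
    )
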