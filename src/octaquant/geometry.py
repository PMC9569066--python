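"""Sector partitions and physical-scale conversions.

Two sectorizations are used:

* **Macular quadrants** — the square frame is cut by its two diagonals into
  four triangular sectors (top, bottom, left, right). Left/right become
  temporal/nasal according to eye laterality.
* **Peripapillary ring** — an annulus (default 1.7 mm inner, 3.4 mm outer
  diameter) centered on the optic nerve head, split into four angular
  sectors matching the retinal nerve fiber layer convention: superior 80°,
  inferior 80°, nasal 110°, temporal 90°. The temporal sector is centered on
  the horizontal axis pointing temporally (image-left for OD, image-right
  for OS).

Physical scale: an en-face field of view of ``fov_deg`` degrees per side is
assumed to subtend ``fov_deg * mm_per_deg`` millimetres on the retina, with
``mm_per_deg = 0.288`` for the emmetropic schematic eye by default.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .image_io import Eye

__all__ = [
    "RegionKind",
    "SectorSet",
    "RingSpec",
    "ScaleSpec",
    "GeometryError",
    "macular_quadrants",
    "ring_sectors",
    "map_laterality",
    "mm_per_px",
]

#: Retinal millimetres per degree of visual angle, emmetropic schematic eye.
DEFAULT_MM_PER_DEG = 0.288

#: Default annulus diameters in mm and angular sector widths in degrees.
DEFAULT_RING_INNER_MM = 1.7
DEFAULT_RING_OUTER_MM = 3.4
DEFAULT_SECTOR_ANGLES = {"superior": 80.0, "inferior": 80.0, "nasal": 110.0, "temporal": 90.0}

ANATOMICAL_NAMES = ("superior", "inferior", "nasal", "temporal")


class GeometryError(ValueError):
    """Sector geometry does not fit the frame."""


class RegionKind(enum.Enum):
    MACULAR_QUADRANTS = "MACULAR_QUADRANTS"
    PERIPAPILLARY_RING = "PERIPAPILLARY_RING"


@dataclass(frozen=True)
class SectorSet:
    """Labeled partition of an analysis region.

    ``labels`` assigns each pixel a sector id (0 = outside every sector);
    ``names`` maps ids to sector names. For macular quadrants the names are
    positional (top/bottom/left/right) until laterality is applied; ring
    sectors are named anatomically at construction because the eye is known.
    """

    labels: np.ndarray
    names: Mapping[int, str]
    region_kind: RegionKind

    def sector_mask(self, name: str) -> np.ndarray:
        ids = [i for i, n in self.names.items() if n == name]
        if not ids:
            raise KeyError(f"no sector named {name!r}; have {sorted(self.names.values())}")
        return self.labels == ids[0]

    def union_mask(self) -> np.ndarray:
        return self.labels > 0


@dataclass(frozen=True)
class RingSpec:
    """Peripapillary annulus specification (physical units).

    ``center_px`` defaults to the frame center (the scan is centered on the
    optic nerve head); override with explicit (row, col) coordinates for
    off-center discs.
    """

    inner_diameter_mm: float = DEFAULT_RING_INNER_MM
    outer_diameter_mm: float = DEFAULT_RING_OUTER_MM
    angles_deg: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SECTOR_ANGLES)
    )
    center_px: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not self.inner_diameter_mm < self.outer_diameter_mm:
            raise ValueError("inner diameter must be smaller than outer diameter")
        total = sum(self.angles_deg.values())
        if abs(total - 360.0) > 1e-9:
            raise ValueError(f"sector angles must sum to 360°, got {total}")
        if set(self.angles_deg) != set(ANATOMICAL_NAMES):
            raise ValueError(f"sector angles must name exactly {ANATOMICAL_NAMES}")


@dataclass(frozen=True)
class ScaleSpec:
    """Physical scale of a cropped frame.

    ``mm_per_px = fov_deg * mm_per_deg / frame_px``.
    """

    fov_deg: float
    frame_px: int
    mm_per_deg: float = DEFAULT_MM_PER_DEG

    def __post_init__(self) -> None:
        if self.fov_deg <= 0 or self.frame_px <= 0 or self.mm_per_deg <= 0:
            raise ValueError("fov_deg, frame_px and mm_per_deg must all be positive")

    @property
    def mm_per_px(self) -> float:
        return self.fov_deg * self.mm_per_deg / self.frame_px


def mm_per_px(scale: ScaleSpec) -> float:
    """Millimetres per pixel of the cropped frame."""
    return scale.mm_per_px


QUADRANT_IDS = {"top": 1, "bottom": 2, "left": 3, "right": 4}


def macular_quadrants(frame_px: int) -> SectorSet:
    """Partition the square frame by its diagonals into four sectors.

    Pixel membership uses pixel-center coordinates relative to the frame
    center. Pixels whose centers lie exactly on a diagonal are assigned to
    the top/bottom sectors. Names are positional; apply
    :func:`map_laterality` (or use the density report) for anatomical names.
    """
    if frame_px < 2:
        raise GeometryError(f"frame_px must be >= 2, got {frame_px}")
    n = int(frame_px)
    c = (n - 1) / 2.0
    rows, cols = np.mgrid[0:n, 0:n]
    y = rows - c  # positive downward
    x = cols - c
    labels = np.zeros((n, n), dtype=np.uint8)
    labels[y >= np.abs(x)] = QUADRANT_IDS["bottom"]
    labels[(-y) >= np.abs(x)] = QUADRANT_IDS["top"]  # center pixel goes to top
    left = (np.abs(x) > np.abs(y)) & (x < 0)
    right = (np.abs(x) > np.abs(y)) & (x > 0)
    labels[left] = QUADRANT_IDS["left"]
    labels[right] = QUADRANT_IDS["right"]
    names = {v: k for k, v in QUADRANT_IDS.items()}
    return SectorSet(labels=labels, names=names, region_kind=RegionKind.MACULAR_QUADRANTS)


RING_IDS = {"superior": 1, "inferior": 2, "nasal": 3, "temporal": 4}


def ring_sectors(
    spec: RingSpec, scale: ScaleSpec, frame_px: int, eye: Eye
) -> SectorSet:
    """Label the peripapillary annulus with anatomical angular sectors.

    A pixel belongs to the annulus when its center distance ``d`` from the
    ring center satisfies ``r_in <= d < r_out`` (half-open, so the partition
    is exact). Within the annulus the polar angle assigns the sector: the
    temporal sector spans +/- half its width around the temporal horizontal
    axis; proceeding from its superior edge the superior, nasal and inferior
    sectors follow contiguously with their specified widths.
    """
    n = int(frame_px)
    s = scale.mm_per_px
    r_in = spec.inner_diameter_mm / 2.0 / s
    r_out = spec.outer_diameter_mm / 2.0 / s
    if spec.center_px is None:
        cy = cx = (n - 1) / 2.0
    else:
        cy, cx = spec.center_px
    if (
        cy - r_out < -0.5
        or cx - r_out < -0.5
        or cy + r_out > n - 0.5
        or cx + r_out > n - 0.5
    ):
        raise GeometryError(
            f"outer ring radius {r_out:.1f}px does not fit a {n}px frame at center "
            f"({cy:.1f}, {cx:.1f})"
        )
    rows, cols = np.mgrid[0:n, 0:n]
    y = rows - cy
    x = cols - cx
    d = np.hypot(y, x)
    in_ring = (d >= r_in) & (d < r_out)

    # Angle phi measured from the superior (up) axis, positive toward temporal.
    up = -y
    temporal = -x if eye is Eye.OD else x
    phi = np.degrees(np.arctan2(temporal, up))  # (-180, 180]

    a = spec.angles_deg
    t_half = a["temporal"] / 2.0
    # temporal: [90 - t_half, 90 + t_half); superior adjacent to its superior
    # edge: [90 - t_half - sup, 90 - t_half); nasal next; inferior closes.
    sup_lo = 90.0 - t_half - a["superior"]
    nas_lo = sup_lo - a["nasal"]

    labels = np.zeros((n, n), dtype=np.uint8)
    tmp = (phi >= 90.0 - t_half) & (phi < 90.0 + t_half)
    sup = (phi >= sup_lo) & (phi < 90.0 - t_half)
    nas = (phi >= nas_lo) & (phi < sup_lo)
    labels[in_ring & tmp] = RING_IDS["temporal"]
    labels[in_ring & sup] = RING_IDS["superior"]
    labels[in_ring & nas] = RING_IDS["nasal"]
    inf = in_ring & (labels == 0)  # remaining arc
    labels[inf] = RING_IDS["inferior"]
    names = {v: k for k, v in RING_IDS.items()}
    return SectorSet(labels=labels, names=names, region_kind=RegionKind.PERIPAPILLARY_RING)


_LATERALITY = {
    ("left", Eye.OD): "temporal",
    ("right", Eye.OD): "nasal",
    ("left", Eye.OS): "nasal",
    ("right", Eye.OS): "temporal",
    ("top", Eye.OD): "superior",
    ("top", Eye.OS): "superior",
    ("bottom", Eye.OD): "inferior",
    ("bottom", Eye.OS): "inferior",
}


def map_laterality(position_label: str, eye: Eye) -> str:
    """Anatomical name of a positional sector for the given eye.

    For the right eye (OD) the image-left sector is temporal and image-right
    is nasal; the mapping is mirrored for the left eye (OS). Top/bottom are
    superior/inferior for both.
    """
    key = (position_label.lower(), eye)
    if key not in _LATERALITY:
        raise ValueError(
            f"invalid position label {position_label!r} (expected left/right/top/bottom)"
        )
    return _LATERALITY[key]
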