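"""Reading, naming and cropping of en-face OCTA angiogram exports.

Angiograms arrive as single-page grayscale TIFF screenshots exported from the
device. Before any quantification they are cropped to a fixed square analysis
frame (962 px for macular scans, 938 px for peripapillary scans) so that every
image of a given region is measured on the same raster. File names follow the
underscore convention ``<code>_<eye>_<target>[_<complex>]``, e.g.
``01_OD_FAZ_SUPERFICIAL`` or ``01_OD_Nerve``; parsing is case-insensitive.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

__all__ = [
    "Region",
    "Complex",
    "Eye",
    "Target",
    "Angiogram",
    "ImageRecord",
    "CROP_PX",
    "FilenameError",
    "CropSizeError",
    "read_angiogram",
    "parse_filename",
    "canonical_name",
    "crop_report",
    "write_results",
]


class Region(enum.Enum):
    """Scanned retinal region: macula or optic nerve head."""

    MACULA = "MACULA"
    ONH = "ONH"


class Complex(enum.Enum):
    """Vascular complex of the en-face slab."""

    SVC = "SVC"
    DVC = "DVC"
    NONE = "NONE"


class Eye(enum.Enum):
    OD = "OD"
    OS = "OS"


class Target(enum.Enum):
    """What the file is meant to be analyzed for."""

    MACULA = "MACULA"
    FAZ = "FAZ"
    NERVE = "NERVE"


#: Side length in pixels of the standard analysis frame per region.
CROP_PX = {Region.MACULA: 962, Region.ONH: 938}


class FilenameError(ValueError):
    """A file name does not follow the naming convention."""


class CropSizeError(ValueError):
    """Raster smaller than the requested analysis frame."""


@dataclass(frozen=True)
class Angiogram:
    """A cropped 8-bit en-face angiogram with its acquisition metadata.

    Attributes
    ----------
    pixels:
        2D ``uint8`` raster, square, of the standard frame size for ``region``.
    region:
        Scanned region (macula or optic nerve head).
    complex:
        Vascular complex the slab represents.
    fov_deg:
        Field of view in degrees per side (10, 15 or 20).
    eye:
        Laterality; drives nasal/temporal sector naming.
    mm_per_px:
        Physical scale of the cropped raster.
    """

    pixels: np.ndarray
    region: Region
    complex: Complex
    fov_deg: float
    eye: Eye
    mm_per_px: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"angiogram raster must be 2D, got shape {px.shape}")
        if self.mm_per_px <= 0:
            raise ValueError("mm_per_px must be positive")
        if self.fov_deg not in (10, 15, 20):
            raise ValueError(f"fov_deg must be one of 10, 15, 20; got {self.fov_deg}")

    @property
    def frame_px(self) -> int:
        return int(self.pixels.shape[0])

    def with_pixels(self, pixels: np.ndarray) -> "Angiogram":
        return replace(self, pixels=pixels)


@dataclass(frozen=True)
class ImageRecord:
    """Fields parsed from an angiogram file name.

    ``path`` is carried for dispatch but excluded from equality so that
    records round-trip through :func:`canonical_name`.
    """

    subject_code: str
    eye: Eye
    target: Target
    complex: Complex
    path: Path | None = field(default=None, compare=False)


def _to_uint8(raster: np.ndarray) -> np.ndarray:
    """Convert a grayscale raster to 8-bit, linearly rescaling wider dtypes.

    Integer inputs are rescaled by the full range of their dtype (a 16-bit
    value of 65535 maps to 255); floats are rescaled by their own maximum.
    """
    raster = np.asarray(raster)
    if raster.dtype == np.uint8:
        return raster
    if np.issubdtype(raster.dtype, np.integer):
        info = np.iinfo(raster.dtype)
        lo, hi = float(info.min), float(info.max)
    else:
        lo = float(raster.min())
        hi = float(raster.max())
        if hi <= lo:
            hi = lo + 1.0
    scaled = (raster.astype(np.float64) - lo) * (255.0 / (hi - lo))
    return np.clip(np.rint(scaled), 0, 255).astype(np.uint8)


def _to_luminance(raster: np.ndarray) -> np.ndarray:
    """Collapse a multi-channel raster to a single luminance channel.

    Uses Rec. 601 weights; a gray RGB image (equal channels) round-trips to
    its single channel unchanged.
    """
    if raster.ndim == 2:
        return raster
    if raster.ndim == 3 and raster.shape[2] in (3, 4):
        rgb = raster[..., :3].astype(np.float64)
        lum = 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]
        if np.issubdtype(raster.dtype, np.integer):
            return np.rint(lum).astype(raster.dtype)
        return lum.astype(raster.dtype)
    raise ValueError(f"cannot interpret raster of shape {raster.shape} as an image")


def read_angiogram(
    path: str | Path,
    *,
    region: Region,
    complex: Complex,
    fov_deg: float,
    eye: Eye,
    mm_per_px: float,
    crop_offset: tuple[int, int] | None = None,
) -> Angiogram:
    """Read a TIFF export, convert to 8-bit grayscale and crop to the frame.

    Multi-channel inputs are converted to luminance, 16-bit inputs rescaled
    linearly to 8-bit, and rasters larger than the standard frame are cropped
    centrally (or at ``crop_offset`` for off-center exports).

    Raises
    ------
    OSError
        If the file cannot be read or decoded.
    ValueError
        If the content is not interpretable as a 2D grayscale image.
    CropSizeError
        If the raster is smaller than the standard analysis frame.
    """
    path = Path(path)
    try:
        raw = tifffile.imread(path)
    except (tifffile.TiffFileError, ValueError) as exc:
        raise OSError(f"cannot decode TIFF {path}: {exc}") from exc
    raw = _to_luminance(np.asarray(raw))
    if raw.ndim != 2:
        raise ValueError(f"{path}: expected 2D grayscale content, got shape {raw.shape}")
    px = _to_uint8(raw)
    px = crop_report(px, region, offset=crop_offset)
    return Angiogram(
        pixels=px,
        region=region,
        complex=complex,
        fov_deg=fov_deg,
        eye=eye,
        mm_per_px=mm_per_px,
    )


_EYE_TOKENS = {e.value: e for e in (Eye.OD, Eye.OS)}
_TARGET_TOKENS = {t.value: t for t in (Target.MACULA, Target.FAZ, Target.NERVE)}
_COMPLEX_TOKENS = {"SUPERFICIAL": Complex.SVC, "DEEP": Complex.DVC}
_SUFFIXES = {".tif", ".tiff"}


def parse_filename(name: str) -> ImageRecord:
    """Parse ``<code>_<eye>_<target>[_<complex>]`` (case-insensitive).

    ``SUPERFICIAL`` maps to the superficial vascular complex (SVC), ``DEEP``
    to the deep complex (DVC); ``NERVE`` files carry no complex token. Extra
    trailing tokens are ignored with a logged warning.
    """
    path = Path(name)
    stem = path.name
    if path.suffix.lower() in _SUFFIXES:
        stem = path.stem
    tokens = stem.split("_")
    if len(tokens) < 3:
        raise FilenameError(
            f"{stem!r}: expected at least 3 underscore-separated tokens "
            "(code_eye_target), got " + str(len(tokens))
        )
    code, eye_tok, target_tok = tokens[0], tokens[1].upper(), tokens[2].upper()
    if eye_tok not in _EYE_TOKENS:
        raise FilenameError(f"{stem!r}: unknown eye token {tokens[1]!r} (expected OD/OS)")
    if target_tok not in _TARGET_TOKENS:
        raise FilenameError(
            f"{stem!r}: unknown target token {tokens[2]!r} (expected MACULA/FAZ/NERVE)"
        )
    eye = _EYE_TOKENS[eye_tok]
    target = _TARGET_TOKENS[target_tok]
    rest = tokens[3:]
    cplx = Complex.NONE
    if target in (Target.MACULA, Target.FAZ):
        if not rest:
            raise FilenameError(
                f"{stem!r}: {target.value} file names require a SUPERFICIAL/DEEP token"
            )
        cplx_tok = rest[0].upper()
        if cplx_tok not in _COMPLEX_TOKENS:
            raise FilenameError(
                f"{stem!r}: unknown complex token {rest[0]!r} (expected SUPERFICIAL/DEEP)"
            )
        cplx = _COMPLEX_TOKENS[cplx_tok]
        rest = rest[1:]
    if rest:
        logger.warning("%r: ignoring trailing tokens %s", stem, rest)
    return ImageRecord(
        subject_code=code, eye=eye, target=target, complex=cplx, path=Path(name)
    )


_COMPLEX_NAMES = {Complex.SVC: "SUPERFICIAL", Complex.DVC: "DEEP"}
_TARGET_NAMES = {Target.FAZ: "FAZ", Target.MACULA: "Macula", Target.NERVE: "Nerve"}


def canonical_name(record: ImageRecord) -> str:
    """Canonical file stem for a record; inverse of :func:`parse_filename`."""
    parts = [record.subject_code, record.eye.value, _TARGET_NAMES[record.target]]
    if record.complex is not Complex.NONE:
        parts.append(_COMPLEX_NAMES[record.complex])
    return "_".join(parts)


def crop_report(
    raw: np.ndarray, region: Region, offset: tuple[int, int] | None = None
) -> np.ndarray:
    """Extract the standard square analysis frame from a device report.

    The crop is centered by default; ``offset`` gives the explicit top-left
    corner (row, col) for off-center exports. Idempotent on already-cropped
    rasters.
    """
    raw = np.asarray(raw)
    if raw.ndim != 2:
        raise ValueError(f"expected 2D raster, got shape {raw.shape}")
    side = CROP_PX[region]
    h, w = raw.shape
    if h < side or w < side:
        raise CropSizeError(
            f"raster {h}x{w} smaller than the {side}x{side} {region.value} frame"
        )
    if offset is None:
        r0 = (h - side) // 2
        c0 = (w - side) // 2
    else:
        r0, c0 = offset
        if r0 < 0 or c0 < 0 or r0 + side > h or c0 + side > w:
            raise CropSizeError(f"offset {offset} puts the {side}px frame outside {h}x{w}")
    return raw[r0 : r0 + side, c0 : c0 + side]


def write_results(
    rows: Sequence[dict], path: str | Path, format: str = "CSV"
) -> Path:
    """Write result records as CSV (canonical) or XLSX (optional mirror).

    One row per analyzed image. Column order follows the first record:
    identifier fields first, then metrics, as assembled by the analyses.
    Numeric cells are written with 6-decimal precision in CSV.
    """
    path = Path(path)
    df = pd.DataFrame(list(rows))
    fmt = format.upper()
    if fmt == "CSV":
        df.to_csv(path, index=False, float_format="%.6f", lineterminator="\n")
    elif fmt == "XLSX":
        df.to_excel(path, index=False)
    else:
        raise ValueError(f"unknown output format {format!r} (expected CSV or XLSX)")
    return path
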