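"""Batch orchestration: walk a folder of TIFF exports, dispatch each image
to its analysis by parsed file name, and write consolidated result tables.

Each image is processed independently; a failure on one image is recorded in
that image's ``status`` column and does not abort the batch. Files are
processed in sorted name order, so reruns over the same folder produce
byte-identical tables.
"""

from __future__ import annotations

import enum
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import faz as faz_mod
from .binarize import binarize, write_mask_tiff
from .density import density_report
from .faz import ContourParams
from .geometry import RingSpec, ScaleSpec, macular_quadrants, ring_sectors
from .image_io import (
    CROP_PX,
    Angiogram,
    Region,
    Target,
    parse_filename,
    read_angiogram,
    write_results,
)

logger = logging.getLogger(__name__)

__all__ = ["Analysis", "RunConfig", "run_batch"]


class Analysis(enum.Enum):
    FAZ = "FAZ"
    MACULA_DENSITY = "MACULA_DENSITY"
    ONH_DENSITY = "ONH_DENSITY"


_ANALYSIS_TARGET = {
    Analysis.FAZ: Target.FAZ,
    Analysis.MACULA_DENSITY: Target.MACULA,
    Analysis.ONH_DENSITY: Target.NERVE,
}
_ANALYSIS_REGION = {
    Analysis.FAZ: Region.MACULA,
    Analysis.MACULA_DENSITY: Region.MACULA,
    Analysis.ONH_DENSITY: Region.ONH,
}

_DENSITY_COLUMNS = [
    "file", "subject_code", "eye", "complex", "fov_deg", "threshold",
    "global", "superior", "inferior", "nasal", "temporal", "status",
]
_FAZ_COLUMNS = [
    "file", "subject_code", "eye", "complex", "fov_deg",
    "area_mm2", "perimeter_mm", "circularity", "converged", "status",
]


@dataclass(frozen=True)
class RunConfig:
    """One batch run over a folder of same-analysis angiograms."""

    input_dir: Path
    output_dir: Path
    analysis: Analysis
    fov_deg: float = 15.0
    mm_per_deg: float = 0.288
    contour: ContourParams = field(default_factory=ContourParams)
    ring: RingSpec = field(default_factory=RingSpec)
    output_format: str = "CSV"
    invert: bool = False
    save_images: bool = True
    crop_offset: tuple[int, int] | None = None


def _process_one(path: Path, config: RunConfig) -> dict[str, Any]:
    record = parse_filename(path.name)
    expected = _ANALYSIS_TARGET[config.analysis]
    if record.target is not expected:
        raise ValueError(
            f"file targets {record.target.value}, but the batch runs "
            f"{config.analysis.value}"
        )
    region = _ANALYSIS_REGION[config.analysis]
    scale = ScaleSpec(
        fov_deg=config.fov_deg, frame_px=CROP_PX[region], mm_per_deg=config.mm_per_deg
    )
    image = read_angiogram(
        path,
        region=region,
        complex=record.complex,
        fov_deg=config.fov_deg,
        eye=record.eye,
        mm_per_px=scale.mm_per_px,
        crop_offset=config.crop_offset,
    )
    row: dict[str, Any] = {
        "file": path.name,
        "subject_code": record.subject_code,
        "eye": record.eye.value,
        "complex": record.complex.value,
        "fov_deg": config.fov_deg,
    }
    out = config.output_dir
    if config.analysis is Analysis.FAZ:
        region_seg, result = faz_mod.segment_and_measure(
            image, params=config.contour, scale=scale
        )
        row.update(
            area_mm2=round(result.area_mm2, 6),
            perimeter_mm=round(result.perimeter_mm, 6),
            circularity=round(result.circularity, 6),
            converged=region_seg.converged,
        )
        if config.save_images:
            faz_mod.write_faz_overlay(image, region_seg, out / f"{path.stem}_faz_overlay.tif")
            faz_mod.write_faz_mask(image, region_seg, out / f"{path.stem}_faz_mask.tif")
    else:
        if config.analysis is Analysis.MACULA_DENSITY:
            sectors = macular_quadrants(image.frame_px)
        else:
            sectors = ring_sectors(config.ring, scale, image.frame_px, record.eye)
        report = density_report(image, sectors, invert=config.invert)
        row["threshold"] = report.threshold_used
        row["global"] = round(report.global_pct, 2)
        for name in ("superior", "inferior", "nasal", "temporal"):
            row[name] = round(report.per_sector[name], 2)
        if config.save_images:
            write_mask_tiff(
                binarize(image, invert=config.invert), out / f"{path.stem}_binary.tif"
            )
    row["status"] = "ok"
    return row


def run_batch(config: RunConfig) -> pd.DataFrame:
    """Process every TIFF in ``config.input_dir``; return the results table.

    The table is also written to ``results_<analysis>.csv`` (and optionally
    ``.xlsx``) in ``config.output_dir``. Per-image failures set
    ``status='error: ...'`` for that row only.
    """
    in_dir = Path(config.input_dir)
    out_dir = Path(config.output_dir)
    if not in_dir.is_dir():
        raise ValueError(f"input directory {in_dir} does not exist")
    files = sorted(
        p for p in in_dir.iterdir() if p.suffix.lower() in (".tif", ".tiff")
    )
    if not files:
        raise ValueError(f"no TIFF files found in {in_dir}")
    out_dir.mkdir(parents=True, exist_ok=True)

    columns = _FAZ_COLUMNS if config.analysis is Analysis.FAZ else _DENSITY_COLUMNS
    rows = []
    for path in files:
        t0 = time.perf_counter()
        try:
            row = _process_one(path, config)
        except Exception as exc:  # fault isolation: one bad image, one bad row
            row = {"file": path.name, "status": f"error: {exc}"}
        elapsed = time.perf_counter() - t0
        logger.info(
            "%s analysis=%s threshold=%s elapsed=%.2fs status=%s",
            path.name, config.analysis.value, row.get("threshold", "-"),
            elapsed, row["status"],
        )
        rows.append({col: row.get(col, "") for col in columns})

    table = pd.DataFrame(rows, columns=columns).sort_values("file", kind="stable")
    table = table.reset_index(drop=True)
    stem = f"results_{config.analysis.value.lower()}"
    write_results(table.to_dict("records"), out_dir / f"{stem}.csv", "CSV")
    if config.output_format.upper() == "XLSX":
        write_results(table.to_dict("records"), out_dir / f"{stem}.xlsx", "XLSX")
    return table
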