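"""Synthetic angiogram phantoms with known ground truth.

Real en-face angiograms show bright curvilinear vessels on a dark
background, a vessel-free foveal avascular zone (FAZ) bounded by a terminal
capillary ring, and — on optic-nerve-head scans — a radial vessel pattern
around a dark disc. The phantoms emulate exactly those statistical features
with controllable parameters (vessel area fraction, FAZ geometry, intensity
separation, additive Gaussian noise), so that every stage of the pipeline
can be validated against exact ground truth without clinical data. Vessel
networks are seeded random-walk polylines, not physiologic vascular trees:
they provide connected bright curvilinear foreground with a controllable
area fraction, which is what the measurement code is sensitive to.

All generators are pure functions of their spec (including the seed): the
same spec yields bit-identical images.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
from scipy import special

from .geometry import (
    RingSpec,
    ScaleSpec,
    macular_quadrants,
    map_laterality,
    ring_sectors,
)
from .image_io import Angiogram, Complex, Eye, Region

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "GenerationError",
    "generate_macular_phantom",
    "generate_onh_phantom",
    "generate_faz_phantom",
    "as_angiogram",
]


class GenerationError(RuntimeError):
    """Target vessel fraction unreachable after bounded painting attempts."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic angiogram.

    ``vessel_fraction`` is either a single target area fraction (of the full
    frame for macular phantoms, of each ring sector for ONH phantoms) or a
    mapping of positional/anatomical sector names to per-sector targets.
    ``faz_axes_px`` are the semi-axes of the FAZ ellipse;
    ``faz_irregularity`` adds a sinusoidal radial perturbation of that
    relative amplitude with ``faz_irregularity_freq`` lobes. Defaults sit in
    the normal physiologic regime: macular density in the 20–40% range and a
    FAZ of roughly 0.25 mm² at a 15° field of view.
    """

    frame_px: int = 962
    region: Region = Region.MACULA
    vessel_fraction: float | Mapping[str, float] = 0.25
    faz_axes_px: tuple[float, float] = (70.0, 60.0)
    faz_irregularity: float = 0.0
    faz_irregularity_freq: int = 6
    vessel_intensity: int = 220
    background_intensity: int = 30
    noise_sd: float = 10.0
    seed: int = 0
    eye: Eye = Eye.OD
    fov_deg: float = 15.0
    mm_per_deg: float = 0.288
    faz_ring: bool = True  # terminal capillary ring delimiting the FAZ
    speckle: bool = False  # multiplicative speckle noise (off by default)

    @property
    def mm_per_px(self) -> float:
        return self.fov_deg * self.mm_per_deg / self.frame_px


@dataclass(frozen=True)
class PhantomTruth:
    """Exact ground truth paired with a generated phantom image."""

    vessel_mask_truth: np.ndarray
    faz_mask_truth: np.ndarray | None
    faz_area_mm2: float
    faz_perimeter_mm: float
    per_sector_fraction: Mapping[str, float]


def _faz_radius(spec: PhantomSpec, theta: np.ndarray, phase: float) -> np.ndarray:
    """Radius of the FAZ boundary at polar angle theta (px)."""
    a, b = spec.faz_axes_px
    base = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    return base * (1.0 + spec.faz_irregularity * np.sin(spec.faz_irregularity_freq * theta + phase))


def _faz_truth_metrics(spec: PhantomSpec, phase: float) -> tuple[float, float]:
    """Analytic area (mm²) and perimeter (mm) of the FAZ boundary curve."""
    s = spec.mm_per_px
    a, b = spec.faz_axes_px
    if spec.faz_irregularity == 0.0:
        area = np.pi * a * b * s * s
        # ellipse circumference 4*a*E(e), complete elliptic integral of 2nd kind
        a_mm, b_mm = max(a, b) * s, min(a, b) * s
        ecc2 = 1.0 - (b_mm / a_mm) ** 2
        perimeter = 4.0 * a_mm * special.ellipe(ecc2)
        return float(area), float(perimeter)
    theta = np.linspace(0.0, 2.0 * np.pi, 8192, endpoint=False)
    r = _faz_radius(spec, theta, phase)
    x, y = r * np.cos(theta), r * np.sin(theta)
    x = np.append(x, x[0])
    y = np.append(y, y[0])
    area_px = 0.5 * abs(np.sum(x[:-1] * y[1:] - x[1:] * y[:-1]))
    perim_px = np.sum(np.hypot(np.diff(x), np.diff(y)))
    return float(area_px * s * s), float(perim_px * s)


def _faz_masks(
    spec: PhantomSpec, phase: float, ring_px: float = 3.0
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize the FAZ interior and its surrounding capillary ring band."""
    n = spec.frame_px
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    dy, dx = yy - c, xx - c
    rho = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    r_b = _faz_radius(spec, theta, phase)
    interior = rho <= r_b
    ring = (rho > r_b) & (rho <= r_b + ring_px)
    return interior, ring


_MAX_WALKS = 100_000


def _paint_walks(
    rng: np.random.Generator,
    painted: np.ndarray,
    allowed: np.ndarray,
    count_region: np.ndarray,
    target_count: int,
    *,
    start_fn,
    direction_fn,
    length_range: tuple[int, int],
    width_range: tuple[int, int],
    turn_sd: float = 0.15,
) -> None:
    """Paint random-walk polylines into ``painted`` until the number of
    painted pixels inside ``count_region`` reaches ``target_count``.

    Painting is clipped to ``allowed``; mutates ``painted`` in place.
    """
    n = painted.shape[0]
    count = int(np.count_nonzero(painted & count_region))
    walks = 0
    stalled = 0
    while count < target_count:
        walks += 1
        if walks > _MAX_WALKS or stalled > 500:
            raise GenerationError(
                f"vessel fraction target unreachable: {count}/{target_count} painted "
                f"after {walks} walks"
            )
        y0, x0 = start_fn()
        heading = direction_fn(y0, x0)
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        width = int(rng.integers(width_range[0], width_range[1] + 1))
        turns = rng.normal(0.0, turn_sd, size=length)
        headings = heading + np.cumsum(turns)
        ys = y0 + np.concatenate(([0.0], np.cumsum(np.sin(headings))))
        xs = x0 + np.concatenate(([0.0], np.cumsum(np.cos(headings))))
        iy = np.rint(ys).astype(np.intp)
        ix = np.rint(xs).astype(np.intp)
        half_lo = width // 2
        half_hi = width - half_lo
        stamped_y = []
        stamped_x = []
        for oy in range(-half_lo, half_hi):
            for ox in range(-half_lo, half_hi):
                stamped_y.append(iy + oy)
                stamped_x.append(ix + ox)
        py = np.concatenate(stamped_y)
        px = np.concatenate(stamped_x)
        ok = (py >= 0) & (py < n) & (px >= 0) & (px < n)
        py, px = py[ok], px[ok]
        lin = np.unique(py * n + px)  # stamp overlaps would double-count
        py, px = lin // n, lin % n
        ok = allowed[py, px] & ~painted[py, px]
        py, px = py[ok], px[ok]
        stalled = stalled + 1 if py.size == 0 else 0
        painted[py, px] = True
        count += int(np.count_nonzero(count_region[py, px]))


def _render(
    spec: PhantomSpec,
    rng: np.random.Generator,
    vessel: np.ndarray,
    base: np.ndarray | None = None,
) -> np.ndarray:
    img = (
        np.full(vessel.shape, float(spec.background_intensity))
        if base is None
        else base.astype(np.float64)
    )
    img[vessel] = float(spec.vessel_intensity)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    if spec.speckle:
        img = img * rng.gamma(16.0, 1.0 / 16.0, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def generate_macular_phantom(spec: PhantomSpec) -> tuple[np.ndarray, PhantomTruth]:
    """Macular phantom: vessel network, central vessel-free FAZ, noise.

    The FAZ interior stays at background intensity; when ``spec.faz_ring``
    is set a 3 px capillary ring is painted along the FAZ boundary, as in
    real angiograms, giving the FAZ a closed bright border. Per-sector
    fraction targets (keys top/bottom/left/right) confine painting to the
    diagonal quadrants; a scalar target is counted over the whole frame.
    """
    n = spec.frame_px
    rng = np.random.default_rng(spec.seed)
    phase = float(rng.uniform(0.0, 2.0 * np.pi))
    interior, ring = _faz_masks(spec, phase)
    vessel = np.zeros((n, n), dtype=bool)
    if spec.faz_ring:
        vessel |= ring
    allowed_base = ~interior & ~ring  # FAZ and its boundary band stay vessel-free

    def rand_start():
        return float(rng.uniform(0, n - 1)), float(rng.uniform(0, n - 1))

    def rand_dir(y0, x0):
        return float(rng.uniform(0.0, 2.0 * np.pi))

    length_range = (max(40, n // 4), max(80, n // 2))
    if isinstance(spec.vessel_fraction, Mapping):
        quads = macular_quadrants(n)
        for name, frac in spec.vessel_fraction.items():
            qmask = quads.sector_mask(name)
            _paint_walks(
                rng, vessel, allowed_base & qmask, qmask,
                int(round(frac * qmask.sum())),
                start_fn=rand_start, direction_fn=rand_dir,
                length_range=length_range, width_range=(1, 4),
            )
    else:
        _paint_walks(
            rng, vessel, allowed_base, np.ones((n, n), dtype=bool),
            int(round(spec.vessel_fraction * n * n)),
            start_fn=rand_start, direction_fn=rand_dir,
            length_range=length_range, width_range=(1, 4),
        )
    img = _render(spec, rng, vessel)
    area, perim = _faz_truth_metrics(spec, phase)
    quads = macular_quadrants(n)
    fractions = {"total": float(np.count_nonzero(vessel)) / (n * n)}
    for name in ("top", "bottom", "left", "right"):
        qmask = quads.sector_mask(name)
        fractions[name] = float(np.count_nonzero(vessel & qmask)) / float(qmask.sum())
    return img, PhantomTruth(
        vessel_mask_truth=vessel,
        faz_mask_truth=interior,
        faz_area_mm2=area,
        faz_perimeter_mm=perim,
        per_sector_fraction=fractions,
    )


def generate_onh_phantom(
    spec: PhantomSpec, ring_spec: RingSpec | None = None
) -> tuple[np.ndarray, PhantomTruth]:
    """Optic-nerve-head phantom: dark disc plus radial vessels.

    Vessels emanate radially from near the center and cross the
    peripapillary annulus. Fraction targets are counted inside each annulus
    sector (anatomical keys superior/inferior/nasal/temporal for
    ``spec.eye``; a scalar applies to all four). Painting for one sector is
    clipped so that it cannot spill into another sector's annulus region.
    """
    spec = replace(spec, region=Region.ONH,
                   frame_px=spec.frame_px if spec.region is Region.ONH else 938)
    n = spec.frame_px
    rng = np.random.default_rng(spec.seed)
    ring_spec = ring_spec or RingSpec()
    scale = ScaleSpec(fov_deg=spec.fov_deg, frame_px=n, mm_per_deg=spec.mm_per_deg)
    sectors = ring_sectors(ring_spec, scale, n, spec.eye)
    s = scale.mm_per_px
    r_in = ring_spec.inner_diameter_mm / 2.0 / s
    r_out = ring_spec.outer_diameter_mm / 2.0 / s
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    rho = np.hypot(yy - c, xx - c)
    disc = rho <= 0.55 * r_in  # dark optic cup

    if isinstance(spec.vessel_fraction, Mapping):
        targets = dict(spec.vessel_fraction)
    else:
        targets = {name: float(spec.vessel_fraction)
                   for name in ("superior", "inferior", "nasal", "temporal")}

    vessel = np.zeros((n, n), dtype=bool)
    outside_ring = sectors.labels == 0
    for sid, name in sectors.names.items():
        frac = targets[name]
        smask = sectors.labels == sid
        # mid-sector angle for radial starts
        sy, sx = np.nonzero(smask)
        angles = np.arctan2(sy - c, sx - c)
        mean_vec = np.arctan2(np.sin(angles).mean(), np.cos(angles).mean())
        spread = 0.9 * np.pi * 0.5

        def start_fn():
            ang = mean_vec + float(rng.uniform(-spread, spread))
            r0 = float(rng.uniform(0.3 * r_in, 0.8 * r_in))
            return c + r0 * np.sin(ang), c + r0 * np.cos(ang)

        def direction_fn(y0, x0):
            return float(np.arctan2(y0 - c, x0 - c) + rng.normal(0.0, 0.15))

        _paint_walks(
            rng, vessel, smask | outside_ring, smask,
            int(round(frac * smask.sum())),
            start_fn=start_fn, direction_fn=direction_fn,
            length_range=(int(r_out - r_in) + 40, int(r_out) + 60),
            width_range=(1, 3), turn_sd=0.05,
        )
    base = np.full((n, n), float(spec.background_intensity))
    base[disc] = 5.0
    vessel &= ~disc
    img = _render(spec, rng, vessel, base=base)
    fractions = {}
    union = sectors.union_mask()
    fractions["total"] = float(np.count_nonzero(vessel & union)) / float(union.sum())
    for sid, name in sectors.names.items():
        smask = sectors.labels == sid
        fractions[name] = float(np.count_nonzero(vessel & smask)) / float(smask.sum())
    return img, PhantomTruth(
        vessel_mask_truth=vessel,
        faz_mask_truth=None,
        faz_area_mm2=0.0,
        faz_perimeter_mm=0.0,
        per_sector_fraction=fractions,
    )


def generate_faz_phantom(
    spec: PhantomSpec, background_mean: float = 180.0, faz_intensity: float = 20.0
) -> tuple[np.ndarray, PhantomTruth]:
    """Dark FAZ shape on a bright textured background.

    Emulates the perifoveal regime seen by the FAZ segmentation: a dark
    avascular region surrounded by dense bright capillary signal. The
    background texture is Gaussian around ``background_mean``.
    """
    n = spec.frame_px
    rng = np.random.default_rng(spec.seed)
    phase = float(rng.uniform(0.0, 2.0 * np.pi))
    interior, _ = _faz_masks(spec, phase)
    base = np.full((n, n), float(background_mean))
    base[interior] = float(faz_intensity)
    img = base
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    if spec.speckle:
        img = img * rng.gamma(16.0, 1.0 / 16.0, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    area, perim = _faz_truth_metrics(spec, phase)
    return img, PhantomTruth(
        vessel_mask_truth=~interior,
        faz_mask_truth=interior,
        faz_area_mm2=area,
        faz_perimeter_mm=perim,
        per_sector_fraction={},
    )


def as_angiogram(
    image: np.ndarray, spec: PhantomSpec, complex: Complex = Complex.SVC
) -> Angiogram:
    """Wrap a phantom raster as an :class:`Angiogram` with matching metadata."""
    return Angiogram(
        pixels=image,
        region=spec.region,
        complex=complex,
        fov_deg=spec.fov_deg,
        eye=spec.eye,
        mm_per_px=spec.mm_per_px,
    )
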