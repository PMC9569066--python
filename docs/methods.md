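# Methods

`octaquant` quantifies en-face optical coherence tomography angiography
(OCTA) images along two axes: vessel density of the macular superficial and
deep vascular complexes (mSVC, mDVC) and of the peripapillary superficial
complex (pSVC), and morphometry of the foveal avascular zone (FAZ). This
note records the models, parameter choices and numerical decisions behind
the implementation, and what the synthetic phantoms do and do not establish.

## Analysis frames and physical scale

Device exports are cropped to a fixed square analysis frame: 962 × 962 px
for macular scans and 938 × 938 px for peripapillary scans, centered in the
export by default (an explicit crop offset is available for off-center
exports). One macular frame size serves all three fields of view (10°, 15°,
20°), so the physical pixel pitch differs per acquisition:

    mm_per_px = fov_deg × mm_per_deg / frame_px

with `mm_per_deg = 0.288` mm/deg by default — the conversion for the
emmetropic schematic eye. Device-internal scaling is not exposed by
exports, so the constant is configurable (`scale.mm_per_deg`); axial-length
correction is not attempted. At 15° this gives 4.49 µm/px (macula) and
4.61 µm/px (peripapillary).

## Binarization

Vessel density requires a binary vessel map. The threshold is chosen by
Otsu's method on the 256-bin histogram of the 8-bit frame: the cut `t`
(background ≤ t < vessels) maximizing the between-class variance
σ²_B(t) = ω₀ω₁(μ₀ − μ₁)². Implementation details that matter for
reproducibility:

- the histogram is used raw — no smoothing, despeckling or top-hat
  pre-filtering; the whole cropped frame contributes;
- inputs of higher bit depth are linearly rescaled to 8-bit first, so the
  threshold is always an integer in [0, 254];
- ties in σ²_B (plateaus across empty histogram bins are common) are broken
  toward the **smallest** threshold; reference implementations differ here
  and the choice is load-bearing for bit-exact reproducibility;
- white (above-threshold) pixels are vessels; an `--invert` flag handles
  atypical exports with dark vessels by thresholding the inverted image,
  which reproduces the direct mask exactly;
- a constant image has no separating threshold and is reported as a
  degenerate-histogram error rather than an arbitrary mask.

The implementation is validated against an independent exhaustive scan of
all 255 candidate thresholds and against `skimage.filters.threshold_otsu`.

## Sector geometry

**Macular quadrants.** The frame is cut by its two diagonals into four
triangular sectors (top, bottom, left, right) with a common apex at the
frame center — the standard macular sectorization. Membership uses pixel
centers; pixels exactly on a diagonal go to the top/bottom sectors (the
center pixel, when one exists, to top). The "total" region is the full
frame, i.e. the union of the four quadrants, so the global density is
exactly the pixel-weighted mean of the quadrant densities.

**Peripapillary ring.** An annulus of 1.7 mm inner and 3.4 mm outer
diameter centered on the optic nerve head (frame center by default,
`ring.center_px` to override). Membership is half-open, `r_in ≤ d < r_out`
on pixel-center distances, so the four angular sectors partition the ring
exactly. Sector widths follow the retinal nerve fiber layer convention:
superior 80°, inferior 80°, nasal 110°, temporal 90°. The angular origin is
not standardized anywhere we could anchor it, so the layout is defined as:
temporal spans ±45° about the temporal horizontal axis; its superior edge
is followed contiguously by superior (80°), then nasal (110°), then
inferior (80°). This places nasal symmetric about the nasal horizontal axis
as well; superior and inferior are each displaced 5° toward the nasal side
of vertical — an unavoidable consequence of the 110°/90° horizontal-sector
asymmetry. Note this asymmetry also means a 180° frame rotation maps the
temporal sector into a strict subset of the nasal sector, not onto it;
exact half-turn symmetry holds only for equal sector widths, and is tested
in that configuration.

**Laterality.** Image-left is temporal in right eyes (OD) and nasal in left
eyes (OS); image-right the opposite; top/bottom are superior/inferior in
both. Quadrant sectors are computed positionally and renamed per eye at
reporting time; ring sectors are built anatomically because the eye is
known at construction.

## Vessel density

Density of a region is `100 × |vessel ∩ region| / |region|` percent. The
peripapillary "total" is the 360° ring only — the inner disc and the frame
corners are excluded. Densities are written with 2-decimal precision.

## FAZ delimitation

The FAZ is segmented on the raw grayscale macular crop (not the binarized
image) by a deterministic region-based level-set evolution:

1. initialize with a disc of radius `seed_radius` (4 px) at the seed — the
   frame center by default, since acquisitions are fovea-centered;
2. each iteration, compute the region's mean intensity and admit every
   8-connected boundary neighbor whose intensity differs from that mean by
   less than `propagation_tolerance` (60 intensity units by default: ≈4–5
   standard deviations of typical background noise, far below the
   ≥100-unit contrast of perifoveal capillary signal);
3. every `smooth_interval` (5) iterations apply a morphological
   closing/opening with a disc of radius `curvature_weight` (1 px) — the
   curvature-regularization term, smoothing the boundary and clipping
   single-pixel protrusions — and keep the connected component containing
   the seed;
4. stop when the pixel set is stationary (converged) or after
   `max_iterations` (500; the region grows at most one pixel ring per
   iteration, so this accommodates any FAZ that fits the frame). A
   non-converged evolution returns its partial region flagged
   `converged=False`.

Interior holes (dark pixels skipped because of noise excursions) are filled
before measurement: the FAZ is by definition simply connected. If the
region reaches the frame border the image offers no closed boundary around
the seed (e.g. a constant image, or a scan without a perifoveal capillary
ring) and a segmentation failure is raised rather than a meaningless
region.

## FAZ metrics

- **Area** = pixel count × `mm_per_px`².
- **Perimeter** = length of the sub-pixel 0.5-level iso-contour polygon of
  the mask, extracted by marching squares after light Gaussian smoothing
  (σ = 2 px, mask padded first). Counting pixel edges instead would
  overestimate a disc's perimeter by up to ~27% and corrupt circularity;
  the smoothed iso-contour of a 100 px disc is within 0.1% of the true
  circumference. The residual discretization excess motivates tolerating
  circularity up to ~1.02 on rasterized shapes.
- **Circularity** = 4π·area/perimeter², 1 for a perfect circle, decreasing
  toward 0 with boundary irregularity. Scale cancels, so circularity is
  independent of `mm_per_deg`.

## Phantoms

The generators render the image features the measurement code is sensitive
to, with exact ground truth:

- *macular*: random-walk polylines (width 1–4 px, persistent heading with
  Gaussian jitter) painted at `vessel_intensity` on `background_intensity`
  until a target area fraction is met (globally or per quadrant), a
  vessel-free elliptical FAZ with optional sinusoidal boundary
  irregularity, a 3 px capillary ring hugging the FAZ boundary (as in real
  angiograms, and what stops the level set), and additive clipped Gaussian
  noise; default intensities 220/30 and fractions in the 15–40% band match
  the normal macular regime;
- *peripapillary*: a dark central disc with radial polylines crossing the
  annulus, per-sector fraction targets honored by clipping each sector's
  painting to that sector's annulus region (defaults in the 40–75% band);
- *FAZ-regime*: a dark FAZ shape on bright Gaussian-textured background,
  the local contrast configuration the segmentation actually sees.

Truth records the exact painted vessel set, the rasterized FAZ set, and
analytic FAZ area/perimeter (πab and the complete elliptic integral for
ellipses; dense polygon quadrature for irregular boundaries). All
generators are pure functions of their spec including the seed.

What the phantoms do **not** emulate: OCTA acquisition physics, projection
and motion artifacts, signal-strength gradients, real capillary topology,
or device segmentation errors. Passing recovery tests therefore
demonstrates that the measurement chain is correct on images with known
truth and realistic first-order statistics — not that any particular
clinical number will be reproduced; normative cohort values require a
clinical dataset.

## Problem sizes and runtime envelope

Validation uses full-size frames (962/938 px). Recovery suites run 20
seeded phantoms per claim (density: per-quadrant targets 0.15–0.40, noise
σ ≤ 15; FAZ: disc r = 50 px and 60 × 30 px ellipse, noise σ = 10);
batch determinism uses a 12-image folder. The complete suite runs in well
under a minute on a single core.

## Known limitations

- The level-set parameters are calibration knobs; numerical agreement with
  any particular interactive segmentation tool on clinical images is not
  claimed.
- The angular origin of the peripapillary sectors and the diagonal (rather
  than rectangular) macular cut are conventions chosen here and exposed as
  configuration; other choices shift sector values on real, anisotropic
  images.
- Margins or annotations inside an export frame are not auto-detected; the
  crop is geometric.
- `mm_per_deg` is a population constant; per-eye axial-length scaling is
  out of scope, so areas in mm² carry the usual schematic-eye caveat.
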