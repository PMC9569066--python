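# octaquant

Standardized, scriptable quantification of en-face optical coherence
tomography angiography (OCTA) images, for researchers who export angiograms
from the device and need reproducible numbers instead of interactive image
editing. It batch-processes folders of TIFF exports and reports:

- **vessel density** (% of vessel pixels) of the macular superficial and
  deep vascular complexes — global and in four sectors (superior, inferior,
  nasal, temporal) — at 10°, 15° or 20° fields of view;
- **peripapillary vessel density** of the superficial complex in an annulus
  of 1.7/3.4 mm diameters around the optic nerve head, global (360°) and in
  the nerve-fiber-layer sectors (superior 80°, inferior 80°, nasal 110°,
  temporal 90°);
- **foveal avascular zone (FAZ)** morphometry: area (mm²), perimeter (mm)
  and circularity.

## Method

Images are cropped to a fixed analysis frame (962 px macular, 938 px
peripapillary) and binarized with Otsu's threshold — the cut *t* maximizing
the between-class variance σ²_B(t) = ω₀ω₁(μ₀−μ₁)² of the intensity
histogram — with white pixels counted as vessels:

    density = 100 · |vessel ∩ region| / |region|   [%]

Image-left/right sectors are named temporal/nasal according to eye
laterality (left is temporal in OD, nasal in OS). The FAZ is delimited on
the grayscale crop by a region-based level-set evolution seeded at the
frame center — the region grows into neighbors within a propagation
tolerance of its evolving mean, with morphological curvature
regularization — and measured as

    area = N_px · s²,   perimeter = |iso-contour polygon| · s,
    circularity = 4π · area / perimeter²

where `s` is the pixel pitch in mm (fov_deg · 0.288 mm/deg ÷ frame_px) and
circularity is 1 for a perfect circle. See `docs/methods.md` for the full
model and parameter rationale.

## Worked example

Name the exports `<code>_<eye>_<target>[_<layer>].tif`, e.g.
`01_OD_FAZ_SUPERFICIAL.tif`, `01_OD_Macula_DEEP.tif`, `01_OD_Nerve.tif`,
one analysis type per folder, then:

```bash
octaquant faz --in faz_scans/ --out results/ --fov 15
```

```
01_OD_FAZ_SUPERFICIAL.tif analysis=FAZ elapsed=0.17s status=ok
02_OD_FAZ_SUPERFICIAL.tif analysis=FAZ elapsed=0.13s status=ok
2 images processed, 0 failed
```

`results/results_faz.csv`:

```
file,subject_code,eye,complex,fov_deg,area_mm2,perimeter_mm,circularity,converged,status
01_OD_FAZ_SUPERFICIAL.tif,01,OD,SVC,15.000000,0.266432,1.837954,0.991121,True,ok
02_OD_FAZ_SUPERFICIAL.tif,02,OD,SVC,15.000000,0.191576,1.551303,1.000363,True,ok
```

Subject 01's FAZ covers 0.266 mm² with a 1.84 mm contour; circularity 0.99
means it is nearly circular. Segmentation overlays and FAZ-only masks are
written next to the results. Density runs look the same:

```bash
octaquant onh --in nerve_scans/ --out results/
```

```
file,subject_code,eye,complex,fov_deg,threshold,global,superior,inferior,nasal,temporal,status
01_OD_Nerve.tif,01,OD,NONE,15.000000,75,55.060000,55.050000,55.060000,55.090000,55.020000,ok
```

i.e. 55.06% of the peripapillary ring is vessel at Otsu threshold 75, with
per-sector densities alongside. `octaquant macula` is the macular analog;
`--format XLSX` mirrors any table to Excel, and `octaquant phantom` writes
synthetic angiograms with exact ground truth for validation. Everything is
also available as a library (`octaquant.density_report`,
`octaquant.segment_faz`, ...).

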