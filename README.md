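# uavpheno

Plot-level sorghum **plant and head counting** from single-capture multispectral
UAV imagery — without orthomosaic stitching. Each breeding plot is analysed in
the one raw capture that views it closest to nadir, preserving the original
spatial and spectral resolution.

The pipeline:

1. **Radiometric calibration** — raw 16-bit DNs → spectral radiance (vendor
   model with vignette polynomial, black level, exposure, gain, row-dependent
   terms) → surface reflectance via a calibrated reference panel.
2. **Band alignment** — the five lenses are not hardware-registered; per-band
   transforms onto the green band are estimated by enhanced-correlation
   maximisation on gradient-magnitude images (per-capture or per-flight
   median mode).
3. **Reverse calculation** — world-space plot polygons and row lines (rows
   buffered ±10 cm) are lifted through the DSM and projected into every
   capture with its 3×4 P matrix; the fully contained view nearest the image
   centre is selected per plot (nadir selection) and the plot sub-image
   extracted.
4. **Plant counting** — OSAVI → per-image OTSU threshold → morphological
   open/close → 8-connected blob count per data row.
5. **Head counting** — two-step masking (GEMI OTSU removes soil, NDVI_RE < 0.3
   removes leaves), contour circularity (4πA/P²) per cluster, Gaussian-KDE
   local minima split clusters into single/double/triple heads, and
   `n_heads = singles + 2·doubles + 3·triples`.

A first-class **synthetic scene generator** (`uavpheno.synth`) renders complete
flights — raw DN bands with injected vignette and band misregistration, panel
capture, camera solutions, DSM, GeoJSON layout — with exact per-plot ground
truth, so the whole pipeline is testable offline.

## CLI

```bash
# generate a synthetic flight with ground truth
uavpheno simulate --out flight/ --stage plants --plot-rows 4 --plot-cols 5 --seed 1

# inspect per-band reflectance calibration factors
uavpheno calibrate flight/

# estimate per-flight band homographies (written as CSV)
uavpheno align flight/ --out flight/out

# run the full pipeline (writes plant_counts.csv / head_counts.csv / coverage.csv)
uavpheno run-all flight/ --stages plants
uavpheno count-heads flight/
```

Inputs for real data follow the same layout `simulate` writes: one directory
per capture with five single-band TIFFs plus a `meta.yaml` of calibration
metadata, a `cameras.csv` of P matrices and positions, a DSM TIFF with a
geotransform sidecar, a GeoJSON plot/row layout, and a reference-panel
capture directory. Configuration is YAML (`PipelineConfig`), with
paper-matching defaults (NDVI_RE threshold 0.3, 10 cm row buffer, 256 OTSU
bins).

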