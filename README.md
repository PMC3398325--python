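# chromaseg

Extraction of chromatin-rich (tumour-nest-like) regions from H&E-stained
photomicrographs, with a pixel-wise evaluation scheme and a synthetic phantom
generator for validating the pipeline without clinical data.

The pipeline has four stages:

1. **Pre-processing** — RGB → optical density (`od = −log10((i+1)/256)`),
   stain separation by inverting an orthonormalized H&E basis, retention of the
   8-bit haematoxylin channel, linear contrast stretch (0.35 % tail saturation
   by default). A comparison mode replaces all of this with a plain grayscale
   conversion.
2. **Segmentation** — isodata (Ridler–Calvard intermeans) automatic threshold;
   dark (stain-dense) pixels become foreground.
3. **Morphological repair** — bright-outlier median removal, binary closing
   (3×3, 1 iteration), dark-outlier median removal.
4. **Particle filtering** — 8-connected component labeling; components smaller
   than 750 pixels are discarded.

Predictions are scored per pixel against ground-truth masks (TP/FP/FN/TN by
mask subtraction) as sensitivity, specificity, PPV and NPV, macro-averaged per
subtype group.

## CLI

```bash
# generate a 9-image synthetic suite (images/, truth/, manifest.csv)
chromaseg simulate --out data/sim --n 9 --seed 17

# single image -> mask (PNG/TIFF), optionally dumping per-stage images
chromaseg run data/sim/images/image_000.png --out mask.png --debug-dir stages/

# batch: run + evaluate a directory against truth masks
chromaseg batch --images data/sim/images --truth data/sim/truth \
    --subtype-map subtypes.csv --out results/

# the same batch without colour deconvolution (grayscale comparison)
chromaseg batch --images data/sim/images --truth data/sim/truth \
    --subtype-map subtypes.csv --out results/ --grayscale

# evaluate pre-computed prediction masks only
chromaseg eval --pred preds/ --truth data/truth --out results/
```

`--subtype-map` is a CSV with `image_id,subtype` columns. `batch` writes
`metrics_<mode>.csv` (one row per image) and `summary_<mode>.csv` (per-group
macro-averages). Every stage parameter can be set in a YAML config passed via
`--config`; CLI flags (`--threshold`, `--min-size`, `--connectivity`,
`--grayscale`) override it. Exit codes: 0 success, 1 usage error, 2 processing
error.

Example config:

```yaml
mode: deconvolution
stains:
  vector_h: [0.644211, 0.716556, 0.266844]
  vector_e: [0.092789, 0.954111, 0.283111]
  contrast_saturation: 0.0035
morphology:
  bright_radius: 2
  bright_deviation: 50
  dark_radius: 2
  dark_deviation: 50
  close_se_halfwidth: 1
  close_iterations: 1
particles:
  min_area: 750
  connectivity: 8
segmentation:
  threshold: auto
```

## Package layout

| module | purpose |
| --- | --- |
| `chromaseg.image_io` | raster I/O, mask encoding conventions |
| `chromaseg.stains` | OD transform, stain basis, deconvolution, contrast, grayscale |
| `chromaseg.segmentation` | histogram, isodata threshold, dark binarization |
| `chromaseg.morphology` | outlier-removal median filter, binary closing, repair |
| `chromaseg.particles` | component labeling, minimum-area filter, summaries |
| `chromaseg.evaluation` | confusion counts, SE/SP/PPV/NPV, macro-averaging |
| `chromaseg.phantom` | synthetic H&E phantoms with exact ground truth |
| `chromaseg.pipeline` / `chromaseg.cli` | orchestration, batch evaluation, CLI |
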