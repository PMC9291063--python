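# phasormp

Spectral-phasor analysis of hyperspectral (lambda-stack) fluorescence
images for detecting, classifying and quantifying microplastics stained
with a solvatochromic dye.

Every pixel of a lambda stack holds an emission spectrum. The package
maps each spectrum to its spectral phasor — the normalized real and
imaginary parts of the spectrum's first Fourier harmonic — so that pixels
with similar spectra cluster into clouds in a polar plot. Circular
cursors drawn on those clouds segment the image into polymer classes
(PP, LDPE/HDPE, PS, PET), connected components of the segmentation are
the detected particles, and per-class areas/counts give the composition
of the sample. A synthetic-scene generator with ground truth makes the
whole pipeline testable without an instrument, and an FTIR peak-matching
module identifies polymers from characteristic infrared absorption peaks.

## Layout

| module | contents |
|---|---|
| `phasormp.spectral` | `WavelengthAxis`, `EmissionSpectrum`, `SpectralImage`, normalization, spectral center of mass |
| `phasormp.io` | multi-page TIFF lambda stacks + YAML axis sidecars, bulk spectrum CSVs |
| `phasormp.phasor` | `compute_phasor`, per-image `phasor_image`, weighted `combine_phasors`, phasor-plot rendering |
| `phasormp.classify` | circular `Cursor` selection, `classify_pixels`, k-means `auto_cursors`, particle extraction, composition fractions, mosaic aggregation |
| `phasormp.synthetic` | stand-in polymer reference spectra (editable YAML), scene generator with shot noise and ground truth, RGB preview |
| `phasormp.ftir` | FTIR reference table, greedy peak matching, peak detection from raw curves |
| `phasormp.pipeline` / `phasormp.cli` | configuration, full-run orchestration, benchmark harness, `phasormp` CLI |

Phasor conventions: the phase uses channel offsets from the axis start;
the period defaults to the axis span and is overridable. The math is
implemented verbatim (counterclockwise-increasing angle); the
conventional clockwise-with-redshift view is applied only when plotting,
by inverting the displayed Y axis.

The default polymer emission spectra in
`src/phasormp/data/polymer_references.yaml` are **synthetic stand-ins**
(no published numeric emission maxima exist for them); edit the file to
use measured spectra.

## CLI

```sh
# generate a synthetic 256x256 lambda stack with ground truth
phasormp simulate --out sim/ --seed 1

# full pipeline: phasor -> cursors -> selection map -> particles -> report
phasormp run sim/scene.tif --auto-k 4 --out results/
# ...or with an explicit cursor set
phasormp run sim/scene.tif --cursors cursors.yaml --out results/

# individual stages
phasormp phasor sim/scene.tif --out phasors/
phasormp classify sim/scene.tif --auto-k 4 --out classified/
phasormp quantify classified/scene_particles.csv --out fractions.json

# identify a polymer from an FTIR peak list (or raw spectrum with --spectrum)
phasormp ftir-id peaks.csv

# score pipeline recovery on seeded synthetic scenes
phasormp benchmark --replicates 5 --out bench.csv
```

`phasormp run` writes per-tile phasor maps (TIFF + CSV), phasor plots,
colored selection maps with JSON legends, particle tables (CSV), the
aggregated composition report (`report.json` / `report.md`) and the fully
resolved configuration, so every run is reproducible from its output
directory.

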