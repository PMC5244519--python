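# retinomapper

Analysis pipeline for widefield intrinsic-signal optical imaging (ISOI)
retinotopy in mouse visual cortex, paired with a forward simulator that
provides ground truth for parameter-recovery testing.

The pipeline implements the classical phase-encoded mapping workflow:

1. **Binning** — raw 12-bit movies (30 fps) are sum-binned 4× temporally
   and 2×2 spatially into 16-bit movies at 7.5 fps
   (`retinomapper.movie_io`).
2. **Fourier mapping** — each pixel's time course is projected onto the
   stimulus frequency (1 cycle / 8 s), yielding magnitude (fractional
   modulation) and phase maps; phase encodes the preferred bar position
   (`retinomapper.fourier_mapping`).
3. **Fidelity gate** — animals whose retinotopic maps fall below a
   calibrated SNR threshold are excluded.
4. **Segmentation** — visual-field-sign (retinotopic Jacobian sign)
   reversals partition cortex into V1 and five higher visual areas (LM,
   LI, AL, RL, merged AM/PM); manually drawn label masks can be imported
   instead (`retinomapper.segmentation`).
5. **Quantification** — a responsive-cortex mask (5×5 Gaussian filter +
   threshold) gates per-area means of the unfiltered magnitude map, which
   are normalized to V1 within each animal
   (`retinomapper.response_quant`).
6. **Statistics** — one-way and two-way ANOVA (Type-III SS for unbalanced
   designs) with Bonferroni post hoc tests, plus simulation-based type-I
   error and power utilities (`retinomapper.cohort_stats`).

`retinomapper.isoi_sim` simulates 12-bit camera movies from a cortical
sheet model (affine retinotopy per area, mirror-image borders, raised-
cosine response waveform, hemodynamic delay, white/drift/physiological
noise) and fast response-level cohorts for statistical calibration.

## CLI

```sh
retinomapper simulate --out sim/ --seed 1 --n-cycles 10
retinomapper bin --in sim/azimuth.tif --out azimuth_binned.tif
retinomapper map --azi sim/azimuth.tif --elev sim/elevation.tif \
                 --grating sim/grating.tif --out maps/
retinomapper segment --maps maps/ --out labels.tif
retinomapper quantify --mag maps/grating_magnitude.tif \
                      --labels labels.tif --out table.csv
retinomapper stats --table cohort.csv --design oneway:genotype
retinomapper run-all --config cohort.yaml --out results/
```

Movies are multi-page 16-bit TIFFs with a JSON metadata sidecar
(stimulus spec, screen geometry, frame rate) written alongside.

## Conventions

- Pixel origin top-left, row-major, y increasing downward.
- Intrinsic signals are reflectance *decreases* on activation; magnitude
  maps are sign-free and the phase offset of π is handled by
  `fourier_mapping.response_phase(signal_sign=-1)`.
- Response phase increases with time-of-response within the cycle;
  `ComplexResponseMap.phase` stores the raw argument of the
  `exp(-i 2π f t)` projection in [−π, π).
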