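# laminq

Quantification of the nuclear lamina in confocal and STED fluorescence
microscopy: apparent **layer thickness** from Gaussian-fitted perpendicular
rim profiles, and **lamin A/C–lamin B1 colocalization** from
Costes-thresholded Pearson correlation — together with a ground-truthed
synthetic lamina image simulator that makes every stage of the pipeline
verifiable.

## The problem

The nuclear lamina is a filamentous meshwork of A- and B-type lamins lining
the inner nuclear membrane. Its true thickness (~14 nm) sits far below the
resolution of confocal scanning laser microscopy (CSLM, effective FWHM
~241 nm) and even of STED microscopy (~60 nm). Two consequences drive this
package:

1. **The measured layer thickness is a resolution readout.** An intensity
   profile drawn perpendicular to the rim at the nuclear mid-plane and fitted
   with a Gaussian yields FWHM = 2√(2 ln 2)·σ. For a sub-resolution layer
   this apparent width is dominated by the point-spread function, so the
   smallest FWHM in a dataset estimates the effective resolution, and
   CSLM-vs-STED comparisons show a large systematic gap.
2. **Resolution inflates apparent colocalization.** Pearson's correlation of
   lamin A/C and lamin B1 pixel intensities (with channel thresholds chosen
   automatically by the Costes regression-scan procedure) is systematically
   higher under a wide PSF, which blends the two networks; STED reveals
   network segregation — e.g. in laminopathy patient fibroblasts — that
   confocal imaging averages away.

Because raw microscopy data for such studies are rarely deposited, the
package ships a simulator: a supersampled two-channel lamina scene (elliptical
mid-plane rim or top-of-nucleus filament meshwork with a tunable shared
fraction ρ and radial channel offset) convolved with a Gaussian PSF, binned
to detector pixels, and corrupted with Poisson + Gaussian noise. Every
measurement can therefore be checked against known ground truth.

## Worked example

```sh
python examples/simulate_and_measure_thickness.py
```

```
true lamina thickness: 14.0 nm
confocal: measured FWHM  247.8 ± 15.7 nm (5/5 positions; forward model predicts 241.2 nm)
    sted: measured FWHM   62.5 ±  3.1 nm (5/5 positions; forward model predicts 60.8 nm)
```

A 14 nm shell reads out as ~241 nm under confocal and ~60 nm under STED
optics: the measurement returns the effective resolution of each modality,
exactly as the forward model (top-hat ⊗ Gaussian PSF) predicts. The other
examples cover colocalization recovery across ρ
(`colocalization_recovery.py`), Richardson–Lucy restoration
(`deconvolution_sharpening.py`), the published patient-fibroblast Pearson
table (`published_pearson_comparison.py`), and a configured end-to-end run
(`full_pipeline.py`).

The same stages are available from the shell:

```sh
laminq simulate --view mid --modality sted --seed 1 --out cell.ome.tif
laminq thickness cell.ome.tif --psf-fwhm-nm 60 --out thickness.csv
laminq simulate --view top --rho 0.5 --modality sted --seed 1 --out top.ome.tif
laminq coloc top.ome.tif --out coloc.csv
laminq run config.yaml
```

## What the library computes

- `simulate`: `SceneConfig`/`OpticsConfig` → `build_lamina_scene` →
  `render_image` (`ImageStack`), plus the ground-truth oracle `true_pearson`.
- `thickness`: `segment_rim` (sub-pixel rim trace with outward normals) →
  `sample_profiles` (five equally spaced perpendicular lines) →
  `fit_gaussian_profile` (Gaussian + smoothed two-level baseline) →
  `measure_thickness` (per-cell mean ± SD with position bookkeeping).
- `colocalization`: `pearson`, `costes_thresholds` (orthogonal regression +
  descending threshold scan until the below-threshold pixels decorrelate),
  `coloc_report`, `dual_profile`.
- `deconvolution`: `richardson_lucy` with the 40-iteration cap and an
  SNR-derived stopping tolerance (`estimate_snr` = 3·√(max/min⁺)).
- `stats`: `welch_t_test` (two-sided, unequal variances), the significance
  star convention, and `build_table` group comparisons.
- `io`/`pipeline`: OME-TIFF round-trips with pixel-size metadata and a
  deterministic, config-hashed end-to-end runner.

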