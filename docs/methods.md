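# Methods

This note documents the models, conventions and numerical choices behind
laminq, in the spirit of a methods appendix: what is assumed, which knobs
matter, and what the synthetic validation does and does not demonstrate.

## Scene model and rendering

**Geometry.** A mid-plane scene is an elliptical shell (semi-axes default
3.5 × 2.5 µm) of radial width `true_thickness` (default 14 nm, the
physiological lamina thickness), rendered as a partial-coverage band on a
supersampled raster (default 5 nm pitch), plus a uniform nucleoplasmic
interior at `nucleoplasm_level` (default 0.1 of the rim peak — diffuse
intranuclear lamin signal is routinely visible on the interior side of rim
profiles). The signed distance to the ellipse uses a first-order normal
approximation, exact to sub-nanometre for a nm-thin shell on a µm-scale
nucleus. A top-of-nucleus scene is a random straight-filament meshwork
(default 2 filaments/µm², mean segment length 1.5 µm, exponential lengths
clipped to [0.15, 3]× the mean): a deliberately minimal generator that
controls overlap statistics without pretending to be a polymer model. A
fraction ρ of the filament skeleton is copied into both channels; the rest
is drawn per channel from independent substreams, so changing ρ never
reshuffles the shared filaments. Channel B can be displaced outward by
`radial_offset` (patient-cell literature motivates 15–20 nm): along the rim
normal in mid-plane scenes, and radially in-plane in top views (the lateral
component of a shell-radius offset near the nuclear apex).

**Shared footprint.** Both top-view channels are multiplied by a common
elliptical envelope (flat to 0.8 of the normalized radius, cosine taper to
zero at 1.0). Real top-of-nucleus images always share this structure — the
meshwork fades where the curved surface leaves the focal plane — and without
it two fully independent networks (ρ = 0) have exactly zero expected
covariance, which leaves the Costes regression slope undefined about half
the time. The envelope makes ρ = 0 a measurable condition rather than a
degenerate one.

**Optics.** The effective PSF is an isotropic 2D Gaussian parameterized by
FWHM: 241 nm (confocal) and 60 nm (STED) by default, the smallest
line-profile FWHM observed for each modality. The supersampled scene is
convolved (reflect padding), box-integrated onto detector pixels (default
30 nm), scaled so the brightest noiseless pixel has expectation
`photons_peak` (default 200 — a realistic peak photon count for
antibody-labelled lamins in both modalities), then Poisson shot noise and
Gaussian read noise (SD 2 counts) are applied and the result clipped at
zero. z-stacks (default 3 slices, 100 nm step) weight each slice by an
axial Gaussian (default 600 nm FWHM); analysis uses the middle slice,
mirroring single-plane analysis of small stacks. Rendering is byte-stable
given (scene, seed, optics).

## Thickness measurement

The rim is segmented automatically: Otsu threshold on a σ = 2 px smoothed
copy, hole filling, largest connected component, morphological closing, then
a marching-squares contour resampled to 400 points. Each point is refined
along its outward normal onto the intensity ridge by quadratic sub-sample
interpolation around the profile peak, evaluated on a lightly smoothed copy
(σ = 1 px): heavier smoothing measurably drags the peak toward the brighter
interior flank because the profile is asymmetric (nucleoplasm inside,
nothing outside). Normals come from tangents of a more heavily smoothed
copy of the trace, so sub-pixel jitter does not tilt them. Manually drawn
rims can be passed in place of the segmentation.

Profiles are sampled at five anchors equally spaced in arc length (the
standard five-positions-per-cell protocol), bilinearly interpolated at
spacing pixel/3 over ± 3 PSF FWHM, with distance signed (negative =
nucleoplasm side). Each profile is fitted with
`A·exp(−(x−c)²/2σ²) + b_in + (b_out−b_in)·Φ((x−c)/σ)` — a Gaussian over a
step baseline smoothed by the same σ, absorbing the interior lamin signal.
A fit is accepted when R² ≥ 0.8 and σ stays inside
[spacing/2, half-length/2]; rejected positions are counted but excluded from
the per-cell mean ± SD (sample SD, n−1), which operationalizes the field
practice of dropping rim positions without a clean single peak. FWHM is
always 2√(2 ln 2)·σ, exactly.

**Digitization correction.** Box integration over detector pixels adds
p²/12 of variance to any profile and bilinear resampling adds a tent-kernel
p²/6 (independent of line orientation); at STED scale (σ ≈ 26 nm, p = 30 nm)
these alone inflate the apparent FWHM by ~10%. Since both kernels are known
exactly, the default pipeline subtracts p²/4 from the fitted σ² so the
reported width estimates the *optical* profile (layer ⊗ PSF); the raw
digitized width is recoverable as √(σ² + p²/4), and the correction can be
switched off (`sampling_correction=False`). With it, a simulated 14 nm
lamina under 60 nm STED optics reads 60–61 nm, matching the closed-form
forward model (`expected_apparent_fwhm`: top-hat ⊗ Gaussian, half-maximum
width found by bracketed root-finding).

Validation of the broadening law (fitted σ ≈ √(σ_t² + σ_p²) for a
Gaussian-profile rim, within 2%) is run on a 10 nm detector grid with
2.5 nm supersampling, where residual digitization is negligible compared to
the tolerance; pixel geometry is a free acquisition parameter, and the fine
grid is the faithful way to isolate the optical closed form.

## Colocalization

Pearson's product-moment coefficient is computed over an explicit pixel
set. Costes thresholds come from an orthogonal (total least squares)
regression `ch2 = a·ch1 + b` — the principal axis of the centred intensity
scatter — followed by a scan of T1 down the sorted unique intensities of
channel 1 with T2 = a·T1 + b locked to the line, stopping at the first T1
whose below-both-thresholds pixel set has Pearson ≤ 0 (or fewer than two
usable pixels). The scan is evaluated with prefix sums over pixels ordered
by max(ch1, (ch2−b)/a), which reproduces the literal descending sweep
exactly at O(n log n). Anti-correlated channels (a ≤ 0) have no valid
thresholds and raise an error recommending the global coefficient. The
below-either variant is available behind a flag. Reports expose
`pearson_global` (all pixels), `pearson_coloc` (above threshold in either
channel — the default comparison statistic), and the re-evaluated below-set
coefficient. Raw p-values are reported without multiplicity adjustment.

Dual-channel line profiles are sampled bilinearly at pixel/3 spacing and
normalized each to its own maximum, the convention of published rim
intensity plots.

## Deconvolution

Classic Richardson–Lucy multiplicative iteration with a Gaussian PSF
(mirror boundary; the symmetric kernel is its own adjoint), capped at 40
iterations. The SNR is estimated as 3·√(max/min⁺) from the image histogram;
min⁺ is the smallest strictly positive value, since the literal minimum of a
background-subtracted image is routinely zero. The stopping tolerance is
1/SNR² on the relative L1 change per iteration — a stated convention mapping
an image-quality estimate onto a stopping rule; both knobs are
configurable. Restoration preserves non-negativity by construction and
conserves flux to well under 1%. Deconvolution is optional in the pipeline:
every measurement property holds with and without it.

## Statistics

Group comparisons use the unequal-variance (Welch) two-sided t-test with
Satterthwaite degrees of freedom — what "Student's t-test, unequal
variances" means operationally — annotated with the star convention
\* p ≤ 0.05, \*\* p ≤ 0.01, \*\*\* p ≤ 0.001, \*\*\*\* p ≤ 0.0001
(thresholds inclusive). Tables report mean ± sample SD with n per group,
all pairwise Welch tests within strata, and the smallest measured FWHM as
the dataset's effective-resolution summary. t-tests default to per-cell
means (positions pooled within a cell first); per-position testing is
available by feeding the un-aggregated rows.

## What the synthetic validation shows — and does not

Passing tests demonstrate that the measurement chain is unbiased and
well-calibrated *for the scene model*: thin smooth shells, straight-segment
meshworks, Gaussian PSFs, Poisson + Gaussian noise. Real images add
structured background, labelling stochasticity, antibody-complex offsets,
aberrations and depth-dependent PSFs, none of which are emulated; absolute
agreement with any particular experiment is therefore not claimed. The
direction and approximate magnitude of the two headline effects —
apparent thickness tracking the PSF, and wide-PSF inflation of measured
colocalization — are robust consequences of the forward model, not of
tuned parameters. Photon budgets and background levels are simulator
choices (no published values exist for the motivating experiments).

At high overlap (ρ ≳ 0.75) the confocal-vs-STED colocalization gap shrinks
toward the per-image sampling noise, so the strict per-seed ordering is
validated at intermediate overlap (ρ = 0.5) and as a trend elsewhere; the
ground-truth (noiseless) ordering holds at every ρ < 1 tested.

## Problem sizes

Validation suites run on compact scenes (nucleus semi-axes 2.0 × 1.5 µm for
mid-plane, 3.0 × 2.2 µm for top views; 10 cells or seeds per property;
2,000 replicates for the Welch null calibration) — sizes chosen so the
whole suite re-runs in a few minutes on one CPU while keeping every
statistical check comfortably powered.

## Known limitations

- The Gaussian effective PSF ignores the STED donut's non-Gaussian tails
  and depth-dependent aberrations.
- Axial structure is schematic (Gaussian slice weighting of a 2D scene);
  no 3D thickness measurement.
- The meshwork generator controls overlap but not physical persistence
  length, junction topology, or face-size statistics of real lamin
  networks.
- The rim segmenter assumes a single dominant, roughly convex nucleus;
  dysmorphic shapes (herniations, deep invaginations) need manual rims.
- The SNR→stopping-tolerance mapping for Richardson–Lucy is a convention,
  not an estimate of any commercial implementation's internals.
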