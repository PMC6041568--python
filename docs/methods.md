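# Methods

`ricespec` re-creates, end to end and on fully synthetic data, a near-surface
imaging-spectroscopy analysis of paddy-rice leaf nitrogen concentration (LNC,
% of leaf dry mass): reflectance calibration, pixel-class separation,
vegetation-index (VI) and multivariate regression of LNC, and a sensitivity
analysis of all of it against spatial resolution. This note documents the
models, the choices that were genuinely open, and what the synthetic results
do and do not show.

## Pipeline

1. **Radiometric calibration.** Raw sensor counts are converted to relative
   reflectance with the empirical-line equation
   `Ref = (DN_target − DN_dark) / (DN_panel − DN_dark) · Ref_panel`,
   using a dark-current vector and a white-reference panel (default panel
   reflectance 0.99). Dark current is treated as a per-band vector, which
   matches pushbroom sensor physics; a per-pixel dark frame would calibrate
   identically through the same code path.
2. **MNF denoising.** The noise covariance is estimated from single-pixel
   horizontal shift differences within scan lines (signal cancels where the
   image is spatially smooth; the residual is ~2x the noise covariance). The
   data are noise-whitened, the top-k whitened principal components retained
   and the transform inverted. k defaults to the number of components with an
   SNR eigenvalue above 2. The estimator assumes spatially smooth scenes;
   on images whose pixels are statistically independent it misreads signal
   as noise, so the test fixtures use smooth abundance fields.
3. **Spectral subset.** Bands outside 400–900 nm are discarded (VNIR sensors
   are noisy outside this window even after smoothing). Processing order is
   calibrate → denoise → subset.
4. **Crop and resolution ladder.** Only the middle half of the swath is kept
   (wide-FOV pushbroom edges carry strong view-angle effects). Resolutions
   are generated by halving the swath width repeatedly — for a 1.3 mm base
   over a 450 mm swath this gives the ten nominal levels 1.3, 2, 4, 7, 14,
   28, 56, 113, 225, 450 mm — and realized by N×N block averaging with
   N = round(nominal / base). Both the nominal label and the realized
   resolution (base × N) are stored, because the labels are not exact
   multiples of the base pixel size. Blocks that do not fit are dropped, not
   padded (padding would bias edge-block spectra). The coarsest level is not
   aggregated at all: the whole cropped image collapses to about one pixel,
   so every leaf pixel type is assigned the whole-image mean spectrum there.
5. **Classification.** Per-pixel EVI, PRI and TCARI drive a three-step
   decision tree: EVI ≤ 0.45 → background; else PRI > −0.058 → leaf,
   otherwise panicle; then TCARI splits sunlit from shaded at 0.172 (leaves)
   and 0.241 (panicles). Ties fall to the background/shaded/panicle side,
   consistent with the printed "≤" of the panicle PRI rule. EVI uses the
   standard three-band form 2.5(R800−R670)/(R800+6·R670−7.5·R470+1).
6. **Threshold adaptation.** At degraded resolutions mixed pixels shift the
   index distributions, so the cut-offs are re-solved to keep class
   *proportions* close to the base-resolution reference: three monotone 1-D
   bisections in tree order (EVI → green fraction, PRI → leaf share among
   vegetation, TCARI → sunlit shares), each to |mismatch| ≤ 0.005 or 60
   iterations. When ties or tiny pixel counts make a share unreachable, the
   nearest-achievable threshold is returned with a warning. Adaptation runs
   per stage on index maps pooled over all plots of an acquisition date (the
   per-stage, not per-plot, reading of the procedure).
7. **VIs and continuum removal.** The registry holds the 16 published
   nitrogen-related indices. VIs are computed on the class-mean spectrum
   (never as means of per-pixel VIs), with nominal wavelengths resolved by
   nearest-band lookup (error beyond 10 nm). Continuum removal divides the
   550–750 nm window by its upper convex hull.
8. **Regression.** Stage-specific models are ordinary least squares of LNC
   on one VI (linear only). Global models are PLSR (mean-centered; latent
   count by leave-one-out CV on the calibration set, choosing the smallest
   count within 0.1% of the minimum CV RMSE — a parsimony rule that is also
   invariant to duplicated samples) and GPR with an anisotropic squared-
   exponential kernel: one lengthscale per band plus a white-noise term,
   bands standardized with calibration statistics, hyperparameters by
   L-BFGS marginal-likelihood maximization from seeded restarts. A small
   lengthscale marks an informative band. Splits are always by replicate
   block (blocks 1–2 calibrate, block 3 validates; configurable), never
   random. Metrics: predictive R² = 1 − SS_res/SS_tot, RMSE in LNC %, and
   squared Spearman rank correlation ρ² (computed on all samples of a scope
   pooled, for correlation tables and profiles).
9. **Sensitivity sweep and optimum.** The sweep records ρ² (VI models) or
   validation R²/RMSE (PLSR/GPR) per resolution × leaf pixel type × method
   × stage scope. The optimal resolution is the coarsest whose metric is
   within δ of the best (δ = 0.03 by default) — a tolerance-band
   formalization of "accuracy stays stable, then deteriorates".

## Synthetic scenes

The generator emulates the study conditions: 12 treatments (2 cultivars ×
N rates 0/100/200/300 kg N/ha with one or two row spacings) × 3 replicate
blocks = 36 plots, six acquisition dates per year across two years
(432 scenes), stage labels from early tillering (ET) to late filling, LNC
declining from ~4.3% to ~1.4% with N rate ordering the trajectories, and
green fraction rising from 0.15 at early tillering (the quoted early-stage
mean) to 0.90 from booting on — the intermediate values 0.35 and 0.60 are a
monotone interpolation chosen once, since only the early-tillering value is
fixed by the source material. Panicles appear from heading (15%, then 25% of
vegetation).

Leaf optics are a parametric Gaussian-absorption model, not radiative
transfer: a flat visible baseline with a green reflectance bump, a sigmoid
red edge to an NIR plateau, and pigment absorption features at 450 and
672 nm whose depth scales with a chlorophyll proxy in [0, 1]. Crucially, the
red-edge inflection also shifts from 706 to 724 nm across the proxy range —
the red-edge shift is what gives MTCI, CI_Red-edge and TCARI-type indices
their chlorophyll sensitivity. A second mechanism matters for the *global*
models: as the canopy closes, multiple scattering raises apparent leaf
reflectance on the NIR plateau (beyond ~755 nm, where leaves are
translucent) by up to 30%. Without it, early-tillering leaves (high LNC,
low chlorophyll) and late-season leaves (low LNC, similar chlorophyll)
would be spectrally identical and a whole-season spectra→LNC model would be
ill-posed; the NIR level is the canopy-structure cue that lets PLSR and
especially GPR fit one model across all stages even though pooled LNC~VI
models fail. The boost is confined to the plateau, so the sub-750 nm
classifier and red-edge bands are unaffected. Shaded variants are darkened
(×0.58) with slightly deepened absorption (×1.05), emulating multiple
scattering at leaf scale.
Panicles are yellow-green (steep reflectance rise between 531 and 570 nm,
hence strongly negative PRI). Backgrounds are water, soil and duckweed.
The shape constants were fixed once so that every endmember lies on its
documented side of all four classification cut-offs over the whole
chlorophyll range the LNC trajectories produce; this is a design requirement
of the generator (a scene whose endmembers straddle the published thresholds
would not represent the system the thresholds were derived from), verified
across 500 library seeds. Per-library seeded jitter (0.5% sd) perturbs
amplitude constants only; band-position constants are pigment chemistry and
are held fixed.

The LNC → chlorophyll-proxy map is stage-specific: early tillering has its
own slope and intercept (young leaves: high LNC, low chlorophyll), later
vegetative and reproductive stages share one map. This emulates nitrogen
dilution and is what breaks a single whole-season LNC~VI model — the
stage-specific-models finding is therefore a property the generator encodes
and the analysis must recover, not a tautology of any single test.

Scene layout places elliptical plant hills along rows (default clump scale
8 base pixels, row spacing one third of the scene width so several rows are
always visible at desk scale). Vegetation, shade, panicle and background-
material masks are drawn by exact-count selection on spatially smooth random
fields, so realized fractions match targets to one pixel and label maps are
clumped rather than salt-and-pepper — block aggregation then mixes spectra
the way a real canopy mosaic would. Noise is multiplicative Gaussian
(sd 0.02 of reflectance) plus a band-correlated smooth baseline wiggle
scaled to 10% of the noise sd; at noise 0 every pixel equals its endmember
exactly, which the calibration round trip and classification tests exploit.

## Problem sizes

Default scenes are 128×128 pixels at 1.3 mm and 2 nm sampling (251 bands).
The replicated qualitative analyses (profile monotonicity, pixel-type
stability, stage-specific vs pooled models, interior optimum) use ten
single-year experiments at 96×96 pixels and 4 nm sampling with the
resolution ladder built from the cropped scene swath; these sizes are the
package's reference configuration for replicated runs and keep a ten-seed
battery to a couple of minutes on one core. Global PLSR/GPR accuracies are
reported at base resolution for one experiment (216 samples, 126 bands).

## Numerical choices and degenerate inputs

- Nearest-band lookup breaks ties toward the lower wavelength and reports
  the distance; VI denominators of zero yield a flagged NaN, never a zero.
- Continuum removal requires ≥3 strictly positive bands in the window; hull
  vertices are set to exactly 1 to remove floating-point residue.
- MNF regularizes a singular noise covariance with a ridge and warns;
  k equal to the band count short-circuits to the identity.
- Empty pixel classes return an explicit missing value (`None`), not zeros;
  profile cells that cannot be computed are recorded as missing.
- Aggregation factors larger than the image raise; factors leaving no
  complete block at a ladder level mark that level unusable for that scene
  size (the coarsest level is exempt via the whole-image rule).
- All stochastic components (endmember jitter, scene layout, noise, plot
  LNC, model restarts) derive from explicit seeds; equal seeds give
  bit-identical scenes and sweeps.

## What passing tests show — and what they do not

The synthetic experiments demonstrate that the *pipeline* recovers the
structure its generator encodes: monotone LNC–VI relations within stage,
their degradation under pixel mixing, the stability advantage of pooled
all-leaf spectra, and the plateau-then-decline resolution profile with an
interior optimum under the tolerance-band rule. Because the generator's
mixing scale (plant-clump size in pixels) sets the mixing onset, the
numeric optimum of a synthetic sweep depends on scene geometry; it is an
interior plateau edge, not a universal constant. Field phenomena the
generator does not emulate — specular reflection from sunlit leaves, BRDF
beyond a scalar shade factor, within-canopy LNC gradients, multi-angle
effects, real instrument noise — mean that absolute accuracies here are
optimistic upper bounds, and per-figure field correlation values are not
reproducible from synthetic data.

## Known limitations

- The endmember model is far below PROSPECT/SAIL fidelity; it is built for
  controllable ground truth, not spectral realism.
- Threshold adaptation matches class proportions, not the (unavailable)
  field threshold trajectories; the direction of threshold drift with
  coarsening is reproduced, the magnitudes are scene-dependent.
- GPR hyperparameter optimization at full spectral dimension is the
  pipeline's slow step; restarts default to 1 and the battery uses VI
  profiles, with multivariate models fitted at selected resolutions.
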