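# ricespec

Imaging-spectroscopy pipeline for estimating **leaf nitrogen concentration
(LNC, % of leaf dry mass)** in paddy rice from near-surface hyperspectral
imagery, and for asking the question such systems raise: *how coarse can the
pixels get before the estimate degrades?*

Nitrogen drives rice photosynthesis and yield, but canopy spectra measured
from above mix leaf signal with water, soil and duckweed background and, late
in the season, with panicles. Millimetre-resolution imaging spectrometers can
separate those components pixel by pixel — at a heavy cost in data volume.
`ricespec` implements the full analysis chain on synthetic rice scenes with
known ground truth:

- **Scene simulation** — 36-plot, two-year experiments (cultivar × N rate ×
  row spacing, 3 replicate blocks, 6 acquisition dates/year), parametric
  endmember spectra over 400–900 nm, stage-dependent LNC trajectories and
  green fractions, exact per-pixel class labels.
- **Cube handling** — ENVI-style header + binary I/O, empirical-line
  calibration `Ref = (DN−DN_dark)/(DN_panel−DN_dark)·Ref_panel`, 400–900 nm
  subsetting, minimum-noise-fraction denoising.
- **Spatial degradation** — middle-half crop, dyadic resolution ladder
  (1.3 → 2, 4, 7, 14, 28, 56, 113, 225, 450 mm for the field geometry) by
  N×N block aggregation.
- **Pixel classification** — EVI/PRI/TCARI decision tree separating
  sunlit/shaded leaves and panicles from background (cut-offs 0.45, −0.058,
  0.172, 0.241 at base resolution), green-fraction bookkeeping, and
  per-resolution threshold adaptation that preserves class proportions.
- **Spectral indices** — the 16 published nitrogen-related VIs (SR family,
  CI_Red-edge, NDVI, GNDVI, ND705, mND705, mSR705, MTCI, PRI, TCARI, OSAVI,
  TCARI/OSAVI, DCNI), nearest-band lookup, convex-hull continuum removal.
- **Regression** — scikit-learn style estimators: per-stage linear LNC~VI
  models, PLSR with leave-one-out latent selection, and ARD Gaussian-process
  regression whose per-band lengthscales rank spectral importance; strict
  replicate-block calibration/validation splits (288/144 global, 144/72
  reproductive, 24/12 per stage-date); R², RMSE and Spearman ρ².
- **Sensitivity analysis** — the full sweep over resolution × pixel type ×
  method, and a tolerance-band rule selecting the coarsest resolution whose
  metric stays within δ of the best.

## Worked example

```python
import numpy as np
from ricespec import (generate_endmembers, generate_scene, SceneConfig,
                      classify_pixels, class_proportions, compute_vi,
                      mean_spectrum_by_class)
from ricespec.synthetic import stage_defaults, wavelength_grid

wl = wavelength_grid(2.0)                      # 400-900 nm, 2 nm sampling
library = generate_endmembers(wl, seed=7)
d = stage_defaults("JT")                       # jointing stage defaults
cfg = SceneConfig(stage="JT", green_fraction=d["green_fraction"], lnc=2.9,
                  shade_fraction=d["shade_fraction"], seed=7)
cube, truth = generate_scene(cfg, library)

labels = classify_pixels(cube)                 # EVI/PRI/TCARI decision tree
props = class_proportions(labels)
print(f"green fraction      : {props.gf:.3f} (target {cfg.green_fraction})")
print(f"accuracy vs truth   : {np.mean(labels == truth):.3f}")

spec, n = mean_spectrum_by_class(cube, labels, "all_leaf")
for vi in ("MTCI", "CI_Red-edge", "TCARI/OSAVI"):
    print(f"{vi:<12} on {n} leaf pixels: {compute_vi(vi, spec, wl):.3f}")
```

prints

```
green fraction      : 0.600 (target 0.6)
accuracy vs truth   : 1.000
MTCI         on 9825 leaf pixels: 2.276
CI_Red-edge  on 9825 leaf pixels: 0.869
TCARI/OSAVI  on 9825 leaf pixels: 0.256
```

The classifier recovers the generator's green fraction exactly and labels
every pixel correctly on this low-noise scene; the red-edge indices computed
on the mean leaf spectrum are the inputs to the stage-specific LNC models.
A full sensitivity sweep is one call:

```python
from ricespec.sensitivity import (SweepConfig, run_resolution_sweep,
                                  select_optimal_resolution)
from ricespec.synthetic import ExperimentDesign

res = run_resolution_sweep(ExperimentDesign(years=(2014,)), seed=1,
                           config=SweepConfig())
print(select_optimal_resolution(res.profile, scope="RP",
                                pixel_type="all_leaf", method="vi:MTCI"))
```

A CLI mirrors the library: `ricespec simulate`, `ricespec sweep`,
`ricespec report` (see `--help`).

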