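"""Synthetic hyperspectral rice scenes with known ground truth.

This module emulates the statistical structure of near-surface hyperspectral
acquisitions over paddy-rice plots: a two-year, 36-plot experiment (12
cultivar x N-rate x row-spacing treatments, 3 replicate blocks), six
acquisition dates per year spanning early tillering to grain filling, ~1.3 mm
pixels over 400-900 nm, and per-plot leaf nitrogen concentration (LNC)
declining from ~4.3% to ~1.4% of dry mass across the season.

Scenes are linear compositions of parametric endmember spectra (sunlit and
shaded leaves and panicles, water, soil, duckweed).  Leaf optics use a
Gaussian-absorption model: a flat visible baseline plus red-edge sigmoid, with
pigment absorption features near 450 and 680 nm whose depth follows a
chlorophyll proxy mapped from LNC with a stage-specific slope (the N-dilution
effect that breaks a single whole-season LNC~VI model).  Shaded variants are
darkened copies with deepened absorption, emulating multiple scattering.

Every sampled fraction (green fraction, shade share, panicle share) is
realized by exact-count selection on spatially smooth score fields, so
generated label maps are clumped (plant hills in rows) rather than
salt-and-pepper, and realized fractions match their targets to within one
pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .cube import CalibrationFrames, SpectralCube

__all__ = [
    "EndmemberLibrary",
    "SceneConfig",
    "ExperimentDesign",
    "CLASS_CODES",
    "CLASS_NAMES",
    "STAGE_PHASES",
    "stage_chl_map",
    "stage_defaults",
    "generate_endmembers",
    "generate_scene",
    "generate_experiment",
    "generate_dn_frames",
]

# per-pixel class codes (ClassMap convention, documented in ENVI headers)
CLASS_CODES = {
    "background": 0,
    "sunlit_leaf": 1,
    "shaded_leaf": 2,
    "sunlit_panicle": 3,
    "shaded_panicle": 4,
}
CLASS_NAMES = {v: k for k, v in CLASS_CODES.items()}

# canonical phenological phases; per-year stage labels map onto them
STAGE_PHASES = {
    "ET": 0, "LT": 1, "JT": 2,
    "EB": 3, "LB": 3, "BT": 3,
    "HD": 4,
    "EF": 5, "LF": 5, "FL": 5,
}
VEGETATIVE_PHASES = (0, 1, 2)

# stage-phase defaults: green fraction, shade share, panicle share, mean LNC (%)
_PHASE_GREEN_FRACTION = (0.15, 0.35, 0.60, 0.90, 0.90, 0.90)
_PHASE_SHADE_FRACTION = (0.25, 0.30, 0.35, 0.40, 0.40, 0.40)
_PHASE_PANICLE_FRACTION = (0.0, 0.0, 0.0, 0.0, 0.15, 0.25)
_PHASE_LNC_BASE = (4.10, 3.50, 2.90, 2.20, 1.90, 1.60)

# N-rate multipliers on the LNC trajectory (N0..N3, kg N/ha 0/100/200/300)
_N_RATE_MULT = (0.80, 0.92, 1.00, 1.08)


def wavelength_grid(step_nm: float = 2.0) -> np.ndarray:
    """Uniform grid from 400 nm with full coverage of 400-900 nm."""
    n_bands = int(np.ceil(500.0 / step_nm)) + 1
    return 400.0 + step_nm * np.arange(n_bands)


def stage_chl_map(stage: str) -> tuple[float, float]:
    """(slope, intercept) of the stage-specific LNC -> chlorophyll-proxy map.

    Early tillering has high LNC but low chlorophyll (young, thin leaves), so
    its map differs in both slope and intercept; later vegetative and all
    reproductive stages share one map.  The proxy is clipped to [0.08, 1].
    """
    phase = STAGE_PHASES[stage]
    if phase == 0:
        return 0.075, -0.05
    return 0.24, -0.06


def _chl_from_lnc(stage: str, lnc: float) -> float:
    slope, intercept = stage_chl_map(stage)
    return float(np.clip(slope * lnc + intercept, 0.08, 1.0))


def stage_defaults(stage: str) -> dict:
    """Default green/shade/panicle fractions and mean LNC for a stage label."""
    phase = STAGE_PHASES[stage]
    return {
        "green_fraction": _PHASE_GREEN_FRACTION[phase],
        "shade_fraction": _PHASE_SHADE_FRACTION[phase],
        "panicle_fraction": _PHASE_PANICLE_FRACTION[phase],
        "lnc": _PHASE_LNC_BASE[phase],
    }


# ---------------------------------------------------------------------------
# Endmember library
# ---------------------------------------------------------------------------

def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _gauss(wl, center, sigma):
    return np.exp(-0.5 * ((wl - center) / sigma) ** 2)


@dataclass
class EndmemberLibrary:
    """Parametric reflectance endmembers on a common wavelength grid.

    Leaf spectra are a function of the chlorophyll proxy (0..1); panicle and
    background spectra are fixed.  ``params`` holds the shape constants, with
    a small seeded jitter so different seeds give slightly different (but
    internally consistent) optical libraries.
    """

    wavelengths: np.ndarray
    params: dict = field(default_factory=dict)

    ROLES = ("sunlit_leaf", "shaded_leaf", "sunlit_panicle", "shaded_panicle",
             "water", "soil", "duckweed")

    # -- leaves ------------------------------------------------------------
    def leaf(self, chl: float, shaded: bool = False,
             nir_scale: float = 1.0) -> np.ndarray:
        """Leaf reflectance at chlorophyll proxy ``chl`` (0 = no pigment).

        Pigment load both deepens the blue/red absorption features and shifts
        the red edge toward longer wavelengths — the red-edge shift is what
        gives MTCI / CI_Red-edge / TCARI-type indices their chlorophyll (and
        hence nitrogen) sensitivity.  ``nir_scale`` raises the NIR plateau
        with canopy density (LAI-driven multiple scattering): apparent leaf
        NIR grows as the canopy closes, which is what lets whole-spectrum
        models separate growth stages that share a chlorophyll level.
        """
        p = self.params
        wl = self.wavelengths
        edge = p["edge_center"] + p["edge_shift"] * float(chl)
        # canopy scattering amplifies reflectance only where leaves are
        # translucent (the NIR plateau), not at the strongly absorbed
        # classifier bands below ~750 nm
        boost = 1.0 + (float(nir_scale) - 1.0) * _sigmoid((wl - 755.0) / 20.0)
        base = (p["leaf_vis"]
                + (p["leaf_nir"] - p["leaf_vis"]) * _sigmoid((wl - edge) / p["edge_width"]) * boost
                + p["green_bump"] * _gauss(wl, 550.0, 35.0))
        depth = p["abs_depth_max"] * float(chl)
        if shaded:
            depth = min(depth * p["shade_deepen"], 0.95)
        absorption = depth * (0.85 * _gauss(wl, 450.0, 35.0) + _gauss(wl, 672.0, 30.0))
        refl = base * (1.0 - absorption)
        if shaded:
            refl = refl * p["shade_factor"]
        return np.clip(refl, 0.0, 1.0)

    # -- panicles ----------------------------------------------------------
    def panicle(self, shaded: bool = False) -> np.ndarray:
        """Yellow-green panicle spectrum; PRI is strongly negative because
        reflectance rises steeply between 531 and 570 nm."""
        p = self.params
        wl = self.wavelengths
        base = (p["pan_base"]
                + p["pan_green_rise"] * _sigmoid((wl - 548.0) / 25.0)
                + p["pan_nir_rise"] * _sigmoid((wl - 712.0) / 16.0))
        dip = p["pan_red_dip"]
        if shaded:
            dip = dip * p["pan_shade_deepen"]
        refl = base - dip * _gauss(wl, 670.0, 32.0)
        if shaded:
            refl = refl * p["shade_factor"]
        return np.clip(refl, 0.0, 1.0)

    # -- backgrounds -------------------------------------------------------
    def water(self) -> np.ndarray:
        wl = self.wavelengths
        return 0.012 + 0.055 * np.exp(-(wl - 400.0) / 260.0)

    def soil(self) -> np.ndarray:
        wl = self.wavelengths
        return 0.12 + 0.16 * (wl - 400.0) / 500.0

    def duckweed(self) -> np.ndarray:
        wl = self.wavelengths
        return (0.075 + 0.05 * _gauss(wl, 550.0, 40.0)
                + 0.10 * _sigmoid((wl - 715.0) / 20.0)
                - 0.02 * _gauss(wl, 670.0, 30.0))

    def spectrum(self, role: str, chl: float = 0.5,
                 nir_scale: float = 1.0) -> np.ndarray:
        """Endmember spectrum for ``role`` (leaves evaluated at ``chl``)."""
        if role == "sunlit_leaf":
            return self.leaf(chl, shaded=False, nir_scale=nir_scale)
        if role == "shaded_leaf":
            return self.leaf(chl, shaded=True, nir_scale=nir_scale)
        if role == "sunlit_panicle":
            return self.panicle(shaded=False)
        if role == "shaded_panicle":
            return self.panicle(shaded=True)
        if role in ("water", "soil", "duckweed"):
            return getattr(self, role)()
        raise KeyError(f"unknown endmember role {role!r}")

    @property
    def spectra(self) -> dict[str, np.ndarray]:
        """Library snapshot at a mid-season chlorophyll proxy of 0.5."""
        return {role: self.spectrum(role) for role in self.ROLES}


_DEFAULT_ENDMEMBER_PARAMS = {
    "leaf_vis": 0.115,        # visible baseline reflectance
    "leaf_nir": 0.55,         # NIR plateau
    "edge_center": 706.0,     # red-edge inflection at chl proxy 0, nm
    "edge_shift": 18.0,       # red-edge shift per unit chl proxy, nm
    "edge_width": 12.0,       # red-edge width, nm
    "green_bump": 0.035,      # green peak amplitude at 550 nm
    "abs_depth_max": 0.48,    # pigment absorption depth at chl proxy 1
    "shade_factor": 0.58,     # brightness of shaded vs sunlit material
    "shade_deepen": 1.05,     # absorption deepening under multiple scattering
    "pan_base": 0.10,
    "pan_green_rise": 0.20,
    "pan_nir_rise": 0.16,
    "pan_red_dip": 0.19,
    "pan_shade_deepen": 1.15,
}


def generate_endmembers(wavelength_grid: np.ndarray, seed: int = 0,
                        jitter: float = 0.005) -> EndmemberLibrary:
    """Build an endmember library on ``wavelength_grid`` (must cover 400-900 nm).

    ``jitter`` applies a small seeded multiplicative perturbation (sd as a
    fraction of each shape constant) so that different seeds yield distinct
    but threshold-consistent optical libraries.
    """
    wl = np.asarray(wavelength_grid, dtype=float)
    if wl[0] > 400.0 or wl[-1] < 900.0:
        raise ValueError(
            f"wavelength grid [{wl[0]}, {wl[-1]}] nm must cover 400-900 nm"
        )
    rng = np.random.default_rng(seed)
    params = {}
    for key, value in _DEFAULT_ENDMEMBER_PARAMS.items():
        if key in ("edge_center", "edge_shift", "edge_width"):
            # band-position constants are pigment chemistry, not sample-to-sample
            # variation; jittering them shifts red-edge indices disproportionately
            params[key] = value
        else:
            params[key] = value * (1.0 + jitter * rng.standard_normal())
    return EndmemberLibrary(wl, params)


# ---------------------------------------------------------------------------
# Scene configuration and generation
# ---------------------------------------------------------------------------

@dataclass
class SceneConfig:
    """Ground-truth description of one synthetic plot scene."""

    stage: str
    green_fraction: float
    lnc: float
    shade_fraction: float = 0.35
    panicle_fraction: float = 0.0
    noise_sd: float = 0.02
    clump_scale_px: float = 8.0
    rows: int = 128
    cols: int = 128
    base_mm: float = 1.3
    row_spacing_px: float | None = None   # default: cols / 3
    seed: int = 0
    lnc_chl_slope: float | None = None    # default: stage-specific map
    lnc_chl_intercept: float | None = None
    nir_scale: float | None = None        # default: derived from green fraction

    def __post_init__(self) -> None:
        if self.stage not in STAGE_PHASES:
            raise ValueError(f"unknown stage label {self.stage!r}")
        if not 0.0 <= self.green_fraction <= 1.0:
            raise ValueError("green fraction must lie in [0, 1]")
        if not 0.5 <= self.lnc <= 5.0:
            raise ValueError("LNC must lie in [0.5, 5.0] % dry mass")
        if not 0.0 <= self.shade_fraction <= 1.0:
            raise ValueError("shade fraction must lie in [0, 1]")
        if STAGE_PHASES[self.stage] in VEGETATIVE_PHASES and self.panicle_fraction != 0.0:
            raise ValueError("panicle fraction must be 0 at vegetative stages")
        if self.clump_scale_px <= 0:
            raise ValueError("clump scale must be positive")

    @property
    def canopy_nir_scale(self) -> float:
        """NIR amplification of leaf endmembers with canopy closure.

        Grows linearly from 1.0 at a green fraction of 0.15 (open early-
        tillering canopy) to 1.3 at 0.90 (closed canopy).
        """
        if self.nir_scale is not None:
            return self.nir_scale
        return float(1.0 + 0.3 * np.clip((self.green_fraction - 0.15) / 0.75, 0.0, 1.0))

    @property
    def chl(self) -> float:
        if self.lnc_chl_slope is not None:
            intercept = self.lnc_chl_intercept or 0.0
            return float(np.clip(self.lnc_chl_slope * self.lnc + intercept, 0.08, 1.0))
        return _chl_from_lnc(self.stage, self.lnc)


def _exact_top_k_mask(score: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask selecting exactly the k highest-scoring entries."""
    mask = np.zeros(score.size, dtype=bool)
    if k > 0:
        idx = np.argpartition(score.ravel(), score.size - k)[score.size - k:]
        mask[idx] = True
    return mask.reshape(score.shape)


def _plant_score_field(cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Smooth vegetation-likelihood field: plant hills arranged in rows.

    Hills sit on a jittered grid (rows of plants at the configured row
    spacing); the score is the maximum of anisotropic radial falloffs from
    each hill center plus smooth noise, so thresholding yields contiguous
    elliptical clumps, not i.i.d. pixels.
    """
    rows, cols = cfg.rows, cfg.cols
    spacing = cfg.row_spacing_px if cfg.row_spacing_px is not None else cols / 3.0
    hill_spacing = max(spacing * 0.6, 4.0)
    col_centers = np.arange(spacing / 2.0, cols, spacing)
    row_centers = np.arange(hill_spacing / 2.0, rows, hill_spacing)
    centers = np.array([
        (r + rng.normal(0, 1.0), c + rng.normal(0, 1.0))
        for r in row_centers for c in col_centers
    ])
    rr, cc = np.mgrid[0:rows, 0:cols]
    pix = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)
    scale = cfg.clump_scale_px
    # anisotropic: clumps stretched along the planting row (row direction)
    d2 = ((pix[:, None, 0] - centers[None, :, 0]) / (1.6 * scale)) ** 2 \
        + ((pix[:, None, 1] - centers[None, :, 1]) / scale) ** 2
    score = np.exp(-d2).max(axis=1).reshape(rows, cols)
    texture = gaussian_filter(rng.standard_normal((rows, cols)), sigma=max(scale / 2.0, 1.0))
    texture = texture / max(texture.std(), 1e-12)
    return score + 0.08 * texture


def generate_scene(config: SceneConfig, library: EndmemberLibrary
                   ) -> tuple[SpectralCube, np.ndarray]:
    """Render one scene; returns ``(cube, true_class_map)``.

    The class map uses :data:`CLASS_CODES`.  Realized green fraction matches
    the configured target to within one pixel (verified, tolerance 0.02);
    shade and panicle shares are realized exactly among vegetation pixels.
    """
    rng = np.random.default_rng(config.seed)
    rows, cols = config.rows, config.cols
    npix = rows * cols
    wl = library.wavelengths

    n_veg = int(np.floor(config.green_fraction * npix + 0.5))
    if n_veg > npix:
        raise ValueError("target green fraction exceeds the image")
    score = _plant_score_field(config, rng)
    veg = _exact_top_k_mask(score, n_veg)
    realized_gf = veg.sum() / npix
    if abs(realized_gf - config.green_fraction) > 0.02:
        raise ValueError(
            f"target green fraction {config.green_fraction} unreachable at "
            f"clump scale {config.clump_scale_px} (realized {realized_gf:.3f})"
        )

    labels = np.zeros((rows, cols), dtype=np.int8)
    veg_idx = np.flatnonzero(veg.ravel())

    # panicle share among vegetation, then sunlit/shaded split of each
    pan_field = gaussian_filter(rng.standard_normal((rows, cols)),
                                sigma=max(config.clump_scale_px / 2.0, 1.0)).ravel()
    shade_field = gaussian_filter(rng.standard_normal((rows, cols)),
                                  sigma=max(config.clump_scale_px / 2.0, 1.0)).ravel()
    n_pan = int(np.floor(config.panicle_fraction * n_veg + 0.5))
    pan_order = veg_idx[np.argsort(pan_field[veg_idx])]
    pan_idx = pan_order[len(pan_order) - n_pan:] if n_pan else np.array([], dtype=int)
    leaf_idx = pan_order[: len(pan_order) - n_pan]

    def _split_shade(idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        n_sh = int(np.floor(config.shade_fraction * idx.size + 0.5))
        order = idx[np.argsort(shade_field[idx])]
        return order[idx.size - n_sh:], order[: idx.size - n_sh]   # shaded, sunlit

    shaded_leaf, sunlit_leaf = _split_shade(leaf_idx)
    shaded_pan, sunlit_pan = _split_shade(pan_idx)

    flat_labels = labels.ravel()
    flat_labels[sunlit_leaf] = CLASS_CODES["sunlit_leaf"]
    flat_labels[shaded_leaf] = CLASS_CODES["shaded_leaf"]
    flat_labels[sunlit_pan] = CLASS_CODES["sunlit_panicle"]
    flat_labels[shaded_pan] = CLASS_CODES["shaded_panicle"]

    # background composition: mostly water, with soil and duckweed patches
    bg_idx = np.flatnonzero(flat_labels == 0)
    bg_field = gaussian_filter(rng.standard_normal((rows, cols)),
                               sigma=max(config.clump_scale_px, 1.0)).ravel()
    bg_order = bg_idx[np.argsort(bg_field[bg_idx])]
    n_soil = int(0.15 * bg_idx.size)
    n_duck = int(0.10 * bg_idx.size)
    soil_idx = bg_order[: n_soil]
    duck_idx = bg_order[len(bg_order) - n_duck:] if n_duck else np.array([], dtype=int)

    chl = config.chl
    nir_scale = config.canopy_nir_scale
    spectra = {
        CLASS_CODES["sunlit_leaf"]: library.leaf(chl, shaded=False, nir_scale=nir_scale),
        CLASS_CODES["sunlit_panicle"]: library.panicle(shaded=False),
        CLASS_CODES["shaded_leaf"]: library.leaf(chl, shaded=True, nir_scale=nir_scale),
        CLASS_CODES["shaded_panicle"]: library.panicle(shaded=True),
    }
    data = np.empty((npix, wl.size), dtype=np.float64)
    data[:] = library.water()
    data[soil_idx] = library.soil()
    data[duck_idx] = library.duckweed()
    for code, spec in spectra.items():
        data[flat_labels == code] = spec

    if config.noise_sd > 0:
        data *= 1.0 + config.noise_sd * rng.standard_normal(data.shape)
        # band-correlated smooth baseline wiggle, scaled with the noise level
        wiggle = gaussian_filter(rng.standard_normal(wl.size), sigma=25.0)
        wiggle *= 0.1 * config.noise_sd / max(np.abs(wiggle).max(), 1e-12)
        data += wiggle[None, :]
        np.clip(data, 0.0, 1.2, out=data)

    meta = {"stage": config.stage, "lnc": config.lnc, "chl": chl,
            "green_fraction": config.green_fraction}
    cube = SpectralCube(data.reshape(rows, cols, wl.size), wl,
                        config.base_mm, meta)
    return cube, flat_labels.reshape(rows, cols)


# ---------------------------------------------------------------------------
# Experiment design
# ---------------------------------------------------------------------------

_YEAR_STAGES = {
    2014: ("ET", "LT", "JT", "LB", "HD", "LF"),
    2015: ("ET", "LT", "JT", "EB", "LB", "EF"),
}


def _default_treatments() -> tuple[dict, ...]:
    """12 treatments: 2 cultivars x {N0/D1, N1/D1, N1/D2, N2/D1, N2/D2, N3/D1}."""
    combos = [("N0", "D1"), ("N1", "D1"), ("N1", "D2"),
              ("N2", "D1"), ("N2", "D2"), ("N3", "D1")]
    return tuple(
        {"cultivar": cv, "n_rate": n, "density": d}
        for cv in ("V1", "V2") for (n, d) in combos
    )


@dataclass
class ExperimentDesign:
    """Two-year, 36-plot multi-date acquisition design."""

    treatments: tuple[dict, ...] = field(default_factory=_default_treatments)
    replicates: tuple[int, ...] = (1, 2, 3)
    years: tuple[int, ...] = (2014, 2015)
    stages_by_year: dict = field(default_factory=lambda: dict(_YEAR_STAGES))

    def __post_init__(self) -> None:
        for year in self.years:
            if year not in self.stages_by_year:
                raise ValueError(f"no stage list for year {year}")

    @property
    def n_plots(self) -> int:
        return len(self.treatments) * len(self.replicates)

    @property
    def n_scenes(self) -> int:
        return sum(self.n_plots * len(self.stages_by_year[y]) for y in self.years)

    def acquisitions(self):
        """Yield (year, date_index, stage) in chronological order."""
        for year in self.years:
            for d, stage in enumerate(self.stages_by_year[year]):
                yield year, d, stage

    def plots(self):
        """Yield (plot_index, treatment, replicate)."""
        i = 0
        for treatment in self.treatments:
            for rep in self.replicates:
                yield i, treatment, rep
                i += 1


def _plot_lnc(stage: str, treatment: dict, rng: np.random.Generator) -> float:
    phase = STAGE_PHASES[stage]
    base = _PHASE_LNC_BASE[phase]
    mult = _N_RATE_MULT[int(treatment["n_rate"][1])]
    cultivar = 1.03 if treatment["cultivar"] == "V2" else 1.0
    lnc = base * mult * cultivar + rng.normal(0.0, 0.12)
    return float(np.clip(lnc, 0.5, 5.0))


def generate_experiment(design: ExperimentDesign, seed: int = 0,
                        scene_kwargs: dict | None = None,
                        render: bool = True):
    """Yield one record per plot per acquisition date.

    Each record is a dict with ``cube`` and ``class_map`` (None when
    ``render=False``; metadata-only iteration is cheap and is how design
    counts are verified) plus plot/stage/treatment metadata and the true LNC.

    Scene seeds derive deterministically from ``seed`` and the (year, date,
    plot) coordinates, so records can be regenerated in isolation.
    """
    scene_kwargs = dict(scene_kwargs or {})
    lib_seed = np.random.SeedSequence([seed, 7]).generate_state(1)[0] % (2 ** 31)
    wl_step = scene_kwargs.pop("wavelength_step_nm", 2.0)
    wavelengths = wavelength_grid(wl_step)
    library = generate_endmembers(wavelengths, seed=int(lib_seed))
    for year, date_idx, stage in design.acquisitions():
        defaults = stage_defaults(stage)
        for plot_idx, treatment, rep in design.plots():
            ss = np.random.SeedSequence([seed, year, date_idx, plot_idx])
            lnc_rng = np.random.default_rng(ss.spawn(1)[0])
            lnc = _plot_lnc(stage, treatment, lnc_rng)
            gf = defaults["green_fraction"]
            if treatment["density"] == "D2":   # wider row spacing, sparser canopy
                gf = max(0.02, gf * 0.88)
            scene_seed = int(ss.generate_state(1)[0] % (2 ** 31))
            meta = {
                "year": year, "date_index": date_idx, "stage": stage,
                "plot_index": plot_idx, "replicate": rep, "lnc": lnc,
                "green_fraction": gf, **treatment,
            }
            cube = class_map = None
            if render:
                cfg = SceneConfig(
                    stage=stage, green_fraction=gf, lnc=lnc,
                    shade_fraction=defaults["shade_fraction"],
                    panicle_fraction=defaults["panicle_fraction"],
                    seed=scene_seed, **scene_kwargs,
                )
                cube, class_map = generate_scene(cfg, library)
                cube.meta.update(meta)
            yield {"cube": cube, "class_map": class_map, **meta}


# ---------------------------------------------------------------------------
# Raw-count (DN) synthesis for the calibration round trip
# ---------------------------------------------------------------------------

def generate_dn_frames(cube: SpectralCube, panel_reflectance: float = 0.99,
                       dark_level: float = 100.0, seed: int | None = None,
                       sensor_noise_sd: float = 0.0) -> CalibrationFrames:
    """Invert the empirical-line calibration: reflectance -> sensor counts.

    Builds dark-current and white-panel frames plus target counts such that
    applying the calibration equation recovers ``cube`` exactly when
    ``sensor_noise_sd`` is 0.  A reflectance-0 pixel maps to the dark level.
    """
    if not 0.0 < panel_reflectance <= 1.0:
        raise ValueError("panel reflectance must lie in (0, 1]")
    bands = cube.n_bands
    # smooth band-dependent gain emulating illumination x sensor response
    wl = cube.wavelengths
    gain = 3000.0 * (0.7 + 0.6 * np.exp(-0.5 * ((wl - 650.0) / 220.0) ** 2))
    dn_dark = np.full(bands, dark_level)
    dn_panel = dn_dark + gain
    dn_target = dn_dark + cube.data / panel_reflectance * gain
    if sensor_noise_sd > 0:
        rng = np.random.default_rng(seed)
        dn_target = dn_target + rng.normal(0.0, sensor_noise_sd, dn_target.shape)
    return CalibrationFrames(dn_target, dn_dark, dn_panel, panel_reflectance,
                             wavelengths=wl, pixel_size_mm=cube.pixel_size_mm,
                             meta=dict(cube.meta))
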