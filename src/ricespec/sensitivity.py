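"""Resolution-sensitivity sweep and optimal-resolution selection.

For every acquisition date the sweep renders the 36 plot scenes, crops the
middle half (edge view-angle effects), classifies at base resolution with the
default thresholds, then walks the resolution ladder: aggregate, re-solve the
thresholds per stage so pooled class proportions match the base-resolution
reference, classify, and average spectra per leaf pixel type.  At the
coarsest ladder entry (the whole swath collapses to about one pixel) all leaf
pixel types receive the whole-image mean spectrum instead.

From the resulting sample table it assembles sensitivity profiles — Spearman
rho^2 of LNC with representative VIs per stage scope, and validation R^2 /
RMSE of global PLSR and GPR models — indexed by resolution x pixel type x
method, and applies a tolerance-band rule to pick the optimal (coarsest
still-accurate) resolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import (
    ThresholdSet,
    adapt_thresholds,
    class_proportions,
    classify_pixels,
    coarsest_level_spectrum,
    mean_spectrum_by_class,
    pixel_index_maps,
    _classify_from_maps,
)
from .cube import subset_spectral
from .indices import VI_NAMES, compute_vi, continuum_removal
from .regression import (
    GPNitrogenRegressor,
    PLSNitrogenRegressor,
    evaluate,
    spearman_rho2,
    split_by_replicate,
)
from .spatial import aggregate, build_resolution_ladder, crop_middle_half
from .synthetic import ExperimentDesign, generate_experiment

__all__ = [
    "SweepConfig",
    "SweepResult",
    "OptimalResolutionReport",
    "extract_samples",
    "build_profile",
    "run_resolution_sweep",
    "select_optimal_resolution",
]

LEAF_PIXEL_TYPES = ("all_leaf", "sunlit_leaf", "shaded_leaf")
REPRESENTATIVE_VIS = ("CI_Red-edge", "MTCI", "TCARI/OSAVI")


@dataclass
class SweepConfig:
    """Knobs of the resolution sweep (methods, scopes, model settings)."""

    pixel_types: tuple[str, ...] = LEAF_PIXEL_TYPES
    methods: tuple[str, ...] = ("vi",)            # subset of {"vi", "plsr", "gpr"}
    vi_names: tuple[str, ...] = REPRESENTATIVE_VIS
    spectra_kinds: tuple[str, ...] = ("reflectance",)  # + "continuum_removed"
    delta: float = 0.03                            # optimal-resolution tolerance
    validation_replicate: int = 3
    adapt_tol: float = 0.005
    scene_kwargs: dict = field(default_factory=dict)
    max_plsr_components: int = 12
    gpr_restarts: int = 1


@dataclass
class SweepResult:
    samples: pd.DataFrame          # one row per scene x resolution x pixel type
    profile: pd.DataFrame          # metric per resolution x pixel type x method x scope
    ladder: object
    config: SweepConfig


@dataclass
class OptimalResolutionReport:
    scope: str
    pixel_type: str
    method: str
    resolution_mm: float
    delta: float
    metric_at_optimum: float
    metric_at_base: float


def _stage_scope(stage: str) -> str:
    """Figure-8 style scope: each vegetative stage on its own, reproductive pooled."""
    return stage if stage in ("ET", "LT", "JT") else "RP"


def extract_samples(design: ExperimentDesign, seed: int,
                    config: SweepConfig | None = None,
                    ladder=None) -> tuple[pd.DataFrame, object]:
    """Render the experiment and extract per-resolution class-mean samples.

    Returns ``(samples, ladder)``.  The ladder defaults to the dyadic ladder
    of the cropped scene swath (its coarsest entry is the whole cropped
    image, handled by the whole-image rule).  Scenes are processed one date
    at a time: thresholds adapt per stage on index maps pooled over the 36
    plots, matching the pooled base-resolution class proportions.
    """
    config = config or SweepConfig()
    records = generate_experiment(design, seed=seed, scene_kwargs=config.scene_kwargs)

    rows: list[dict] = []
    current: list[dict] = []
    current_key = None

    def flush(batch: list[dict]) -> None:
        nonlocal ladder
        if not batch:
            return
        cropped = [crop_middle_half(r["cube"]) for r in batch]
        base = cropped[0]
        if ladder is None:
            ladder = build_resolution_ladder(base.pixel_size_mm,
                                             base.shape[1] * base.pixel_size_mm)
        base_maps = [pixel_index_maps(c) for c in cropped]
        base_thr = ThresholdSet(stage=batch[0]["stage"],
                                resolution_mm=base.pixel_size_mm)
        base_labels = [_classify_from_maps(m, base_thr) for m in base_maps]
        reference = class_proportions(np.concatenate([lb.ravel() for lb in base_labels]))

        levels = list(ladder.levels)
        for li, level in enumerate(levels):
            is_base = li == 0
            is_coarsest = li == len(levels) - 1
            if is_coarsest:
                for rec, cube in zip(batch, cropped):
                    spectrum = coarsest_level_spectrum(cube)
                    for pixel_type in config.pixel_types:
                        rows.append(_sample_row(rec, level, pixel_type, spectrum,
                                                cube.wavelengths,
                                                n_pixels=cube.shape[0] * cube.shape[1],
                                                config=config))
                continue
            if is_base:
                agg_cubes = cropped
                maps = base_maps
                thresholds = base_thr
            else:
                if level.factor > min(base.shape[0], base.shape[1]):
                    continue   # no complete block; level unusable at this scene size
                agg_cubes = [aggregate(c, level.factor) for c in cropped]
                maps = [pixel_index_maps(c) for c in agg_cubes]
                pooled = {k: np.concatenate([m[k].ravel() for m in maps])
                          for k in ("evi", "pri", "tcari")}
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    thresholds = adapt_thresholds(
                        pooled, reference, stage=batch[0]["stage"],
                        resolution_mm=level.realized_mm, tol=config.adapt_tol)
            for rec, cube, m in zip(batch, agg_cubes, maps):
                labels = _classify_from_maps(m, thresholds)
                for pixel_type in config.pixel_types:
                    spectrum, count = mean_spectrum_by_class(cube, labels, pixel_type)
                    rows.append(_sample_row(rec, level, pixel_type, spectrum,
                                            cube.wavelengths, n_pixels=count,
                                            config=config))

    for rec in records:
        key = (rec["year"], rec["date_index"])
        if key != current_key and current:
            flush(current)
            current = []
        current_key = key
        current.append(rec)
    flush(current)

    samples = pd.DataFrame(rows)
    return samples, ladder


def _sample_row(rec: dict, level, pixel_type: str, spectrum, wavelengths,
                n_pixels: int, config: SweepConfig) -> dict:
    row = {
        "year": rec["year"], "date_index": rec["date_index"], "stage": rec["stage"],
        "scope": _stage_scope(rec["stage"]),
        "plot_index": rec["plot_index"], "replicate": rec["replicate"],
        "cultivar": rec["cultivar"], "n_rate": rec["n_rate"], "density": rec["density"],
        "lnc": rec["lnc"], "resolution_mm": level.nominal_mm,
        "realized_mm": level.realized_mm, "pixel_type": pixel_type,
        "n_pixels": n_pixels,
    }
    if spectrum is None:
        row["spectrum"] = None
        for name in VI_NAMES:
            row[name] = np.nan
    else:
        row["spectrum"] = np.asarray(spectrum)
        for name in VI_NAMES:
            row[name] = compute_vi(name, spectrum, wavelengths)
    return row


# ---------------------------------------------------------------------------
# Profiles and models
# ---------------------------------------------------------------------------

def build_profile(samples: pd.DataFrame, config: SweepConfig,
                  wavelengths: np.ndarray | None = None) -> pd.DataFrame:
    """Assemble the sensitivity profile table from the sample table.

    VI rows carry Spearman rho^2 of LNC with each representative VI per stage
    scope (all samples of the scope pooled); PLSR/GPR rows carry validation
    R^2 and RMSE of global models fitted on calibration replicates.
    """
    out: list[dict] = []
    resolutions = sorted(samples["resolution_mm"].unique())

    if "vi" in config.methods:
        for scope in sorted(samples["scope"].unique()):
            for pixel_type in config.pixel_types:
                for vi in config.vi_names:
                    for res in resolutions:
                        sub = samples[(samples["scope"] == scope)
                                      & (samples["pixel_type"] == pixel_type)
                                      & (samples["resolution_mm"] == res)]
                        sub = sub.dropna(subset=[vi])
                        value = np.nan
                        if len(sub) >= 3 and sub[vi].nunique() > 1 and sub["lnc"].nunique() > 1:
                            value = spearman_rho2(sub[vi].to_numpy(), sub["lnc"].to_numpy())
                        out.append({"scope": scope, "pixel_type": pixel_type,
                                    "method": f"vi:{vi}", "resolution_mm": res,
                                    "metric": "rho2", "value": value, "n": len(sub)})

    for method in ("plsr", "gpr"):
        if method not in config.methods:
            continue
        for kind in config.spectra_kinds:
            for pixel_type in config.pixel_types:
                for res in resolutions:
                    sub = samples[(samples["pixel_type"] == pixel_type)
                                  & (samples["resolution_mm"] == res)]
                    sub = sub[[s is not None for s in sub["spectrum"]]]
                    if len(sub) < 10:
                        continue
                    X = np.vstack(sub["spectrum"].tolist())
                    if kind == "continuum_removed":
                        if wavelengths is None:
                            raise ValueError("continuum-removed profiles need the wavelength grid")
                        X = np.vstack([
                            continuum_removal(x, wavelengths, 550.0, 750.0)[0] for x in X
                        ])
                    y = sub["lnc"].to_numpy()
                    frame = sub[["replicate", "stage", "year"]].copy().reset_index(drop=True)
                    cal_mask = (frame["replicate"] != config.validation_replicate).to_numpy()
                    if cal_mask.sum() < 5 or (~cal_mask).sum() < 3:
                        continue
                    if method == "plsr":
                        model = PLSNitrogenRegressor(max_components=config.max_plsr_components)
                    else:
                        model = GPNitrogenRegressor(n_restarts=config.gpr_restarts)
                    model.fit(X[cal_mask], y[cal_mask])
                    m = evaluate(model, X[~cal_mask], y[~cal_mask])
                    out.append({"scope": "global", "pixel_type": pixel_type,
                                "method": f"{method}:{kind}", "resolution_mm": res,
                                "metric": "r2", "value": m.r2, "n": int(len(sub))})
                    out.append({"scope": "global", "pixel_type": pixel_type,
                                "method": f"{method}:{kind}", "resolution_mm": res,
                                "metric": "rmse", "value": m.rmse, "n": int(len(sub))})
    return pd.DataFrame(out)


def run_resolution_sweep(design: ExperimentDesign, seed: int = 0,
                         config: SweepConfig | None = None,
                         ladder=None) -> SweepResult:
    """Full sweep: render -> degrade -> adapt -> classify -> VIs -> models."""
    config = config or SweepConfig()
    samples, ladder = extract_samples(design, seed, config, ladder)
    from .synthetic import wavelength_grid
    wavelengths = wavelength_grid(config.scene_kwargs.get("wavelength_step_nm", 2.0))
    profile = build_profile(samples, config, wavelengths)
    return SweepResult(samples, profile, ladder, config)


def select_optimal_resolution(profile: pd.DataFrame, scope: str,
                              pixel_type: str = "all_leaf",
                              method: str | None = None,
                              delta: float = 0.03) -> OptimalResolutionReport:
    """Coarsest resolution whose metric is within ``delta`` of the best.

    Higher is better (rho^2 or R^2 profiles).  Missing cells are ignored; an
    all-missing profile raises.
    """
    sub = profile[(profile["scope"] == scope) & (profile["pixel_type"] == pixel_type)]
    if method is not None:
        sub = sub[sub["method"] == method]
    sub = sub[sub["metric"].isin(["rho2", "r2"])].dropna(subset=["value"])
    if sub.empty:
        raise ValueError(f"no usable profile cells for scope={scope!r}, "
                         f"pixel_type={pixel_type!r}, method={method!r}")
    if sub["resolution_mm"].nunique() < 2:
        raise ValueError("profile must cover at least 2 resolutions")
    # average over methods if several remain
    series = sub.groupby("resolution_mm")["value"].mean().sort_index()
    best = series.max()
    eligible = series[series >= best - delta]
    chosen = float(eligible.index.max())
    return OptimalResolutionReport(
        scope=scope, pixel_type=pixel_type, method=method or "mean",
        resolution_mm=chosen, delta=delta,
        metric_at_optimum=float(series.loc[chosen]),
        metric_at_base=float(series.iloc[0]),
    )
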