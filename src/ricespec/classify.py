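"""Pixel classification of rice canopy scenes and threshold adaptation.

Per-pixel EVI, PRI and TCARI drive a three-step decision tree:

1. EVI <= t_evi            -> background (water / soil / duckweed)
2. else PRI > t_pri        -> leaf, otherwise panicle
3. TCARI above the class-specific cut-off -> sunlit, otherwise shaded

Default cut-offs at the 1.3 mm base resolution are EVI 0.45, PRI -0.058 and
TCARI 0.172 (leaves) / 0.241 (panicles).  At degraded resolutions mixed pixels
shift the index distributions, so the cut-offs are re-solved by monotone
bisection in tree order to keep the class proportions (green fraction, leaf
share, sunlit shares) close to the base-resolution reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .cube import SpectralCube
from .indices import evi, nearest_band
from .synthetic import CLASS_CODES

__all__ = [
    "ThresholdSet",
    "GreenFractionRecord",
    "ClassProportions",
    "pixel_index_maps",
    "classify_pixels",
    "green_fraction",
    "class_proportions",
    "adapt_thresholds",
    "mean_spectrum_by_class",
    "coarsest_level_spectrum",
]

DEFAULT_THRESHOLDS = {
    "evi": 0.45,
    "pri": -0.058,
    "tcari_leaf": 0.172,
    "tcari_panicle": 0.241,
}


@dataclass(frozen=True)
class ThresholdSet:
    """EVI/PRI/TCARI cut-offs for one stage x resolution."""

    evi: float = DEFAULT_THRESHOLDS["evi"]
    pri: float = DEFAULT_THRESHOLDS["pri"]
    tcari_leaf: float = DEFAULT_THRESHOLDS["tcari_leaf"]
    tcari_panicle: float = DEFAULT_THRESHOLDS["tcari_panicle"]
    stage: str | None = None
    resolution_mm: float | None = None

    def __post_init__(self) -> None:
        for name in ("evi", "pri", "tcari_leaf", "tcari_panicle"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"threshold {name} must be finite")


@dataclass(frozen=True)
class GreenFractionRecord:
    gf: float
    stage: str | None = None
    resolution_mm: float | None = None
    is_reference: bool = False   # computed at base resolution

    def __post_init__(self) -> None:
        if not 0.0 <= self.gf <= 1.0:
            raise ValueError("green fraction must lie in [0, 1]")


@dataclass(frozen=True)
class ClassProportions:
    """Tree-ordered class shares used as the adaptation target."""

    gf: float                 # vegetation share of all pixels
    leaf_share: float         # leaf share among vegetation
    sunlit_leaf_share: float  # sunlit share among leaves
    sunlit_panicle_share: float  # sunlit share among panicles


def pixel_index_maps(cube: SpectralCube) -> dict[str, np.ndarray]:
    """Per-pixel EVI, PRI and TCARI maps (nearest-band reflectances)."""
    wl = cube.wavelengths

    def band(nm: float) -> np.ndarray:
        return cube.data[:, :, nearest_band(wl, nm)].astype(float)

    r470, r531, r550, r570 = band(470), band(531), band(550), band(570)
    r670, r700, r800 = band(670), band(700), band(800)
    with np.errstate(divide="ignore", invalid="ignore"):
        evi_map = evi(r800, r670, r470)
        pri_map = (r531 - r570) / (r531 + r570)
        tcari_map = 3.0 * ((r700 - r670) - 0.2 * (r700 - r550) * (r700 / r670))
    return {"evi": evi_map, "pri": pri_map, "tcari": tcari_map}


def _classify_from_maps(maps: dict[str, np.ndarray], t: ThresholdSet) -> np.ndarray:
    evi_map, pri_map, tcari_map = maps["evi"], maps["pri"], maps["tcari"]
    labels = np.zeros(evi_map.shape, dtype=np.int8)
    veg = evi_map > t.evi
    leaf = veg & (pri_map > t.pri)
    panicle = veg & ~leaf
    labels[leaf & (tcari_map > t.tcari_leaf)] = CLASS_CODES["sunlit_leaf"]
    labels[leaf & ~(tcari_map > t.tcari_leaf)] = CLASS_CODES["shaded_leaf"]
    labels[panicle & (tcari_map > t.tcari_panicle)] = CLASS_CODES["sunlit_panicle"]
    labels[panicle & ~(tcari_map > t.tcari_panicle)] = CLASS_CODES["shaded_panicle"]
    return labels


def classify_pixels(cube: SpectralCube, thresholds: ThresholdSet | None = None
                    ) -> np.ndarray:
    """Apply the decision tree; returns a class map using :data:`CLASS_CODES`."""
    t = thresholds or ThresholdSet()
    return _classify_from_maps(pixel_index_maps(cube), t)


def green_fraction(class_map: np.ndarray, stage: str | None = None,
                   resolution_mm: float | None = None,
                   is_reference: bool = False) -> GreenFractionRecord:
    """Share of non-background pixels."""
    gf = float(np.mean(class_map != CLASS_CODES["background"]))
    return GreenFractionRecord(gf, stage, resolution_mm, is_reference)


def class_proportions(class_map: np.ndarray) -> ClassProportions:
    """Tree-ordered shares of a class map (NaN-free; empty parents give 0)."""
    flat = np.asarray(class_map).ravel()
    n = flat.size
    veg = flat != CLASS_CODES["background"]
    n_veg = int(veg.sum())
    leaf = (flat == CLASS_CODES["sunlit_leaf"]) | (flat == CLASS_CODES["shaded_leaf"])
    n_leaf = int(leaf.sum())
    n_pan = n_veg - n_leaf
    n_sun_leaf = int((flat == CLASS_CODES["sunlit_leaf"]).sum())
    n_sun_pan = int((flat == CLASS_CODES["sunlit_panicle"]).sum())
    return ClassProportions(
        gf=n_veg / n,
        leaf_share=n_leaf / n_veg if n_veg else 0.0,
        sunlit_leaf_share=n_sun_leaf / n_leaf if n_leaf else 0.0,
        sunlit_panicle_share=n_sun_pan / n_pan if n_pan else 0.0,
    )


def _bisect_threshold(values: np.ndarray, target_upper_share: float,
                      start: float, tol: float, max_iter: int,
                      what: str) -> float:
    """Solve t so that mean(values > t) ~= target_upper_share.

    The share is non-increasing in t, which guarantees bisection validity.
    Returns the nearest-achievable threshold with a warning when the target
    share is unreachable (e.g. heavy ties or an empty bracket).
    """
    values = values[np.isfinite(values)]
    if values.size == 0:
        warnings.warn(f"{what}: no finite index values; keeping starting threshold")
        return start

    def share(t: float) -> float:
        return float(np.mean(values > t))

    if abs(share(start) - target_upper_share) <= tol:
        return start
    lo = float(values.min()) - 1e-9   # share(lo) = 1
    hi = float(values.max())          # share(hi) = 0
    if target_upper_share >= 1.0:
        return lo
    if target_upper_share <= 0.0:
        return hi
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        s = share(mid)
        if abs(s - target_upper_share) <= tol:
            return mid
        if s > target_upper_share:
            lo = mid
        else:
            hi = mid
    # tied index values can make the target share unreachable; return the
    # nearest-achievable side of the final bracket
    candidates = [lo, 0.5 * (lo + hi), hi]
    best = min(candidates, key=lambda t: abs(share(t) - target_upper_share))
    if abs(share(best) - target_upper_share) > tol:
        warnings.warn(
            f"{what}: target share {target_upper_share:.3f} unreachable to "
            f"tolerance {tol}; returning nearest-achievable threshold"
        )
    return best


def adapt_thresholds(maps_or_cube, reference: ClassProportions,
                     stage: str | None = None,
                     resolution_mm: float | None = None,
                     tol: float = 0.005, max_iter: int = 60) -> ThresholdSet:
    """Re-solve the cut-offs at a degraded resolution.

    Three monotone 1-D bisections run in tree order: the EVI cut-off matches
    the reference green fraction; the PRI cut-off then matches the leaf share
    among vegetation; the two TCARI cut-offs finally match the sunlit shares
    among leaves and panicles.  ``maps_or_cube`` may be a cube or a dict of
    precomputed index maps (pooled over plots of one stage).
    """
    maps = maps_or_cube if isinstance(maps_or_cube, dict) else pixel_index_maps(maps_or_cube)
    start = ThresholdSet(stage=stage, resolution_mm=resolution_mm)

    t_evi = _bisect_threshold(maps["evi"].ravel(), reference.gf,
                              start.evi, tol, max_iter, "EVI threshold")
    veg = maps["evi"] > t_evi
    t_pri = _bisect_threshold(maps["pri"][veg].ravel(), reference.leaf_share,
                              start.pri, tol, max_iter, "PRI threshold")
    leaf = veg & (maps["pri"] > t_pri)
    panicle = veg & ~leaf
    t_tcari_leaf = _bisect_threshold(
        maps["tcari"][leaf].ravel(), reference.sunlit_leaf_share,
        start.tcari_leaf, tol, max_iter, "leaf TCARI threshold")
    t_tcari_pan = _bisect_threshold(
        maps["tcari"][panicle].ravel(), reference.sunlit_panicle_share,
        start.tcari_panicle, tol, max_iter, "panicle TCARI threshold")
    return replace(start, evi=t_evi, pri=t_pri,
                   tcari_leaf=t_tcari_leaf, tcari_panicle=t_tcari_pan)


# ---------------------------------------------------------------------------
# Class-mean spectra
# ---------------------------------------------------------------------------

PIXEL_TYPES = ("all_leaf", "sunlit_leaf", "shaded_leaf", "whole_image")


def mean_spectrum_by_class(cube: SpectralCube, class_map: np.ndarray,
                           pixel_type: str) -> tuple[np.ndarray | None, int]:
    """Per-band mean over the selected pixel type; returns (spectrum, count).

    ``all_leaf`` is the union of sunlit and shaded leaves; ``whole_image``
    averages every pixel.  Zero matching pixels yield ``(None, 0)`` rather
    than a spectrum of zeros.
    """
    if pixel_type not in PIXEL_TYPES:
        raise ValueError(f"pixel type must be one of {PIXEL_TYPES}, got {pixel_type!r}")
    flat = np.asarray(class_map).ravel()
    data = cube.data.reshape(-1, cube.n_bands)
    if pixel_type == "whole_image":
        mask = np.ones(flat.size, dtype=bool)
    elif pixel_type == "all_leaf":
        mask = (flat == CLASS_CODES["sunlit_leaf"]) | (flat == CLASS_CODES["shaded_leaf"])
    else:
        mask = flat == CLASS_CODES[pixel_type]
    count = int(mask.sum())
    if count == 0:
        return None, 0
    return data[mask].mean(axis=0), count


def coarsest_level_spectrum(base_cube: SpectralCube) -> np.ndarray:
    """Whole-image mean spectrum of the base-resolution cropped cube.

    At the coarsest ladder entry (the full 450 mm swath collapses to a single
    pixel) no leaf/background separation is possible, so all three leaf pixel
    types are assigned this whole-image average.
    """
    return base_cube.data.reshape(-1, base_cube.n_bands).mean(axis=0)
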