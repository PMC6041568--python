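"""Published nitrogen-related vegetation indices and continuum removal.

The registry holds the 16 indices commonly used for crop nitrogen assessment:
simple ratios (SR variants, CI_Red-edge), normalized differences (NDVI, GNDVI,
ND705, mND705, mSR705, MTCI, PRI) and combined indices (TCARI, OSAVI,
TCARI/OSAVI, DCNI).  Each definition names its nominal wavelengths; actual
reflectances are taken from the nearest available band (within 10 nm).

EVI is kept alongside the registry (it drives vegetation/background
separation, not nitrogen estimation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "VIDefinition",
    "VI_REGISTRY",
    "VI_NAMES",
    "nearest_band",
    "compute_vi",
    "evi",
    "continuum_removal",
    "registry_table",
]

MAX_BAND_DISTANCE_NM = 10.0


def nearest_band(wavelengths: np.ndarray, target_nm: float,
                 max_distance_nm: float = MAX_BAND_DISTANCE_NM) -> int:
    """Index of the band closest to ``target_nm``; ties go to the lower band.

    Raises ``ValueError`` when the nearest band is farther than
    ``max_distance_nm`` from the target.
    """
    wavelengths = np.asarray(wavelengths, dtype=float)
    if wavelengths.size == 0:
        raise ValueError("empty wavelength axis")
    dist = np.abs(wavelengths - target_nm)
    idx = int(np.argmin(dist))  # argmin returns the first (lower-wavelength) tie
    if dist[idx] > max_distance_nm:
        raise ValueError(
            f"no band within {max_distance_nm} nm of {target_nm} nm "
            f"(nearest is {wavelengths[idx]:.1f} nm)"
        )
    return idx


@dataclass(frozen=True)
class VIDefinition:
    """A vegetation index: name, nominal wavelengths (nm) and its formula.

    ``func`` receives reflectances in the order of ``bands_nm``.
    """

    name: str
    bands_nm: tuple[float, ...]
    expression: str
    func: Callable[..., float]
    group: str


def _tcari(r700, r670, r550):
    return 3.0 * ((r700 - r670) - 0.2 * (r700 - r550) * (r700 / r670))


def _osavi(r800, r670):
    return (1 + 0.16) * (r800 - r670) / (r800 + r670 + 0.16)


_DEFS = [
    # --- simple ratio indices ---
    VIDefinition("SR[800,675]", (800, 675), "R800/R675",
                 lambda a, b: a / b, "ratio"),
    VIDefinition("SR[810,560]", (810, 560), "R810/R560",
                 lambda a, b: a / b, "ratio"),
    VIDefinition("SR[750,550]", (750, 550), "R750/R550",
                 lambda a, b: a / b, "ratio"),
    VIDefinition("SR[750,710]", (750, 710), "R750/R710",
                 lambda a, b: a / b, "ratio"),
    VIDefinition("CI_Red-edge", (800, 720), "R800/R720 - 1",
                 lambda a, b: a / b - 1.0, "ratio"),
    # --- normalized difference indices ---
    VIDefinition("NDVI", (800, 670), "(R800-R670)/(R800+R670)",
                 lambda a, b: (a - b) / (a + b), "normalized"),
    VIDefinition("GNDVI", (750, 550), "(R750-R550)/(R750+R550)",
                 lambda a, b: (a - b) / (a + b), "normalized"),
    VIDefinition("ND705", (750, 705), "(R750-R705)/(R750+R705)",
                 lambda a, b: (a - b) / (a + b), "normalized"),
    VIDefinition("mND705", (750, 705, 445), "(R750-R705)/(R750+R705-2*R445)",
                 lambda a, b, c: (a - b) / (a + b - 2 * c), "normalized"),
    VIDefinition("mSR705", (750, 445, 705), "(R750-R445)/(R705-R445)",
                 lambda a, b, c: (a - b) / (c - b), "normalized"),
    VIDefinition("MTCI", (750, 710, 680), "(R750-R710)/(R710-R680)",
                 lambda a, b, c: (a - b) / (b - c), "normalized"),
    VIDefinition("PRI", (531, 570), "(R531-R570)/(R531+R570)",
                 lambda a, b: (a - b) / (a + b), "normalized"),
    # --- combined vegetation indices ---
    VIDefinition("TCARI", (700, 670, 550),
                 "3*[(R700-R670)-0.2*(R700-R550)*(R700/R670)]",
                 _tcari, "combined"),
    VIDefinition("OSAVI", (800, 670), "(1+0.16)*(R800-R670)/(R800+R670+0.16)",
                 _osavi, "combined"),
    VIDefinition("TCARI/OSAVI", (700, 670, 550, 800), "TCARI/OSAVI",
                 lambda r700, r670, r550, r800:
                     _tcari(r700, r670, r550) / _osavi(r800, r670), "combined"),
    # two nested left-to-right divisions, as printed in the source literature
    VIDefinition("DCNI", (720, 700, 670),
                 "(R720-R700)/(R700-R670)/(R720-R670+0.03)",
                 lambda a, b, c: (a - b) / (b - c) / (a - c + 0.03), "combined"),
]

VI_REGISTRY: dict[str, VIDefinition] = {d.name: d for d in _DEFS}
VI_NAMES: tuple[str, ...] = tuple(VI_REGISTRY)
assert len(VI_REGISTRY) == 16


def compute_vi(name: str, spectrum: np.ndarray, wavelengths: np.ndarray) -> float:
    """Evaluate a registered index on one spectrum using nearest-band lookup.

    Returns NaN (flagged via ``warnings`` semantics left to the caller) when a
    denominator vanishes; raises ``KeyError`` for unknown names.
    """
    try:
        definition = VI_REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown vegetation index {name!r}; known: {sorted(VI_REGISTRY)}")
    spectrum = np.asarray(spectrum, dtype=float)
    refl = [spectrum[nearest_band(wavelengths, wl)] for wl in definition.bands_nm]
    with np.errstate(divide="ignore", invalid="ignore"):
        value = definition.func(*refl)
    if not math.isfinite(value):
        return float("nan")
    return float(value)


def evi(r800: np.ndarray, r670: np.ndarray, r470: np.ndarray) -> np.ndarray:
    """Enhanced vegetation index, three-band form.

    EVI = 2.5 (R_NIR - R_red) / (R_NIR + 6 R_red - 7.5 R_blue + 1)
    """
    return 2.5 * (r800 - r670) / (r800 + 6.0 * r670 - 7.5 * r470 + 1.0)


def registry_table():
    """Machine-readable registry (list of dicts: name, bands, expression)."""
    return [
        {"name": d.name, "bands_nm": list(d.bands_nm), "expression": d.expression,
         "group": d.group}
        for d in _DEFS
    ]


# ---------------------------------------------------------------------------
# Continuum removal
# ---------------------------------------------------------------------------

def _upper_hull(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Indices of the upper convex hull of the polyline (x, y), left to right."""
    hull: list[int] = []
    for i in range(len(x)):
        while len(hull) >= 2:
            i1, i2 = hull[-2], hull[-1]
            # pop i2 if it lies below the chord i1 -> i
            cross = (x[i2] - x[i1]) * (y[i] - y[i1]) - (x[i] - x[i1]) * (y[i2] - y[i1])
            if cross >= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    return np.asarray(hull)


def continuum_removal(spectrum: np.ndarray, wavelengths: np.ndarray,
                      lo_nm: float = 550.0, hi_nm: float = 750.0
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Divide a spectrum by its upper convex hull over [lo_nm, hi_nm].

    Returns ``(values, window_wavelengths)``; values lie in (0, 1] with the
    window endpoints exactly 1 (they are hull vertices by construction).
    """
    wavelengths = np.asarray(wavelengths, dtype=float)
    spectrum = np.asarray(spectrum, dtype=float)
    keep = (wavelengths >= lo_nm) & (wavelengths <= hi_nm)
    x, y = wavelengths[keep], spectrum[keep]
    if x.size < 3:
        raise ValueError(f"need at least 3 bands in [{lo_nm}, {hi_nm}] nm, found {x.size}")
    if np.any(y <= 0):
        raise ValueError("continuum removal requires strictly positive reflectance in the window")
    hull_idx = _upper_hull(x, y)
    hull_y = np.interp(x, x[hull_idx], y[hull_idx])
    values = y / hull_y
    # hull vertices divide to exactly 1; clamp fp residue elsewhere
    values = np.minimum(values, 1.0)
    values[hull_idx] = 1.0
    return values, x
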