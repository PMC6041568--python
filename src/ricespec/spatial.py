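"""Spatial degradation: middle-half crop, resolution ladder, block aggregation.

The sensitivity analysis degrades ~1.3 mm base-resolution imagery to a dyadic
ladder of nominal resolutions obtained by halving the 450 mm swath repeatedly
(450, 225, 113, ... mm).  Each nominal entry maps to an integer N x N
aggregation factor; both the nominal label and the realized resolution
(base x N) are kept, since the printed labels are not exact multiples of the
base pixel size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cube import SpectralCube

__all__ = ["ResolutionLadder", "crop_middle_half", "build_resolution_ladder", "aggregate"]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class LadderLevel:
    nominal_mm: float       # the label (e.g. 28)
    factor: int             # N x N aggregation factor
    realized_mm: float      # base_mm * factor


@dataclass(frozen=True)
class ResolutionLadder:
    base_mm: float
    swath_mm: float
    levels: tuple[LadderLevel, ...]

    @property
    def nominal(self) -> list[float]:
        return [lv.nominal_mm for lv in self.levels]

    @property
    def factors(self) -> list[int]:
        return [lv.factor for lv in self.levels]

    def __len__(self) -> int:
        return len(self.levels)

    def __iter__(self):
        return iter(self.levels)


def build_resolution_ladder(base_mm: float, swath_mm: float) -> ResolutionLadder:
    """Dyadic resolution ladder from base pixel size to the full swath.

    Entries are ``swath / 2^k`` rounded to the nearest mm (half up, floor of
    2 mm), descending k, stopping once the rounded value falls below
    1.5 x base; the exact base resolution is prepended.  Aggregation factors
    are ``round(nominal / base)``.
    """
    if not base_mm < swath_mm:
        raise ValueError("base resolution must be finer than the swath")
    entries: list[float] = []
    k = 0
    while True:
        raw = swath_mm / 2 ** k
        rounded = _round_half_up(raw)
        if rounded < 1.5 * base_mm:
            break
        entries.append(float(max(2, rounded)))
        k += 1
    entries = sorted(set(entries))
    levels = [LadderLevel(base_mm, 1, base_mm)]
    for nominal in entries:
        n = max(1, _round_half_up(nominal / base_mm))
        levels.append(LadderLevel(nominal, n, base_mm * n))
    return ResolutionLadder(base_mm, swath_mm, tuple(levels))


def crop_middle_half(cube: SpectralCube) -> SpectralCube:
    """Keep the central 50% of columns (rows and bands untouched).

    The crop avoids the strong view-angle (BRDF) effects near the swath edges
    of a wide-FOV pushbroom sensor.  Odd widths floor the kept width, centered.
    """
    cols = cube.shape[1]
    if cols < 2:
        raise ValueError("cube must have at least 2 columns to crop")
    keep = cols // 2
    start = (cols - keep) // 2
    data = cube.data[:, start:start + keep, :]
    return SpectralCube(data, cube.wavelengths, cube.pixel_size_mm, dict(cube.meta))


def aggregate(cube: SpectralCube, n: int) -> SpectralCube:
    """Average non-overlapping n x n pixel blocks per band.

    Trailing rows/columns that do not fill a block are dropped (padding would
    bias edge-block spectra toward replicated pixels).  Pixel size is
    multiplied by n; ``n == 1`` is the identity.
    """
    if n < 1:
        raise ValueError("aggregation factor must be >= 1")
    if n == 1:
        return cube
    rows, cols, bands = cube.shape
    out_r, out_c = rows // n, cols // n
    if out_r == 0 and out_c == 0:
        raise ValueError(f"aggregation factor {n} exceeds both image dimensions {rows}x{cols}")
    if out_r == 0 or out_c == 0:
        raise ValueError(f"aggregation factor {n} leaves no complete {n}x{n} block in a {rows}x{cols} image")
    trimmed = cube.data[: out_r * n, : out_c * n, :]
    blocks = trimmed.reshape(out_r, n, out_c, n, bands)
    data = blocks.mean(axis=(1, 3))
    return SpectralCube(data, cube.wavelengths, cube.pixel_size_mm * n, dict(cube.meta))
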