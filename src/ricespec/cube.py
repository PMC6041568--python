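"""Hyperspectral cube container, ENVI-style I/O and radiometric preprocessing.

The in-memory container is :class:`SpectralCube`, a (rows, cols, bands)
reflectance array with a strictly increasing wavelength axis in nanometres and
a pixel size in millimetres.  On disk, cubes use the classic ENVI layout: an
ASCII ``.hdr`` sidecar declaring dimensions, interleave, data type and the
wavelength list, next to a flat binary file.

Radiometric preprocessing covers the empirical-line reflectance calibration
from raw sensor counts (dark current + white reference panel), spectral
subsetting to the 400-900 nm window where pushbroom VNIR sensors are
well-behaved, and minimum-noise-fraction (MNF) denoising.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "SpectralCube",
    "CalibrationFrames",
    "read_cube",
    "write_cube",
    "calibrate_reflectance",
    "subset_spectral",
    "mnf_denoise",
]


@dataclass
class SpectralCube:
    """Reflectance cube with a wavelength axis.

    Parameters
    ----------
    data : ndarray, shape (rows, cols, bands)
        Unitless reflectance (or raw counts for DN cubes).
    wavelengths : ndarray, shape (bands,)
        Band-centre wavelengths in nm, strictly increasing.
    pixel_size_mm : float
        Ground sampling distance of one pixel, in mm.
    meta : dict
        Free-form plot metadata (plot id, stage, year, date, ...).
    """

    data: np.ndarray
    wavelengths: np.ndarray
    pixel_size_mm: float = 1.3
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"cube data must be 3-D (rows, cols, bands), got shape {self.data.shape}")
        if self.data.shape[2] != self.wavelengths.size:
            raise ValueError(
                f"band count mismatch: data has {self.data.shape[2]} bands, "
                f"wavelength axis has {self.wavelengths.size}"
            )
        if self.wavelengths.size > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise ValueError("cube must have at least one row and one column")
        if self.pixel_size_mm <= 0:
            raise ValueError("pixel size must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def with_data(self, data: np.ndarray, **meta_updates) -> "SpectralCube":
        """Copy of this cube with new pixel data (same wavelength axis)."""
        cube = replace(self, data=data, meta={**self.meta, **meta_updates})
        return cube


@dataclass
class CalibrationFrames:
    """Raw frames needed for empirical-line reflectance calibration.

    ``dn_target`` holds sensor counts per pixel per band; ``dn_dark`` is the
    dark-current level per band (pushbroom sensors accumulate dark current per
    detector column, which maps to a per-band vector after co-registration);
    ``dn_panel`` is the white-reference-panel count per band and ``ref_panel``
    the known panel reflectance (e.g. 0.99 for a BaSO4 panel).
    """

    dn_target: np.ndarray          # (rows, cols, bands)
    dn_dark: np.ndarray            # (bands,)
    dn_panel: np.ndarray           # (bands,)
    ref_panel: float | np.ndarray  # scalar or (bands,)
    wavelengths: np.ndarray | None = None
    pixel_size_mm: float = 1.3
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dn_target = np.asarray(self.dn_target, dtype=float)
        self.dn_dark = np.asarray(self.dn_dark, dtype=float)
        self.dn_panel = np.asarray(self.dn_panel, dtype=float)
        ref = np.asarray(self.ref_panel, dtype=float)
        if np.any(ref <= 0) or np.any(ref > 1):
            raise ValueError("panel reflectance must lie in (0, 1]")


# ---------------------------------------------------------------------------
# ENVI-style I/O
# ---------------------------------------------------------------------------

_DTYPE_CODES = {4: np.float32, 5: np.float64, 12: np.uint16, 2: np.int16, 1: np.uint8}
_CODE_FOR_DTYPE = {np.dtype(v): k for k, v in _DTYPE_CODES.items()}


def _header_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".hdr") if path.suffix != ".hdr" else path


def _parse_envi_header(text: str) -> dict:
    """Parse 'key = value' ENVI header fields, including {...} lists."""
    fields: dict[str, str] = {}
    # join brace-delimited multi-line values first
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def write_cube(cube: SpectralCube, path: str | Path, interleave: str = "bil",
               dtype: str | np.dtype = "float32") -> None:
    """Write *cube* as an ENVI-style header + flat binary pair.

    ``path`` names the binary file; the header goes to ``path + '.hdr'``.
    """
    path = Path(path)
    interleave = interleave.lower()
    if interleave not in ("bil", "bsq", "bip"):
        raise ValueError(f"unsupported interleave {interleave!r}")
    dtype = np.dtype(dtype)
    if dtype not in _CODE_FOR_DTYPE:
        raise ValueError(f"unsupported dtype {dtype}")
    rows, cols, bands = cube.shape
    arr = cube.data.astype(dtype)
    if interleave == "bip":          # (lines, samples, bands)
        out = arr
    elif interleave == "bil":        # (lines, bands, samples)
        out = np.transpose(arr, (0, 2, 1))
    else:                            # bsq: (bands, lines, samples)
        out = np.transpose(arr, (2, 0, 1))
    out = np.ascontiguousarray(out)
    out.tofile(path)
    wl = ", ".join(f"{w:.17g}" for w in cube.wavelengths)
    header = (
        "ENVI\n"
        "file type = ENVI Standard\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        f"data type = {_CODE_FOR_DTYPE[dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"pixel size mm = {cube.pixel_size_mm}\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    for key, value in cube.meta.items():
        header += f"; meta {key} = {value}\n"
    _header_path(path).write_text(header)


def read_cube(path: str | Path) -> SpectralCube:
    """Read an ENVI-style cube written by :func:`write_cube` (or compatible)."""
    path = Path(path)
    hdr_path = _header_path(path)
    if not hdr_path.exists():
        raise FileNotFoundError(f"missing ENVI header {hdr_path}")
    text = hdr_path.read_text()
    fields = _parse_envi_header(text)
    for required in ("samples", "lines", "bands", "interleave", "data type"):
        if required not in fields:
            raise ValueError(f"ENVI header missing required field {required!r}")
    cols = int(fields["samples"])
    rows = int(fields["lines"])
    bands = int(fields["bands"])
    interleave = fields["interleave"].lower()
    code = int(fields["data type"])
    if code not in _DTYPE_CODES:
        raise ValueError(f"unsupported ENVI data type code {code}")
    dtype = np.dtype(_DTYPE_CODES[code])
    if "wavelength" not in fields:
        raise ValueError("ENVI header missing required field 'wavelength'")
    wl_text = fields["wavelength"].strip()
    if not (wl_text.startswith("{") and wl_text.endswith("}")):
        raise ValueError("malformed 'wavelength' field: expected brace-delimited list")
    wavelengths = np.array([float(tok) for tok in wl_text[1:-1].split(",") if tok.strip()])
    if wavelengths.size != bands:
        raise ValueError(
            f"'wavelength' list has {wavelengths.size} entries but 'bands' declares {bands}"
        )
    expected = rows * cols * bands * dtype.itemsize
    actual = path.stat().st_size
    if actual != expected:
        raise ValueError(
            f"binary size mismatch for field 'bands'/'lines'/'samples': header implies "
            f"{expected} bytes, file has {actual}"
        )
    raw = np.fromfile(path, dtype=dtype)
    if interleave == "bip":
        data = raw.reshape(rows, cols, bands)
    elif interleave == "bil":
        data = np.transpose(raw.reshape(rows, bands, cols), (0, 2, 1))
    elif interleave == "bsq":
        data = np.transpose(raw.reshape(bands, rows, cols), (1, 2, 0))
    else:
        raise ValueError(f"unsupported interleave {interleave!r} in field 'interleave'")
    pixel_size = float(fields.get("pixel size mm", 1.0))
    meta = {}
    for line in text.splitlines():
        m = re.match(r";\s*meta\s+(\S+)\s*=\s*(.*)", line)
        if m:
            meta[m.group(1)] = m.group(2)
    return SpectralCube(np.ascontiguousarray(data), wavelengths, pixel_size, meta)


# ---------------------------------------------------------------------------
# Radiometric calibration
# ---------------------------------------------------------------------------

def calibrate_reflectance(frames: CalibrationFrames) -> SpectralCube:
    """Empirical-line calibration of raw counts to relative reflectance.

    Per pixel and band::

        Ref_target = (DN_target - DN_dark) / (DN_panel - DN_dark) * Ref_panel

    Raises
    ------
    ZeroDivisionError
        If the panel count equals the dark level at any band (reported with
        the offending band index).
    """
    denom = frames.dn_panel - frames.dn_dark
    bad = np.nonzero(denom == 0)[0]
    if bad.size:
        raise ZeroDivisionError(
            f"panel counts equal dark current at band index {bad[0]} "
            f"(and {bad.size - 1} more)" if bad.size > 1 else
            f"panel counts equal dark current at band index {bad[0]}"
        )
    ref = (frames.dn_target - frames.dn_dark) / denom * np.asarray(frames.ref_panel, dtype=float)
    bands = frames.dn_target.shape[2]
    wl = frames.wavelengths if frames.wavelengths is not None else np.arange(bands, dtype=float)
    return SpectralCube(ref, wl, frames.pixel_size_mm, dict(frames.meta))


def subset_spectral(cube: SpectralCube, lo_nm: float, hi_nm: float) -> SpectralCube:
    """Retain bands with ``lo_nm <= wavelength <= hi_nm`` (order preserved)."""
    keep = (cube.wavelengths >= lo_nm) & (cube.wavelengths <= hi_nm)
    if not keep.any():
        raise ValueError(
            f"spectral subset [{lo_nm}, {hi_nm}] nm does not overlap the wavelength "
            f"axis [{cube.wavelengths[0]}, {cube.wavelengths[-1]}] nm"
        )
    return SpectralCube(cube.data[:, :, keep], cube.wavelengths[keep],
                        cube.pixel_size_mm, dict(cube.meta))


# ---------------------------------------------------------------------------
# MNF denoising
# ---------------------------------------------------------------------------

def _mnf_noise_covariance(data: np.ndarray) -> np.ndarray:
    """Noise covariance from single-pixel horizontal shift differences.

    Differencing neighbouring samples within a scan line cancels the (spatially
    smooth) signal and leaves ~2x the noise covariance, consistent with a
    pushbroom acquisition geometry.
    """
    diffs = data[:, 1:, :] - data[:, :-1, :]
    flat = diffs.reshape(-1, data.shape[2])
    return np.cov(flat, rowvar=False, bias=False) / 2.0


def mnf_denoise(cube: SpectralCube, k_components: int | None = None,
                snr_threshold: float = 2.0) -> SpectralCube:
    """Minimum-noise-fraction denoising.

    The noise covariance is estimated from horizontal single-pixel shift
    differences, the data are noise-whitened, principal components of the
    whitened data are computed, the top ``k_components`` retained and the
    transform inverted.  When ``k_components`` is None, components with an
    SNR eigenvalue above ``snr_threshold`` are kept.

    Output shape always equals the input shape.
    """
    rows, cols, bands = cube.shape
    if rows < 2 or cols < 2:
        raise ValueError("MNF requires at least a 2x2 image")
    if k_components is not None:
        if not 1 <= k_components <= bands:
            raise ValueError(f"k_components must be in [1, {bands}]")
        if k_components == bands:
            return cube.with_data(cube.data.copy())

    X = cube.data.reshape(-1, bands).astype(float)
    mean = X.mean(axis=0)
    Xc = X - mean

    Sigma_n = _mnf_noise_covariance(cube.data.astype(float))
    # guard: regularize a (near-)singular noise covariance
    eps = 1e-12 * max(np.trace(Sigma_n) / bands, 1e-30)
    evals_n, evecs_n = np.linalg.eigh(Sigma_n)
    if evals_n.min() <= eps:
        warnings.warn("singular noise covariance in MNF; applying ridge regularization")
        floor = max(eps, 1e-10 * max(evals_n.max(), 1.0))
        evals_n = np.maximum(evals_n, floor)
    # whitening matrix W = U diag(1/sqrt(l)) U^T
    W = evecs_n @ np.diag(1.0 / np.sqrt(evals_n)) @ evecs_n.T

    Z = Xc @ W
    Sigma_z = np.cov(Z, rowvar=False, bias=False)
    evals_z, evecs_z = np.linalg.eigh(Sigma_z)
    order = np.argsort(evals_z)[::-1]
    evals_z, evecs_z = evals_z[order], evecs_z[:, order]

    if k_components is None:
        k_components = max(1, int(np.sum(evals_z > snr_threshold)))

    V = evecs_z[:, :k_components]
    # project onto top-k MNF components and invert the whitening
    W_inv = evecs_n @ np.diag(np.sqrt(evals_n)) @ evecs_n.T
    denoised = (Z @ V) @ V.T @ W_inv + mean
    return cube.with_data(denoised.reshape(rows, cols, bands))
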